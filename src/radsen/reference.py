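"""Reference parameter values for the chronic HUVEC irradiation design.

These constants describe the study design this package models: human
umbilical vein endothelial cells grown under continuous Cs-137 gamma
exposure at 0 (sham), 1.4, 2.4 and 4.1 mGy/h, passaged weekly with three
biological replicates, scored for population growth ratio and for the
percentage of SA-beta-gal positive (senescent) cells until proliferation
arrest.  The fitted logistic parameters per dose rate (carrying capacity
K in ratio units, growth rate r per week; senescence rate p per week with
its reported SD) serve as generating values for the synthetic-data module
and as ground truth in parameter-recovery checks.  A replicative-
senescence series from non-irradiated SBL5 primary fibroblasts (an
external long-horizon dataset spanning roughly 60 weeks) is included to
exercise the senescence model far from the irradiated regime.

Per-condition sampling grids are reconstructed from the reported fit
degrees of freedom and the weekly passaging schedule: growth series have
dof + 3 weekly points, senescence series dof + 2 points drawn from the
staining schedule {1, 3, 6, 10, 12, 15} truncated at growth arrest.
"""

from __future__ import annotations

from .exposure import ExposureCondition
from .kinetics import GrowthParams, SenescenceParams

__all__ = [
    "DOSE_RATES",
    "GROWTH_RATES",
    "GROWTH_RATE_SD",
    "CARRYING_CAPACITY",
    "SENESCENCE_RATES",
    "SENESCENCE_RATE_SD",
    "SENESCENCE_S0",
    "GROWTH_WEEKS",
    "SENESCENCE_WEEKS",
    "FIBROBLAST_P",
    "FIBROBLAST_P_SD",
    "FIBROBLAST_WEEKS",
    "growth_params",
    "senescence_params",
    "ISODOSE_CONDITIONS",
    "FIG_OVERLAP_2GY",
    "FIG_OVERLAP_4GY",
]

#: Dose rates of the four exposure arms, mGy/h (0 = sham control).
DOSE_RATES = (0.0, 1.4, 2.4, 4.1)

#: Fitted logistic growth rate r per week, by dose rate.
GROWTH_RATES = {0.0: 1.450, 1.4: 1.164, 2.4: 1.052, 4.1: 0.960}
GROWTH_RATE_SD = {0.0: 0.022, 1.4: 0.015, 2.4: 0.041, 4.1: 0.043}

#: Fitted carrying capacity K (ratio units N/N0), by dose rate.
CARRYING_CAPACITY = {0.0: 1.89e6, 1.4: 7.02e4, 2.4: 3.03e3, 4.1: 3.70e2}

#: Fitted senescence rate p per week, by dose rate.
SENESCENCE_RATES = {0.0: 0.184, 1.4: 0.215, 2.4: 0.252, 4.1: 0.532}
SENESCENCE_RATE_SD = {0.0: 0.027, 1.4: 0.017, 2.4: 0.037, 4.1: 0.102}

#: Baseline senescent fraction S(0) in percent used to pin the shape B
#: (B = 100/S0 - 1).  B is not identifiable from the published rates
#: alone; ~1% spontaneous staining is typical of early-passage HUVEC
#: cultures, rising to ~2% for the arms that senesce fastest.
SENESCENCE_S0 = {0.0: 1.0, 1.4: 1.0, 2.4: 2.0, 4.1: 2.0}

#: Weekly growth sampling grids per dose rate (reconstructed from fit dof:
#: 14/14/11/7 residual dof with 3 free parameters).
GROWTH_WEEKS = {
    0.0: tuple(range(1, 18)),   # 17 points
    1.4: tuple(range(1, 18)),   # 17 points
    2.4: tuple(range(1, 15)),   # 14 points
    4.1: tuple(range(1, 11)),   # 10 points
}

#: Senescence staining grids per dose rate (dof 4/4/3/1 with 2 free params),
#: truncated where each arm stopped growing.
SENESCENCE_WEEKS = {
    0.0: (1, 3, 6, 10, 12, 15),
    1.4: (1, 3, 6, 10, 12, 15),
    2.4: (1, 3, 6, 10, 12),
    4.1: (1, 3, 6),
}

#: External replicative-senescence reference (SBL5 fibroblasts, unirradiated):
#: rate per week, its SD, and 8 sampling points spanning ~60 weeks (dof 6).
FIBROBLAST_P = 0.160
FIBROBLAST_P_SD = 0.018
FIBROBLAST_WEEKS = tuple(round(5 + k * 55 / 7, 2) for k in range(8))
FIBROBLAST_S0 = 1.0


def growth_params(dose_rate: float) -> GrowthParams:
    """Generating growth parameters for one arm, with A = K - 1 so the
    curve starts exactly at ratio 1."""
    return GrowthParams.from_carrying_capacity(
        K=CARRYING_CAPACITY[dose_rate], r=GROWTH_RATES[dose_rate]
    )


def senescence_params(dose_rate: float) -> SenescenceParams:
    """Generating senescence parameters for one arm (B pinned by S(0))."""
    return SenescenceParams.from_initial_percent(
        s0=SENESCENCE_S0[dose_rate], p=SENESCENCE_RATES[dose_rate]
    )


#: The four proteomics time points that form the two isodose comparisons
#: (~2 Gy delivered at 1.4 vs 4.1 mGy/h; ~4 Gy at 2.4 vs 4.1 mGy/h).
ISODOSE_CONDITIONS = (
    ExposureCondition("1.4mGyh_10wk", 1.4, 10),   # 2.35 Gy
    ExposureCondition("4.1mGyh_3wk", 4.1, 3),     # 2.07 Gy
    ExposureCondition("2.4mGyh_10wk", 2.4, 10),   # 4.03 Gy
    ExposureCondition("4.1mGyh_6wk", 4.1, 6),     # 4.13 Gy
)

#: Observed overlap structure of the ~2 Gy isodose proteome comparison:
#: 130 vs 61 deregulated proteins, 9 shared, split 2 up / 3 down / 4 contra.
FIG_OVERLAP_2GY = {
    "n_a": 130, "n_b": 61,
    "up_both": ("ACTN1", "CAPN2"),
    "down_both": ("IDH2", "PPIB", "PDIA4"),
    "contra": ("AHNAK", "ITGB1", "MCAM", "PRCP"),
}

#: Observed overlap structure of the ~4 Gy comparison: 270 vs 54 proteins,
#: 14 shared, split 7 up / 4 down / 3 contra.
FIG_OVERLAP_4GY = {
    "n_a": 270, "n_b": 54,
    "up_both": ("ACTN1", "CD44", "HSP90AA1", "PLBD2", "RAB7A", "TPR", "VCL"),
    "down_both": ("HIST1H1E", "PPIB", "PDIA4", "SERPINH1"),
    "contra": ("RCN1", "RNH1", "TAGLN2"),
}
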