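"""Synthetic study-shaped data: replicate time series and deregulation lists.

The generator emulates the chronic-irradiation study design end to end so
that every pipeline stage can be exercised without the deposited raw
data: per-condition logistic growth and senescence trajectories observed
as replicate means with SEMs (three biological replicates by default,
multiplicative Gaussian noise with a fixed coefficient of variation), and
paired deregulation lists plus gene-set collections with fully controlled
shared / unique / contra-regulated structure.

Randomness is keyed by a single study seed fanned out into independent
per-condition, per-endpoint streams (via hashed child seeds), so adding a
condition to a design leaves the draws of the existing conditions
untouched.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import reference as ref
from .exposure import ExposureCondition
from .kinetics import (
    GrowthParams,
    SenescenceParams,
    TimeSeries,
    logistic_growth,
    logistic_senescence,
)
from .omics import DeregEntry, DeregulationList, GeneSet

__all__ = [
    "ConditionSpec",
    "StudyDesign",
    "OmicsScenario",
    "generate_timeseries",
    "generate_omics",
    "default_study_design",
    "isodose_overlap_scenario",
]

#: Default replicate noise: coefficient of variation of a single replicate
#: measurement around the model curve.  Error bars in growth/senescence
#: time courses of this kind scale with the mean; 5% is a realistic
#: between-replicate spread for counted cultures.
DEFAULT_NOISE_CV = 0.05


@dataclass(frozen=True)
class ConditionSpec:
    """One arm of a study design with its generating kinetics."""

    condition: ExposureCondition
    growth: GrowthParams | None = None
    senescence: SenescenceParams | None = None
    growth_weeks: tuple[float, ...] = ()
    senescence_weeks: tuple[float, ...] = ()


@dataclass(frozen=True)
class StudyDesign:
    """A full synthetic study: arms, replication and noise level."""

    conditions: tuple[ConditionSpec, ...]
    n_replicates: int = 3
    noise_cv: float = DEFAULT_NOISE_CV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for spec in self.conditions:
            for grid in (spec.growth_weeks, spec.senescence_weeks):
                if grid and not all(0 < t <= 60 for t in grid):
                    raise ValueError(
                        f"{spec.condition.label}: sampling weeks must lie in (0, 60]"
                    )


def _stream(seed: int, label: str, endpoint: str) -> np.random.Generator:
    """Independent generator for one (condition, endpoint) pair."""
    key = zlib.crc32(f"{label}/{endpoint}".encode())
    return np.random.default_rng(np.random.SeedSequence((seed, key)))


def _observe(model_vals: np.ndarray, rng: np.random.Generator,
             n_rep: int, cv: float, lower: float, upper: float | None):
    """Replicate draws model*(1+eps), eps ~ N(0, cv), truncated to bounds."""
    if cv == 0:  # degenerate noise: means equal the model exactly, SEM = 0
        return model_vals.copy(), np.zeros_like(model_vals)
    reps = model_vals[None, :] * (1.0 + cv * rng.standard_normal((n_rep, len(model_vals))))
    reps = np.clip(reps, lower, upper)
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if n_rep > 1 else np.zeros_like(mean)
    return mean, sd / np.sqrt(n_rep)


def generate_timeseries(design: StudyDesign) -> list[TimeSeries]:
    """Replicate-summarised growth and senescence series for every arm.

    Each observation is the mean of ``n_replicates`` draws
    ``model(t) * (1 + eps)`` with ``eps ~ N(0, noise_cv)``, truncated so
    growth ratios stay positive and senescence percentages stay within
    [0, 100]; the SEM is sd/sqrt(n).  With ``noise_cv = 0`` the means equal
    the closed-form model exactly and every SEM is zero.  Output is
    deterministic for a fixed design seed.
    """
    out: list[TimeSeries] = []
    for spec in design.conditions:
        label = spec.condition.label
        if spec.growth is not None and spec.growth_weeks:
            t = np.asarray(spec.growth_weeks, dtype=float)
            model = logistic_growth(t, spec.growth)
            rng = _stream(design.seed, label, "growth")
            mean, sem = _observe(model, rng, design.n_replicates,
                                 design.noise_cv, 1e-9, None)
            out.append(TimeSeries(label, "growth_ratio", t, mean, sem,
                                  np.full_like(t, design.n_replicates)))
        if spec.senescence is not None and spec.senescence_weeks:
            t = np.asarray(spec.senescence_weeks, dtype=float)
            model = logistic_senescence(t, spec.senescence)
            rng = _stream(design.seed, label, "senescence")
            mean, sem = _observe(model, rng, design.n_replicates,
                                 design.noise_cv, 0.0, 100.0)
            out.append(TimeSeries(label, "senescence_percent", t, mean, sem,
                                  np.full_like(t, design.n_replicates)))
    return out


def default_study_design(noise_cv: float = DEFAULT_NOISE_CV,
                         seed: int = 0,
                         include_fibroblast: bool = True) -> StudyDesign:
    """The four-arm chronic-irradiation design with its reference kinetics.

    Arms at 0 (sham), 1.4, 2.4 and 4.1 mGy/h with the published fitted
    growth/senescence parameters as generating truth and the
    reconstructed per-arm sampling grids; optionally the external
    fibroblast replicative-senescence series (senescence endpoint only,
    8 points over ~60 weeks).
    """
    specs = []
    for dr in ref.DOSE_RATES:
        duration = max(ref.GROWTH_WEEKS[dr])
        specs.append(ConditionSpec(
            condition=ExposureCondition(f"{dr:g}mGyh", dr, duration),
            growth=ref.growth_params(dr),
            senescence=ref.senescence_params(dr),
            growth_weeks=tuple(float(w) for w in ref.GROWTH_WEEKS[dr]),
            senescence_weeks=tuple(float(w) for w in ref.SENESCENCE_WEEKS[dr]),
        ))
    if include_fibroblast:
        specs.append(ConditionSpec(
            condition=ExposureCondition("fibroblast_SBL5", 0.0, 60),
            senescence=SenescenceParams.from_initial_percent(
                ref.FIBROBLAST_S0, ref.FIBROBLAST_P),
            senescence_weeks=ref.FIBROBLAST_WEEKS,
        ))
    return StudyDesign(tuple(specs), n_replicates=3, noise_cv=noise_cv, seed=seed)


# ---------------------------------------------------------------------------
# deregulation lists and gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OmicsScenario:
    """Controlled overlap structure for a pair of deregulation lists.

    ``n_shared`` identifiers appear in both lists, split into the three
    signed categories; the remainders are unique to each list.  A gene-set
    collection of ``n_pathways`` sets is drawn from a universe of
    ``universe_size`` identifiers, with the first ``n_enriched`` sets
    deliberately over-sampling list a's identifiers so that enrichment is
    detectable by construction.
    """

    n_a: int
    n_b: int
    n_shared: int
    n_up_both: int
    n_down_both: int
    n_contra: int
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 60)
    n_enriched: int = 5
    universe_size: int = 2000
    shared_symbols: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up_both + self.n_down_both + self.n_contra != self.n_shared:
            raise ValueError("signed shared categories must sum to n_shared")
        if self.n_shared > min(self.n_a, self.n_b):
            raise ValueError("n_shared exceeds a list size")
        if self.universe_size < self.n_a + self.n_b - self.n_shared:
            raise ValueError("universe too small for the requested lists")
        if self.shared_symbols and len(self.shared_symbols) != self.n_shared:
            raise ValueError("shared_symbols must have length n_shared")
        if not 0 <= self.n_enriched <= self.n_pathways:
            raise ValueError("n_enriched must be within [0, n_pathways]")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi <= self.universe_size:
            raise ValueError("invalid pathway_size_range")


def generate_omics(scenario: OmicsScenario
                   ) -> tuple[DeregulationList, DeregulationList,
                              list[GeneSet], frozenset[str]]:
    """Two deregulation lists, a gene-set collection and the universe.

    Identifiers are synthetic symbols SYN0001... unless ``shared_symbols``
    supplies real names for the shared block.  Directions follow the
    prescribed signed categories for shared identifiers (contra: up in a,
    down in b) and alternate for unique ones.  Deterministic per seed.
    """
    sc = scenario
    rng = np.random.default_rng(np.random.SeedSequence((sc.seed, 0x0A11)))
    width = max(4, len(str(sc.universe_size)))
    universe = [f"SYN{i + 1:0{width}d}" for i in range(sc.universe_size)]

    shared = list(sc.shared_symbols) if sc.shared_symbols else universe[: sc.n_shared]
    if sc.shared_symbols:
        # splice the real symbols into the universe in place of synthetic ones
        universe[: sc.n_shared] = shared
    pool = universe[sc.n_shared:]
    n_uniq_a = sc.n_a - sc.n_shared
    n_uniq_b = sc.n_b - sc.n_shared
    uniq_a = pool[:n_uniq_a]
    uniq_b = pool[n_uniq_a: n_uniq_a + n_uniq_b]

    def entry(ident: str, direction: int) -> DeregEntry:
        mag = direction * float(rng.uniform(0.3, 3.0))
        return DeregEntry(ident, direction, round(mag, 3))

    entries_a, entries_b = [], []
    for i, ident in enumerate(shared):
        if i < sc.n_up_both:
            da = db = +1
        elif i < sc.n_up_both + sc.n_down_both:
            da = db = -1
        else:  # contra-regulated: up in a, down in b
            da, db = +1, -1
        entries_a.append(entry(ident, da))
        entries_b.append(entry(ident, db))
    entries_a += [entry(ident, 1 if k % 2 == 0 else -1)
                  for k, ident in enumerate(uniq_a)]
    entries_b += [entry(ident, 1 if k % 2 == 0 else -1)
                  for k, ident in enumerate(uniq_b)]

    list_a = DeregulationList("condition_a", "merged", tuple(entries_a))
    list_b = DeregulationList("condition_b", "merged", tuple(entries_b))

    ids_a = [e.identifier for e in entries_a]
    sets: list[GeneSet] = []
    lo, hi = sc.pathway_size_range
    for j in range(sc.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if j < sc.n_enriched and ids_a:
            # enriched sets draw about half their members from list a
            n_from_a = min(max(size // 2, 1), len(ids_a))
            members = list(rng.choice(ids_a, size=n_from_a, replace=False))
            rest = rng.choice(sc.universe_size, size=size, replace=False)
            members += [universe[i] for i in rest][: size - n_from_a]
        else:
            idx = rng.choice(sc.universe_size, size=size, replace=False)
            members = [universe[i] for i in idx]
        sets.append(GeneSet(f"PATHWAY_{j + 1:03d}", frozenset(members)))

    return list_a, list_b, sets, frozenset(universe)


def isodose_overlap_scenario(comparison: str, seed: int = 0,
                             **overrides) -> OmicsScenario:
    """Scenario reproducing one of the study's isodose proteome overlaps.

    ``comparison`` is ``"2Gy"`` (1.4 mGy/h x 10 wk vs 4.1 mGy/h x 3 wk:
    130 vs 61 proteins, 9 shared as 2 up / 3 down / 4 contra) or ``"4Gy"``
    (2.4 mGy/h x 10 wk vs 4.1 mGy/h x 6 wk: 270 vs 54 proteins, 14 shared
    as 7 up / 4 down / 3 contra), with the observed shared symbols spliced
    in.
    """
    fig = {"2Gy": ref.FIG_OVERLAP_2GY, "4Gy": ref.FIG_OVERLAP_4GY}.get(comparison)
    if fig is None:
        raise ValueError(f"comparison must be '2Gy' or '4Gy', got {comparison!r}")
    symbols = tuple(fig["up_both"]) + tuple(fig["down_both"]) + tuple(fig["contra"])
    kwargs = dict(
        n_a=fig["n_a"], n_b=fig["n_b"], n_shared=len(symbols),
        n_up_both=len(fig["up_both"]), n_down_both=len(fig["down_both"]),
        n_contra=len(fig["contra"]), shared_symbols=symbols, seed=seed,
    )
    kwargs.update(overrides)
    return OmicsScenario(**kwargs)
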