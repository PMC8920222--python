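# radsen

Kinetics of proliferation arrest and premature senescence in chronically
irradiated endothelial cells — logistic growth/senescence fitting,
cumulative-dose bookkeeping, dose-rate trends, and signed multi-omics
overlap with gene-set over-representation.

Primary endothelial cultures (HUVECs) kept under continuous low-dose-rate
gamma exposure (0–4.1 mGy/h for weeks) grow more slowly and senesce
faster than controls.  `radsen` is for analysts who want to quantify that
dose-rate dependence from replicate time-series data: the population
ratio N(t)/N0 and the percentage S(t) of SA-β-gal-stained cells are each
fitted with a logistic law,

    N(t)/N0 = K / (1 + A e^{−rt})        S(t) = 100 / (1 + B e^{−pt})

by SEM-weighted nonlinear least squares (Levenberg–Marquardt on log
parameters), yielding rates r and p per week with uncertainties.  The
fitted rates are then regressed on dose rate (weighted linear vs
linear-quadratic, extra-sum-of-squares F test), exposure arms are paired
by near-equal cumulative dose (dose rate × 168 h/wk × weeks), and the
deregulation lists of an isodose pair are compared as up/down/contra
signed overlaps with one-sided Fisher enrichment + Benjamini–Hochberg
FDR against user-supplied GMT gene sets.  A synthetic-data module
generates study-shaped inputs (replicate noise, controlled overlap
structure) so the whole pipeline is testable without any downloads.

## Worked example

```python
import radsen as rs
from radsen import reference as ref

# noise-free synthetic series from the built-in four-arm study design
design = rs.default_study_design(noise_cv=0.0, seed=0)
series = {(s.condition, s.endpoint): s for s in rs.generate_timeseries(design)}

fit = rs.fit_growth(series[("4.1mGyh", "growth_ratio")])
print(f"r = {fit.params.r:.3f}/wk  K = {fit.params.K:.0f}  dof = {fit.dof}")
# r = 0.960/wk  K = 370  dof = 7

sen = rs.fit_senescence(series[("4.1mGyh", "senescence_percent")])
print(f"p = {sen.params.p:.3f}/wk")
# p = 0.532/wk

print(f"growth-rate reduction vs sham: "
      f"{rs.percent_change(1.450, fit.params.r):.1f}%")
# growth-rate reduction vs sham: 33.8%

# isodose pairing of the four proteomics time points
pairs = rs.pair_isodose(list(ref.ISODOSE_CONDITIONS))
for p in pairs:
    print(p.condition_a.label, p.condition_b.label,
          f"{p.dose_a:.2f} vs {p.dose_b:.2f} Gy")
# 4.1mGyh_3wk 1.4mGyh_10wk 2.07 vs 2.35 Gy
# 2.4mGyh_10wk 4.1mGyh_6wk 4.03 vs 4.13 Gy

# signed overlap of the ~2 Gy comparison (130 vs 61 deregulated proteins)
a, b, sets, universe = rs.generate_omics(rs.isodose_overlap_scenario("2Gy"))
ov = rs.classify_overlap(a, b)
print(ov.n_up_both, ov.n_down_both, ov.n_contra, ov.n_unique_a, ov.n_unique_b)
# 2 3 4 121 52
```

The recovered r = 0.960/wk is the growth rate of the 4.1 mGy/h arm — a
33.8% reduction against the sham rate 1.450/wk — and p = 0.532/wk is
that arm's senescence rate, the fastest of the four.  The 2 Gy isodose
comparison shares 9 proteins, 2 concordantly up, 3 concordantly down and
4 contra-regulated.

A `radsen` console script wraps the same stages
(`radsen simulate | fit | trends | doses | omics | fixtures | run`);
`radsen run --outdir out --seed 0` executes the full pipeline and writes
TSV reports plus a reproducibility manifest.

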