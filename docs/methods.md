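# Methods

## The system being modelled

Primary endothelial cultures (HUVECs) passaged weekly under continuous
low-dose-rate gamma exposure stop proliferating after a number of weeks
and accumulate senescent cells, faster at higher dose rates.  The package
models two replicate-summarised endpoints per exposure arm:

* the **population growth ratio** N(t)/N0 (counted over seeded cells,
  cumulated across passages), and
* the **percentage S(t) of SA-β-gal positive cells**, a histochemical
  senescence marker.

Four arms are built in as the reference design: 0 (sham), 1.4, 2.4 and
4.1 mGy/h, with three biological replicates per time point, plus an
external long-horizon replicative-senescence series from unirradiated
SBL5 fibroblasts used to exercise the senescence model over ~60 weeks.

## Kinetic model

Both endpoints follow logistic kinetics, justified by the fixed monolayer
area and finite nutrients of a flask culture:

    dN/dt = r N (1 − N/K)        ⇔        N(t)/N0 = K / (1 + A e^{−rt})

with carrying capacity `K` (ratio units), shape `A` and growth rate `r`
per week.  In ratio units the natural convention is `A = K − 1`, which
makes N(0)/N0 = 1 exactly.  Because reported carrying capacities only
make dimensional sense in ratio units, the generator always uses
`A = K − 1`; the fitter nevertheless fits (K, A, r) independently by
default, with `constrain_shape=True` available to tie `A = K − 1`.  The
unconstrained default mirrors how such fits are conventionally run and
costs one degree of freedom.

Senescence uses the same law with the asymptote pinned at 100% (every
cell eventually stains), leaving shape `B` and rate `p` free:

    S(t) = 100 / (1 + B e^{−pt})

The population-doubling transform `PD = log2(N/N0)` is provided for
reporting.

## Fitting

Weighted nonlinear least squares: minimise Σ wᵢ (yᵢ − f(tᵢ))² with
wᵢ = 1/SEMᵢ² when every SEM is positive, unweighted otherwise.
Implementation choices:

* **Positivity** — parameters are fitted on the log scale
  (Levenberg–Marquardt via `scipy.optimize.least_squares`), so K, A, r,
  B, p can never go negative on noisy data.  Reported SDs are mapped
  back to natural scale by the delta method (sd(θ) = θ·sd(log θ)).
* **SD convention** — the parameter covariance is (JᵀJ)⁻¹ scaled by the
  reduced chi-square, the convention of classic LM fit routines (verified
  numerically identical to `scipy.optimize.curve_fit` with
  `absolute_sigma=False`).  With zero residual dof the scale is set to 0.
* **Initial guesses** (when no `init` is given) are deterministic and
  scale-aware: K = 1.5·max(y), r or p = 4/(t-range) (a logistic rises
  over ~4 time constants), A or B by inverting the model through the
  first data point.
* **Convergence** — relative RSS change and step tolerance 1e−10,
  gradient tolerance 1e−8, iteration budget 500.  Non-convergence is a
  flagged `FitResult`, not an exception.
* **Degenerate inputs** — a flat series (no growth signal) or a
  senescence series saturated at 100% is flagged non-converged without
  attempting the fit.
* Fits are invariant to uniform rescaling of all SEMs (the weights cancel
  in the argmin, and the reduced-chi-square scaling cancels in the SDs).

`predict_with_band` propagates the natural-scale covariance to a
pointwise first-order SD band via numerically differenced gradients.

### Calibration of the reported SDs

A Monte-Carlo experiment the acceptance suite runs (CV = 5%
multiplicative noise, n = 3 replicates, 200 seeds, all nine reference
rates) shows that "±3 reported SDs" covers the generating rate in only
~90% of fits, not the ~99.7% a Gaussian reading would suggest.  Two real
effects cause this: (i) standardised residuals (y − f)/SEM with SEM
*estimated* from three replicates are t₂-distributed — heavy-tailed with
infinite variance — which makes inverse-SEM² weights occasionally huge
and the scaled covariance anti-conservative; and (ii) for the arms with
only 1–2 residual dof the pivot is t-distributed with that dof, and
P(|t₁| < 3) ≈ 0.80.  This is a property of the (x, y, y-SD)-weighted
procedure itself at n = 3, not of this implementation (whose SDs are
bit-identical to `curve_fit`'s); users comparing a parameter against
±k·SD bands at such replication levels should treat them as descriptive,
not as calibrated confidence intervals.

## Exposure bookkeeping

Cumulative dose = dose rate × 168 h/week × weeks / 1000 (Gy); a week is
exactly 168 hours.  The reporting helper rounds half-away-from-zero to
2 decimals below 3 Gy and 1 decimal above, reproducing the mixed
precision of the tabulated doses (0.24, 0.71, 1.41, 2.35 … vs 4.0, 4.1,
6.9).  Isodose pairing admits condition pairs whose unrounded doses
differ by a relative gap ≤ 0.15 (default): the two built-in comparisons
(2.35 vs 2.07 Gy, gap 0.121; 4.03 vs 4.13 Gy, gap 0.024) pass, while
cross-dose pairs (≥ 0.42) are rejected.

## Dose-rate trends

Fitted rates vs dose rate are summarised by weighted least squares
(weights 1/SD², solved in closed form by the normal equations) at degree
1 or 2.  The rate SDs are treated as known — coefficient SDs are the
unscaled (XᵀWX)⁻¹ diagonal — because they come from the upstream kinetic
fits, not from the trend residuals (two-stage estimation).  Linear vs
linear-quadratic is decided by the extra-sum-of-squares F test (α = 0.05
by default); with four dose rates this is a 1-vs-1-dof test, which stays
defined where information criteria become degenerate.  With the built-in
rate tables, the growth-rate slope is negative and the senescence-rate
slope positive (a ≈34% growth-rate reduction at 4.1 mGy/h vs sham); no
ground-truth preference between linear and quadratic is asserted.

## Signed omics overlap and enrichment

Deregulation lists carry (identifier, direction ±1, optional log-ratio);
matching is case-insensitive exact symbol matching, with no alias or
ortholog resolution.  Direction derives from the log-ratio's sign when no
explicit direction is given; an explicit direction wins over a
contradictory sign, with a warning.  Merging the transcript and protein
layers of one condition takes the union; an identifier whose layers
disagree in sign is kept once, flagged as conflicting, with the direction
of the larger |log-ratio| (transcript's call when magnitudes are
missing).  Overlap between two conditions partitions the shared
identifiers into up-in-both / down-in-both / contra-regulated; the three
counts always sum to the shared-set size, and the contra count is
symmetric in the input order.

Over-representation is one-sided (enrichment only): for a universe of M
identifiers, a gene set with n members in the universe and a query of N
identifiers with k hits, p = P(X ≥ k) from the hypergeometric tail
(`scipy.stats.hypergeom`), with Benjamini–Hochberg step-up FDR across
all tested sets (`statsmodels`).  The universe must be supplied
explicitly — typically all quantified identifiers — because enrichment
p-values are meaningless without a stated background.  No linker-gene /
network augmentation is performed: published pathway tables produced by
network-augmented tools (which insert connector genes before testing) are
therefore structural references only, not numerical targets for this
stage.

## Synthetic data generator

The generator emulates the study design, not the instruments:

* **Time series** — replicate values model(t)·(1 + ε), ε ~ N(0, CV),
  truncated to the physical ranges (ratios > 0, percentages in [0, 100]);
  reported mean, SEM = sd/√n, n.  Default CV = 5% and n = 3: error bars
  in this kind of counted-culture data scale with the mean, and 5% is a
  realistic between-replicate spread.  Sampling grids per arm are
  reconstructed from the published fit dof and the weekly passaging
  schedule (growth: 17/17/14/10 weekly points; senescence:
  {1,3,6,10,12,15} truncated per arm to 6/6/5/3 points; fibroblasts: 8
  points over weeks 5–60).  The shape B of each senescence arm is pinned
  by a baseline S(0) — 1% spontaneous staining for the sham-like arms and
  the fibroblasts, 2% for the two fastest-senescing arms — because B is
  not identifiable from the published rates alone.
* **Deregulation lists** — synthetic symbols (SYN0001…) partitioned into
  a shared block with prescribed up/down/contra counts and unique blocks,
  with the option to splice in the real shared symbols of the two
  isodose comparisons; gene sets drawn from the universe, the first
  `n_enriched` of them over-sampling list a's identifiers (~half their
  members) so enrichment is detectable by construction.
* **Seeding** — one study seed fans out to per-(condition, endpoint)
  streams keyed by a label hash, so extending a design never perturbs
  existing draws.

What the generator does **not** emulate: raw microarray/MS intensities,
missing values, batch effects, replicate-correlated noise, or real
pathway topology.  Passing recovery tests therefore demonstrates the
estimation machinery is correct under the stated noise model, not that
real cultures obey it.

## Problem sizes

The default verification workloads are deliberately small: noise-free
recovery uses the per-arm grids above; the Monte-Carlo coverage study
uses 200 seeds × 9 fits; the enrichment oracle sweep enumerates every
(set size, query size, hit count) composition for universes up to 25
identifiers; the null-enrichment FDR check uses 100 seeds × 30 pathways.
All of these were chosen as the smallest sizes at which the respective
statistical statements are meaningful.

## Known limitations

* Growth and senescence are fitted independently per arm; no joint or
  hierarchical model links arms or endpoints.
* Dose rate enters the trend stage as an error-free covariate.
* The logistic law underfits arms with transient growth suppression
  (cultures that slow down and later catch up with controls).
* Alternative growth laws (Gompertz, Richards) are out of scope; the
  fitter interface is the extension point.
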