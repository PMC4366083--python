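# Methods

## The question

Applied researchers routinely factor-analyse Likert items — five-category
ordered responses ("strongly disagree" … "strongly agree") — even though the
factor model assumes interval-level measurement. `likertfa` quantifies the
resulting risk of *over-dimensionalisation*: concluding that more than one
latent factor underlies a set of items that is, by construction, strictly
unidimensional. The whole package is a Monte-Carlo experiment: simulate
unidimensional ordinal data under controlled conditions, analyse each dataset
the ways practitioners do, and tabulate how often each procedure reports more
than one dimension.

## Response model

Respondents hold positions θ on a single latent continuum (roughly 0–100).
Four population distributions are studied, chosen to span realistic shapes
and variances:

| family       | parameters                              | note |
|--------------|-----------------------------------------|------|
| normal       | N(50, 20)                               | the conventional assumption |
| skew-normal  | Azzalini ξ=15, ω=25, α=5                | smallest variance, skewness ≈ 0.85 |
| bimodal      | ½·N(25,10) + ½·N(75,10)                 | Bernoulli(½) component per respondent |
| uniform      | U(0, 100)                               | largest variance |

Each of the 27 pool items is four ascending category boundaries on the
continuum; the deterministic **true score** of a respondent is
1 + #{boundaries ≤ θ} (category k+1 includes its lower boundary — the
convention is measure-zero for continuous θ but fixed for tests). Manifest
responses add a **discretised ordinal error**: per respondent × item a draw
z ~ N(0,1) shifts the true category by 0/1/2/3 steps according to which
cutoff interval |z| falls in, in direction sign(z), truncated to 1..5.
Cutoffs (1, 2, 3) give the *large* error level (≈31.7% of responses
perturbed before truncation), (1.2, 2.2, 3) the *small* one (≈23.0%). The
error acts only on responses; the latent sample is untouched.

The design grid crosses 4 distributions × {5, 8, 10} items × 2 error levels,
n = 2000 respondents per dataset, items drawn uniformly without replacement
from the pool, with a fresh latent sample per dataset. The full design has
100 replicates per cell (2400 datasets). Per-condition seeds derive
deterministically from one master seed; rerunning a grid reproduces every
response matrix bitwise.

## Correlations

The **Pearson branch** correlates the integer codes directly. The
**polychoric branch** uses the standard two-step estimator: thresholds
τ_k = Φ⁻¹(cumulative marginal proportion) with empty categories collapsed,
then ρ̂ maximising the bivariate-normal rectangle-probability likelihood
Σ n_ij log π_ij(ρ; τ) by bounded scalar search on (−0.999, 0.999)
(tolerance 1e-6, cell probabilities floored at 1e-12, no continuity
correction). Rectangle probabilities come from an in-package Gauss–Legendre
implementation of the Drezner–Wesolowsky/Genz bivariate normal CDF
(≈1e-15 accuracy, verified against direct quadrature). Pairwise estimates
are assembled without smoothing; a degenerate or non-convergent pair, or a
non-positive-definite assembly, marks the whole polychoric branch of that
dataset missing — failures are excluded, not repaired, and risk percentages
use the post-exclusion denominators.

## Dimensionality verdicts

Eigenvalue rules operate on the unreduced correlation matrix:

* **K1**: count of eigenvalues strictly > 1 (threshold configurable; 0.7 and
  1.40 variants are exposed but unused).
* **Parallel analysis**: leading observed eigenvalues exceeding the 95th
  centile of eigenvalues from 100 random n×p standard-normal datasets
  (Pearson eigenvalues as the reference for both branches; an
  ordinal-reference option exists but is not the default), stopping at the
  first failure.
* **Acceleration factor**: elbow at the largest second difference
  e_{i+1} − 2e_i + e_{i−1}; retained = elbow − 1, floored at 1.

Model-fit rules: minres EFA (uniquenesses minimising squared off-diagonal
residuals via L-BFGS-B, loadings from the reduced-matrix eigendecomposition,
SMC start, ψ ∈ [1e-4, 1]) for k = 1 and 2, with ML discrepancy
F = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p evaluated at the minres solution and
Bartlett-corrected χ² = (n − 1 − (2p+5)/6 − 2k/3)·F. The 1-factor model is
rejected by the Δχ² test (Δdf = df₁ − df₂, α = 1e-5, Δ clamped at 0) or by
RMSEA = √(max(χ²−df,0)/(df(n−1))) > 0.10. The 1-factor ML CFA fixes the
latent variance at 1, optimises p loadings and p uniquenesses with analytic
gradients (ψ ≥ 1e-4; binding bound ⇒ Heywood flag, case retained), and is
rejected by χ² = (n−1)·F at α = .001, AGFI < 0.90
(GFI = 1 − tr[(Σ⁻¹S−I)²]/tr[(Σ⁻¹S)²], AGFI = 1 − [p(p+1)/(2df)](1−GFI)),
or RMSEA > 0.10. The (n−1)·F convention is immaterial against (n)·F at
n = 2000. Evaluating the ML discrepancy at the minres solution (rather than
refitting by ML) matches the behaviour of the common EFA stacks; an ML refit
changes the 5-item 1-factor mean χ² by roughly −30 of ~510 and neither
changes any verdict pattern.

Over-dimensionalisation = retained factors ≥ 2 (retention rules) or
rejection of the 1-factor model (fit rules). Risk tables pool the two error
levels (their effect is marginal; the harvest keeps them separate for the
regressions) and report cell percentages by distribution × item count.

## Driver regressions

Per dataset: the spread of item locations = IQR (linear-interpolation
quantiles; with only 5–10 medians the quantile rule matters and is fixed
here) of the items' interpolated medians
IM = m − 0.5 + (n/2 − F_{m−1})/f_m; the skew disparity = range of the items'
moment skewnesses g1 = m₃/m₂^{3/2} (no small-sample correction; n = 2000).
Ten OLS models (statsmodels, conventional standard errors) regress the fit
statistics — cube-rooted where χ²-distributed, which demonstrably tames the
heteroskedasticity — on these two predictors plus the error dummy and
distribution/item-count dummies (references: normal, 5 items), listwise per
model. Because R² is composition-dependent, the regressions are fitted on
an item-count-balanced design (scaled harvests replicate 5-item cells more
heavily, which depresses the polychoric RMSEA/AGFI R²s by a few
hundredths). `predict_fit` applies the fitted coefficients to a hypothetical item
set and cubes back for the χ² models; it reproduces the *procedure* of
predicting the fit one should expect for truly unidimensional data.

## Problem sizes and reproducibility

The analysis scripts, the test suite and `scripts/acceptance.py` run the
replication at 100 datasets per 5-item cell (the full per-cell count) and 25
per 8-/10-item cell — 1200 datasets — which this package treats as its
standard scaled replication; `analysis/02_run_grid.py --full` runs the
complete 2400-dataset design. Replication checks use Monte-Carlo bands:
3 binomial standard errors (floor 3 percentage points) for cell
percentages, max(5% relative, 3 SE) for grid averages. All randomness
funnels through per-condition seeds spawned from one master seed; parallel
analysis sub-seeds from the dataset seed, shared between branches of the
same dataset.

## What the simulator does and does not emulate

It emulates: categorisation of a continuous latent trait through
heterogeneous item boundaries, ordinal symmetric response error with
decreasing probabilities of larger deviations, realistic marginal response
shapes (skewed populations pile mass into extreme categories), and
item-sampling variability in location spread and skew. It does **not**
emulate correlated errors across items, respondent styles (acquiescence,
extreme responding), multidimensional traits, missing data, or other
category counts than five. Passing replication checks therefore shows that
the analysis machinery reproduces the documented behaviour of factor
analysis on *this* class of unidimensional ordinal data — not that any
particular real survey is unidimensional.

## Known limitations and deliberate choices

* Mixture weights (½/½) and Bernoulli component membership for the bimodal
  population are the package's own choice where only the two components are
  documented.
* The polychoric estimator is two-step, not joint ML; at n = 2000 the
  difference is far inside the Monte-Carlo bands used anywhere downstream.
* K1 uses strict ">" at the threshold; ties have probability zero here.
* The parallel-analysis reference is continuous-normal/Pearson for both
  branches; matched-marginal ordinal references are available as an option
  but change polychoric-branch retention only slightly and are untested
  against published cell values.
* The worked fit prediction for an 8-item/spread-2/skew-range-2.5 scenario
  under a normal population (low error) lands near 0.30 RMSEA from the
  fitted coefficients of models C/D — far beyond the 0.10 rejection rule
  for data that are unidimensional by construction. The prediction is a
  linear combination of estimated coefficients; the procedure, not any
  particular third decimal, is the contract here.
* No model respecification beyond the 1- vs 2-factor EFA comparison is
  attempted; adapted CFA models would be invalid given the known true
  structure.
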