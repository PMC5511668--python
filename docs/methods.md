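# Methods

## Data model and evaluability filter

The unit of observation is a nucleus with integer HER2 and CEP17 signal
counts, an optional position in µm (per-case Cartesian frame, arbitrary
origin — only distances are used) and an optional segmentation-QC label.
Three sources are distinguished: `CD` (observer-corrected automated counts,
treated as ground truth), `AD` (raw automated counts over all detected
nuclei) and `MP` (conventional manual counts of 40–60 selected nuclei,
usually without coordinates). Counts must be integers; fractional values
are rejected rather than rounded so that provenance stays explicit.

Before any statistic, nuclei with insufficient signals are excluded. The
default `FilterRule(2, 2)` keeps nuclei with at least two signals of each
probe — the strict reading of excluding nuclei "without signals or with
only one signal"; the looser reading (at least one of each) is
`FilterRule(1, 1)`. Two consequences of this filter matter for
interpretation and are visible throughout the synthetic experiments:

* conditioning a near-Poisson channel with mean ≈ 2 on "≥ 2 observed"
  raises its mean by roughly +0.9, so post-filter means sit well above the
  population means;
* disomic cells fail the HER2 ≥ 2 cut far more often than amplified cells,
  so the filter *enriches* amplified cells: a planted 15% subclone is
  roughly 23% of the filtered set. Tests of planted-fraction recovery
  therefore compare against the subclone share of the filtered set, not
  the raw mixture weight.

## Guideline encoding

Dual-probe amplification uses the 2013 dual-probe rules: positive iff
ratio ≥ 2.0 or mean HER2 ≥ 6.0; equivocal iff ratio < 2.0 and
4.0 ≤ mean HER2 < 6.0; negative otherwise. The per-tumor ratio is the
ratio of sums (Σ HER2 / Σ CEP17 over filtered cells), algebraically equal
to the quotient of the two means. Polysomy is mean CEP17 ≥ 3 (inclusive).
GH bounds are strict (5% < amplified-cell % < 50%), and the per-cell
comparisons are strict (> 2.2 for the ratio, > 6 for HER2-only). A
separate, inclusive-lower-bound band (5 ≤ % < 25 by default) marks
"potentially heterogeneous" automated data. All cut-offs live in
`GuidelineThresholds` and are configurable.

## Mixture fit and bimodality indicators

A two-component univariate Gaussian mixture with unequal variances is
fitted by EM to each per-cell variable (HER2, CEP17, ratio on filtered
cells; the filter guarantees CEP17 ≥ 2 so the ratio is defined).
Numerical choices:

* deterministic initialization: component means at the 25th/75th sample
  percentiles, equal weights, pooled variance. When those percentiles
  coincide (common on integer counts) the 10th/90th are used, then
  mean ± sd/2 — a fixed tie-break chain so results reproduce exactly.
  Optional multi-start (seeded, still deterministic) via
  `FitSettings(n_starts=...)`.
* convergence when the log-likelihood changes by < 1e-6, capped at 500
  iterations; component variances floored at 1e-3; responsibilities
  computed in log space.
* components reported with μ₁ ≤ μ₂; a zero-variance sample raises a
  degenerate-sample error (profiles report such a variable as unimodal
  with D = 0 by default).

Ashman's D = √2·|μ₁−μ₂|/√(σ₁²+σ₂²) with the conventional D > 2 bimodality
call, and the bimodality index BI = √(p(1−p))·|μ₁−μ₂|/σ_pooled with
σ_pooled = √((σ₁²+σ₂²)/2), are both computed from the same
unequal-variance fit — one fit, two indicators — rather than refitting an
equal-variance model for BI. Both are location- and scale-invariant up to
the (absolute) variance floor.

Two estimator behaviors are worth knowing. First, on low-count integer
data the likelihood rewards splitting the lattice (for example a
component on the cells with exactly two signals), which inflates D for
distributions that are not biologically bimodal; CEP17 at disomic levels
is the most affected, and case-level CEP17 bimodality flags should be
read with that in mind. Second, at small sample sizes (tens of cells) the
unpenalized two-component MLE will split almost any sample — about half of
size-40 subsamples of a unimodal Gaussian yield D > 2 (sklearn's
GaussianMixture behaves the same way) — so D > 2 is meaningful only at
large cell counts. The subsampling module exists precisely to quantify
this: detection rates at manual-scale samples are dominated by estimator
noise, and only the large-sample end of the curve is trustworthy. This
also means the simulated detection-rate curves here do not reproduce one
qualitative feature sometimes reported for this assay — very *low*
detection rates below 200 cells — which requires a more conservative
small-sample fitting procedure than a faithful ML fit.

## Subsampling simulation

For a per-cell sample, subsamples of each size in
{40, 60, 100, 200, 400, 600, 800, 1000} are drawn without replacement
(default 1000 iterations; 100 in the test suite and acceptance script to
keep runtimes in seconds), the mixture is fitted to each, and the
fraction of iterations with D > 2 gives the detection-rate curve.
Degenerate subsamples count as non-detections and are tallied separately.
"Robust" detection is operationalized as a detection rate ≥ 0.95; the
reported robust sample size is the smallest qualifying size with no
smoothing across the grid.

## Spatial dispersion

Amplified nuclei (per-cell ratio > 2.2, strict) are reduced to their
positions; each point's Euclidean nearest-neighbor distance is computed
exactly (k-d tree), and the case statistic is the median (midpoint
convention). Group contrasts use the natural log of the median distance
and a Welch two-sample t-test — the log because nearest-neighbor distances
are right-skewed, Welch because group variances differ by construction.

## Concordance and QC

Method agreement per case-level variable (mean HER2, mean CEP17, ratio)
uses the paired t-test (mean difference, 95% t-interval, two-sided p;
zero-variance differences handled exactly) and OLS of the automated value
on the reference with r², slope and intercept p-values. QC review tallies
convert to percentages with the nucleus rows over the total nucleus count
and each signal row over that channel's detected total; display values are
rounded half-up to one decimal, exact values retained.

## Synthetic cohorts

Each case is a mixture of cell populations with per-channel truncated
negative binomial counts (mean m, dispersion k, variance m + m²/k; large k
approaches Poisson — the minimum noise this family allows). Positions are
uniform over a 880 × 650 µm field (≈ 4 fields of view at 0.16 µm/px) for
scattered populations, or Gaussian (40 µm sd) around a few uniformly
placed centers for clustered ones. The observation model derives AD from
the ground truth by per-signal binomial thinning (default detect
probability 0.97) and whole-nucleus dropout (default 0.09, matching a ~9%
nucleus miss rate), and MP as a 40-nucleus sample without replacement
(+20 when the case is flagged equivocal), optionally biased toward
signal-rich nuclei ((HER2+CEP17)^b weights, default b = 0 since the bias
magnitude is not quantified anywhere). With these defaults AD slightly
undercounts and MP does not, reproducing the automated-underestimation
direction. All randomness flows from one cohort seed through per-case
`SeedSequence` spawn keys.

Archetypes plant the clinically meaningful case types; their parameters
were chosen so that the *post-filter* indicators land in the intended
guideline category (the truncation shifts above make this non-trivial):

| archetype | populations (weight × HER2/CEP17 mean) | planted truth |
|---|---|---|
| `negative` | 1.0 × 2.0/1.8 | negative, disomic |
| `amplified` | 0.9 × 12/1.9 (k=100) + 0.1 × 2.0/1.8 | positive |
| `equivocal_polysomy` | 1.0 × 4.6/3.8 | equivocal, polysomic |
| `gh` | 0.85 × 2.0/1.8 + 0.15 × 14/2.0 (k=100, clustered) | GH, HER2-bimodal |
| `bimodal_negative` | 0.75 × 1.5/1.8 + 0.25 × 8.0/2.5 (k=50) | HER2-bimodal |

Disomic CEP17 means are set to 1.8 because the ≥ 2 filter pushes a mean-2
channel to ≈ 2.9, a hair from the polysomy cut-off. The default 50-case
cohort mixes all five archetypes; factor/cluster experiments use the
four-group mix (12 amplified / 14 negative / 12 equivocal-polysomy /
12 gh) at 1000 cells per case, sizes within the realistic 200–1800
nuclei-per-section range.

What the generator does **not** emulate: nuclear truncation geometry
(signal loss from sectioning), correlated HER2/CEP17 loss within a
nucleus, observer-specific selection habits, or segmentation errors as
such (only their net undercounting effect). Its Poisson-floor noise is
wider than real per-nucleus counts at true copy number 2, which inflates
the filter's exclusion rate (≈ 2/3 of disomic cells) and the background
amplified-cell fraction (≈ 5% false per-cell calls); passing tests
therefore demonstrate correct statistical machinery under a conservative
noise model, not clinical performance on real slides.

## Factor analysis and clustering

The 14-variable case matrix (amplified-cell % by MP and AD, mean HER2,
mean CEP17 and ratio by both procedures, plus Ashman's D and BI of the
three automated per-cell variables) is standardized; factors are
extracted from the correlation matrix by principal components (top-3
eigenvectors scaled by √eigenvalue), rotated with raw varimax, with
regression-method scores F = Z·L·(LᵀL)⁻¹. Extraction, rotation and scores
are implemented directly (the algorithms are a few dozen lines);
sklearn's maximum-likelihood `FactorAnalysis` serves only as an
independent cross-check in tests, since it is a different extraction
method. Factor signs are canonicalized so each factor's largest loading
is positive. Factors are auto-labelled amplification / polysomy /
bimodality by the block of variables with the highest mean absolute
loading, blocks claiming factors in that priority order.

Cases are stratified by k-means on the factor scores (k = 4 by default,
50 restarts, deterministic per seed); clusters are relabelled 1..k by
decreasing size for stable output. The cluster summary table counts, per
cluster, the amplification categories, polysomy, both GH flags and the
three D > 2 flags, with a Total column that the per-cluster counts must
sum to.

Known limitation: with only two strongly informative latent directions
(amplification and CEP17 level) plus a noisy bimodality direction,
4-means occasionally trades a planted-group boundary for a split along
bimodality noise; across design-phase replicates the archetype-recovery
ARI was ≥ 0.7 in 11 of 12 cohorts (minimum 0.63).

## Problem sizes

Default test and acceptance problem sizes — 800–3500 cells per case, 100
subsampling iterations, 50-case cohorts, 100-seed recovery loops — were
chosen so the whole suite runs in well under a minute per module while
keeping Monte-Carlo error small relative to every asserted margin.
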