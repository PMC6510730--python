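# Methods

This note documents the models, estimators and numerical conventions the
package implements, the assumptions behind them, and what the synthetic
study conditions do and do not establish about real plate data.

## Growth-parameter extraction

**Model-free definitions.** No parametric growth model is fitted. The
saturated density *K* is the mean of the three consecutive
background-corrected OD600 reads that include the maximum read
(`numpy.argmax` convention: the first maximum on ties). When the maximum
sits at the first or last read the three reads are anchored at that edge
and the curve carries an `edge_max` flag, an early warning that it may not
have saturated. The growth rate *r* is the maximal specific rate: the
slope of ln OD against time in the exponential period, in h⁻¹ (natural
log; the base of the "logarithmic slope" is a convention, and e is the
standard one for exponential rates).

**Background.** The optical background of plate and medium is the
per-timepoint mean of the designated medium-only wells, subtracted from
every sample well. Corrected reads may be slightly negative; they are only
floored when logs are taken. Adding a constant to all wells of a plate
therefore cancels exactly.

**The exponential window (step 1).** The window ends at the first read
reaching `sat_fraction * K` (default 0.9) and starts just after the last
read below the noise floor (default 0.01 OD) before that point. Anchoring
the start at the *last* crossing rather than the first is what excludes
isolated lag-phase spikes: a single high read followed by sub-floor reads
cannot drag the window start forward. A window shorter than
`min_window_points` (default 4) falls back to the longest non-decreasing
above-floor run and flags `too_few_slopes`; a curve that never exceeds the
floor is `zero_growth` with r = 0 and is *kept* downstream, because zero
growth is information about the medium.

**Slopes (step 2).** Three estimators of the per-read log-slope are
provided; all agree exactly on exact exponentials, so the choice only
matters under read noise:

* `pairwise` — forward differences between neighbouring reads;
* `gradient` — the numerical gradient of ln OD (central differences on
  interior reads, one-sided at the edges);
* `regression` (default) — the least-squares slope of ln OD over the
  `slope_window` (default 9) nearest reads, the stencil shrinking
  one-sidedly at the window edges.

With additive read noise of sd 0.005 OD and a window that starts at
OD 0.01, a two-point slope at the window start has a log-noise sd of about
0.5 per read; the maximal-slope statistic is then dominated by noise and
the extracted rate is badly scattered and biased. The wide regression
stencil suppresses this by roughly w^(3/2). Measured on the default
synthetic conditions, the median relative rate error is ~28% with pairwise
slopes, ~18% with the gradient, and ~13% with the 9-read regression; the
default is therefore the regression estimator. The cost is a mild
compression of contrasts: fast, low-density wells are systematically
under-measured by a few percent (the slope declines over the stencil, and
a small-K well has a short window), which the synthetic design accounts
for (below).

**Outlier slopes (step 3).** The box-plot rule: quartiles by linear
interpolation of order statistics, and closed Tukey fences
`[Q1 - k·IQR, Q3 + k·IQR]` with k = 1.5. A degenerate IQR of zero retains
equal slopes. A `below_q1` compatibility mode discards only slopes
strictly below the first quartile, and `none` disables the step (the
ablation variant). Step 3 earns its keep with spike-sensitive point
slopes: a single corrupted read produces one extreme positive and one
extreme negative neighbouring slope, both far outside the fences. Under
the smoothed default estimator a single-read spike is spread so thinly
across the stencil that it rarely produces a removable outlier — the
smoothing itself is the spike defense there. The package's ablation
property (filter on vs off, spiked curves) is therefore evaluated in the
`gradient` configuration, where the filter is the sole defense and wins on
20/20 seeds.

**The rate (step 4).** The maximal surviving slope is averaged with its
nearest surviving neighbour on each side (at most three values; one
neighbour at a boundary), and floored at zero.

**Refinement.** A curve is *incomplete* when the least-squares ln-OD slope
over its final `plateau_window` reads (default 9) exceeds
`plateau_slope_tol` (default 0.02 h⁻¹) while the curve ever rose above the
noise floor — it was still climbing when the run ended, so its K is not a
saturated density. Incomplete curves are removed and logged;
`refine_dataset` never removes a curve whose final-window slope is within
tolerance. The window of 9 reads (4 h at 30-min sampling) keeps the false
removal rate of genuinely saturated low-K curves (K ≈ 0.15 OD, log-noise
~0.04 per read) near 2%, where a 5-read pairwise mean would miscall ~20%.

**Aggregation.** Per combination: arithmetic mean and standard error of r
and K; the SE is undefined for a single replicate and combinations below
`n_min` (default 3) replicates are flagged.

## Ion features

Ten compounds expand linearly into 13 components (glucose, NH4, Mg, Fe, K,
Na, thiamine, leucine, histidine, SO4, PO4, Cl, H); hydrate water
contributes nothing and thiamine hydrochloride contributes one H⁺ and one
Cl⁻. Concentrations are log₁₀ mM; a zero concentration is floored one
decade below its column's smallest positive value (recorded in the feature
matrix's metadata), and an all-zero column is an error unless dropped.

The column order is part of the method: the tree learner breaks exact
split ties by column index, and perfectly confounded pairs — a nutrient
and the counter-ion it was dosed with, such as Mg²⁺ and SO₄²⁻ from MgSO₄ —
produce exactly tied splits whenever the other sulfate sources are already
fixed on a branch. Ordering primary nutrients before counter-ions
attributes such splits to the biologically meaningful member of the pair;
the split-stability report still reveals the confounding, since across
resampled folds the counter-ion appears wherever the partition differs.
Pairwise Pearson correlations of the log features (the design diagnostic)
make the confounding visible directly: components dosed by a single shared
salt correlate at exactly 1.

## CART learner

Greedy binary recursive partitioning minimising the summed squared error
of the children; candidate thresholds are arithmetic midpoints between
consecutive distinct sorted values of each feature, so on log₁₀ features a
back-transformed threshold is the geometric mean of two adjacent tested
concentrations. Rows equal to the threshold go left. Splitting stops at
`max_depth`, below `2*min_leaf` samples (min_leaf defaults to 5), or when
no split reduces the error. Ties are broken deterministically by lower
column index, then lower threshold; an improvement must exceed a relative
1e-9 of the incumbent's error to displace it, so identical partitions
reached through different features tie exactly instead of being decided by
summation round-off. The root split equals exhaustive enumeration over all
(feature, midpoint) candidates by construction, and predictions match
scikit-learn's regression trees on shared configurations (used as an
independent cross-check in the tests, never as the implementation).

Cross-validation uses seeded uniform random partitions into k near-equal
folds (k = 5, no stratification). Depth selection fixes the smallest depth
whose cross-validated mse changes by at most `tol` (default 0.001, on the
target's squared scale) when the next depth in the grid is tried, reusing
one fold partition across depths so the comparison is paired; if no
plateau appears, the depth of minimal mean mse is returned. Split
stability refits the tree on every training fold and reports, for each
node position (root, root.L, ...), the frequency of each split feature.

## Decision readout

The best (worst) path is the root-to-leaf path with maximal (minimal) leaf
mean, ties to the larger then leftmost leaf. Per chemical on a path, `>`
thresholds tighten the lower bound and `<=` thresholds the upper bound,
back-transformed as 10^x mM; unconstrained sides are filled from the
design's tested range, since the data say nothing outside it. A chemical
in both best paths is called *uniform* when the open interiors of its two
intervals intersect and *trade_off* otherwise — intervals that touch only
at an endpoint are a trade-off, because the two objectives still demand
different concentrations. Chemicals in only one path are *unshared*.
Intervals come from the single best leaf; alternative high-performing
leaves are visible in the tree rendering but are not merged into the
intervals.

Spearman's rank correlation (average ranks on ties, t-approximation on
n − 2 df) links r and K at curve or combination level. The OLS baseline
regresses the target on all 13 features plus an intercept, with two-sided
p-values and no multiplicity correction; a rank-deficient design (e.g.
perfectly confounded ion pairs) raises an error naming the collinear
columns rather than reporting unidentifiable coefficients.

## Synthetic study conditions

The generator's defaults are the study conditions the pipeline is
validated under: C = 225 combinations drawn without replacement from a
432-point grid over seven varied compounds, N = 5 replicate wells, reads
every 0.5 h for 48 h, additive Gaussian read noise of 0.005 OD, detector
background 0.08 OD, inoculum od0 = 1e-3, normal lag (mean 1.5 h, sd
0.5 h), and a 5% per-well chance each of a lag-phase spike, an
exponential-phase spike (+0.1–0.3 OD on one read), and a truncation.
Growth is logistic; a truncated well is time-shifted so the run ends
mid-exponential, which is observationally equivalent to cutting the record
before the plateau and is what the incompleteness rule must catch.

Grid levels are chosen so adjacent-level geometric means land exactly on
the planted decision boundaries: NH₄⁺ 20/200 mM around 63.2 mM
(= √(20·200)), glucose 20/200/400 mM around the same 63.2 mM boundary,
Mg²⁺ 5/100 mM around 22.4 mM, Fe²⁺ 0.1/10 mM around 1.0 mM. The planted
response is a product of piecewise-constant window functions on the ion
profile. For the rate (r_max = 0.8 h⁻¹): ammonium below 63.2 mM limits to
0.52, between 63.2 and 282.8 mM is optimal, and above 282.8 mM gives zero
growth; magnesium is optimal in (0.1, 22.4] mM, reduced (0.75) above and
zero when depleted; glucose above 63.2 mM reduces to 0.7; iron below 1 mM
mildly limits (0.85). For the density (k_max = 1.0 OD): iron below 1 mM
limits sharply (0.4, the top decider); ammonium is optimal below 63.2 mM,
reduced (0.8) up to 282.8 mM, zero above; magnesium is optimal above
22.4 mM; glucose above 63.2 mM reduces to 0.55. K is forced to zero
wherever r is zero — a culture that never grows never accumulates density.
Thus ammonium and magnesium are planted trade-off chemicals, glucose a
uniform one, and iron a shared-direction limiter; the shared factors
(glucose, iron, a weak thiamine limitation) give the population its weak
positive r–K correlation despite the trade-offs pulling the parameters
apart. The iron rule is *limitation* rather than toxicity: with a
low-iron-optimal rate rule, the best rate cell of the design is the
SO₄-minimal corner and a single split on the composite SO₄ feature (the
sum of three sulfate salts) can isolate it, displacing magnesium from the
depth-4 best path; with iron-limitation the best rate cell is interior in
SO₄ and single-feature splits win. Factor magnitudes were set so that the
greedy split order on *measured* rates — which compress planted contrasts
through the smoothing bias and a K-dependent under-measurement of roughly
K^0.15 — keeps ammonium at the rate root and iron at the density root with
about a twofold error-reduction margin over the runner-up.

Replicate wells receive lognormal jitter on (r, K) with sd 0.10 and 0.05,
anticorrelated at −0.5: replicate-level fluctuations trade speed against
yield, the canonical rate–yield tension, at magnitudes that stay inside
the recovery conditions (median recovery of the per-combination truth
within 15% for r and 5% for K). This within-combination variability is
also what makes replicate averaging genuinely denoise the rank correlation
between r and K, so the per-combination Spearman coefficient exceeds the
per-curve one; the effect is a stochastic ordering with roughly a 95%
per-seed rate under the default conditions, which is why the corresponding
acceptance test evaluates it at three seeds and requires a majority.

**What the synthetic conditions do not show.** Real plate data have
continuous concentration–response relationships, spatial plate effects,
evaporation, condensation artifacts, diauxic shifts and pipetting error in
the actual (vs nominal) concentrations; none are modelled. The planted
response is piecewise-constant on the design grid, which favours
axis-aligned trees by construction — passing recovery tests demonstrates
that the pipeline finds structure of this kind when present, not that real
growth responses have it. The measured-vs-planted compression of fast
cells is a property of the default slope estimator that users comparing
absolute rates across very different K regimes should keep in mind.

## Degenerate inputs and conventions

Curves shorter than 3 reads cannot yield K; windows shorter than 2
positive reads yield r = 0 with `zero_growth`; all-equal targets yield a
single-leaf tree; constant feature columns are never split and correlate
as NaN; a Spearman correlation with a constant column is reported missing;
zero concentrations are floored as described; all randomized operations
(design subsampling, fold assignment, stability resampling, simulation)
are driven by explicit integer seeds and are bit-reproducible.
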