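# Methods

## Multivariate multiscale sample entropy

The engine computes, for a p-channel epoch, the multivariate sample
entropy at coarse-graining scales ε = 1…ε_max.  Conventions, in the
order they matter numerically:

* **Normalization.** Each channel is centred and scaled to unit sample
  variance once, on the original scale-1 series.  Coarse-grained copies
  are *not* re-standardized, so the similarity threshold `r` is an
  absolute tolerance on the common scale-1 units (the Costa multiscale
  convention).  Because block-averaging shrinks the variance of
  weakly-correlated signals, match probabilities rise with ε and
  white-like signals show decaying profiles — this is intended, not an
  artifact.
* **Coarse-graining.** Non-overlapping block means of length ε;
  trailing remainder samples are dropped (output length ⌊N/ε⌋).
  Coarse-graining composes: scales a·b equal successive a then b
  whenever the lengths divide evenly (property-tested).
* **Composite delay vectors (CDVs).** Row i concatenates, channel by
  channel, the lagged samples `x_k[i + j·τ_k]`, j = 0…m_k−1; there are
  `N − n` rows with `n = max(M)·max(τ)`.  Defaults `m_k = 2`, `τ_k = 1`.
* **Similarity.** Chebyshev distance with a *non-strict* threshold
  (distance ≤ r counts; ties at exactly r are matches), self-matches
  excluded.  `B_i = P_i/(count−1)` and `B` is the mean over i.
* **Extension.** Two conventions for the (m+1)-dimensional conditional:
  - `per_channel` (default): the embedding of one channel at a time
    grows by one sample, pooling `p·(N−n)` vectors of length m+1.  The
    extra sample is inserted **at the end of that channel's block**.
    This layout matters: appending it as a trailing coordinate instead
    would align the m base coordinates of all p channel-extensions and
    flood the count with trivial cross-extension matches (measurably
    producing negative entropies on white noise).  With the block-insert
    layout, vectors from different channel-extensions are compared on
    genuinely shifted coordinates.
  - `simultaneous`: every channel gains its next sample; the `N − n`
    vectors grow to length m+p.  Both variants coincide at p = 1
    (asserted in tests).  The per-channel rule is the default because it
    is the convention of the reference multivariate-entropy
    implementations this analysis family builds on.
* **Entropy.** `−ln(B^{m+1}/B^m)`.  Zero match counts yield NaN (with a
  log entry), never ±∞; profile aggregation over epochs skips NaNs and
  records the per-scale epoch count; an all-NaN profile is an error.
* **Counting.** Exact by three interchangeable methods: a numba kernel
  on vectors sorted by their first coordinate (default; candidate pairs
  pruned by a sliding window), a blocked vectorized path with a
  configurable block size (memory-bounded), and the brute-force double
  loop used as the oracle in tests.  All three agree exactly on random
  instances (property-tested, 50 instances).

Sample-size guideline: a profile warns when the coarsest scale retains
fewer than `p·10^max(M)` samples (for the default 4-channel, m = 2
setting: 400), the standard rule of thumb for stable sample-entropy
estimates.

### Choice of r in the synthetic shape tests

The package default is the study value `r = 0.15`.  That value is only
workable when channels are strongly correlated (as neighbouring scalp
electrodes are): for p = 4 channels at m_k = 2 the base vectors live in
8 dimensions, and for channel-wise *independent* unit-variance noise
the per-pair match probability is (2Φ(0.15/√2)−1)^8 ≈ 3·10⁻⁹ —
zero expected matches even in 10,240-sample epochs, hence undefined
entropy.  The synthetic generator draws channels independently, so all
signal-level shape and end-to-end tests use `r = 0.5`, where match
counts are stable; the shape properties being asserted (white-noise
profiles decay; 1/f profiles are flatter with a higher coarse tail) are
qualitative and hold for any reasonable r.

## Scalar profile features

* `AUC`: trapezoidal area over the scale *index* (unit spacing), i.e.
  Σ (v_ε + v_{ε+1})/2 — 11·c for a constant profile c over 12 scales.
* `MaxSlope`: the **signed** maximum of (v_j − v_i)/(j − i) over pairs
  1 ≤ i < j ≤ 4; a falling fine-scale profile gives a negative value.
* `AvgEnt`: mean of scales 9–12.
* Differences are first-named minus second-named set over the pairs
  F−P, FL−PL, FR−PR, FL−FR, PL−PR, ML−MR; antisymmetry and the
  45-column schema are asserted in tests.  Subjects missing any of the
  nine sets are excluded with a log entry.

## gf factor

The factor is the leading eigenvector of the 6×6 correlation matrix of
the test scores (principal-component solution), with loadings scaled by
√eigenvalue, scores standardized to mean 0 / SD 1, and explained
variance = eigenvalue/6.  The eigen-decomposition convention is
identified by the structure of typical batteries: equal loadings λ give
a first eigenvalue 1 + 5λ², so a factor carrying ~61.8% of the variance
corresponds to λ ≈ 0.7356 — the default loading of the synthetic score
generator.  The exact EFA estimator behind published analyses of this
kind is usually unstated; the principal-component solution is the
reproducible canonical choice.

## PLS regression and inference

PLS1 (NIPALS) on predictors standardized within the analysed group and
centred response.  The in-package core returns coefficient paths for
every component count, per-component explained response variance
(q_k²·‖t_k‖²/SS_y), and per-observation leave-one-out residuals; it is
cross-checked in tests against `sklearn.cross_decomposition.
PLSRegression` (agreement to 1e-10) and against the least-squares
solution at full rank (known PLS limit).

* **CV scheme**: leave-one-out; component 0 predicts the training-fold
  mean.  Configurable in principle, LOO is the default because it is
  deterministic and the common default of the R implementations this
  analysis style uses.
* **Component selection**: (a) first local minimum of the CV curve —
  smallest k with curve[k] < curve[k−1] and curve[k] ≤ curve[k+1], the
  last point qualifying if the curve is still decreasing; a flat curve
  selects 0 with a warning; (b) van der Voet's randomization test —
  paired sign-flip test (n_perm = 10,000 by default) on differences of
  squared LOO residuals between each candidate and the PRESS-minimal
  model, returning the smallest k not significantly worse at α = .05.
  Under pure-noise responses the selector keeps the 0-component model
  in ≥ 95% of replicates (the level of the test; measured ~100%,
  i.e. conservative, because the PRESS minimum is itself noisy).
* **Bootstrap relevance**: subjects resampled with replacement,
  standardization + fit repeated per replicate, fixed component count.
  A predictor is *relevant* when its 95% interval excludes zero.
  Degenerate replicates (a constant predictor column) are redrawn and
  counted.  Interval flavours:
  - `percentile` (default): empirical 2.5/97.5 percentiles.  Measured
    false-positive rate under a global null (n = 119, 45 predictors):
    ~5–6%, i.e. nominal.
  - `bc`: bias-corrected percentile.  Provided because applied work in
    this area reports BC intervals, but **not** the default: under the
    null the bootstrap distribution of a PLS coefficient is median-
    shrunk toward zero (resampling dilutes the chance alignment the
    full-sample fit found), the BC z₀ correction therefore shifts both
    interval ends away from zero, and the measured false-positive rate
    inflates to ~16–35%.  Use BC only for comparability with legacy
    reports.
* **Group analyses** filter rows by sex code (M/W), re-standardize
  within the group, report both selection criteria, and sort relevant
  predictors by |coefficient| within positive/negative blocks.  No
  automatic outlier removal is performed; an explicit subject-exclusion
  list is accepted instead (outlier criteria in published analyses of
  this design are typically unstated, so silent automation would be
  unverifiable).

## Synthetic data

Signal level: each channel is
`pink_weight·pink + (1−pink_weight)·white + alpha_amp·sin(2π·10t + φ)`
with channel-wise independent unit-variance noise draws; the 10 Hz
phase φ is shared across channels (the only cross-channel dependence).
Pink noise is spectrally shaped (rFFT weights 1/√f, DC zeroed) —
deterministic, fast, dependency-free.  Recordings carry 10–20 labels so
every built-in channel set is selectable.

What it emulates: the qualitative multiscale signatures — white-like
signals decay across scales, 1/f-dominated signals keep a flatter,
higher coarse-scale tail — and a controllable complexity parameter.
What it does not: volume conduction (inter-channel correlation),
artifacts, nonstationarity, realistic spectra or profile magnitudes;
synthetic parameter ranges reproduce profile *shapes*, not the
amplitudes of any real dataset.  Passing tests therefore validate the
computational chain and its statistical calibration, not biological
claims.

**Pink-weight range of end-to-end cohorts.**  Coarse-scale entropy is
*not* monotone in the pink weight at every epoch length: with
2,048-sample epochs the coarsest scale retains only ~170 samples, and a
heavily 1/f-weighted mixture wanders so smoothly there that delay
vectors match densely and AvgEnt falls again beyond pink_weight ≈ 0.4
(measured; at 10,240 samples the rise continues to ≈ 0.5).  Cohorts
that use the pink weight as the complexity-driving parameter therefore
vary it over [0, 0.4] by default, where AvgEnt increases monotonically
at both epoch lengths, making the planted complexity–gf link
well-defined.

Feature level: 45 predictor columns drawn from MVN(0, Σ) (identity Σ by
default) with `gf = Xβ + N(0, σ²)` and alternating sex labels.  The 18
difference columns are free draws here — the A−B identity holds only
for tables assembled from actual profiles — because an identity Σ is
exactly what null-calibration experiments need.  Sex has no generative
effect unless the user supplies sex-specific effects, so sex-stratified
analyses can be tested under the null and under constructed
differences.

Test-score batteries: `score_j = λ_j·gf + √(1−λ_j²)·noise`, mapped
affinely onto plausible raw-score scales for the six tests (means/SDs
of typical administrations).

## Problem sizes used in the checked experiments

Chosen so the full suite runs in a few minutes on one CPU while keeping
Monte-Carlo error well inside the asserted tolerances: the iid closed
form uses 10 seeds × 100,000 samples (tolerance ±0.05; observed error
≈ 0.003); profile-shape assertions use 20 replicate pairs of 4-channel
10,240-sample epochs; bootstrap calibration uses 60 null cohorts ×
B = 500 (SE of the flag rate ≈ 0.5 percentage points against a ±2-point
band); selector level uses 40 replicates at n_perm = 1,000; the
end-to-end cohort uses 20 subjects with one 2,048-sample epoch each.
`scripts/acceptance.py` re-measures the same quantities at slightly
smaller replicate counts.

## Known limitations

* No EEG preprocessing (filtering, re-referencing, ICA, bad-channel
  handling): inputs are assumed cleaned; only the final
  |amplitude| > 111 μV epoch rejection is applied.
* Refined/composite MSE variants, frequency-resolved entropy and
  surrogate testing are out of scope.
* BC bootstrap intervals are anti-conservative for PLS coefficients
  under the null (see above); results based on them should be read
  accordingly.
* The bias-corrected-and-accelerated (BCa) variant is not implemented
  (no acceleration constant), matching the plain-BC convention of the
  tools this analysis style uses.
* Epoch extraction starts at sample 0 with no overlap or jitter;
  epoch counts are not equalized across subjects.
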