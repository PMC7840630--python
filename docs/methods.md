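# Methods

This note documents the models, estimators and numerical choices behind
`lcmsqc`, and what the synthetic data do and do not emulate.

## Batch design

Injection sequences follow the pooled-QC bracketing convention: each batch
opens with `qc_lead = 7` QC injections, closes with `qc_tail = 2`, and
separates consecutive segments of at most `segment = 4` randomly ordered
samples with a single shared QC. The first `equilibration_qcs = 5` QCs of a
batch equilibrate the platform and are flagged unusable for drift fitting.
Batches are filled greedily up to `max_injections_per_batch = 95` total
injections. With 64 samples this yields 88 injections and 24 QCs, 19 of
them usable — the interior brackets are *shared* single QCs (…QC, 4
samples, QC…); reading "bracketed by two QCs" as one on each side is a
design choice, configurable through the layout parameters.

## Signal-drift model and correction

The generator multiplies each feature's true mean by a relative-sensitivity
curve `d(o)` over injection order `o`, with `d(first) = 1` and
`d(last) = 1 − a` for amplitude `a` (shapes: linear, exponential, monotone
random spline). Defaults of `a = 0.15` (positive mode) and `0.25`
(negative mode) are illustrative of the stronger decay seen in negative
ion mode, not measured constants.

Correction is per feature × batch:

1. **Smoothing.** Tricube-weighted local linear regression (LOWESS) of
   usable-QC intensity on injection order. The smoother is evaluated
   through explicit hat-matrix rows, so it is a linear operator in the QC
   intensities; this gives vectorization across features sharing a batch
   layout, exact leave-one-out rows, and a well-defined small-window limit.
   The neighborhood size is `k = max(2, ceil(span · n))`; at `k = 2` the
   local line passes through the two nearest points, so the smoother
   interpolates the QC data exactly — the right behavior for noise-free
   data, exposed as `span_policy="interpolate"`.
2. **Span selection.** The span is chosen per feature and batch by
   leave-one-out cross-validation over the grid
   {0.3, 0.45, 0.6, 0.75, 0.9, 1.0}, ties broken toward the largest
   (smoothest) span. LOO-CV is our choice of optimization criterion,
   following the pooled-QC correction literature; a fixed span can be
   supplied instead.
3. **Interpolation.** A cubic spline through the smoothed QC points defines
   `c(o)` at every order; beyond the first/last usable QC the nearest end
   value is held constant, and predictions are floored at 1% of the QC
   median so corrected intensities never flip sign.
4. **Normalization.** `corrected = raw / c(o) · ref` with `ref` the
   feature's median usable-QC intensity across **all** batches. A global
   (not per-batch) reference is essential: dividing by the batch's own QC
   curve removes the batch's sensitivity level, and rescaling by a global
   constant keeps intensities on the raw scale while harmonizing batches.
   Consequently the absolute scale of corrected data is anchored at the
   QC median (equivalently, at the median drift level of the usable QC
   orders); all relative quantities — class contrasts, fold changes,
   CVs — are unaffected.

Features with 1–3 usable QCs in a batch fall back to QC-median division;
with none, they are left uncorrected. Every cell carries a provenance flag
(`curve`, `median_fallback`, `uncorrected`) and the per-feature × batch
report records span, QC count and pre/post QC CV. The minimum of 4 QC
points for curve fitting balances spline stability against batch length.

## Noise model

All technical noise is multiplicative log-normal: a coefficient of
variation `cv` maps to the log-scale σ via `cv = sqrt(exp(σ²) − 1)`, so
intensities stay positive and per-level CVs are exact. Nested draws are
per feature × batch (default CV 31.2%), per feature × extract (0.6%) and
per feature × injection (8.6%) — the raw inter-batch, extraction and
instrument variation levels typical of a maintained ESI-QTOF platform that
the package is designed to correct. QC injections are re-injections of one
pooled extract and therefore carry batch and injection terms but no
extraction term. Missing values arise from a detection floor (default 100
counts, rarely active at the default mean range 10⁴–10⁶) plus independent
dropout, and are recorded as NaN, never zero.

What the generator does **not** emulate: correlated drift across features,
heteroscedastic (intensity-dependent) CVs, retention-time shifts, adduct
and isotope structure, or missingness that depends on class. Passing tests
therefore demonstrate correctness of the estimators under the stated
statistical model, not robustness to all failure modes of real data.

## Validation estimators

* **Recovery / matrix effect.** `R = (Ā − D̄)/(B̄ − D̄)`,
  `ME = (B̄ − D̄)/C̄`; suppression bands weak < 25%, medium 25–50%,
  strong > 50%, `ME > 1` reported as enhancement. `B̄ ≤ D̄` (spike
  indistinguishable from background) and `C̄ = 0` are signalled as errors.
  The generator constructs group means so the estimators return configured
  truth exactly in the noise-free limit.
* **Variance components.** Balanced two-level nested ANOVA
  (batch → extract → injection) solved by expected mean squares:
  `σ²_inj = MS_w`, `σ²_ext = (MS_e − MS_w)/n_r`,
  `σ²_batch = (MS_b − MS_e)/(n_e n_r)`; negative estimates truncate to
  zero with a flag. For balanced designs these equal the REML solution
  whenever all components are interior, which the test suite verifies
  against a numerical restricted-likelihood optimizer. CVs are reported on
  the intensity scale against the grand mean by default (`scale="log"`
  maps log-scale variances back through the log-normal CV relation);
  on multiplicative data the intensity-scale estimates carry a small
  (≈ `sqrt(1 + cv_batch²)`) upward bias in the lower components, well
  inside the accuracy needed to rank variance sources. Unbalanced designs
  are rejected rather than approximated.
* **Linear range.** Under the through-origin model `y = a·x`, a
  provisional slope is anchored on the lowest three levels and the highest
  level is dropped while its mean response deviates from the anchored line
  by more than 10% (configurable); slope and r² are then refit on the
  retained prefix. Anchoring matters: a through-origin fit over all levels
  is dominated by the highest concentrations, so the slope tracks the
  saturation and the deviation of a flattened top level shrinks below any
  threshold. The anchored rule replaces visual inspection with a
  deterministic, prefix-preserving criterion.
* **Fold-change accuracy.** Duplicates are averaged within batch; the
  fold change of a level versus baseline is the ratio of means of the
  per-batch averages, tested with a two-sample two-tailed equal-variance
  *t*-test (3 + 3 batch means ⇒ df = 4). The relative error is measured on
  the concentration difference, `|(FC_exp − 1) − (FC_nom − 1)|/(FC_nom − 1)`,
  the scale on which small spikes are meaningfully compared. The analytic
  power uses the noncentral *t* with pooled SD
  `cv·sqrt((1 + FC²)/2)/sqrt(duplicates)` (multiplicative noise scales with
  the level mean); its negligible lower tail is clamped to zero where the
  numerics underflow.

## Profiling

PCA runs on column-mean-centered, unscaled log2 matrices via SVD; the
largest-magnitude loading of each component is made positive so signs are
deterministic, and features containing missing values are dropped and
reported, not imputed. Per-feature one-way fixed-effects F-tests are
adjusted with Benjamini–Hochberg. Hierarchical clustering uses Euclidean
distance with average linkage on per-feature z-standardized (display
scale) profiles; leaf order follows scipy's deterministic tie-breaking by
input index, and dendrograms export to Newick.

## Targeted quantification

EICs sum centroid intensities within ± 20 ppm (QTOF-appropriate default)
of the quantifier m/z per scan. Peak areas are trapezoidal integrals over
an RT window (default half-width 0.1 min) after subtracting a linear
baseline anchored at the medians of the first/last three points inside the
window — robust to constant offsets and, unlike a global minimum, to
neighboring peaks; the integrand is floored at zero so noise dips do not
subtract area. Equivalence with any vendor integrator is not claimed. mzML
I/O is self-contained: a reader for centroided spectra (uncompressed or
zlib, 32/64-bit floats) and a minimal writer used to produce synthetic
fixtures.

## Problem sizes and determinism

Default test and acceptance scales — 500–1000 features, 88-injection
single-batch or 3 × 40-injection multi-batch designs, 200–2000 Monte-Carlo
replicates — were chosen so each analysis completes in seconds to about a
minute on one CPU while leaving Monte-Carlo error well below the margins
being tested. All randomness flows through `numpy.random.default_rng`
seeds carried in configs; identical config and seed give bit-identical
tables, and pipeline outputs embed the seed and config hash in a JSON
sidecar.

## Known limitations

* The correction assumes QCs track biological samples' drift; analytes
  absent from the pool cannot be corrected.
* Span optimization minimizes QC prediction error, which can slightly
  over-smooth very short batches; the minimum-QC rule (4 points) makes the
  curve fall back to median scaling in sparse batches.
* The FDR null analysis assumes features are independent; correlated
  feature families in real data widen the q-value error bars.
* Linear-range anchoring presumes the three lowest levels are linear; a
  series saturating from the very bottom returns "no linear range" rather
  than a fit.
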