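# lcmsqc

Pooled-QC signal-drift correction, method-validation statistics and
profiling analytics for multi-batch untargeted LC-MS metabolomics — with a
synthetic-data generator that produces feature tables, validation
experiments and chromatograms with known ground truth.

## The problem

Untargeted LC-MS metabolite profiling measures thousands of features
(m/z–retention-time pairs) across injections organized in analytical
batches. Detector sensitivity decays systematically with injection order
(ion-source contamination), and batch-to-batch offsets typically dwarf all
other technical variation. The standard remedy is a pooled quality-control
(QC) sample — a mixture of aliquots of all study samples — injected
repeatedly throughout every batch. `lcmsqc` implements the computational
side of that design for analysts who process feature tables or targeted
peak areas in Python:

* **Batch layout** — bracketed designs (lead/tail QC blocks, a QC between
  every segment of four samples, ≤ 95 injections per batch, the first five
  QCs flagged as equilibration runs).
* **Drift correction** — per feature and batch, a LOWESS curve
  `c(o)` is fitted to QC intensity versus injection order `o`
  (tricube-weighted local linear regression, leave-one-out span selection,
  cubic-spline interpolation); every intensity is corrected as
  `x' = x / c(o) · ref`, where `ref` is the feature's median QC intensity
  across batches, removing within-batch drift and between-batch offsets at
  once.
* **Feature quality control** — removal of features with QC CV > 30% (and,
  for targeted tables, mean QC intensity < 2000 counts), dry-weight
  normalization, replicate averaging, log2 transform.
* **Validation statistics** —
  recovery `R = (Ā − D̄)/(B̄ − D̄)` and matrix effect
  `ME = (B̄ − D̄)/C̄` from the four-group spike design
  (A: spiked before extraction, B: after, C: solvent blank, D: non-spiked);
  balanced nested ANOVA `σ²_batch / σ²_extraction / σ²_injection` via
  expected mean squares; through-origin linear-range estimation
  (`y = a·x`); fold-change accuracy with equal-variance two-tailed
  *t*-tests on per-batch means (3 batches ⇒ df = 4) and closed-form
  noncentral-*t* power.
* **Profiling** — PCA on mean-centered log2 data, per-feature one-way
  ANOVA with Benjamini–Hochberg FDR, average-linkage hierarchical
  clustering with heatmap and Newick export.
* **Targeted quantification** — quantifier-ion extracted-ion chromatograms
  (± 20 ppm) from centroided mzML, trapezoidal peak integration with
  edge-anchored baseline subtraction.

The synthetic generator reproduces the statistical structure of such
studies — monotone within-batch drift, log-normal nested noise
(batch/extraction/injection), cultivar effects, spike-in groups, saturating
dilution series — so every estimator can be checked against configured
truth.

## Worked example

```python
import lcmsqc as L
from lcmsqc.featqc import qc_cv
from lcmsqc.synthdata import SyntheticConfig

design = L.cultivar_design(seed=5, max_injections_per_batch=40)  # 3 batches
config = SyntheticConfig(n_features=300, drift_amplitude=0.20,
                         drift_shape="exponential", cv_injection=0.086,
                         cv_extraction=0.006, cv_batch=0.312, seed=11)
table, truth = L.simulate_feature_table(config, design)
corrected, report = L.apply_correction(table)
print(f"median raw QC CV       : {qc_cv(table).median():.1%}")
print(f"median corrected QC CV : {qc_cv(corrected).median():.1%}")
```

prints

```
median raw QC CV       : 23.9%
median corrected QC CV : 6.3%
```

The raw QC CV mixes 31.2% batch offsets, a 20% within-batch drift and 8.6%
injection noise; after normalizing each feature to its QC curve, only
injection-level noise remains. `examples/` contains one narrative script
per capability (batch design, drift correction, validation statistics,
profiling, targeted quantification); each prints what it computes and what
the numbers mean, e.g. `examples/03_validation_statistics.py`:

```
aminohippurate_like  recovery 86.8%   matrix effect 58.8% (medium suppression)
5 batches x 5 extracts x 4 injections:  CV batch 45.1%, extraction 0.5%, injection 8.9%
linear range: 9 of 11 levels retained (r^2 = 0.9990); excluded: [252.4 400. ]
```

A thin CLI mirrors the library
(`lcmsqc simulate | filter | correct | validate-* | quantify | profile`);
every output directory carries a `run_info.json` sidecar with the seed and
configuration hash, and reruns with the same seed are byte-identical.

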