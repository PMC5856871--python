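# metaproc

Post-processing for untargeted GC-/LC-MS metabolomics feature matrices.

Untargeted chromatography–mass-spectrometry experiments produce a
deconvoluted table of features (peaks characterized by m/z and retention
time) × samples. Before any statistics, that table needs cleaning:
inconsistently detected features must go, missing intensities must be
imputed, per-sample dilution and injection-order drift must be corrected,
and features need candidate metabolite annotations. `metaproc` implements
that post-processing path as a library and a CLI for analysts who already
have a peak table (from XCMS, OpenMS or vendor software — peak picking
itself is out of scope):

* **Feature filtering** — delete features missing in more than 50% of the
  pooled QCs or with QC RSD above 20% (defaults, configurable); or, without
  QCs, keep features whose mean study intensity exceeds the mean blank
  intensity by a fold factor.
* **Imputation** — small-value replacement (½ × feature minimum),
  feature-wise K-nearest-neighbour imputation, or iterative random-forest
  imputation with the increase-of-difference stopping rule.
* **Normalization** — probabilistic quotient normalization
  (d_s = median_f(x_sf / ref_f), ref = per-feature QC median) or sum
  normalization to a per-sample total of 100.
* **Drift/batch correction (RLSC)** — per-feature robust LOESS of intensity
  on injection order through the QCs, x′ = x / fit(order) × m_f, which
  removes drift and merges analytical blocks.
* **Annotation** — accurate-mass search against HMDB/LIPID MAPS-style
  compound tables under an adduct model (M = (mz·|z| − shift)/multimer),
  default 5 ppm.
* **Synthetic runs** — a generator with full ground truth (drift curves,
  batch offsets, dilution factors, censoring masks) for validation.

See `docs/methods.md` for the statistical details and defaults.

## Worked example

Generate a synthetic two-batch run with drift, then process it:

```bash
metaproc synth --preset two-batch --seed 1 --out demo/
metaproc run --config pipeline.yaml
```

with `pipeline.yaml`:

```yaml
io:
  feature_table: demo/feature_table.csv
  sample_metadata: demo/sample_metadata.csv
output_dir: demo/out
seed: 1
stages:
  - {name: batch_correct, anchor: qc, span: 0.75, degree: 2}
  - {name: qc_filter, max_qc_missing_pct: 50, max_qc_rsd_pct: 20}
  - {name: impute, method: knn, k: 10}
  - {name: normalize, method: pqn, reference: qc}
  - {name: annotate, adducts: positive, ppm_tol: 5}
```

Batch correction is placed first here deliberately: this run carries a 2×
offset between its two blocks plus a 50% within-batch drift, so QC RSDs
computed on the *raw* matrix exceed 20% for essentially every feature and
an upfront QC filter would (correctly, per its rule) delete them all. After
RLSC merges the blocks the QCs are tight again. The run prints:

```
wrote 200 samples x 50 features to demo
pipeline finished: 200 samples x 50 features, 0 annotation hits, 5 stages -> demo/out
```

— RLSC divides out the drift (per-feature QC RSDs before and after are in
`demo/out/reports.jsonl`), all 50 features then survive the QC filter, the
matrix is complete so imputation is a no-op, PQN rescales each sample by
its median quotient against the QC reference, and zero annotation hits are
expected because the synthetic m/z values are random. The same
stages are available as individual subcommands (`metaproc filter qc`,
`metaproc impute`, `metaproc normalize`, `metaproc batch-correct`,
`metaproc annotate`) that read and write the same CSV layout, and as
library functions:

```python
from metaproc import (generate_dataset, preset, filter_by_qc,
                      QcFilterParams, correct_rlsc, RlscParams)

matrix, samples, features, truth = generate_dataset(preset("drifty", seed=1))
filtered, report = filter_by_qc(matrix, samples, QcFilterParams())
corrected, report = correct_rlsc(filtered, samples, RlscParams())
print(report.per_feature_metrics["F0001"])
# {'qc_rsd_before': 12.084039535547259, 'qc_rsd_after': 4.415898318045365}
```

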