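# Methods

`metaproc` post-processes untargeted GC-/LC-MS metabolomics data starting
from the deconvoluted feature table (peak picking is upstream and out of
scope). This note documents the statistical procedures, their assumptions,
the defaults and why they were chosen, and what the synthetic test data do
and do not establish.

## Data model

The central object is a samples × features matrix of non-negative
intensities with an explicit missing-value marker (NaN in memory, an empty
field on disk; a stored 0 is a measured zero, distinct from missing). Files
use the common deconvolution-export layout — features as rows, one
intensity column per sample — and are transposed on read. Whether a literal
0 in a file means "undetected" is tool-dependent, so it is a reader flag
(`zeros_as_missing`, default true, since most deconvolution software emits
0 for undetected features). Every stage returns a new matrix plus a
machine-readable `StageReport`; nothing mutates its input, so stages can be
freely reordered and re-run.

## Feature filtering

Pooled QCs are assumed to contain every signal present in the study
samples; under stable instrument performance each signal should be detected
consistently across QC injections. Two per-feature criteria flag
inconsistent detection:

* missing fraction across QCs strictly above `max_qc_missing_pct`
  (default **50%**);
* relative standard deviation (sample SD / mean × 100, over non-missing QC
  values) strictly above `max_qc_rsd_pct` (default **20%**).

Boundary values are retained (the rules read "more than" / "higher than").
A feature observed in at most one QC, or with zero mean, has an undefined
RSD and is deleted under the RSD criterion — it is by construction
inconsistently detected. The two criteria act as independent deletion rules
by default (`qc_rule="or"`); a conjunctive variant (`"and"`) is available
because the alternative reading — delete only features failing both — is
defensible.

The blank-based alternative (for runs without QCs, or to remove background)
retains a feature iff its mean study intensity strictly exceeds
`fold_factor` × its mean blank intensity, and its missingness among study
samples is ≤ `max_sample_missing_pct`. There is no field-wide consensus
default for the fold factor; the CLI suggests 3, a common choice for
background subtraction. A feature absent from all blanks has blank mean 0
and always passes the fold test. Missing percentages are computed against
the count of samples of the relevant type, never the whole run; the
missingness scope is study samples only by default (`scope="study+qc"`
available).

## Missing-value imputation

Three imputers, chosen per dataset (missingness mechanisms differ):

* **SV (small value)** — each missing cell of a feature becomes half the
  feature's minimum observed value, a limit-of-detection surrogate.
  Appropriate when missingness is mostly censoring. The phrase "minimum for
  a given feature in a given sample" is ambiguous between a per-feature and
  a per-sample minimum; the standard per-feature reading is the default
  (`sv_scope="feature"`), the per-sample variant is selectable.
* **KNN** — feature-wise, as in expression-matrix KNN imputation: the
  objects being matched are features, distance is Euclidean over
  co-observed samples rescaled by (total samples / co-observed samples) so
  sparsely co-observed pairs are penalized, and the imputed cell is the
  unweighted mean of the k (default **10**) nearest features' values in
  that sample (neighbours missing there are skipped; if all are missing the
  feature's own mean is used). Ties in distance break by feature index, so
  the result is deterministic.
* **RF** — iterative random-forest imputation: initialize missing cells
  with feature means; visit features in ascending-missingness order, each
  regressed on all others (forest of **100** trees) using its originally
  observed rows; stop when the convergence statistic
  Σ(X_new − X_old)² / Σ(X_new²) first increases, returning the previous
  iterate, with a cap of 10 rounds as a safety net. Seeded per
  (iteration, feature), so a fixed seed gives bit-identical output.

No log transformation is applied before KNN/RF by default (an off-by-default
flag exists). All imputers preserve originally observed cells exactly and
are no-ops on complete matrices. Imputation is ordered after feature
filtering in the default pipeline, so all-missing features have normally
been removed already.

## Normalization

**PQN** estimates a per-sample dilution factor: (i) reference spectrum =
per-feature median over the QCs when present (the default, overridable to
all samples); (ii) quotients of the sample's intensities against the
reference, over features with positive reference value and observed
intensity; (iii) division of the sample by the median quotient. Even-count
medians are the mean of the two middle order statistics. Features with
reference value 0 are excluded from the quotient list but still divided by
the dilution factor, keeping the sample on one scale. PQN tolerates missing
cells (quotients over observed cells only), so it can run before imputation
if reordered.

**Sum normalization** divides each sample by its non-missing total and
multiplies by 100, so every sample's non-missing intensities sum to 100.

Both are scale-equivariant per sample (a per-sample multiplier is absorbed
exactly) and never change the missing mask or the sample/feature sets.

## Drift and batch correction (RLSC)

LC-MS intensity drifts smoothly with injection order; the drift is treated
as multiplicative, which motivates a ratio-based correction. Per feature
and per batch, a robust LOESS curve of intensity versus injection order is
fitted through the anchor samples (the QCs by default, or all non-blank
samples with `anchor="all"`), and each cell is corrected as

    x' = x / fitted(order) × m_f

where `m_f` is the feature's median over the anchor samples of the whole
run. Dividing by the batch-local fit removes drift *and* the batch's own
level; multiplying by the run-wide anchor median restores a common
interpretable scale, which is what merges analytical blocks.

The LOESS is the conventional robust configuration, all config-exposed:
span **0.75**, local polynomial degree **2**, tricube neighbourhood
weights, **4** bisquare robustness reweighting passes
(weights `(1 − (r/6s)²)²` with `s` the median absolute residual).
Predictions at non-anchor injection orders interpolate linearly between
fitted anchor values and clamp (constant extrapolation) beyond the first or
last anchor, avoiding wild polynomial tails for early/late study samples.
Numerical details: local fits are computed by weighted least squares
centred at the prediction point; the polynomial degree degrades gracefully
when fewer distinct x-values carry weight; a batch whose usable anchor
count for a feature is below degree + 2 falls back to anchor-median scaling
for that feature (recorded in the report); non-positive fitted values
invalidate the cell to MISSING rather than produce negative intensities,
and the report counts these exactly. Correction is per batch by default;
a single fit across contiguous batches is available (`per_batch=false`).

## Accurate-mass annotation

Features are matched to compound tables (HMDB/LIPID MAPS-style TSV dumps:
id, name, formula, monoisotopic mass) through an adduct model. Each adduct
hypothesis inverts the observed m/z to a neutral mass
`M = (mz·|z| − shift)/multimer`; every compound within the ppm window
(|M − m|/m·10⁶ ≤ tol, default **5 ppm**, typical Q-TOF accuracy) is a hit.
Default adducts: positive [M+H]+, [M+Na]+, [M+K]+, [M+NH4]+, [2M+H]+;
negative [M−H]−, [M+Cl]−, [M+HCOO]−, [2M−H]−; user-extensible via TSV.
Mass conventions: proton 1.00727646 Da, electron masses included in adduct
shifts; formula masses use most-abundant-isotope atomic masses (C = 12
exactly). The candidate window is located by binary search on the
mass-sorted table; hits are ranked per feature by |ppm error|, ties by
compound id. Matching is per adduct hypothesis, so one feature may carry
hits under several adducts — exact mass alone cannot distinguish isomers or
a monomer-of-one-compound from a dimer-of-its-half, and the package reports
all such hits rather than guessing. A curated ~50-compound table (common
metabolites and lipids with CHNOPS formulas, masses derived from the
formulas) ships with the package so annotation is testable offline.

## Synthetic data generator

The generator emulates the structure the stages assume, with complete
ground truth: lognormal feature abundances (log-mean 10, log-SD 1.5 —
arbitrary instrument units); biological variation as a per-sample factor
model on the log scale with correlation ρ between features
(`bio_log_sd`, default 0.5, splits into a shared factor √ρ·u and an
independent part √(1−ρ)·ε); QCs as exact replicates of the pooled study
mean, noisy only through the shared multiplicative noise (CV `noise_cv`);
blanks carrying only a contaminant subset of features at pool-comparable
intensity, injected at the start of the sequence; per-sample dilution
factors (lognormal, `dilution_log_sd`) on study samples only, since QCs
and blanks are aliquots of one pool; linear multiplicative drift of
relative amplitude `drift_amplitude` across each batch; per-batch
multiplicative offsets; LOD censoring applied to the noise-free value (so
the threshold is a knowable truth property) at quantile `lod_quantile`;
and MCAR masking at `mcar_rate`. Every factor is stored, so observed =
true × dilution × drift × batch × noise holds cell-exactly.

Presets fix the study conditions used by the tests: `drifty` is a
200-injection single batch (160 study + a QC every 5th injection), drift
amplitude 0.5, 50 features, 5% noise; `two-batch` splits that run into two
blocks with a 2× offset; `sparse` adds ρ = 0.7 correlation, 5% LOD
censoring and 10% MCAR; `clean` disables all corruption except dilution.
Imputation-recovery experiments use 100 study samples × 20 features with
ρ = 0.7 and 10% MCAR, averaged over 10 seeds — sizes chosen so the full
recovery suite runs in minutes on one core while keeping the per-seed
estimates stable.

What the generator does **not** emulate: correlated missingness between
features, retention-time shifts, isotope/adduct peak redundancy within the
matrix, heteroscedastic electronic noise floors, or class-specific absence
(MNAR by group). Passing recovery tests therefore show the algorithms are
implemented correctly and behave as intended under their own assumptions,
not that those assumptions hold for any particular real dataset.

## Pipeline

Default stage order: QC filter → blank filter (skipped when the run has no
blanks) → imputation → normalization → batch correction → annotation. The
order is fully configurable; batch correction may equally run before PQN,
both orders are supported. One global seed fans out per-stage
(`seed + stage index`), so a single stage re-run with its recorded seed
reproduces the pipeline's result. Outputs are `processed_matrix.csv`
(export layout), `annotations.tsv`, `reports.jsonl` (one JSON object per
stage, timestamp-free so identical config + seed runs are byte-identical)
and `run.log` (timestamped, the only non-reproducible output).

## Known limitations

* The QC filter's OR default is a judgement call; datasets curated under
  the conjunctive reading will retain more features (use `qc_rule="and"`).
* KNN imputation is O(features² × samples) per incomplete feature; for very
  wide matrices (>5k features) RF or SV is the pragmatic choice.
* RLSC assumes anchors span each batch's injection range; with sparse QCs
  the clamped extrapolation flattens correction at the run edges.
* Annotation is accurate-mass only: no isotope-pattern or MS/MS evidence,
  so hits are candidate annotations (level ≥ 3), not identifications.
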