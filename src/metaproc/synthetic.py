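"""Synthetic LC–MS run generator with full ground truth.

Emulates the statistical structure the pipeline assumes: lognormal feature
abundances with factor-model correlation across features, pooled-QC
replicates inserted periodically into the injection sequence, blanks that
carry only contaminant features, per-sample dilution factors, smooth
multiplicative injection-order drift, per-batch offsets, multiplicative
noise, and two missingness mechanisms (censoring below a detection limit,
applied to the noise-free value so the threshold is a knowable ground-truth
property, and completely-at-random masking).

Every corrupting factor is stored in :class:`GroundTruth`, so each observed
cell factorizes exactly as ``true x dilution x drift x batch x noise`` —
the basis for recovery tests of filtering, imputation, normalization and
drift correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import CompoundRecord, formula_monoisotopic_mass
from .errors import ParameterError
from .model import FeatureMatrix, FeatureRecord, SampleRecord, SampleType


@dataclass
class SynthParams:
    """Generator settings; the defaults describe a modest single-batch run
    with mild drift and sparse missingness."""

    n_study: int = 40
    n_qc: int = 10
    n_blank: int = 3
    n_features: int = 60
    n_batches: int = 1
    qc_every: int = 5
    base_intensity_log_mean: float = 10.0
    base_intensity_log_sd: float = 1.5
    feature_correlation: float = 0.3
    bio_log_sd: float = 0.5
    drift_amplitude: float = 0.0
    batch_offsets: Sequence[float] | None = None
    noise_cv: float = 0.05
    lod_quantile: float = 0.0
    mcar_rate: float = 0.0
    contaminant_fraction: float = 0.05
    dilution_log_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_study, self.n_qc, self.n_blank, self.n_features) < 0:
            raise ParameterError("counts must be >= 0")
        if self.n_features < 1 or self.n_study < 1:
            raise ParameterError("need at least one study sample and one feature")
        if not 0 <= self.feature_correlation < 1:
            raise ParameterError("feature_correlation must be in [0, 1)")
        for name in ("lod_quantile", "mcar_rate", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ParameterError(f"{name} must be in [0, 1)")
        if self.qc_every < 1:
            raise ParameterError("qc_every must be >= 1")
        run_len = self.n_study + self.n_qc
        if self.n_qc > 0 and self.n_qc * self.qc_every > run_len:
            raise ParameterError(
                f"cannot place {self.n_qc} QCs every {self.qc_every} injections "
                f"in a run of {run_len}"
            )
        if self.batch_offsets is not None and len(self.batch_offsets) != self.n_batches:
            raise ParameterError("batch_offsets length must equal n_batches")


class MissingMechanism(Enum):
    OBSERVED = "observed"
    LOD = "lod"
    MCAR = "mcar"


@dataclass
class GroundTruth:
    """Everything needed to reconstruct each observed cell exactly."""

    true_intensities: pd.DataFrame  # samples x features, drift/dilution-free
    missing_mechanism: pd.DataFrame  # samples x features of MissingMechanism
    contaminant_feature_ids: list[str]
    drift_factors: pd.Series  # per sample
    batch_factors: pd.Series  # per sample
    noise_factors: pd.DataFrame  # samples x features
    true_dilution_factors: pd.Series  # per sample
    lod_threshold: float
    drift_curves: dict = field(default_factory=dict)  # batch -> (a, b) of g(t)=a+b*t

    def reconstruct(self) -> pd.DataFrame:
        """observed = true x dilution x drift x batch x noise (pre-censoring)."""
        scale = (
            self.true_dilution_factors * self.drift_factors * self.batch_factors
        )
        return self.true_intensities.mul(scale, axis=0) * self.noise_factors


def _injection_layout(params: SynthParams) -> list[tuple[str, SampleType]]:
    """Blanks first, then study injections with a QC every ``qc_every``-th
    position (the qc_every-th, 2*qc_every-th, ... injections of the run)."""
    layout: list[tuple[str, SampleType]] = [
        (f"BLK{i+1:02d}", SampleType.BLANK) for i in range(params.n_blank)
    ]
    run_len = params.n_study + params.n_qc
    qc_positions = {
        (i + 1) * params.qc_every for i in range(params.n_qc)
    }
    s = q = 0
    for pos in range(1, run_len + 1):
        if pos in qc_positions:
            q += 1
            layout.append((f"QC{q:02d}", SampleType.QC))
        else:
            s += 1
            layout.append((f"S{s:03d}", SampleType.STUDY))
    return layout


def generate_dataset(
    params: SynthParams,
) -> tuple[FeatureMatrix, list[SampleRecord], list[FeatureRecord], GroundTruth]:
    """Generate one synthetic run; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    layout = _injection_layout(params)
    n_total = len(layout)
    n_feat = params.n_features
    sample_ids = [sid for sid, _ in layout]
    types = [t for _, t in layout]

    # feature descriptors: m/z in a typical small-molecule range, RT in s
    mzs = np.sort(rng.uniform(80.0, 1000.0, size=n_feat))
    rts = rng.uniform(30.0, 1200.0, size=n_feat)
    feature_ids = [f"F{j+1:04d}" for j in range(n_feat)]
    features = [
        FeatureRecord(feature_id=fid, mz=float(m), rt=float(r))
        for fid, m, r in zip(feature_ids, mzs, rts)
    ]

    # base abundances: lognormal per feature, factor-model correlation rho
    mu = rng.normal(params.base_intensity_log_mean, params.base_intensity_log_sd, n_feat)
    rho = params.feature_correlation
    study_rows = [i for i, t in enumerate(types) if t is SampleType.STUDY]
    true = np.zeros((n_total, n_feat))
    for i in study_rows:
        u = rng.normal()
        eps = rng.normal(size=n_feat)
        delta = params.bio_log_sd * (np.sqrt(rho) * u + np.sqrt(1 - rho) * eps)
        true[i, :] = np.exp(mu + delta)

    # QCs replicate the pool (mean of study true intensities); blanks carry
    # only contaminants at sample-comparable intensity
    pool = true[study_rows, :].mean(axis=0)
    for i, t in enumerate(types):
        if t is SampleType.QC:
            true[i, :] = pool
    n_contam = int(round(params.contaminant_fraction * n_feat))
    contam_idx = rng.choice(n_feat, size=n_contam, replace=False) if n_contam else np.array([], dtype=int)
    contam_ids = [feature_ids[j] for j in sorted(contam_idx)]
    for i, t in enumerate(types):
        if t is SampleType.BLANK:
            if n_contam:
                true[i, contam_idx] = pool[contam_idx] * rng.lognormal(0.0, 0.1, n_contam)

    # per-sample dilution (QCs and blanks are aliquots of one pool: factor 1)
    dilution = np.ones(n_total)
    if params.dilution_log_sd > 0:
        for i in study_rows:
            dilution[i] = rng.lognormal(0.0, params.dilution_log_sd)

    # batches: contiguous chunks of the (non-blank) run; blanks go to batch 1
    run_rows = [i for i, t in enumerate(types) if t is not SampleType.BLANK]
    batch_of = np.zeros(n_total, dtype=int)
    chunks = np.array_split(np.array(run_rows), params.n_batches)
    for b, chunk in enumerate(chunks):
        batch_of[chunk] = b
    offsets = np.asarray(
        params.batch_offsets if params.batch_offsets is not None
        else np.ones(params.n_batches)
    )

    # smooth monotone multiplicative drift, linear within each batch
    orders = np.arange(1, n_total + 1, dtype=float)
    drift = np.ones(n_total)
    drift_curves: dict = {}
    if params.drift_amplitude != 0:
        for b, chunk in enumerate(chunks):
            if len(chunk) == 0:
                continue
            o = orders[chunk]
            span = max(o.max() - o.min(), 1.0)
            a = 1.0
            slope = params.drift_amplitude / span
            drift[chunk] = a + slope * (o - o.min())
            drift_curves[str(b + 1)] = (a, slope, float(o.min()))

    sigma = np.sqrt(np.log1p(params.noise_cv**2))
    noise = (
        rng.lognormal(-(sigma**2) / 2.0, sigma, size=(n_total, n_feat))
        if params.noise_cv > 0 else np.ones((n_total, n_feat))
    )

    scale = dilution * drift * offsets[batch_of]
    observed = true * scale[:, None] * noise

    # censoring: noise-free value below the LOD threshold -> MISSING (LOD)
    noise_free = true * scale[:, None]
    mechanism = np.full((n_total, n_feat), MissingMechanism.OBSERVED, dtype=object)
    positive = noise_free[noise_free > 0]
    lod = float(np.quantile(positive, params.lod_quantile)) if params.lod_quantile > 0 else 0.0
    if lod > 0:
        mechanism[(noise_free <= lod) & (noise_free > 0)] = MissingMechanism.LOD
    mechanism[noise_free == 0] = MissingMechanism.LOD  # undetected (true absence)
    if params.mcar_rate > 0:
        mcar = rng.random((n_total, n_feat)) < params.mcar_rate
        mechanism[mcar & (mechanism == MissingMechanism.OBSERVED)] = MissingMechanism.MCAR

    observed = observed.copy()
    observed[mechanism != MissingMechanism.OBSERVED] = np.nan

    samples = [
        SampleRecord(
            sample_id=sid,
            sample_type=t,
            batch=str(batch_of[i] + 1),
            injection_order=int(orders[i]),
            class_label=("case" if (t is SampleType.STUDY and i % 2 == 0) else
                         "control" if t is SampleType.STUDY else None),
        )
        for i, (sid, t) in enumerate(layout)
    ]
    matrix = FeatureMatrix(pd.DataFrame(observed, index=sample_ids, columns=feature_ids))
    truth = GroundTruth(
        true_intensities=pd.DataFrame(true, index=sample_ids, columns=feature_ids),
        missing_mechanism=pd.DataFrame(mechanism, index=sample_ids, columns=feature_ids),
        contaminant_feature_ids=contam_ids,
        drift_factors=pd.Series(drift, index=sample_ids),
        batch_factors=pd.Series(offsets[batch_of], index=sample_ids, dtype=float),
        noise_factors=pd.DataFrame(noise, index=sample_ids, columns=feature_ids),
        true_dilution_factors=pd.Series(dilution, index=sample_ids),
        lod_threshold=lod,
        drift_curves=drift_curves,
    )
    return matrix, samples, features, truth


# ---------------------------------------------------------------------------
# Presets

def preset(name: str, seed: int = 0) -> SynthParams:
    """Named study conditions used throughout the test suite.

    * ``clean`` — no drift, noise, batches or missingness; dilution only.
    * ``drifty`` — 200-injection single batch (160 study + 40 QCs every 5th
      injection), monotone multiplicative drift of amplitude 0.5, 50
      features, 5% multiplicative noise.
    * ``two-batch`` — the drifty run split into two blocks with a 2x offset
      on the second.
    * ``sparse`` — correlated features with LOD censoring and 10% MCAR.
    """
    if name == "clean":
        return SynthParams(
            n_study=20, n_qc=5, n_blank=2, n_features=30, qc_every=5,
            drift_amplitude=0.0, noise_cv=0.0, lod_quantile=0.0, mcar_rate=0.0,
            contaminant_fraction=0.1, dilution_log_sd=0.3, seed=seed,
        )
    if name == "drifty":
        return SynthParams(
            n_study=160, n_qc=40, n_blank=0, n_features=50, qc_every=5,
            drift_amplitude=0.5, noise_cv=0.05, lod_quantile=0.0,
            mcar_rate=0.0, contaminant_fraction=0.0, dilution_log_sd=0.0,
            seed=seed,
        )
    if name == "two-batch":
        return SynthParams(
            n_study=160, n_qc=40, n_blank=0, n_features=50, qc_every=5,
            n_batches=2, batch_offsets=(1.0, 2.0),
            drift_amplitude=0.5, noise_cv=0.05, lod_quantile=0.0,
            mcar_rate=0.0, contaminant_fraction=0.0, dilution_log_sd=0.0,
            seed=seed,
        )
    if name == "sparse":
        return SynthParams(
            n_study=100, n_qc=20, n_blank=3, n_features=40, qc_every=6,
            feature_correlation=0.7, drift_amplitude=0.0, noise_cv=0.05,
            lod_quantile=0.05, mcar_rate=0.10, contaminant_fraction=0.1,
            dilution_log_sd=0.2, seed=seed,
        )
    raise ParameterError(f"unknown preset {name!r}; choose clean/drifty/two-batch/sparse")


_CURATED_CORE = (
    ("SYN0001", "Water", "H2O"),
    ("SYN0002", "Glucose", "C6H12O6"),
    ("SYN0003", "Alanine", "C3H7NO2"),
    ("SYN0004", "Palmitic acid", "C16H32O2"),
    ("SYN0005", "Cholesterol", "C27H46O"),
)

_CHNOPS = ("C", "H", "N", "O", "P", "S")


def make_compound_fixture(n: int, seed: int = 0) -> list[CompoundRecord]:
    """``n`` compounds with valid CHNOPS formulas; the first five are a
    curated core with hand-verifiable masses, the rest random but valid."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[CompoundRecord] = []
    for cid, name, formula in _CURATED_CORE[:n]:
        records.append(
            CompoundRecord(
                compound_id=cid, name=name, formula=formula,
                monoisotopic_mass=formula_monoisotopic_mass(formula),
                source="custom",
            )
        )
    i = len(records)
    while len(records) < n:
        i += 1
        nc = int(rng.integers(2, 30))
        nh = int(rng.integers(nc, 2 * nc + 3))
        no = int(rng.integers(0, 8))
        nn = int(rng.integers(0, 4))
        np_ = int(rng.integers(0, 2))
        ns = int(rng.integers(0, 2))
        counts = dict(zip(_CHNOPS, (nc, nh, nn, no, np_, ns)))
        formula = "".join(f"{el}{c}" for el, c in counts.items() if c > 0)
        records.append(
            CompoundRecord(
                compound_id=f"SYN{i:04d}",
                name=f"synthetic compound {i}",
                formula=formula,
                monoisotopic_mass=formula_monoisotopic_mass(formula),
                source="custom",
            )
        )
    return records
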