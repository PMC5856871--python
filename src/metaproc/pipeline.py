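"""Config-driven pipeline runner.

Chains the processing stages in a configurable order — by default
QC filter → blank filter (when blanks exist) → imputation → normalization →
batch correction → annotation — each stage consuming the previous stage's
matrix. Stage reports are written as JSON lines, the processed matrix and
annotation table as CSV/TSV, and a human-readable log records parameters
and per-stage counts.

One global seed fans out deterministically to per-stage seeds
(``seed + stage index``), so a single stage re-run with its recorded seed
reproduces the pipeline's result for that stage.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import __version__
from .annotation import (
    ADDUCT_SETS,
    AnnotationHit,
    load_bundled_compounds,
    read_adduct_table,
    read_compound_table,
    search_accurate_mass,
    write_annotation_table,
)
from .batch_correction import RlscParams, correct_rlsc
from .errors import MetaprocError, ValidationError
from .filtering import BlankFilterParams, QcFilterParams, filter_by_blank, filter_by_qc
from .imputation import ImputationParams, impute
from .io import ColumnMapping, read_feature_table, read_sample_metadata, write_feature_table
from .model import FeatureMatrix, FeatureRecord, SampleRecord, StageReport
from .normalization import compute_reference_spectrum, normalize_pqn, normalize_sum

VALID_STAGES = (
    "qc_filter",
    "blank_filter",
    "impute",
    "normalize",
    "batch_correct",
    "annotate",
)

DEFAULT_STAGES = [
    {"name": "qc_filter"},
    {"name": "blank_filter"},
    {"name": "impute", "method": "knn"},
    {"name": "normalize", "method": "pqn"},
    {"name": "batch_correct"},
    {"name": "annotate"},
]


@dataclass
class PipelineConfig:
    feature_table: str
    sample_metadata: str
    output_dir: str = "metaproc_out"
    mapping: ColumnMapping = field(default_factory=ColumnMapping)
    stages: list[dict] = field(default_factory=lambda: [dict(s) for s in DEFAULT_STAGES])
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValidationError("stages: the stage list must be non-empty")
        for i, st in enumerate(self.stages):
            name = st.get("name")
            if name not in VALID_STAGES:
                raise ValidationError(
                    f"stages[{i}].name: unknown stage {name!r}; "
                    f"valid stages are {list(VALID_STAGES)}"
                )
        _validate_stage_params(self.stages)


def _validate_stage_params(stages: list[dict]) -> None:
    """Range-check stage parameters eagerly so errors name the field."""
    for i, st in enumerate(stages):
        opts = {k: v for k, v in st.items() if k != "name"}
        try:
            if st["name"] == "qc_filter":
                QcFilterParams(**opts)
            elif st["name"] == "blank_filter":
                BlankFilterParams(**opts)
            elif st["name"] == "impute":
                ImputationParams(**{"method": "knn", **opts})
            elif st["name"] == "batch_correct":
                RlscParams(**{k: v for k, v in opts.items() if k != "order"})
            elif st["name"] == "normalize":
                method = opts.get("method", "pqn")
                if method not in ("pqn", "sum"):
                    raise MetaprocError(f"method must be 'pqn' or 'sum', got {method!r}")
                if opts.get("reference", "qc") not in ("qc", "all"):
                    raise MetaprocError("reference must be 'qc' or 'all'")
            elif st["name"] == "annotate":
                if opts.get("adducts", "positive") not in ADDUCT_SETS and not os.path.exists(
                    str(opts.get("adducts", ""))
                ):
                    raise MetaprocError(
                        f"adducts must be one of {sorted(ADDUCT_SETS)} or an adduct TSV path"
                    )
                if not float(opts.get("ppm_tol", 5.0)) > 0:
                    raise MetaprocError("ppm_tol must be > 0")
        except TypeError as exc:
            raise ValidationError(f"stages[{i}] ({st['name']}): {exc}") from None
        except MetaprocError as exc:
            raise ValidationError(f"stages[{i}] ({st['name']}): {exc}") from None


def validate_config(path: str | os.PathLike) -> PipelineConfig:
    """Parse, default and schema-check a pipeline YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("pipeline config must be a YAML mapping")
    io_cfg = raw.get("io", {})
    for key in ("feature_table", "sample_metadata"):
        if key not in io_cfg:
            raise ValidationError(f"io.{key}: required path is missing")
    mapping_cfg = io_cfg.get("mapping", {})
    known = set(ColumnMapping.__dataclass_fields__)
    unknown = set(mapping_cfg) - known
    if unknown:
        raise ValidationError(f"io.mapping: unknown keys {sorted(unknown)}")
    mapping = ColumnMapping(**mapping_cfg)
    stages = raw.get("stages")
    if stages is None:
        stages = [dict(s) for s in DEFAULT_STAGES]
    if not isinstance(stages, list):
        raise ValidationError("stages must be a list of stage mappings")
    return PipelineConfig(
        feature_table=io_cfg["feature_table"],
        sample_metadata=io_cfg["sample_metadata"],
        output_dir=raw.get("output_dir", "metaproc_out"),
        mapping=mapping,
        stages=stages,
        seed=int(raw.get("seed", 0)),
    )


def _run_stage(
    stage: dict,
    index: int,
    matrix: FeatureMatrix,
    samples: Sequence[SampleRecord],
    features: Sequence[FeatureRecord],
    seed: int,
) -> tuple[FeatureMatrix, list[AnnotationHit] | None, StageReport]:
    name = stage["name"]
    opts = {k: v for k, v in stage.items() if k != "name"}
    stage_seed = (seed + index) % (2**31 - 1)
    if name == "qc_filter":
        out, report = filter_by_qc(matrix, samples, QcFilterParams(**opts))
        return out, None, report
    if name == "blank_filter":
        out, report = filter_by_blank(matrix, samples, BlankFilterParams(**opts))
        return out, None, report
    if name == "impute":
        params = ImputationParams(**{"method": "knn", **opts, "seed": opts.get("seed", stage_seed)})
        out, report = impute(matrix, params)
        return out, None, report
    if name == "normalize":
        method = opts.get("method", "pqn")
        if method == "sum":
            out, report = normalize_sum(matrix)
        else:
            ref = compute_reference_spectrum(
                matrix, samples, source=opts.get("reference", "qc")
            )
            out, report = normalize_pqn(matrix, ref)
        return out, None, report
    if name == "batch_correct":
        params = RlscParams(**{**opts, "seed": opts.get("seed", stage_seed)})
        out, report = correct_rlsc(matrix, samples, params)
        return out, None, report
    if name == "annotate":
        db_path = opts.get("db")
        db = read_compound_table(db_path) if db_path else load_bundled_compounds()
        adducts_opt = opts.get("adducts", "positive")
        adducts = (
            ADDUCT_SETS[adducts_opt]
            if adducts_opt in ADDUCT_SETS
            else read_adduct_table(adducts_opt)
        )
        present = set(matrix.feature_ids)
        feats = [f for f in features if f.feature_id in present]
        hits = search_accurate_mass(feats, db, adducts, float(opts.get("ppm_tol", 5.0)))
        report = StageReport(
            stage_name="annotation",
            parameters={
                "db": db_path or "bundled",
                "adducts": str(adducts_opt),
                "ppm_tol": float(opts.get("ppm_tol", 5.0)),
            },
            n_features_in=matrix.shape[1],
            n_features_out=matrix.shape[1],
            n_samples_in=matrix.shape[0],
            n_samples_out=matrix.shape[0],
            extra={
                "n_hits": len(hits),
                "n_annotated_features": len({h.feature_id for h in hits}),
                "n_unannotated_features": matrix.shape[1]
                - len({h.feature_id for h in hits}),
            },
        )
        return matrix, hits, report
    raise ValidationError(f"unknown stage {name!r}")


def run_pipeline(
    config: PipelineConfig,
) -> tuple[FeatureMatrix, list[AnnotationHit], list[StageReport]]:
    """Run all configured stages and write outputs to ``config.output_dir``.

    Outputs: ``processed_matrix.csv`` (features x samples, the export
    layout), ``annotations.tsv`` when an annotate stage ran,
    ``reports.jsonl`` (one JSON object per stage, timestamp-free so runs
    are byte-reproducible) and ``run.log`` (timestamped, human-readable).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {msg}")

    log(f"metaproc {__version__} starting; seed={config.seed}")
    matrix, features = read_feature_table(config.feature_table, config.mapping)
    samples = read_sample_metadata(config.sample_metadata)
    known = set(matrix.sample_ids)
    samples = [s for s in samples if s.sample_id in known]
    log(
        f"loaded {matrix.shape[0]} samples x {matrix.shape[1]} features "
        f"({matrix.n_missing()} missing cells)"
    )

    reports: list[StageReport] = []
    hits: list[AnnotationHit] = []
    skipped: list[str] = []
    from .model import SampleType, sample_ids_of_type  # local to avoid cycle noise

    for i, stage in enumerate(config.stages):
        name = stage["name"]
        if name == "blank_filter" and not sample_ids_of_type(samples, SampleType.BLANK):
            skipped.append(name)
            log(f"stage {i} ({name}): skipped, run has no blank samples")
            continue
        try:
            matrix, stage_hits, report = _run_stage(
                stage, i, matrix, samples, features, config.seed
            )
        except MetaprocError as exc:
            log(f"stage {i} ({name}) FAILED: {exc}")
            _write_log(out_dir, log_lines)
            raise MetaprocError(f"stage {i} ({name}) failed: {exc}") from exc
        if stage_hits is not None:
            hits = stage_hits
        reports.append(report)
        log(
            f"stage {i} ({name}): {report.n_features_in} -> {report.n_features_out} "
            f"features, parameters={json.dumps(report.to_dict(include_timestamp=False)['parameters'], sort_keys=True)}"
        )

    keep = set(matrix.feature_ids)
    final_features = [f for f in features if f.feature_id in keep]
    write_feature_table(matrix, final_features, out_dir / "processed_matrix.csv")
    if any(s["name"] == "annotate" for s in config.stages):
        write_annotation_table(hits, final_features, out_dir / "annotations.tsv")
    with open(out_dir / "reports.jsonl", "w") as fh:
        for r in reports:
            fh.write(json.dumps(r.to_dict(include_timestamp=False), sort_keys=True) + "\n")
    log(f"done: {matrix.shape[0]} samples x {matrix.shape[1]} features, {len(hits)} annotation hits")
    _write_log(out_dir, log_lines)
    return matrix, hits, reports


def _write_log(out_dir: Path, lines: list[str]) -> None:
    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(lines) + "\n")
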