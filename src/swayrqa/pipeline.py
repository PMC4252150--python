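"""End-to-end orchestration: cohort directory → feature table → correlations.

``run_pipeline`` reads a cohort directory laid out as written by
:func:`swayrqa.synthetic_data.gen_cohort` (one sub-directory per subject with
quiet-stance and flow traces + manifests, throttle CSVs and a ratings index),
computes every per-subject sway and vection feature, assembles the feature
table, runs the correlation table and paired contrasts, and writes
``features.csv``, ``correlations.csv`` and ``report.yaml`` to the output
directory. A subject with missing files keeps NaN in the affected features
(with a logged warning) rather than aborting the run.

``compute_subject_features`` is the in-memory workhorse, usable without any
disk I/O — e.g. directly on generator output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .errors import SwayError
from .io_sessions import (
    CoPTrace,
    SessionManifest,
    VectionRecord,
    read_cop_trace,
    read_manifest,
    read_throttle,
    write_feature_table,
)
from .linear_measures import log_area_ratio, romberg_ratio, sway_summary
from .preprocess import FilterSpec, boxcar_downsample, butterworth_filter
from .rqa import RQAParams, analyze_series, series_recurrence_rate
from .stats import TABLE_LINEAR_PAIRS, TABLE_RQA_PAIRS, correlation_table, paired_t
from .vepr_vection import aggregate_vection, compute_vepr

__all__ = ["PipelineConfig", "PipelineResult", "compute_subject_features", "run_pipeline"]

log = logging.getLogger(__name__)

#: RQA feature columns that require the full recurrence matrix.
_FULL_RQA_FEATURES = ("det_eo", "det_ec", "lam_eo", "lam_ec")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run depends on, recorded in the run report."""

    input_dir: str | Path = "."
    output_dir: str | Path = "out"
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    boxcar_width: int = 10
    rqa_params: RQAParams = field(default_factory=RQAParams)
    latency_cutoff: float = 5.0
    rqa_full: bool = True  # False: recurrence rate only (no DET/LAM), much faster
    pairs: tuple = tuple(TABLE_RQA_PAIRS + TABLE_LINEAR_PAIRS)


@dataclass
class PipelineResult:
    features: pd.DataFrame
    correlations: pd.DataFrame
    report: dict


def _quiet_features(
    trace: CoPTrace, config: PipelineConfig, suffix: str, out: dict
) -> None:
    filtered = butterworth_filter(trace, config.filter_spec)
    summary = sway_summary(filtered)
    out[f"path_{suffix}"] = summary.path_length
    out[f"area_{suffix}"] = summary.area
    reduced = boxcar_downsample(filtered, config.boxcar_width)
    if config.rqa_full:
        res = analyze_series(reduced.ap, config.rqa_params)
        out[f"rr_{suffix}"] = res.rr
        out[f"det_{suffix}"] = res.det
        out[f"lam_{suffix}"] = res.lam
    else:
        out[f"rr_{suffix}"] = series_recurrence_rate(reduced.ap, config.rqa_params)


def compute_subject_features(
    subject_id: str,
    config: PipelineConfig,
    quiet_open: CoPTrace | None = None,
    quiet_closed: CoPTrace | None = None,
    flow_expanding: tuple[CoPTrace, SessionManifest] | None = None,
    flow_contracting: tuple[CoPTrace, SessionManifest] | None = None,
    vection_expanding: list[VectionRecord] | None = None,
    vection_contracting: list[VectionRecord] | None = None,
) -> dict:
    """One feature-table row from in-memory session data.

    Absent inputs leave their features as NaN; derived ratios need both
    quiet-stance conditions.
    """
    row: dict = {"subject_id": subject_id}
    if quiet_open is not None:
        _quiet_features(quiet_open, config, "eo", row)
    if quiet_closed is not None:
        _quiet_features(quiet_closed, config, "ec", row)
    if quiet_open is not None and quiet_closed is not None:
        row["romberg"] = romberg_ratio(row["path_ec"], row["path_eo"])
        row["log_area_ratio"] = log_area_ratio(row["area_eo"], row["area_ec"])
        row["rr_diff"] = row["rr_eo"] - row["rr_ec"]
    for direction, session in (
        ("expanding", flow_expanding),
        ("contracting", flow_contracting),
    ):
        if session is not None:
            trace, manifest = session
            filtered = butterworth_filter(trace, config.filter_spec)
            row[f"vepr_{direction}"] = compute_vepr(filtered, manifest, direction).mean_vepr
    for direction, records in (
        ("expanding", vection_expanding),
        ("contracting", vection_contracting),
    ):
        if records:
            summary = aggregate_vection(records, cutoff=config.latency_cutoff)
            row[f"verbal_{direction}"] = summary.verbal_mean
            row[f"throttle_max_{direction}"] = summary.throttle_max_mean
            row[f"latency_{direction}"] = summary.latency_mean
    return row


def _load_quiet(sdir: Path, eyes: str, rate_hint: float | None):
    manifest_path = sdir / f"quiet_{eyes}.yaml"
    if manifest_path.exists():
        manifest = read_manifest(manifest_path)
        return read_cop_trace(
            sdir / manifest.trace_file,
            rate=manifest.rate,
            ap_forward_sign=manifest.ap_forward_sign,
        )
    csv_path = sdir / f"quiet_{eyes}.csv"
    if csv_path.exists():
        return read_cop_trace(csv_path, rate=rate_hint)
    return None


def _load_flow(sdir: Path, direction: str):
    manifest_path = sdir / f"flow_{direction}.yaml"
    if not manifest_path.exists():
        return None
    manifest = read_manifest(manifest_path)
    trace = read_cop_trace(
        sdir / manifest.trace_file,
        rate=manifest.rate,
        ap_forward_sign=manifest.ap_forward_sign,
    )
    return trace, manifest


def _load_vection(sdir: Path, subject_id: str) -> dict[str, list[VectionRecord]]:
    ratings_path = sdir / "ratings.csv"
    out: dict[str, list[VectionRecord]] = {"expanding": [], "contracting": []}
    if not ratings_path.exists():
        return out
    ratings = pd.read_csv(ratings_path)
    for _, rec in ratings.iterrows():
        t, level = read_throttle(sdir / rec["throttle_file"])
        out[rec["condition"]].append(
            VectionRecord(
                subject_id=subject_id,
                condition=rec["condition"],
                trial_index=int(rec["trial_index"]),
                throttle_time=t,
                throttle_level=level,
                verbal=float(rec["verbal"]),
            )
        )
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis over a cohort directory.

    Deterministic for fixed inputs and config; the report records every
    parameter, per-subject warnings, and the number of correlations
    computed (no multiplicity adjustment is applied — consumers can).
    """
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise SwayError(f"input directory {input_dir} does not exist")
    subject_dirs = sorted(d for d in input_dir.iterdir() if d.is_dir())
    if not subject_dirs:
        raise SwayError(f"no subject directories under {input_dir}")

    rows: list[dict] = []
    warnings: list[str] = []
    for sdir in subject_dirs:
        subject_id = sdir.name
        kwargs: dict = {}
        try:
            kwargs["quiet_open"] = _load_quiet(sdir, "open", None)
            kwargs["quiet_closed"] = _load_quiet(sdir, "closed", None)
            kwargs["flow_expanding"] = _load_flow(sdir, "expanding")
            kwargs["flow_contracting"] = _load_flow(sdir, "contracting")
            vection = _load_vection(sdir, subject_id)
            kwargs["vection_expanding"] = vection["expanding"]
            kwargs["vection_contracting"] = vection["contracting"]
        except SwayError as exc:
            raise type(exc)(f"stage load, subject {subject_id}: {exc}") from exc
        for key, value in kwargs.items():
            if value is None or value == []:
                msg = f"{subject_id}: missing {key}; dependent features set to NaN"
                warnings.append(msg)
                log.warning(msg)
        try:
            rows.append(compute_subject_features(subject_id, config, **kwargs))
        except SwayError as exc:
            raise type(exc)(f"stage features, subject {subject_id}: {exc}") from exc

    features = pd.DataFrame(rows)
    pairs = [p for p in config.pairs if p[0] in features.columns and p[1] in features.columns]
    results = correlation_table(features, pairs)
    correlations = pd.DataFrame(
        [
            {"feature": r.feature, "outcome": r.outcome, "r": r.r, "p": r.p,
             "n": r.n, "note": r.note}
            for r in results
        ]
    )

    contrasts: dict[str, dict] = {}
    for name, a_col, b_col in (
        ("path_closed_vs_open", "path_ec", "path_eo"),
        ("verbal_contracting_vs_expanding", "verbal_contracting", "verbal_expanding"),
    ):
        if a_col in features.columns and b_col in features.columns:
            try:
                res = paired_t(features[a_col], features[b_col])
                contrasts[name] = {
                    "mean_diff": res.mean_diff, "t": res.t, "df": res.df, "p": res.p,
                }
            except SwayError as exc:
                contrasts[name] = {"error": str(exc)}

    report = {
        "swayrqa_version": _pkg_version,
        "input_dir": str(input_dir),
        "n_subjects": len(features),
        "filter": {
            "order": config.filter_spec.order,
            "cutoff_hz": config.filter_spec.cutoff_hz,
        },
        "boxcar_width": config.boxcar_width,
        "rqa": {
            "m": config.rqa_params.m,
            "tau": config.rqa_params.tau,
            "radius": config.rqa_params.radius,
            "lmin": config.rqa_params.lmin,
            "norm": config.rqa_params.norm,
            "theiler": config.rqa_params.theiler,
            "radius_mode": config.rqa_params.radius_mode,
            "full_measures": config.rqa_full,
        },
        "latency_cutoff_pct": config.latency_cutoff,
        "n_correlations": len(correlations),
        "multiplicity_adjustment": "none",
        "paired_contrasts": contrasts,
        "warnings": warnings,
    }

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_feature_table(features, out_dir / "features.csv")
    correlations.to_csv(out_dir / "correlations.csv", index=False, float_format="%.6g")
    with open(out_dir / "report.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)

    return PipelineResult(features=features, correlations=correlations, report=report)
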