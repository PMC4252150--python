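"""Visually-evoked postural responses (VEPRs) and vection summaries.

A VEPR is the shift of mean anterior-posterior CoP position during an
optic-flow block relative to the block immediately before it (which controls
for slow postural drift). With the forward-positive convention, expanding
flow — simulating forward self-motion — typically drives *backward*
(negative) sway and contracting flow forward (positive) sway.

Vection strength per trial is summarised from the throttle trace (maximum
deflection, and latency = first time the rating reaches a cutoff, 5% by
default) and the end-of-trial verbal rating; trials aggregate to per-subject,
per-direction means. A trial whose throttle never reaches the cutoff has a
*missing* latency — a value, not an error — and such trials are excluded
(and counted) when averaging latencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ScheduleError
from .io_sessions import BlockLabel, CoPTrace, SessionManifest, VectionRecord
from .preprocess import segment_session

__all__ = [
    "VEPR",
    "VectionSummary",
    "compute_vepr",
    "throttle_max",
    "throttle_latency",
    "aggregate_vection",
]


@dataclass(frozen=True)
class VEPR:
    """Per-repeat and mean flow-evoked AP shifts, forward-positive mm."""

    subject_id: str
    flow_direction: str  # "expanding" | "contracting"
    per_repeat: tuple[float, ...]
    mean_vepr: float


@dataclass(frozen=True)
class VectionSummary:
    """Per-subject, per-direction vection outcome means."""

    subject_id: str
    condition: str
    verbal_mean: float
    throttle_max_mean: float
    latency_mean: float  # NaN if no trial ever crossed the cutoff
    n_trials: int
    n_latency_missing: int


def compute_vepr(
    trace: CoPTrace, manifest: SessionManifest, flow_direction: str | None = None
) -> VEPR:
    """Mean AP shift of each flow block against its preceding block.

    Requires every flow block to have a block before it (the first block of
    the session schedule must not be flow). Adding a constant to the whole
    AP channel leaves the result unchanged.
    """
    segments = segment_session(trace, manifest)
    if flow_direction is None:
        flow_direction = (
            "expanding" if "expanding" in manifest.condition.value else "contracting"
        )
    diffs: list[float] = []
    for i, seg in enumerate(segments):
        if seg.label is not BlockLabel.FLOW:
            continue
        if i == 0:
            raise ScheduleError(
                f"flow block at schedule position 0 has no preceding baseline "
                f"({manifest.subject_id})"
            )
        baseline = segments[i - 1]
        flow_mean = float(np.mean(trace.ap[seg.start : seg.end]))
        base_mean = float(np.mean(trace.ap[baseline.start : baseline.end]))
        diffs.append(flow_mean - base_mean)
    if not diffs:
        raise ScheduleError(f"no flow blocks in manifest for {manifest.subject_id}")
    return VEPR(
        subject_id=manifest.subject_id,
        flow_direction=flow_direction,
        per_repeat=tuple(diffs),
        mean_vepr=float(np.mean(diffs)),
    )


def throttle_max(record: VectionRecord) -> float:
    """Maximum throttle deflection (percent) over the trial."""
    if len(record.throttle_level) == 0:
        raise DataError("empty throttle trace")
    return float(np.max(record.throttle_level))


def throttle_latency(record: VectionRecord, cutoff: float = 5.0) -> float:
    """Time (s) of the first sample at or above ``cutoff`` percent; NaN if never."""
    if len(record.throttle_level) == 0:
        raise DataError("empty throttle trace")
    hits = np.flatnonzero(record.throttle_level >= cutoff)
    if hits.size == 0:
        return math.nan
    return float(record.throttle_time[hits[0]])


def aggregate_vection(
    records: list[VectionRecord], cutoff: float = 5.0
) -> VectionSummary:
    """Average verbal, throttle-max and latency over one subject/direction.

    Latency is averaged only over trials where the cutoff was reached; the
    number of missing-latency trials is reported alongside.
    """
    if not records:
        raise DataError("no vection records to aggregate")
    subject = records[0].subject_id
    condition = records[0].condition
    if any(r.subject_id != subject or r.condition != condition for r in records):
        raise DataError("records mix subjects or flow directions")
    verbal = float(np.mean([r.verbal for r in records]))
    tmax = float(np.mean([throttle_max(r) for r in records]))
    latencies = np.array([throttle_latency(r, cutoff=cutoff) for r in records])
    defined = latencies[np.isfinite(latencies)]
    return VectionSummary(
        subject_id=subject,
        condition=condition,
        verbal_mean=verbal,
        throttle_max_mean=tmax,
        latency_mean=float(np.mean(defined)) if defined.size else math.nan,
        n_trials=len(records),
        n_latency_missing=int(len(records) - defined.size),
    )
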