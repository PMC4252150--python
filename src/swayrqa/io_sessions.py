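"""Reading and writing force-plate sessions in plain-text formats.

Centre-of-pressure (CoP) traces, throttle vection ratings and the derived
per-subject feature table are stored as UTF-8 comma-separated files with a
header row and ``.`` decimals; session manifests are YAML mappings. No vendor
binary formats are supported — exporting to CSV is the acquisition software's
job.

Conventions
-----------
* CoP is stored in **millimetres**, anterior-posterior (AP) **forward
  positive**, medial-lateral (ML) rightward positive. Plotting traditions in
  posturography often draw forward sway as negative y; conversion happens at
  read time via the manifest flag ``ap_forward_sign`` (``-1`` flips an
  export that uses the negative-forward convention), never downstream.
* Sampling must be uniform: hardware-clocked plates are, and resampling is
  deliberately out of scope, so a non-uniform time column is an error rather
  than something to silently repair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConsistencyError, DataError, FormatError, ParameterError

__all__ = [
    "Condition",
    "BlockLabel",
    "CoPTrace",
    "SessionManifest",
    "VectionRecord",
    "FEATURE_COLUMNS",
    "read_cop_trace",
    "write_cop_trace",
    "read_manifest",
    "write_manifest",
    "read_throttle",
    "write_throttle",
    "read_feature_table",
    "write_feature_table",
    "validate_feature_table",
]

log = logging.getLogger(__name__)

#: Tolerance on the deviation of each time step from 1/rate, in seconds.
TIME_STEP_TOL = 1e-9


class Condition(str, Enum):
    """Experimental conditions a session manifest can declare."""

    QUIET_EYES_OPEN = "quiet_eyes_open"
    QUIET_EYES_CLOSED = "quiet_eyes_closed"
    STANDING_FLOW_EXPANDING = "standing_flow_expanding"
    STANDING_FLOW_CONTRACTING = "standing_flow_contracting"
    SEATED_VECTION_EXPANDING = "seated_vection_expanding"
    SEATED_VECTION_CONTRACTING = "seated_vection_contracting"


class BlockLabel(str, Enum):
    BLANK = "blank"
    FLOW = "flow"
    FIXATION = "fixation"


@dataclass(frozen=True)
class CoPTrace:
    """A uniformly sampled two-channel centre-of-pressure trajectory.

    Parameters
    ----------
    time : array of seconds, strictly increasing with constant step 1/rate.
    ap : anterior-posterior CoP in millimetres, forward positive.
    ml : medial-lateral CoP in millimetres, rightward positive.
    rate : sampling rate in Hz.
    """

    time: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        ap = np.asarray(self.ap, dtype=float)
        ml = np.asarray(self.ml, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "ap", ap)
        object.__setattr__(self, "ml", ml)
        if self.rate <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.rate}")
        if not (len(time) == len(ap) == len(ml)):
            raise DataError(
                f"channel lengths differ: time={len(time)} ap={len(ap)} ml={len(ml)}"
            )
        if len(time) < 2:
            raise DataError("a CoP trace needs at least 2 samples")
        dt = np.diff(time)
        if np.any(dt <= 0):
            raise DataError("time must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.rate)) > TIME_STEP_TOL:
            raise DataError(
                f"non-uniform sampling: time steps deviate from 1/{self.rate} Hz "
                f"by more than {TIME_STEP_TOL} s"
            )
        if not (np.all(np.isfinite(ap)) and np.all(np.isfinite(ml))):
            raise DataError("ap/ml contain non-finite values")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Covered duration in seconds, counting one step past the last sample."""
        return len(self) / self.rate

    def with_channels(self, ap: np.ndarray, ml: np.ndarray) -> "CoPTrace":
        """Same clock, new channel values (used by filters)."""
        return CoPTrace(time=self.time, ap=ap, ml=ml, rate=self.rate)


@dataclass(frozen=True)
class SessionManifest:
    """Metadata binding a CoP trace to its experimental structure."""

    subject_id: str
    condition: Condition
    rate: float
    blocks: tuple = ()  # tuple of (BlockLabel, duration_s)
    trace_file: str | None = None
    ap_forward_sign: int = 1

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ParameterError("manifest rate must be positive")
        if self.ap_forward_sign not in (1, -1):
            raise ParameterError("ap_forward_sign must be +1 or -1")
        blocks = []
        for label, dur in self.blocks:
            label = BlockLabel(label)
            dur = float(dur)
            if dur <= 0:
                raise ParameterError(f"block duration must be > 0, got {dur}")
            blocks.append((label, dur))
        object.__setattr__(self, "blocks", tuple(blocks))
        if self.condition in (
            Condition.STANDING_FLOW_EXPANDING,
            Condition.STANDING_FLOW_CONTRACTING,
        ) and not self.blocks:
            raise ParameterError(
                f"{self.condition.value} requires a non-empty block schedule"
            )

    @property
    def schedule_duration(self) -> float:
        return float(sum(d for _, d in self.blocks))


@dataclass(frozen=True)
class VectionRecord:
    """One seated-vection trial: throttle trace plus end-of-trial verbal rating.

    Throttle levels are percent of full deflection in [0, 100], sampled from
    trial (stimulus) onset; the verbal rating is the 0–100 magnitude estimate
    given after the trial.
    """

    subject_id: str
    condition: str  # "expanding" | "contracting"
    trial_index: int
    throttle_time: np.ndarray
    throttle_level: np.ndarray
    verbal: float

    def __post_init__(self) -> None:
        t = np.asarray(self.throttle_time, dtype=float)
        lv = np.asarray(self.throttle_level, dtype=float)
        object.__setattr__(self, "throttle_time", t)
        object.__setattr__(self, "throttle_level", lv)
        if self.condition not in ("expanding", "contracting"):
            raise ParameterError(f"unknown flow direction {self.condition!r}")
        if self.trial_index < 1:
            raise ParameterError("trial_index starts at 1")
        if len(t) != len(lv):
            raise DataError("throttle time/level length mismatch")
        if len(t) and np.any(np.diff(t) <= 0):
            raise DataError("throttle time must be strictly increasing")
        if len(lv) and (np.min(lv) < 0 or np.max(lv) > 100):
            raise DataError("throttle levels must lie in [0, 100]")
        if not 0 <= self.verbal <= 100:
            raise DataError(f"verbal rating {self.verbal} outside [0, 100]")


#: Stable column order of the per-subject feature table.
FEATURE_COLUMNS = [
    "path_eo",
    "path_ec",
    "romberg",
    "area_eo",
    "area_ec",
    "log_area_ratio",
    "vepr_expanding",
    "vepr_contracting",
    "rr_eo",
    "rr_ec",
    "rr_diff",
    "det_eo",
    "det_ec",
    "lam_eo",
    "lam_ec",
    "verbal_expanding",
    "verbal_contracting",
    "throttle_max_expanding",
    "throttle_max_contracting",
    "latency_expanding",
    "latency_contracting",
]


# ---------------------------------------------------------------------------
# CoP traces
# ---------------------------------------------------------------------------

def read_cop_trace(
    path: str | Path,
    rate: float | None = None,
    ap_forward_sign: int = 1,
) -> CoPTrace:
    """Read a CoP trace from a CSV with columns ``time``, ``ap``, ``ml``.

    ``rate`` may be given explicitly (the file's time column is then checked
    against it) or omitted, in which case it is inferred from the median time
    step. ``ap_forward_sign=-1`` flips an export using the negative-forward
    plotting convention into the internal forward-positive one.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty trace file: {path}") from exc
    missing = {"time", "ap", "ml"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if len(df) == 0:
        raise DataError(f"{path}: no data rows")
    time = df["time"].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        raise DataError(f"{path}: time column not strictly increasing")
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(time)))
    trace = CoPTrace(
        time=time,
        ap=ap_forward_sign * df["ap"].to_numpy(dtype=float),
        ml=df["ml"].to_numpy(dtype=float),
        rate=float(rate),
    )
    log.debug("read %d CoP samples at %g Hz from %s", len(trace), trace.rate, path)
    return trace


def write_cop_trace(trace: CoPTrace, path: str | Path) -> None:
    """Write a trace as CSV; numeric round-trip is lossless to 1e-9."""
    df = pd.DataFrame({"time": trace.time, "ap": trace.ap, "ml": trace.ml})
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path, check_trace: bool = True) -> SessionManifest:
    """Read a YAML session manifest.

    When ``check_trace`` is true and the manifest names a trace file, the
    block schedule is verified to fit inside the trace duration.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such manifest: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise FormatError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: manifest must be a mapping")
    try:
        condition = Condition(raw["condition"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing key {exc}") from exc
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    try:
        manifest = SessionManifest(
            subject_id=str(raw["subject_id"]),
            condition=condition,
            rate=float(raw["rate"]),
            blocks=tuple((b[0], float(b[1])) for b in raw.get("blocks", []) or []),
            trace_file=raw.get("trace_file"),
            ap_forward_sign=int(raw.get("ap_forward_sign", 1)),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing key {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if check_trace and manifest.trace_file is not None:
        trace_path = (path.parent / manifest.trace_file).resolve()
        if trace_path.exists():
            trace = read_cop_trace(trace_path, rate=manifest.rate)
            if manifest.schedule_duration > trace.duration + TIME_STEP_TOL:
                raise ConsistencyError(
                    f"{path}: block schedule ({manifest.schedule_duration} s) "
                    f"exceeds trace duration ({trace.duration} s)"
                )
    return manifest


def write_manifest(manifest: SessionManifest, path: str | Path) -> None:
    doc = {
        "subject_id": manifest.subject_id,
        "condition": manifest.condition.value,
        "rate": manifest.rate,
        "blocks": [[label.value, dur] for label, dur in manifest.blocks],
        "trace_file": manifest.trace_file,
        "ap_forward_sign": manifest.ap_forward_sign,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Throttle traces
# ---------------------------------------------------------------------------

def read_throttle(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (time_s, throttle_pct) CSV; levels outside [0, 100] are an error."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty throttle file: {path}") from exc
    missing = {"time_s", "throttle_pct"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    lv = df["throttle_pct"].to_numpy(dtype=float)
    if len(t) == 0:
        raise DataError(f"{path}: no data rows")
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: time not strictly increasing")
    if np.min(lv) < 0 or np.max(lv) > 100:
        raise DataError(f"{path}: throttle level outside [0, 100]")
    return t, lv


def write_throttle(time_s: np.ndarray, level_pct: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"time_s": time_s, "throttle_pct": level_pct}).to_csv(
        path, index=False, float_format="%.12g"
    )


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a per-subject feature table.

    Requires a ``subject_id`` column with unique entries; reorders known
    feature columns into the stable order; checks sign constraints on the
    finite values (paths/areas/ratios strictly positive, recurrence rates in
    (0, 1]). Missing values stay as NaN.
    """
    if "subject_id" not in table.columns:
        raise FormatError("feature table needs a subject_id column")
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise DataError(f"duplicate subject_id(s): {dupes}")
    ordered = ["subject_id"] + [c for c in FEATURE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in ordered]
    table = table[ordered + extra].copy()
    positive = ["path_eo", "path_ec", "romberg", "area_eo", "area_ec"]
    for col in positive:
        if col in table.columns:
            vals = table[col].to_numpy(dtype=float)
            bad = np.isfinite(vals) & (vals <= 0)
            if bad.any():
                raise DataError(f"column {col}: non-positive finite value(s)")
    for col in ("rr_eo", "rr_ec"):
        if col in table.columns:
            vals = table[col].to_numpy(dtype=float)
            bad = np.isfinite(vals) & ((vals <= 0) | (vals > 1))
            if bad.any():
                raise DataError(f"column {col}: recurrence rate outside (0, 1]")
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the feature table as CSV; NaN serialises as an empty field."""
    validate_feature_table(table).to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return validate_feature_table(pd.read_csv(path))
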