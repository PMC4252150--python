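"""Conditioning of raw CoP traces: filtering, boxcar averaging, segmentation.

The pipeline order is: zero-phase Butterworth low-pass on the 1000 Hz trace,
then (for the recurrence branch only) non-overlapping 10-sample boxcar
averaging down to 100 Hz. Linear measures run on the filtered, un-reduced
trace; recurrence measures run on the reduced one, where the default
embedding delay of 15 samples spans 150 ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConsistencyError, DataError, ParameterError, ScheduleError
from .io_sessions import BlockLabel, CoPTrace, SessionManifest

__all__ = [
    "FilterSpec",
    "Segment",
    "butterworth_filter",
    "boxcar_downsample",
    "segment_session",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification.

    CoP signal energy in quiet stance sits below a few Hz, so the default
    10 Hz cutoff removes measurement noise while leaving sway untouched. The
    filter is applied forward-backward (zero phase), so the effective
    magnitude response is the squared Butterworth response.
    """

    order: int = 5
    cutoff_hz: float = 10.0
    kind: str = "lowpass"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError(f"filter order must be >= 1, got {self.order}")
        if self.cutoff_hz <= 0:
            raise ParameterError("cutoff must be positive")
        if self.kind != "lowpass":
            raise ParameterError(f"unsupported filter kind {self.kind!r}")


@dataclass(frozen=True)
class Segment:
    """Half-open sample range [start, end) carrying a block label."""

    label: BlockLabel
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ParameterError(f"invalid segment bounds [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def butterworth_filter(trace: CoPTrace, spec: FilterSpec | None = None) -> CoPTrace:
    """Zero-phase low-pass both channels; clock and length are unchanged."""
    spec = spec or FilterSpec()
    nyquist = trace.rate / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ParameterError(
            f"cutoff {spec.cutoff_hz} Hz >= Nyquist {nyquist} Hz at rate {trace.rate}"
        )
    if len(trace) <= 3 * spec.order:
        raise DataError(
            f"trace of {len(trace)} samples too short for order-{spec.order} "
            "zero-phase filtering"
        )
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=trace.rate, output="sos")
    return trace.with_channels(
        ap=signal.sosfiltfilt(sos, trace.ap),
        ml=signal.sosfiltfilt(sos, trace.ml),
    )


def boxcar_downsample(trace: CoPTrace, width: int, mode: str = "decimate") -> CoPTrace:
    """Average over ``width``-sample boxcar windows.

    ``decimate`` (default) takes non-overlapping windows — true downsampling
    to rate/width, discarding (and logging) any trailing remainder shorter
    than one window. ``moving`` applies a centred moving average of the same
    width at the original rate, for diagnostics.
    """
    if width < 1:
        raise ParameterError(f"boxcar width must be >= 1, got {width}")
    if len(trace) < width:
        raise DataError(f"trace of {len(trace)} samples shorter than width {width}")
    if mode not in ("decimate", "moving"):
        raise ParameterError(f"unknown boxcar mode {mode!r}")
    if width == 1:
        return trace
    if mode == "moving":
        kernel = np.ones(width) / width
        pad = width // 2
        ap = np.convolve(trace.ap, kernel, mode="same")
        ml = np.convolve(trace.ml, kernel, mode="same")
        # edges are partial-window artifacts; keep length, document in methods
        return trace.with_channels(ap=ap, ml=ml)
    n_windows = len(trace) // width
    dropped = len(trace) - n_windows * width
    if dropped:
        log.info("boxcar_downsample: discarding %d trailing sample(s)", dropped)
    take = n_windows * width

    def reduce(x: np.ndarray) -> np.ndarray:
        return x[:take].reshape(n_windows, width).mean(axis=1)

    return CoPTrace(
        time=reduce(trace.time),
        ap=reduce(trace.ap),
        ml=reduce(trace.ml),
        rate=trace.rate / width,
    )


def segment_session(trace: CoPTrace, manifest: SessionManifest) -> list[Segment]:
    """Cut a trace into block segments per the manifest schedule.

    Segments tile [0, Σ durations) in samples with no gap or overlap;
    boundaries fall at round(cumulative duration × rate).
    """
    if not manifest.blocks:
        raise ScheduleError(
            f"manifest for {manifest.subject_id}/{manifest.condition.value} "
            "has no blocks to segment"
        )
    if abs(manifest.rate - trace.rate) > 1e-9:
        raise ConsistencyError(
            f"manifest rate {manifest.rate} != trace rate {trace.rate}"
        )
    if manifest.schedule_duration > trace.duration + 1e-9:
        raise ConsistencyError(
            f"schedule of {manifest.schedule_duration} s exceeds trace of "
            f"{trace.duration} s"
        )
    edges = np.round(
        np.cumsum([0.0] + [dur for _, dur in manifest.blocks]) * trace.rate
    ).astype(int)
    segments = [
        Segment(label=label, start=int(edges[i]), end=int(edges[i + 1]))
        for i, (label, _) in enumerate(manifest.blocks)
    ]
    if segments[-1].end > len(trace):
        raise ConsistencyError("rounded schedule exceeds trace length")
    return segments
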