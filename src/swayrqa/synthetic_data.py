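"""Synthetic cohorts: quiet-stance CoP traces, flow sessions, vection ratings.

The generator's job is to produce data with the *statistical structure* the
analysis pipeline assumes, not biomechanically realistic sway. One latent
scalar per subject — visual dependence ``v`` in [0, 1], the degree to which
the subject's postural control leans on vision — drives every condition
contrast:

* **Quiet stance.** Both axes follow a mean-reverting (AR(1)/Ornstein-
  Uhlenbeck-like) process with a ~1 s reversion time, which keeps 60 s
  traces stationary enough for recurrence analysis. Eyes-*open* AP sway
  scale grows with ``v`` (from 0.65 to 1.5 times the base scale), plus a
  slow sinusoid of amplitude shrinking in ``v``; eyes-*closed* sway sits at
  a fixed 1.6 times the base scale — above the eyes-open scale for every
  subject, so eyes-closed paths always exceed eyes-open paths. Under an
  absolute recurrence radius, larger-amplitude sway is less recurrent, so
  this makes the eyes-open recurrence rate (and the open-minus-closed
  recurrence difference) *decrease* in ``v`` while eyes-closed recurrence
  stays nearly flat — the pattern the analysis is built to detect — and
  makes the eyes-open/eyes-closed sway-area ratio grow with ``v``.
* **Flow sessions.** The same baseline process, with the AP mean shifted
  during flow blocks: backward (−gain·v) for expanding flow and forward
  (+k·gain·v, k > 1) for contracting flow, matching the forward/backward
  asymmetry of real visually-evoked responses.
* **Vection.** Per-trial verbal ratings rise linearly with ``v`` (plus
  between-subject and trial noise), contracting flow rated above expanding;
  the throttle rises sigmoidally to a plateau tied to the trial's verbal
  rating, with onset earlier for high-``v`` subjects.

The cohort-level ``coupling`` parameter is the target Pearson correlation
between the recurrence-rate difference feature (eyes open − eyes closed)
and mean verbal vection; its magnitude sets the between-subject rating
noise and its sign fixes the direction of the v → rating mapping. Because
the recurrence difference *decreases* in ``v`` by construction, a negative
coupling (the realistic case) means ratings increase with ``v``.

Every output is a pure function of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .errors import ParameterError
from .io_sessions import (
    BlockLabel,
    Condition,
    CoPTrace,
    SessionManifest,
    VectionRecord,
    write_cop_trace,
    write_manifest,
    write_throttle,
)

__all__ = [
    "SubjectParams",
    "CohortSpec",
    "subject_params",
    "gen_quiet_stance",
    "gen_flow_session",
    "gen_vection",
    "gen_cohort",
]

#: Reversion time of the baseline sway process, seconds.
REVERSION_TIME_S = 1.0
#: ML noise scale relative to AP.
ML_SCALE = 0.6
#: Eyes-open AP sway scale: base_noise * (OPEN_SD_BASE + OPEN_SD_SPAN * v).
OPEN_SD_BASE = 0.65
OPEN_SD_SPAN = 0.85
#: Eyes-closed AP sway scale: base_noise * CLOSED_SD_FACTOR, above the
#: eyes-open scale for every v in [0, 1].
CLOSED_SD_FACTOR = 1.6
#: Forward-shift multiplier for contracting relative to expanding flow.
CONTRACTING_GAIN_FACTOR = 7.0
#: Verbal-rating model: verbal = 100 * (beta0[direction] + beta1 * v_eff).
VERBAL_BETA0 = {"expanding": 0.15, "contracting": 0.38}
VERBAL_BETA1 = 0.45
#: Throttle plateau as a fraction of the trial's verbal rating (the
#: construction bound: throttle max never exceeds this ceiling).
THROTTLE_CEILING_FRACTION = 0.85
#: Sigmoid rise time constant (s) and onset-delay model parameters.
THROTTLE_RISE_S = 0.8
THROTTLE_ONSET_BASE_S = 1.5
THROTTLE_ONSET_SPAN_S = 5.0
THROTTLE_ONSET_EXPANDING_EXTRA_S = 0.3
#: Seated-vection trial length (s) and throttle sampling rate (Hz).
TRIAL_DURATION_S = 30.0
THROTTLE_RATE_HZ = 100.0
#: Standing flow-session block pattern, repeated three times.
FLOW_BLOCK_PATTERN = (
    BlockLabel.BLANK,
    BlockLabel.FLOW,
    BlockLabel.BLANK,
    BlockLabel.FIXATION,
)
FLOW_REPEATS = 3


def flow_schedule(block_duration: float = 30.0) -> tuple[tuple[BlockLabel, float], ...]:
    """The blank/flow/blank/fixation x3 schedule with equal block durations."""
    return tuple(
        (label, block_duration)
        for _ in range(FLOW_REPEATS)
        for label in FLOW_BLOCK_PATTERN
    )

_CONDITION_STREAM = {
    "quiet_open": 11,
    "quiet_closed": 12,
    "flow_expanding": 21,
    "flow_contracting": 22,
    "vection_expanding": 31,
    "vection_contracting": 32,
    "subject_effect": 41,
}


@dataclass(frozen=True)
class SubjectParams:
    """Latent parameters of one synthetic subject."""

    subject_id: str
    v: float  # visual dependence in [0, 1]
    base_noise: float = 7.5  # base stationary sway scale, mm
    periodic_amp: float = 3.0  # eyes-open oscillation amplitude at v = 0, mm
    periodic_freq: float = 0.3  # Hz
    vepr_gain: float = 2.5  # mm of backward shift per unit v (expanding)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.v <= 1.0:
            raise ParameterError(f"visual dependence must be in [0, 1], got {self.v}")
        if self.base_noise <= 0:
            raise ParameterError("base_noise must be > 0")
        if self.periodic_amp < 0:
            raise ParameterError("periodic_amp must be >= 0")
        if self.periodic_freq <= 0:
            raise ParameterError("periodic_freq must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Study-level generation parameters (defaults mirror the emulated design)."""

    n_subjects: int = 13
    rate: float = 1000.0  # force-plate sampling, Hz
    duration: float = 60.0  # quiet-stance recording, s
    coupling: float = -0.7  # target corr(rr_diff, verbal vection)
    rating_noise_sd: float = 8.0  # trial-to-trial verbal noise, percent
    n_trials: int = 8  # seated-vection trials per direction
    block_duration: float = 30.0  # flow-session block length, s
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("a cohort needs at least 2 subjects")
        if self.rate <= 0 or self.duration <= 0:
            raise ParameterError("rate and duration must be positive")
        if not -1.0 <= self.coupling <= 1.0:
            raise ParameterError("coupling must be in [-1, 1]")
        if self.rating_noise_sd < 0:
            raise ParameterError("rating_noise_sd must be >= 0")
        if self.block_duration <= 0:
            raise ParameterError("block_duration must be > 0")


def _rng(p: SubjectParams, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(p.seed), _CONDITION_STREAM[stream]])


def _ar1(rng: np.random.Generator, n: int, dt: float, sd: float) -> np.ndarray:
    """Stationary mean-reverting noise: exact AR(1) discretisation of an
    Ornstein-Uhlenbeck process with reversion time REVERSION_TIME_S."""
    phi = math.exp(-dt / REVERSION_TIME_S)
    w = rng.standard_normal(n) * (sd * math.sqrt(1.0 - phi * phi))
    w[0] = rng.standard_normal() * sd  # stationary start
    return lfilter([1.0], [1.0, -phi], w)


def _time_axis(spec: CohortSpec, duration: float) -> np.ndarray:
    n = int(round(duration * spec.rate))
    return np.arange(n) / spec.rate


def gen_quiet_stance(p: SubjectParams, eyes: str, spec: CohortSpec) -> CoPTrace:
    """One 60 s quiet-stance trace for ``eyes`` in {"open", "closed"}."""
    if eyes not in ("open", "closed"):
        raise ParameterError(f"eyes must be 'open' or 'closed', got {eyes!r}")
    stream = "quiet_open" if eyes == "open" else "quiet_closed"
    rng = _rng(p, stream)
    time = _time_axis(spec, spec.duration)
    dt = 1.0 / spec.rate
    if eyes == "open":
        sd = p.base_noise * (OPEN_SD_BASE + OPEN_SD_SPAN * p.v)
        amp = p.periodic_amp * (1.0 - p.v)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        ap = _ar1(rng, len(time), dt, sd) + amp * np.sin(
            2.0 * math.pi * p.periodic_freq * time + phase
        )
    else:
        sd = p.base_noise * CLOSED_SD_FACTOR
        ap = _ar1(rng, len(time), dt, sd)
    ml_sd = ML_SCALE * sd
    ml = _ar1(rng, len(time), dt, ml_sd)
    return CoPTrace(time=time, ap=ap, ml=ml, rate=spec.rate)


def gen_flow_session(
    p: SubjectParams, direction: str, spec: CohortSpec
) -> tuple[CoPTrace, SessionManifest]:
    """One standing optic-flow session (360 s) and its matching manifest."""
    if direction not in ("expanding", "contracting"):
        raise ParameterError(f"unknown flow direction {direction!r}")
    rng = _rng(p, f"flow_{direction}")
    schedule = flow_schedule(spec.block_duration)
    total = sum(d for _, d in schedule)
    time = _time_axis(spec, total)
    dt = 1.0 / spec.rate
    ap = _ar1(rng, len(time), dt, p.base_noise)
    ml = _ar1(rng, len(time), dt, ML_SCALE * p.base_noise)
    if direction == "expanding":
        shift = -p.vepr_gain * p.v
    else:
        shift = CONTRACTING_GAIN_FACTOR * p.vepr_gain * p.v
    t0 = 0.0
    for label, dur in schedule:
        if label is BlockLabel.FLOW:
            i0 = int(round(t0 * spec.rate))
            i1 = int(round((t0 + dur) * spec.rate))
            ap[i0:i1] += shift
        t0 += dur
    condition = (
        Condition.STANDING_FLOW_EXPANDING
        if direction == "expanding"
        else Condition.STANDING_FLOW_CONTRACTING
    )
    manifest = SessionManifest(
        subject_id=p.subject_id,
        condition=condition,
        rate=spec.rate,
        blocks=schedule,
    )
    return CoPTrace(time=time, ap=ap, ml=ml, rate=spec.rate), manifest


def _subject_effect(p: SubjectParams, spec: CohortSpec) -> float:
    """Between-subject rating deviation; its sd realises |coupling|.

    The systematic part of the rating has sd beta1*100*sd(v) across a
    uniform-v cohort; the deviation sd is chosen so the v -> rating
    correlation magnitude targets |coupling|.
    """
    rho = abs(spec.coupling)
    if rho >= 1.0:
        return 0.0
    signal_sd = VERBAL_BETA1 * 100.0 * math.sqrt(1.0 / 12.0)
    noise_sd = signal_sd * math.sqrt(1.0 / rho**2 - 1.0) if rho > 0 else 1e6
    rng = _rng(p, "subject_effect")
    return float(rng.standard_normal() * min(noise_sd, 1e6))


def gen_vection(
    p: SubjectParams, direction: str, n_trials: int, spec: CohortSpec
) -> list[VectionRecord]:
    """Seated-vection trials: throttle traces plus verbal ratings."""
    if direction not in ("expanding", "contracting"):
        raise ParameterError(f"unknown flow direction {direction!r}")
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    rng = _rng(p, f"vection_{direction}")
    v_eff = p.v if spec.coupling <= 0 else 1.0 - p.v
    base = 100.0 * (VERBAL_BETA0[direction] + VERBAL_BETA1 * v_eff)
    base += _subject_effect(p, spec)
    t = np.arange(int(round(TRIAL_DURATION_S * THROTTLE_RATE_HZ))) / THROTTLE_RATE_HZ
    onset = (
        THROTTLE_ONSET_BASE_S
        + THROTTLE_ONSET_SPAN_S * (1.0 - p.v)
        + (THROTTLE_ONSET_EXPANDING_EXTRA_S if direction == "expanding" else 0.0)
    )
    # subjects differ in how much of the throttle range they use relative to
    # their verbal reports; keeps the two measures tied without being collinear
    usage = float(np.clip(1.0 - abs(rng.standard_normal()) * 0.12, 0.6, 1.0))
    records = []
    for trial in range(1, n_trials + 1):
        verbal = float(np.clip(base + rng.standard_normal() * spec.rating_noise_sd, 0.0, 100.0))
        ceiling = THROTTLE_CEILING_FRACTION * verbal
        plateau = ceiling * usage * min(1.0, 0.95 + 0.05 * rng.standard_normal())
        level = max(plateau, 0.0) / (1.0 + np.exp(-(t - onset) / THROTTLE_RISE_S))
        jitter = rng.standard_normal(len(t)) * 0.3
        level = np.clip(np.minimum(level + jitter, ceiling), 0.0, 100.0)
        records.append(
            VectionRecord(
                subject_id=p.subject_id,
                condition=direction,
                trial_index=trial,
                throttle_time=t,
                throttle_level=level,
                verbal=verbal,
            )
        )
    return records


def subject_params(spec: CohortSpec, **overrides) -> list[SubjectParams]:
    """Draw per-subject latent parameters from the master seed.

    Visual dependence is uniform on [0, 1]; per-subject seeds are spawned
    from the master seed so every downstream draw is reproducible.
    ``overrides`` forwards fixed values (e.g. ``vepr_gain``) to every subject.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    v_rng = np.random.default_rng(ss.spawn(1)[0])
    vs = v_rng.uniform(0.0, 1.0, size=spec.n_subjects)
    children = ss.spawn(spec.n_subjects + 1)[1:]
    return [
        SubjectParams(
            subject_id=f"S{i + 1:02d}",
            v=float(vs[i]),
            seed=int(children[i].generate_state(1, dtype=np.uint32)[0]),
            **overrides,
        )
        for i in range(spec.n_subjects)
    ]


def gen_cohort(spec: CohortSpec, out_dir: str | Path, **overrides) -> dict:
    """Write a full cohort to ``out_dir`` and return its metadata.

    Layout: one directory per subject containing quiet-stance traces +
    manifests, flow sessions + manifests, per-trial throttle CSVs and a
    ``ratings.csv`` indexing the vection trials. ``cohort.yaml`` at the root
    records the spec and every subject's latent parameters and seed, which
    suffices to regenerate the dataset bit-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = subject_params(spec, **overrides)
    meta_subjects = []
    for p in params:
        sdir = out / p.subject_id
        sdir.mkdir(exist_ok=True)
        for eyes, cond in (("open", Condition.QUIET_EYES_OPEN),
                           ("closed", Condition.QUIET_EYES_CLOSED)):
            trace = gen_quiet_stance(p, eyes, spec)
            fname = f"quiet_{eyes}.csv"
            write_cop_trace(trace, sdir / fname)
            write_manifest(
                SessionManifest(
                    subject_id=p.subject_id,
                    condition=cond,
                    rate=spec.rate,
                    trace_file=fname,
                ),
                sdir / f"quiet_{eyes}.yaml",
            )
        for direction in ("expanding", "contracting"):
            trace, manifest = gen_flow_session(p, direction, spec)
            fname = f"flow_{direction}.csv"
            write_cop_trace(trace, sdir / fname)
            write_manifest(
                SessionManifest(
                    subject_id=manifest.subject_id,
                    condition=manifest.condition,
                    rate=manifest.rate,
                    blocks=manifest.blocks,
                    trace_file=fname,
                ),
                sdir / f"flow_{direction}.yaml",
            )
        rating_rows = []
        for direction in ("expanding", "contracting"):
            for rec in gen_vection(p, direction, spec.n_trials, spec):
                tname = f"throttle_{direction}_{rec.trial_index:02d}.csv"
                write_throttle(rec.throttle_time, rec.throttle_level, sdir / tname)
                rating_rows.append(
                    {
                        "subject_id": p.subject_id,
                        "condition": direction,
                        "trial_index": rec.trial_index,
                        "verbal": rec.verbal,
                        "throttle_file": tname,
                    }
                )
        pd.DataFrame(rating_rows).to_csv(
            sdir / "ratings.csv", index=False, float_format="%.12g"
        )
        meta_subjects.append(
            {
                "subject_id": p.subject_id,
                "v": p.v,
                "base_noise": p.base_noise,
                "periodic_amp": p.periodic_amp,
                "periodic_freq": p.periodic_freq,
                "vepr_gain": p.vepr_gain,
                "seed": p.seed,
            }
        )
    meta = {
        "spec": {
            "n_subjects": spec.n_subjects,
            "rate": spec.rate,
            "duration": spec.duration,
            "coupling": spec.coupling,
            "rating_noise_sd": spec.rating_noise_sd,
            "n_trials": spec.n_trials,
            "block_duration": spec.block_duration,
            "master_seed": spec.master_seed,
        },
        "subjects": meta_subjects,
    }
    with open(out / "cohort.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return meta
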