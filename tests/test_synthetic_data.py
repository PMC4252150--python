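import math

import numpy as np
import pytest
import yaml

from swayrqa.errors import ParameterError
from swayrqa.io_sessions import BlockLabel
from swayrqa.preprocess import boxcar_downsample, butterworth_filter
from swayrqa.linear_measures import path_length
from swayrqa.rqa import RQAParams, series_recurrence_rate
from swayrqa.synthetic_data import (
    CohortSpec,
    SubjectParams,
    gen_cohort,
    gen_flow_session,
    gen_quiet_stance,
    gen_vection,
    subject_params,
)
from swayrqa.vepr_vection import compute_vepr, throttle_latency, throttle_max

# short traces keep the recurrence analyses cheap; the full 60 s / 30 s-block
# study scale is exercised in the acceptance tests
FAST = CohortSpec(n_subjects=4, duration=6.0, block_duration=2.0, n_trials=3,
                  master_seed=5)


def _subject(v, seed=11, **kwargs):
    return SubjectParams(subject_id="SX", v=v, seed=seed, **kwargs)


def _rr_of(trace, width=10):
    reduced = boxcar_downsample(butterworth_filter(trace), width)
    return series_recurrence_rate(reduced.ap, RQAParams())


class TestQuietStance:
    def test_deterministic_from_seed(self):
        a = gen_quiet_stance(_subject(0.4), "open", FAST)
        b = gen_quiet_stance(_subject(0.4), "open", FAST)
        np.testing.assert_array_equal(a.ap, b.ap)
        np.testing.assert_array_equal(a.ml, b.ml)

    def test_shape_and_rate(self):
        trace = gen_quiet_stance(_subject(0.5), "closed", FAST)
        assert len(trace) == 6000
        assert trace.rate == 1000.0

    def test_low_visual_dependence_more_recurrent_eyes_open(self):
        # construction contract, in expectation over >= 10 seeds
        rr0, rr1 = [], []
        for seed in range(10):
            rr0.append(_rr_of(gen_quiet_stance(_subject(0.0, seed), "open", FAST)))
            rr1.append(_rr_of(gen_quiet_stance(_subject(1.0, seed), "open", FAST)))
        assert np.mean(rr0) > np.mean(rr1)
        assert np.mean([a > b for a, b in zip(rr0, rr1)]) >= 0.9

    def test_eyes_closed_paths_exceed_eyes_open_on_cohort(self):
        spec = CohortSpec(n_subjects=20, duration=6.0, master_seed=3)
        po, pc = [], []
        for p in subject_params(spec):
            po.append(path_length(butterworth_filter(gen_quiet_stance(p, "open", spec))))
            pc.append(path_length(butterworth_filter(gen_quiet_stance(p, "closed", spec))))
        assert np.mean(pc) > np.mean(po)

    def test_invalid_eyes_rejected(self):
        with pytest.raises(ParameterError):
            gen_quiet_stance(_subject(0.5), "shut", FAST)


class TestFlowSession:
    def test_manifest_matches_schedule(self):
        trace, manifest = gen_flow_session(_subject(0.5), "expanding", FAST)
        assert len(manifest.blocks) == 12
        assert all(dur == 2.0 for _, dur in manifest.blocks)
        assert manifest.schedule_duration == pytest.approx(trace.duration)
        assert [b[0] for b in manifest.blocks[:4]] == [
            BlockLabel.BLANK, BlockLabel.FLOW, BlockLabel.BLANK, BlockLabel.FIXATION]

    def test_zero_gain_gives_near_zero_vepr(self):
        p = _subject(0.8, vepr_gain=0.0, base_noise=1.0)
        trace, manifest = gen_flow_session(p, "contracting", FAST)
        result = compute_vepr(butterworth_filter(trace), manifest)
        assert abs(result.mean_vepr) < 1.0  # noise-level only

    def test_injected_contracting_shift_recovered(self):
        # v=1, gain 9/7 => injected forward shift of 9 mm; low noise
        p = _subject(1.0, vepr_gain=9.0 / 7.0, base_noise=1.0)
        trace, manifest = gen_flow_session(p, "contracting", FAST)
        result = compute_vepr(butterworth_filter(trace), manifest)
        assert result.mean_vepr == pytest.approx(9.0, abs=1.0)
        assert len(result.per_repeat) == 3

    def test_expanding_backward_contracting_forward_and_asymmetric(self):
        veprs = {"expanding": [], "contracting": []}
        for seed in range(6):
            p = _subject(0.8, seed=seed)
            for direction in veprs:
                trace, manifest = gen_flow_session(p, direction, FAST)
                veprs[direction].append(
                    compute_vepr(butterworth_filter(trace), manifest).mean_vepr)
        assert np.mean(veprs["expanding"]) < 0 < np.mean(veprs["contracting"])
        assert abs(np.mean(veprs["contracting"])) > abs(np.mean(veprs["expanding"]))


class TestVection:
    def test_monotone_verbal_in_v(self):
        means = []
        for v in (0.0, 0.25, 0.5, 0.75, 1.0):
            recs = gen_vection(_subject(v), "expanding", 8,
                               CohortSpec(coupling=-1.0, rating_noise_sd=0.0))
            means.append(np.mean([r.verbal for r in recs]))
        assert means == sorted(means)
        assert means[0] < means[-1]

    def test_zero_noise_zero_v_gives_exact_baseline(self):
        recs = gen_vection(_subject(0.0), "expanding", 3,
                           CohortSpec(coupling=-1.0, rating_noise_sd=0.0))
        assert all(r.verbal == pytest.approx(15.0) for r in recs)

    def test_throttle_max_below_verbal_linked_ceiling(self):
        for v in (0.1, 0.5, 0.9):
            for recs in (gen_vection(_subject(v), "expanding", 5, FAST),
                         gen_vection(_subject(v), "contracting", 5, FAST)):
                for r in recs:
                    assert throttle_max(r) <= 0.85 * r.verbal + 1e-9

    def test_contracting_rated_above_expanding(self):
        p = _subject(0.5)
        exp = np.mean([r.verbal for r in gen_vection(p, "expanding", 8, FAST)])
        con = np.mean([r.verbal for r in gen_vection(p, "contracting", 8, FAST)])
        assert con > exp

    def test_latency_decreases_with_v(self):
        spec = CohortSpec(coupling=-1.0, rating_noise_sd=0.0)
        lat = []
        for v in (0.2, 0.8):
            recs = gen_vection(_subject(v), "contracting", 4, spec)
            lat.append(np.nanmean([throttle_latency(r) for r in recs]))
        assert lat[1] < lat[0]


class TestCohort:
    def test_full_layout_on_disk(self, small_cohort_dir, small_cohort_spec):
        subjects = sorted(d.name for d in small_cohort_dir.iterdir() if d.is_dir())
        assert len(subjects) == small_cohort_spec.n_subjects
        sdir = small_cohort_dir / subjects[0]
        for fname in ("quiet_open.csv", "quiet_open.yaml", "quiet_closed.csv",
                      "flow_expanding.csv", "flow_expanding.yaml",
                      "flow_contracting.yaml", "ratings.csv"):
            assert (sdir / fname).exists()
        n_throttle = len(list(sdir.glob("throttle_*.csv")))
        assert n_throttle == 2 * small_cohort_spec.n_trials

    def test_metadata_records_seeds_and_params(self, small_cohort_dir, small_cohort_spec):
        meta = yaml.safe_load((small_cohort_dir / "cohort.yaml").read_text())
        assert meta["spec"]["master_seed"] == small_cohort_spec.master_seed
        assert len(meta["subjects"]) == small_cohort_spec.n_subjects
        assert all("seed" in s and "v" in s for s in meta["subjects"])

    def test_regeneration_bit_identical(self, tmp_path, small_cohort_spec):
        a, b = tmp_path / "a", tmp_path / "b"
        gen_cohort(small_cohort_spec, a)
        gen_cohort(small_cohort_spec, b)
        for fa in sorted(a.rglob("*.csv")):
            fb = b / fa.relative_to(a)
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_subject_params_reproducible_and_in_range(self):
        spec = CohortSpec(n_subjects=10, master_seed=77)
        ps1 = subject_params(spec)
        ps2 = subject_params(spec)
        assert [p.v for p in ps1] == [p.v for p in ps2]
        assert all(0.0 <= p.v <= 1.0 for p in ps1)
        assert all(p.seed < 2**32 for p in ps1)
        assert len({p.subject_id for p in ps1}) == 10
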