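import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swayrqa.errors import ConsistencyError, DataError, ParameterError
from swayrqa.rqa import (
    RQAParams,
    analyze_series,
    embed,
    line_histograms,
    recurrence_matrix,
    recurrence_rate,
    rqa_measures,
    rr_difference,
    series_recurrence_rate,
)

# ---------------------------------------------------------------------------
# Independent brute-force oracles (plain loops, no shared code paths)
# ---------------------------------------------------------------------------

def oracle_matrix(vectors, radius, norm="euclidean", theiler=0):
    n = len(vectors)
    out = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if theiler > 0 and abs(i - j) <= theiler:
                continue
            if norm == "euclidean":
                d = math.sqrt(sum((a - b) ** 2 for a, b in zip(vectors[i], vectors[j])))
            else:
                d = max(abs(a - b) for a, b in zip(vectors[i], vectors[j]))
            out[i, j] = d <= radius
    return out


def oracle_runs(values):
    runs, current = [], 0
    for value in values:
        if value:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def oracle_histograms(matrix, theiler=0):
    n = matrix.shape[0]
    diag, vert = {}, {}
    for k in range(theiler + 1 if theiler else 1, n):
        for off in (k, -k):
            line = [matrix[i, i + off] for i in range(max(0, -off), min(n, n - off))]
            for run in oracle_runs(line):
                diag[run] = diag.get(run, 0) + 1
    for col in range(n):
        for run in oracle_runs(matrix[:, col]):
            vert[run] = vert.get(run, 0) + 1
    return diag, vert


class TestEmbed:
    def test_enumerated_small_case(self):
        vectors = embed(np.array([1.0, 2, 3, 4, 5]), m=2, tau=2)
        np.testing.assert_array_equal(vectors, [[1, 3], [2, 4], [3, 5]])

    def test_m1_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(embed(x, 1, 3)[:, 0], x)

    def test_study_scale_count(self, rng):
        vectors = embed(rng.normal(size=6000), m=8, tau=15)
        assert vectors.shape == (5895, 8)

    @given(n=st.integers(2, 400), m=st.integers(1, 10), tau=st.integers(1, 20))
    @settings(max_examples=60, deadline=None)
    def test_count_identity(self, n, m, tau):
        x = np.arange(n, dtype=float)
        span = (m - 1) * tau + 1
        if n < span:
            with pytest.raises(DataError):
                embed(x, m, tau)
        else:
            vectors = embed(x, m, tau)
            assert vectors.shape == (n - (m - 1) * tau, m)
            # each row is an arithmetic slice of the series
            np.testing.assert_array_equal(vectors[0], x[0 : span : tau])

    def test_too_short_series_rejected(self):
        with pytest.raises(DataError):
            embed(np.zeros(10), m=8, tau=15)


class TestRecurrenceMatrix:
    def test_constant_series_all_ones(self):
        vectors = embed(np.zeros(30), 3, 2)
        params = RQAParams(m=3, tau=2, radius=1.0)
        assert recurrence_matrix(vectors, params).all()

    def test_boundary_distance_counts_as_recurrent(self):
        vectors = np.array([[0.0, 0.0], [3.0, 4.0]])
        matrix = recurrence_matrix(vectors, RQAParams(m=2, tau=1, radius=5.0))
        assert matrix.all()
        just_below = recurrence_matrix(vectors, RQAParams(m=2, tau=1, radius=4.999))
        assert not just_below[0, 1]

    @pytest.mark.parametrize("norm", ["euclidean", "maximum"])
    @pytest.mark.parametrize("theiler", [0, 2])
    def test_matches_bruteforce_oracle(self, rng, norm, theiler):
        vectors = rng.normal(0, 1.0, size=(200, 4))
        params = RQAParams(m=4, tau=1, radius=1.5, norm=norm, theiler=theiler)
        np.testing.assert_array_equal(
            recurrence_matrix(vectors, params),
            oracle_matrix(vectors, 1.5, norm=norm, theiler=theiler),
        )

    def test_symmetric_with_unit_diagonal(self, rng):
        vectors = embed(rng.normal(size=120), 3, 4)
        matrix = recurrence_matrix(vectors, RQAParams(m=3, tau=4, radius=1.0))
        assert np.array_equal(matrix, matrix.T)
        assert matrix.diagonal().all()

    def test_fraction_radius_mode_scales_with_amplitude(self, rng):
        x = rng.normal(size=300)
        params = RQAParams(radius=0.2, m=2, tau=1, radius_mode="fraction_of_mean_distance")
        rr_small = recurrence_rate(recurrence_matrix(embed(x, 2, 1), params))
        rr_big = recurrence_rate(recurrence_matrix(embed(100.0 * x, 2, 1), params))
        assert rr_small == pytest.approx(rr_big, abs=1e-12)


class TestRecurrenceRate:
    def test_all_ones(self):
        assert recurrence_rate(np.ones((10, 10), dtype=bool)) == 1.0

    def test_identity_only(self):
        assert recurrence_rate(np.eye(10, dtype=bool)) == pytest.approx(0.1)

    def test_is_mean_of_entries(self, rng):
        matrix = rng.random((50, 50)) < 0.3
        assert recurrence_rate(matrix) == pytest.approx(matrix.sum() / 2500)

    def test_monotone_in_radius(self, rng):
        x = rng.normal(size=400)
        rates = [
            series_recurrence_rate(x, RQAParams(m=3, tau=2, radius=r))
            for r in (0.2, 0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert rates == sorted(rates)

    def test_fast_path_equals_matrix_route(self, rng):
        x = rng.normal(size=500)
        params = RQAParams(m=5, tau=3, radius=1.2)
        fast = series_recurrence_rate(x, params)
        slow = recurrence_rate(recurrence_matrix(embed(x, 5, 3), params))
        assert fast == pytest.approx(slow, abs=1e-12)


class TestLineHistograms:
    def test_all_ones_5x5_enumeration(self):
        matrix = np.ones((5, 5), dtype=bool)
        diag, vert = line_histograms(matrix)
        # both triangles: one maximal line per off-identity diagonal
        assert diag == {4: 2, 3: 2, 2: 2, 1: 2}
        assert vert == {5: 5}

    def test_identity_only_has_no_diagonal_lines(self):
        diag, vert = line_histograms(np.eye(8, dtype=bool))
        assert diag == {}
        assert vert == {1: 8}

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(5):
            matrix = rng.random((60, 60)) < 0.25
            matrix = matrix | matrix.T
            np.fill_diagonal(matrix, True)
            diag, vert = line_histograms(matrix)
            odiag, overt = oracle_histograms(matrix)
            assert diag == odiag
            assert vert == overt

    def test_periodic_signal_dominated_by_long_diagonals(self, rng):
        t = np.arange(600) / 100.0
        x = np.sin(2 * np.pi * 2.0 * t)
        params = RQAParams(m=4, tau=5, radius=0.2)
        matrix = recurrence_matrix(embed(x, 4, 5), params)
        diag, _ = line_histograms(matrix)
        # recurrent mass concentrated in long lines
        long_points = sum(l * c for l, c in diag.items() if l >= 10)
        assert long_points / sum(l * c for l, c in diag.items()) > 0.9


class TestMeasures:
    def test_sine_highly_deterministic(self):
        t = np.arange(1500) / 100.0
        x = 300.0 * np.sin(2 * np.pi * 0.4 * t)  # amplitude >> radius
        res = analyze_series(x, RQAParams())
        assert res.det >= 0.95

    def test_sine_more_deterministic_than_noise(self, rng):
        t = np.arange(800) / 100.0
        sine = 15.0 * np.sin(2 * np.pi * 0.4 * t)
        res_sine = analyze_series(sine, RQAParams())
        noise = rng.normal(0, 8.0, 800)  # rr well off 0 and 1 at radius 30
        res_noise = analyze_series(noise, RQAParams())
        assert math.isfinite(res_noise.det)
        assert res_noise.det < res_sine.det

    def test_constant_series_perfect_recurrence(self):
        res = analyze_series(np.zeros(300), RQAParams(m=2, tau=1, radius=1.0, lmin=2))
        assert res.rr == 1.0
        assert res.det == pytest.approx(1.0, abs=0.01)
        assert res.lam == pytest.approx(1.0, abs=0.01)

    def test_no_line_reaching_lmin_gives_nan_not_zero(self):
        matrix = np.eye(12, dtype=bool)
        matrix[2, 7] = matrix[7, 2] = True  # one isolated off-identity point
        res = rqa_measures(matrix, RQAParams(m=2, tau=1, radius=1.0, lmin=4))
        assert math.isnan(res.det)
        assert math.isnan(res.l_mean)
        assert math.isnan(res.entr)

    def test_entropy_zero_for_single_line_length(self):
        # two separated diagonal lines of identical length 4 (plus identity)
        n = 16
        matrix = np.eye(n, dtype=bool)
        for s in (1, 9):
            for i in range(s, s + 4):
                matrix[i, i + 3] = matrix[i + 3, i] = True
        res = rqa_measures(matrix, RQAParams(m=2, tau=1, radius=1.0, lmin=4))
        assert res.entr == pytest.approx(0.0, abs=1e-12)

    def test_shuffling_destroys_determinism(self, rng):
        # amplitude chosen so the shuffled series still has defined DET
        t = np.arange(700) / 100.0
        x = 15.0 * np.sin(2 * np.pi * 0.5 * t)
        params = RQAParams()
        det_original = analyze_series(x, params).det
        wins = 0
        for _ in range(10):
            det_shuffled = analyze_series(rng.permutation(x), params).det
            if math.isfinite(det_shuffled) and det_original > det_shuffled:
                wins += 1
        assert wins == 10

    def test_trend_negative_for_drifting_series(self, rng):
        x = rng.normal(0, 5.0, 1200) + np.linspace(0, 120.0, 1200)
        res = analyze_series(x, RQAParams(m=2, tau=4, radius=10.0))
        assert res.trend < 0


class TestRRDifference:
    def test_equal_rates_zero(self):
        params = RQAParams()
        a = _result(0.05, params)
        assert rr_difference(a, a) == 0.0

    def test_signed_and_antisymmetric(self):
        params = RQAParams()
        a, b = _result(0.02, params), _result(0.05, params)
        assert rr_difference(a, b) == pytest.approx(-0.03)
        assert rr_difference(b, a) == pytest.approx(0.03)

    def test_params_mismatch_rejected(self):
        a = _result(0.02, RQAParams(radius=30.0))
        b = _result(0.05, RQAParams(radius=25.0))
        with pytest.raises(ConsistencyError):
            rr_difference(a, b)


def _result(rr, params):
    from swayrqa.rqa import RQAResult

    return RQAResult(rr=rr, det=0.5, lam=0.5, l_mean=5.0, tt=4.0, entr=1.0,
                     trend=0.0, n_embedded=100, params=params)


def test_bad_params_rejected():
    for kwargs in ({"m": 0}, {"tau": 0}, {"radius": 0.0}, {"lmin": 1},
                   {"theiler": -1}, {"norm": "manhattan"}):
        with pytest.raises(ParameterError):
            RQAParams(**kwargs)
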