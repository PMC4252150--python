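"""Recurrence quantification analysis (RQA) of sway time series.

The phase space of a scalar series ``x`` is reconstructed by time-delay
embedding: vector i is ``(x_i, x_{i+tau}, ..., x_{i+(m-1)tau})`` for an
embedding dimension ``m`` and delay ``tau``. Two reconstructed states are
*recurrent* when their distance is at most a radius ``eps``; the binary,
symmetric recurrence matrix ``R[i, j] = dist(v_i, v_j) <= eps`` collects all
such pairs, and the scalar measures summarise its structure:

* ``RR``  — recurrence rate, ``sum(R) / N^2``: the probability that any
  state recurs. As defined here it *includes* the identity line (i == j)
  when no Theiler window is applied.
* ``DET`` — fraction of off-identity recurrent points lying on diagonal
  lines of length >= ``lmin`` (deterministic, rule-following stretches).
* ``L``   — mean length of those diagonal lines; ``ENTR`` — Shannon entropy
  (nats) of their length distribution.
* ``LAM`` / ``TT`` — the vertical-line analogues (laminar, "trapped"
  states): fraction of recurrent points on vertical lines >= ``lmin`` and
  their mean length.
* ``trend`` — least-squares slope of recurrence density per diagonal versus
  distance from the identity line; drift away from stationarity shows up as
  a negative trend.

Defaults (m=8, tau=15, radius=30 in signal units, lmin=4) are the standard
quiet-stance CoP settings for 60 s series reduced to 100 Hz. All structural
computation here (embedding, matrix, line histograms, measures) is authored
in this module; SciPy supplies only pairwise distances and a k-d tree used
by the fast recurrence-rate counter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import ConsistencyError, DataError, ParameterError

__all__ = [
    "RQAParams",
    "RQAResult",
    "embed",
    "recurrence_matrix",
    "recurrence_rate",
    "series_recurrence_rate",
    "line_histograms",
    "rqa_measures",
    "analyze_series",
    "rr_difference",
    "plot_recurrence",
]


@dataclass(frozen=True)
class RQAParams:
    """Parameters of the recurrence analysis.

    ``radius`` is interpreted in absolute signal units (mm for CoP work) by
    default; ``radius_mode="fraction_of_mean_distance"`` instead scales it by
    the mean off-diagonal phase-space distance, which makes analyses
    comparable across signals of different amplitude. ``theiler`` excludes a
    band of ``|i - j| <= theiler`` around the identity line; at the default 0
    the identity line itself is kept, so RR of an N-vector series is at least
    1/N.
    """

    m: int = 8
    tau: int = 15
    radius: float = 30.0
    lmin: int = 4
    norm: str = "euclidean"  # or "maximum"
    theiler: int = 0
    radius_mode: str = "absolute"  # or "fraction_of_mean_distance"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError(f"embedding dimension must be >= 1, got {self.m}")
        if self.tau < 1:
            raise ParameterError(f"delay must be >= 1, got {self.tau}")
        if self.radius <= 0:
            raise ParameterError(f"radius must be > 0, got {self.radius}")
        if self.lmin < 2:
            raise ParameterError(f"line minimum must be >= 2, got {self.lmin}")
        if self.theiler < 0:
            raise ParameterError("theiler window must be >= 0")
        if self.norm not in ("euclidean", "maximum"):
            raise ParameterError(f"unknown norm {self.norm!r}")
        if self.radius_mode not in ("absolute", "fraction_of_mean_distance"):
            raise ParameterError(f"unknown radius mode {self.radius_mode!r}")


@dataclass(frozen=True)
class RQAResult:
    """Scalar recurrence measures plus the parameters that produced them.

    Measures that are undefined for a matrix (e.g. no diagonal line reaches
    ``lmin``) are NaN, never silently zero.
    """

    rr: float
    det: float
    lam: float
    l_mean: float
    tt: float
    entr: float
    trend: float
    n_embedded: int
    params: RQAParams


# ---------------------------------------------------------------------------
# Embedding and matrix
# ---------------------------------------------------------------------------

def embed(series: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Time-delay embed a scalar series into an (n_embedded, m) array.

    n_embedded = N - (m-1) * tau; row i is (x_i, x_{i+tau}, ..., x_{i+(m-1)tau}).
    """
    x = np.ascontiguousarray(series, dtype=float)
    if x.ndim != 1:
        raise ParameterError("series must be one-dimensional")
    if m < 1 or tau < 1:
        raise ParameterError("m and tau must be >= 1")
    span = (m - 1) * tau + 1
    if len(x) < span:
        raise DataError(
            f"series of length {len(x)} too short to embed with m={m}, tau={tau} "
            f"(needs >= {span})"
        )
    if m == 1:
        return x[:, None].copy()
    window = np.lib.stride_tricks.sliding_window_view(x, span)
    return window[:, ::tau].copy()


def _effective_radius(dist: np.ndarray, params: RQAParams) -> float:
    if params.radius_mode == "absolute":
        return params.radius
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    return params.radius * float(dist[off].mean())


def recurrence_matrix(vectors: np.ndarray, params: RQAParams) -> np.ndarray:
    """Binary symmetric recurrence matrix of an embedded vector set.

    A pair at distance exactly equal to the radius counts as recurrent
    (``<=`` convention). With ``theiler > 0`` every entry within the band
    ``|i - j| <= theiler`` — including the identity line — is forced to 0;
    with ``theiler = 0`` the identity line is kept (all ones).
    """
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    if v.shape[0] < 2:
        raise DataError("need at least 2 embedded vectors")
    metric = "euclidean" if params.norm == "euclidean" else "chebyshev"
    dist = cdist(v, v, metric=metric)
    eps = _effective_radius(dist, params)
    rec = dist <= eps
    if params.theiler > 0:
        n = rec.shape[0]
        idx = np.arange(n)
        band = np.abs(idx[:, None] - idx[None, :]) <= params.theiler
        rec[band] = False
    return rec


def recurrence_rate(matrix: np.ndarray) -> float:
    """Density of recurrent points: sum(R) / N^2 over the full matrix."""
    r = np.asarray(matrix)
    if r.size == 0:
        raise DataError("empty recurrence matrix")
    return float(np.count_nonzero(r) / r.size)


def series_recurrence_rate(series: np.ndarray, params: RQAParams) -> float:
    """Recurrence rate of a scalar series without materialising the matrix.

    For the default configuration (Euclidean norm, absolute radius,
    theiler = 0) recurrent pairs are counted with a k-d tree, which keeps
    memory at O(n) and is much faster than building the N x N matrix for the
    ~6000-vector series a 60 s quiet-stance trace produces. Any other
    configuration falls back to the explicit matrix. Results agree exactly
    with ``recurrence_rate(recurrence_matrix(...))``.
    """
    vectors = embed(series, params.m, params.tau)
    if (
        params.norm == "euclidean"
        and params.radius_mode == "absolute"
        and params.theiler == 0
    ):
        tree = cKDTree(vectors)
        # counts ordered pairs (i, j), i == j included -> equals sum(R)
        pairs = tree.count_neighbors(tree, params.radius)
        return float(pairs) / float(len(vectors)) ** 2
    return recurrence_rate(recurrence_matrix(vectors, params))


# ---------------------------------------------------------------------------
# Line structures
# ---------------------------------------------------------------------------

def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a 1-D boolean array."""
    if mask.size == 0:
        return np.empty(0, dtype=int)
    padded = np.empty(mask.size + 2, dtype=np.int8)
    padded[0] = padded[-1] = 0
    padded[1:-1] = mask
    edges = np.flatnonzero(np.diff(padded))
    return edges[1::2] - edges[0::2]


def line_histograms(
    matrix: np.ndarray, theiler: int = 0
) -> tuple[dict[int, int], dict[int, int]]:
    """Histograms of maximal diagonal and vertical line lengths.

    Diagonal lines are counted over *both* triangles (the matrix is
    symmetric, so every off-identity structure appears twice — consistent
    with denominators that sum the full matrix); the identity line is always
    excluded, as are diagonals within the Theiler band. Vertical lines are
    counted down every column of the matrix exactly as given.
    """
    r = np.asarray(matrix, dtype=bool)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise DataError("recurrence matrix must be square")
    n = r.shape[0]
    diag_hist: dict[int, int] = {}
    for k in range(max(1, theiler + 1), n):
        for lengths in (_run_lengths(np.diagonal(r, k)),
                        _run_lengths(np.diagonal(r, -k))):
            for length in lengths:
                diag_hist[int(length)] = diag_hist.get(int(length), 0) + 1
    vert_hist: dict[int, int] = {}
    for col in range(n):
        for length in _run_lengths(r[:, col]):
            vert_hist[int(length)] = vert_hist.get(int(length), 0) + 1
    return diag_hist, vert_hist


def _weighted_stats(hist: dict[int, int], lmin: int) -> tuple[float, float, float]:
    """(sum l*P(l) for l>=lmin, mean length, entropy) — NaNs when empty."""
    lengths = np.array([l for l in hist if l >= lmin], dtype=float)
    if lengths.size == 0:
        return 0.0, float("nan"), float("nan")
    counts = np.array([hist[int(l)] for l in lengths], dtype=float)
    points = float(np.sum(lengths * counts))
    mean_len = points / float(np.sum(counts))
    p = counts / counts.sum()
    entropy = float(-np.sum(p * np.log(p)))
    return points, mean_len, entropy


def _diag_trend(matrix: np.ndarray, theiler: int) -> float:
    """Slope of per-diagonal recurrence density vs distance from identity.

    Fitted over diagonals k = theiler+1 .. 0.9*N (the corner-most 10% of
    diagonals carry too few points to estimate a density reliably).
    """
    r = np.asarray(matrix, dtype=bool)
    n = r.shape[0]
    k_max = int(np.floor(0.9 * n))
    ks = np.arange(theiler + 1, max(theiler + 2, k_max))
    if ks.size < 2:
        return float("nan")
    density = np.array(
        [np.count_nonzero(np.diagonal(r, int(k))) / (n - k) for k in ks],
        dtype=float,
    )
    slope = np.polyfit(ks, density, 1)[0]
    return float(slope)


def rqa_measures(matrix: np.ndarray, params: RQAParams) -> RQAResult:
    """All scalar recurrence measures of a matrix.

    DET divides diagonal-line points by all off-identity recurrent points;
    LAM divides vertical-line points by all recurrent points counted down
    columns (the whole matrix). When no line of a kind reaches ``lmin`` the
    dependent measures are NaN.
    """
    r = np.asarray(matrix, dtype=bool)
    rr = recurrence_rate(r)
    diag_hist, vert_hist = line_histograms(r, theiler=params.theiler)
    diag_points, l_mean, entr = _weighted_stats(diag_hist, params.lmin)
    vert_points, tt, _ = _weighted_stats(vert_hist, params.lmin)

    off_identity = float(np.count_nonzero(r) - np.count_nonzero(np.diagonal(r)))
    total = float(np.count_nonzero(r))
    det = diag_points / off_identity if off_identity > 0 else float("nan")
    lam = vert_points / total if total > 0 else float("nan")
    if diag_points == 0.0:
        det = float("nan")
    if vert_points == 0.0:
        lam = float("nan")

    n_embedded = r.shape[0]
    return RQAResult(
        rr=rr,
        det=det,
        lam=lam,
        l_mean=l_mean,
        tt=tt,
        entr=entr,
        trend=_diag_trend(r, params.theiler),
        n_embedded=n_embedded,
        params=params,
    )


def analyze_series(series: np.ndarray, params: RQAParams | None = None) -> RQAResult:
    """Embed a scalar series and compute all recurrence measures."""
    params = params or RQAParams()
    vectors = embed(series, params.m, params.tau)
    return rqa_measures(recurrence_matrix(vectors, params), params)


def rr_difference(result_open: RQAResult, result_closed: RQAResult) -> float:
    """Eyes-open minus eyes-closed recurrence rate.

    Negative values mean the eyes-closed series is the more recurrent one.
    Both results must come from identical parameters.
    """
    if result_open.params != result_closed.params:
        raise ConsistencyError(
            "recurrence rates computed with different parameters are not comparable"
        )
    return result_open.rr - result_closed.rr


def plot_recurrence(matrix: np.ndarray, rate: float | None = None, ax=None):
    """Draw a recurrence plot (dot per recurrent pair, both axes time).

    Returns the matplotlib Axes. Import of matplotlib is deferred so the
    analysis path stays plotting-free.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    r = np.asarray(matrix, dtype=bool)
    extent = None
    if rate is not None:
        t_max = r.shape[0] / rate
        extent = (0.0, t_max, 0.0, t_max)
    ax.imshow(r, origin="lower", cmap="Greys", interpolation="none", extent=extent)
    unit = "s" if rate is not None else "samples"
    ax.set_xlabel(f"time ({unit})")
    ax.set_ylabel(f"time ({unit})")
    return ax
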