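"""Linear sway measures: path length, confidence-ellipse area, ratios.

These are the conventional stabilometry summaries. Path length is the total
distance travelled by the CoP,

    L = sum_i sqrt((ap_{i+1}-ap_i)^2 + (ml_{i+1}-ml_i)^2),

and sway area is the area of the 95% prediction ellipse obtained from the
eigen-decomposition (PCA) of the 2x2 AP/ML covariance matrix: semi-axes
sqrt(q * lambda_k) with q the chi-square(2 dof) quantile at the requested
coverage (5.991 at 0.95). The Romberg ratio divides the eyes-closed path by
the eyes-open path; the sway-area ratio is reported log-transformed, so that
equal areas map to 0 and swapping conditions flips the sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError, DegenerateGeometryError, ParameterError
from .io_sessions import CoPTrace

__all__ = [
    "EllipseFit",
    "SwaySummary",
    "path_length",
    "confidence_ellipse",
    "romberg_ratio",
    "log_area_ratio",
    "sway_summary",
]

#: Largest acceptable condition number of the covariance matrix.
_COND_MAX = 1e10


@dataclass(frozen=True)
class EllipseFit:
    """A coverage ellipse for a 2-D CoP point cloud (millimetre units)."""

    center: tuple[float, float]  # (ap, ml)
    semi_axes: tuple[float, float]  # (a, b), a >= b
    orientation: float  # radians, angle of the major axis in the (ap, ml) plane
    area: float  # mm^2
    lambda1: float  # larger covariance eigenvalue, mm^2
    lambda2: float
    coverage_quantile: float

    def contains(self, ap: np.ndarray, ml: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        d_ap = np.asarray(ap, dtype=float) - self.center[0]
        d_ml = np.asarray(ml, dtype=float) - self.center[1]
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = c * d_ap + s * d_ml
        w = -s * d_ap + c * d_ml
        a, b = self.semi_axes
        return (u / a) ** 2 + (w / b) ** 2 <= 1.0


@dataclass(frozen=True)
class SwaySummary:
    """Per-trace linear summary used to populate the feature table."""

    path_length: float  # mm
    area: float  # mm^2
    ap_mean: float  # mm
    ap_sd: float  # mm
    ap_range: float  # mm


def path_length(trace: CoPTrace) -> float:
    """Total CoP excursion: summed Euclidean inter-sample distances (mm)."""
    if len(trace) < 2:
        raise DataError("path length needs at least 2 samples")
    return float(np.sum(np.hypot(np.diff(trace.ap), np.diff(trace.ml))))


def confidence_ellipse(
    trace: CoPTrace,
    coverage: float = 0.95,
    small_sample: bool = False,
) -> EllipseFit:
    """Fit the coverage (prediction) ellipse of the AP/ML point cloud.

    The sample covariance (n-1 denominator) is eigen-decomposed; semi-axes
    are sqrt(q * lambda_k). By default q is the chi-square(2) quantile at
    ``coverage``; with ``small_sample=True`` the F-based correction
    q = 2 (n-1)/(n-2) F_{coverage; 2, n-2} is used instead, which matters
    only at small n.
    """
    if not 0 < coverage < 1:
        raise ParameterError(f"coverage must be in (0, 1), got {coverage}")
    n = len(trace)
    if n < 3:
        raise DataError("ellipse fit needs at least 3 points")
    pts = np.column_stack([trace.ap, trace.ml])
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam2, lam1 = float(evals[0]), float(evals[1])
    if lam1 <= 0 or lam2 <= 0 or lam1 / lam2 > _COND_MAX:
        raise DegenerateGeometryError(
            "covariance is (near-)singular: points are constant or collinear"
        )
    if small_sample:
        if n < 4:
            raise DataError("small-sample correction needs n >= 4")
        q = 2.0 * (n - 1) / (n - 2) * float(sps.f.ppf(coverage, 2, n - 2))
    else:
        q = float(sps.chi2.ppf(coverage, df=2))
    major = evecs[:, 1]
    return EllipseFit(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(np.sqrt(q * lam1)), float(np.sqrt(q * lam2))),
        orientation=float(np.arctan2(major[1], major[0])),
        area=float(np.pi * q * np.sqrt(lam1 * lam2)),
        lambda1=lam1,
        lambda2=lam2,
        coverage_quantile=q,
    )


def romberg_ratio(path_closed: float, path_open: float) -> float:
    """Eyes-closed path divided by eyes-open path; > 1 means vision helps."""
    if path_closed <= 0 or path_open <= 0:
        raise ParameterError("path lengths must be positive")
    return path_closed / path_open


def log_area_ratio(area_open: float, area_closed: float) -> float:
    """Natural log of the eyes-open / eyes-closed sway-area ratio."""
    if area_open <= 0 or area_closed <= 0:
        raise ParameterError("areas must be positive")
    return float(np.log(area_open / area_closed))


def sway_summary(trace: CoPTrace, coverage: float = 0.95) -> SwaySummary:
    """Path length, ellipse area and AP summary statistics for one trace."""
    fit = confidence_ellipse(trace, coverage=coverage)
    return SwaySummary(
        path_length=path_length(trace),
        area=fit.area,
        ap_mean=float(np.mean(trace.ap)),
        ap_sd=float(np.std(trace.ap, ddof=1)),
        ap_range=float(np.ptp(trace.ap)),
    )
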