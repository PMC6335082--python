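"""Circular centralization and dispersion measures.

All angles are in radians on the half-open interval (-pi, pi].  The two
central estimators used throughout the package are the circular mean
direction (direction of the resultant vector) and the Fisher circular
median (the *data* angle minimizing the summed circular distance to all
other angles).  The median is robust to outliers and is the primary
per-neuron orientation estimator; the mean is kept as support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMeanError

__all__ = [
    "wrap_angle",
    "circular_distance",
    "resultant",
    "mean_direction",
    "fisher_median",
    "circular_quartiles",
    "CircularSummary",
    "summarize",
]

_TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Reduce angle(s) to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.mod(theta + np.pi, _TWO_PI) - np.pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def circular_distance(a, b):
    """Shortest angular separation between ``a`` and ``b``, in [0, pi].

    Computed as ``pi - |pi - (|a - b| mod 2*pi)|``; broadcasts over arrays.
    """
    d = np.mod(np.abs(np.asarray(a, float) - np.asarray(b, float)), _TWO_PI)
    out = np.pi - np.abs(np.pi - d)
    return out if out.ndim else float(out)


def resultant(angles, weights=None):
    """Resultant vector components ``(C, S)`` and length ``R`` of unit vectors."""
    theta = np.asarray(angles, dtype=float)
    if theta.size == 0:
        raise ValueError("need at least one angle")
    if weights is None:
        c = float(np.sum(np.cos(theta)))
        s = float(np.sum(np.sin(theta)))
    else:
        w = np.asarray(weights, dtype=float)
        c = float(np.sum(w * np.cos(theta)))
        s = float(np.sum(w * np.sin(theta)))
    return c, s, float(np.hypot(c, s))


def mean_direction(angles, weights=None, tol=1e-9):
    """Circular mean direction: four-quadrant angle of the resultant vector.

    Raises
    ------
    UndefinedMeanError
        If the mean resultant length R/n falls below ``tol`` (perfectly
        balanced angle sets have no meaningful mean direction).
    """
    theta = np.asarray(angles, dtype=float)
    c, s, r = resultant(theta, weights)
    n = theta.size if weights is None else float(np.sum(weights))
    if r <= tol * max(n, 1.0):
        raise UndefinedMeanError(
            f"resultant length {r:.3e} below tolerance; mean direction undefined"
        )
    return wrap_angle(np.arctan2(s, c))


def _distance_sums(theta, weights, chunk=512):
    """Sum of circular distances from every data angle to every data angle.

    Chunked so memory stays O(chunk * n) for large clouds.
    """
    n = theta.size
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    sums = np.empty(n)
    for start in range(0, n, chunk):
        cand = theta[start : start + chunk, None]
        d = np.mod(np.abs(theta[None, :] - cand), _TWO_PI)
        d = np.pi - np.abs(np.pi - d)
        sums[start : start + chunk] = d @ w
    return sums


def fisher_median(angles, weights=None):
    """Fisher circular median: the data angle minimizing summed circular distance.

    The median is always one of the input angles.  Ties (which occur for
    symmetric configurations) are broken by the candidate closest to the
    circular mean direction, then by the smallest angle; when the mean is
    undefined the smallest tied angle wins.
    """
    theta = wrap_angle(np.atleast_1d(np.asarray(angles, dtype=float)))
    if theta.size == 0:
        raise ValueError("need at least one angle")
    if theta.size == 1:
        return float(theta[0])
    sums = _distance_sums(theta, weights)
    best = sums.min()
    ties = np.flatnonzero(sums <= best + 1e-12 * max(1.0, abs(best)))
    if ties.size == 1:
        return float(theta[ties[0]])
    try:
        mu = mean_direction(theta, weights)
        key = circular_distance(theta[ties], mu)
        order = np.lexsort((theta[ties], np.round(key, 12)))
    except UndefinedMeanError:
        order = np.argsort(theta[ties])
    return float(theta[ties[order[0]]])


def circular_quartiles(angles, method="weibull"):
    """First and third circular quartiles ``(q25, q75)``.

    All angles are rotated so the Fisher median sits at 0, linear
    percentiles are taken on the rotated line (-pi, pi], and the results
    are rotated back.  ``method`` is any linear-interpolation rule accepted
    by :func:`numpy.percentile`; the default ``"weibull"`` interpolates the
    empirical CDF at (n+1)p.
    """
    theta = np.atleast_1d(np.asarray(angles, dtype=float))
    if theta.size < 4:
        raise ValueError("circular quartiles require at least 4 angles")
    med = fisher_median(theta)
    rotated = wrap_angle(theta - med)
    q25, q75 = np.percentile(rotated, [25.0, 75.0], method=method)
    return float(wrap_angle(q25 + med)), float(wrap_angle(q75 + med))


@dataclass(frozen=True)
class CircularSummary:
    """Centralization summary of one angle set."""

    n: int
    c: float
    s: float
    resultant_length: float
    mean: float | None  # None when the resultant vanishes
    median: float
    q25: float | None
    q75: float | None

    @property
    def iqr_arc(self):
        """Counterclockwise arc width from q25 to q75, in [0, 2*pi)."""
        if self.q25 is None or self.q75 is None:
            return None
        return float(np.mod(self.q75 - self.q25, _TWO_PI))


def summarize(angles, weights=None, method="weibull"):
    """Compute mean/median/quartile summary for one set of angles."""
    theta = np.atleast_1d(np.asarray(angles, dtype=float))
    c, s, r = resultant(theta, weights)
    try:
        mu = mean_direction(theta, weights)
    except UndefinedMeanError:
        mu = None
    med = fisher_median(theta, weights)
    if theta.size >= 4:
        q25, q75 = circular_quartiles(theta, method=method)
    else:
        q25 = q75 = None
    return CircularSummary(
        n=int(theta.size), c=c, s=s, resultant_length=r,
        mean=mu, median=med, q25=q25, q75=q75,
    )
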