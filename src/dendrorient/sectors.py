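"""Per-neuron anatomical sector geometry.

Each neuron sees the four map reference points along rays from its soma.
All angles are measured counterclockwise from the posterior ray (the
global reference direction), so the posterior ray sits at 0 by
construction.  In the default ``bisector`` mode the circle is split at the
angular bisectors between circularly adjacent rays, so each direction's
sector is the arc closest to its own ray; ``rays`` mode instead uses the
rays themselves as boundaries, each sector spanning from its direction's
ray counterclockwise to the next ray.  Sector arcs are half-open: a point
exactly on a boundary belongs to the counterclockwise-adjacent sector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .circstats import circular_distance, wrap_angle
from .errors import GeometryError
from .io import DIRECTIONS

__all__ = ["signed_angle", "SectorPartition", "SectorAssignment",
           "build_partition", "assign_sectors"]

log = logging.getLogger(__name__)

_TWO_PI = 2.0 * np.pi


def signed_angle(a, v):
    """Signed angle from vector ``a`` to vector(s) ``v``, in (-pi, pi].

    Computed as atan2(a x v, a . v) (counterclockwise positive), which
    resolves the quadrant unambiguously.  ``v`` may be an (n, 2) array.
    """
    a = np.asarray(a, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.allclose(a, 0.0):
        raise GeometryError("reference vector a is zero")
    single = v.ndim == 1
    v2 = v.reshape(-1, 2)
    norms = np.linalg.norm(v2, axis=1)
    if np.any(norms == 0.0):
        raise GeometryError("zero vector passed to signed_angle")
    cross = a[0] * v2[:, 1] - a[1] * v2[:, 0]
    dot = a[0] * v2[:, 0] + a[1] * v2[:, 1]
    ang = np.arctan2(cross, dot)
    ang = np.where(ang == -np.pi, np.pi, ang)
    return float(ang[0]) if single else ang


@dataclass(frozen=True)
class SectorPartition:
    """Four half-open angular sectors around one soma.

    ``boundaries`` are sorted boundary angles in (-pi, pi]; interval k is
    [boundaries[k], boundaries[k+1]) (the last wraps around) and carries
    direction label ``interval_labels[k]``.  ``ray_angles`` are the angles
    of the soma->p_j rays measured from the posterior ray (posterior = 0).
    """

    soma: tuple
    posterior_axis: tuple  # map-frame vector soma -> p_posterior
    ray_angles: dict
    boundaries: tuple
    interval_labels: tuple
    mode: str

    @property
    def arc_fractions(self):
        """PS_j: fraction of the full circle occupied by each sector."""
        b = np.asarray(self.boundaries)
        widths = np.mod(np.roll(b, -1) - b, _TWO_PI)
        # a zero width from roll means a full-circle wrap of the last interval
        widths[widths == 0.0] = _TWO_PI
        return {lab: float(w / _TWO_PI) for lab, w in zip(self.interval_labels, widths)}

    def angles_of(self, points):
        """Angle alpha of each map-frame point, measured from the posterior ray."""
        v = np.asarray(points, dtype=float).reshape(-1, 2) - np.asarray(self.soma)
        return signed_angle(np.asarray(self.posterior_axis), v)

    def sector_of(self, alpha):
        """Direction label(s) of angle(s) alpha (measured from the posterior ray)."""
        alpha = np.atleast_1d(wrap_angle(np.asarray(alpha, dtype=float)))
        b = np.asarray(self.boundaries)
        idx = np.searchsorted(b, alpha, side="right") - 1
        idx[idx < 0] = len(b) - 1  # below the first boundary: wrapped last interval
        labels = np.asarray(self.interval_labels, dtype=object)
        return labels[idx]


@dataclass
class SectorAssignment:
    """Per-point sector labels for one neuron's segment cloud."""

    labels: np.ndarray  # (n,) direction labels for the kept points
    counts: dict  # direction -> point count
    n_skipped: int = 0  # points coincident with the soma

    @property
    def total(self):
        return int(sum(self.counts.values()))


def build_partition(soma, reference_points, mode="bisector") -> SectorPartition:
    """Build the four-sector partition for one neuron.

    Parameters
    ----------
    soma : (2,) map-plane soma position.
    reference_points : mapping direction -> (x, y) map reference points.
    mode : "bisector" (default; boundaries at angular bisectors between
        adjacent rays) or "rays" (boundaries at the rays themselves).
    """
    o = np.asarray(soma, dtype=float)
    for j in DIRECTIONS:
        if np.allclose(np.asarray(reference_points[j], float), o):
            raise GeometryError(f"reference point {j!r} coincides with the soma")
    a = np.asarray(reference_points["posterior"], float) - o
    rays = {
        j: signed_angle(a, np.asarray(reference_points[j], float) - o)
        for j in DIRECTIONS
    }
    # rays["posterior"] == 0 by construction
    vals = np.array([rays[j] for j in DIRECTIONS])
    for i in range(4):
        for k in range(i + 1, 4):
            if circular_distance(vals[i], vals[k]) < 1e-12:
                raise GeometryError(
                    f"rays toward {DIRECTIONS[i]!r} and {DIRECTIONS[k]!r} coincide"
                )
    order = sorted(DIRECTIONS, key=lambda j: rays[j])
    sorted_rays = np.array([rays[j] for j in order])

    if mode == "bisector":
        gaps = np.mod(np.roll(sorted_rays, -1) - sorted_rays, _TWO_PI)
        bounds = wrap_angle(sorted_rays + gaps / 2.0)
    elif mode == "rays":
        bounds = sorted_rays.copy()
    else:
        raise ValueError(f"unknown boundary mode {mode!r}")

    perm = np.argsort(bounds)
    bounds_sorted = bounds[perm]
    if mode == "rays":
        # interval [ray_j, next ray) carries the label of its lower ray
        labels = tuple(order[k] for k in perm)
    else:
        # each interval contains exactly one ray; label it by that ray
        labels = []
        for k in range(4):
            lo = bounds_sorted[k]
            hi = bounds_sorted[(k + 1) % 4]
            width = np.mod(hi - lo, _TWO_PI)
            inside = [
                j for j in DIRECTIONS
                if np.mod(rays[j] - lo, _TWO_PI) < width or width == 0.0
            ]
            if len(inside) != 1:
                raise GeometryError(
                    f"sector construction failed: interval {k} contains {inside}"
                )
            labels.append(inside[0])
        labels = tuple(labels)

    return SectorPartition(
        soma=tuple(o),
        posterior_axis=tuple(a),
        ray_angles=rays,
        boundaries=tuple(float(b) for b in bounds_sorted),
        interval_labels=labels,
        mode=mode,
    )


def assign_sectors(cloud, partition: SectorPartition) -> SectorAssignment:
    """Label every dendritic sample point with its anatomical sector.

    Points coincident with the soma have no direction; they are skipped
    and counted in ``n_skipped`` (with a log warning).
    """
    vec = cloud.vectors
    norms = np.linalg.norm(vec, axis=1)
    keep = norms > 0.0
    n_skipped = int((~keep).sum())
    if n_skipped:
        log.warning("%d sample point(s) coincide with the soma; skipped", n_skipped)
    if keep.sum() == 0:
        return SectorAssignment(
            labels=np.empty(0, dtype=object),
            counts={j: 0 for j in DIRECTIONS},
            n_skipped=n_skipped,
        )
    alpha = signed_angle(np.asarray(partition.posterior_axis), vec[keep])
    labels = partition.sector_of(alpha)
    counts = {j: int(np.sum(labels == j)) for j in DIRECTIONS}
    return SectorAssignment(labels=labels, counts=counts, n_skipped=n_skipped)
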