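"""Oriented and expansion circular histograms (OCH / ECH).

Both plots show a neuron's dendritic mass as stacks of dots at unit-degree
bearings around the soma, colored by anatomical sector (orange dorsal,
dark green ventral, blue posterior, purple anterior).  The OCH adds the
Fisher median (red arrow), the circular mean (blue arrow), the
interquartile arc (light green, quartile dots at its ends) and
threshold-shaded wedges over the DLRM-preferred sectors (darker = more
thresholds passed).  The ECH instead distributes the dots over concentric
rings of 25 um distance-to-soma bands, its central statistics drawn from
first-ring points only.

Every render also writes a sidecar CSV of the binned counts next to the
image, so figures stay testable without pixel comparison.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .circstats import summarize, wrap_angle
from .io import DIRECTIONS
from .sectors import SectorPartition, signed_angle

__all__ = [
    "SECTOR_COLORS", "och_sidecar", "ech_sidecar",
    "render_och", "render_ech", "render_map_overview",
]

SECTOR_COLORS = {
    "dorsal": "orange",
    "ventral": "darkgreen",
    "posterior": "blue",
    "anterior": "purple",
}

RING_WIDTH = 25.0  # um per ECH ring


def _check_cloud(cloud):
    if len(cloud) == 0:
        raise ValueError("no dendrite: empty segment cloud")


def _absolute_bearings(cloud, partition: SectorPartition):
    """Map-frame bearing, relative angle alpha and sector of each point."""
    vec = cloud.vectors
    keep = np.linalg.norm(vec, axis=1) > 0
    vec = vec[keep]
    alpha = signed_angle(np.asarray(partition.posterior_axis), vec)
    bearing = np.arctan2(vec[:, 1], vec[:, 0])
    sector = partition.sector_of(alpha)
    return bearing, alpha, sector, keep


def och_sidecar(cloud, partition: SectorPartition) -> pd.DataFrame:
    """Per-degree, per-sector dot counts (degree measured from the posterior ray)."""
    _check_cloud(cloud)
    _, alpha, sector, _ = _absolute_bearings(cloud, partition)
    degree = np.floor(np.mod(np.degrees(alpha), 360.0)).astype(int)
    df = pd.DataFrame({"degree": degree, "sector": sector})
    out = df.groupby(["degree", "sector"], sort=True).size().reset_index(name="count")
    return out


def ech_sidecar(cloud, partition: SectorPartition) -> pd.DataFrame:
    """Per-ring, per-degree, per-sector dot counts; ring = floor(distance/25)."""
    _check_cloud(cloud)
    _, alpha, sector, keep = _absolute_bearings(cloud, partition)
    degree = np.floor(np.mod(np.degrees(alpha), 360.0)).astype(int)
    ring = np.floor(cloud.distances[keep] / RING_WIDTH).astype(int)
    df = pd.DataFrame({"ring": ring, "degree": degree, "sector": sector})
    return df.groupby(["ring", "degree", "sector"], sort=True).size().reset_index(name="count")


def _posterior_bearing(partition):
    ax = partition.posterior_axis
    return math.atan2(ax[1], ax[0])


def _draw_arrow(ax, theta, r, color):
    ax.annotate(
        "", xy=(theta, r), xytext=(0.0, 0.0),
        arrowprops=dict(arrowstyle="-|>", color=color, lw=2.0,
                        patchA=None, patchB=None, shrinkA=0, shrinkB=0),
    )


def _sector_wedges(ax, partition, levels, rmax, weak):
    """Shade each preferred sector's full arc; darker = more thresholds passed."""
    base = _posterior_bearing(partition)
    bounds = list(partition.boundaries)
    for k, lab in enumerate(partition.interval_labels):
        lo = bounds[k]
        hi = bounds[(k + 1) % 4]
        width = np.mod(hi - lo, 2.0 * np.pi) or 2.0 * np.pi
        lvl = levels.get(lab, 0)
        if lvl == 0 and lab not in weak:
            continue
        alpha = 0.08 if lvl == 0 else 0.15 * lvl
        ax.bar(
            base + lo + width / 2.0, rmax, width=width, bottom=0.0,
            color=SECTOR_COLORS[lab], alpha=alpha, edgecolor="none", zorder=0,
        )


def _stacked_dots(ax, bearings, sectors, r0=1.0, dr=0.15):
    deg = np.floor(np.mod(np.degrees(bearings), 360.0)).astype(int)
    order = np.lexsort((sectors.astype(str), deg))
    deg, bearings = deg[order], bearings[order]
    sectors = sectors[order]
    rmax = r0
    stack = {}
    rs = np.empty(len(deg))
    for i, d in enumerate(deg):
        k = stack.get(d, 0)
        rs[i] = r0 + k * dr
        stack[d] = k + 1
        rmax = max(rmax, rs[i])
    colors = [SECTOR_COLORS[s] for s in sectors]
    ax.scatter(bearings, rs, s=4, c=colors, linewidths=0, zorder=3)
    return rmax


def render_och(cloud, partition, ratios, summary=None, out="och.png",
               thresholds=(1.1, 1.2, 1.3)):
    """Render the oriented circular histogram of one neuron.

    ``ratios`` is the neuron's OrientationRatios (TL/PS values, which do
    not depend on the threshold); ``summary`` a CircularSummary of the
    point angles alpha (computed here when omitted).  Writes the image to
    ``out`` and the per-degree count sidecar to ``out`` + '.csv'.
    """
    _check_cloud(cloud)
    bearing, alpha, sector, _ = _absolute_bearings(cloud, partition)
    if summary is None:
        summary = summarize(alpha)
    base = _posterior_bearing(partition)
    ts = sorted(thresholds)
    levels = {
        j: sum(1 for t in ts if ratios.ratio[j] > t) for j in DIRECTIONS
    }
    weak = {j for j in DIRECTIONS if 1.0 < ratios.ratio[j]}

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    rmax = _stacked_dots(ax, bearing, sector)
    _sector_wedges(ax, partition, levels, rmax * 1.05, weak)
    # IQR arc (counterclockwise from q25 to q75), quartile end dots
    if summary.q25 is not None:
        span = np.mod(summary.q75 - summary.q25, 2.0 * np.pi)
        arc = base + summary.q25 + np.linspace(0.0, span, 64)
        r_arc = rmax * 0.55
        ax.plot(arc, np.full_like(arc, r_arc), color="lightgreen", lw=5,
                solid_capstyle="round", zorder=2)
        ax.scatter([arc[0], arc[-1]], [r_arc, r_arc], s=60, color="lightgreen",
                   zorder=2, edgecolors="none")
    _draw_arrow(ax, base + summary.median, rmax * 0.8, "red")
    if summary.mean is not None:
        _draw_arrow(ax, base + summary.mean, rmax * 0.7, "blue")
    ax.set_rticks([])
    ax.set_title("OCH")
    fig.savefig(out, dpi=150)
    plt.close(fig)
    och_sidecar(cloud, partition).to_csv(str(out) + ".csv", index=False)
    return Path(out)


def render_ech(cloud, partition, out="ech.png"):
    """Render the expansion circular histogram of one neuron.

    Dots sit on concentric rings of 25 um distance-to-soma bands; the
    median/mean arrows and IQR arc are computed from first-ring points
    only.  Writes the image and a (ring, degree, sector, count) sidecar.
    """
    _check_cloud(cloud)
    bearing, alpha, sector, keep = _absolute_bearings(cloud, partition)
    dist = cloud.distances[keep]
    ring = np.floor(dist / RING_WIDTH).astype(int)
    base = _posterior_bearing(partition)

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    rmax = 1.0
    for rg in np.unique(ring):
        m = ring == rg
        r0 = float(rg) + 1.0
        rmax = max(rmax, _stacked_dots(ax, bearing[m], sector[m], r0=r0, dr=0.02))
        ax.plot(np.linspace(0, 2 * np.pi, 181), np.full(181, r0),
                color="0.85", lw=0.6, zorder=1)
    first = ring == 0
    if first.sum() >= 1:
        s = summarize(alpha[first])
        _draw_arrow(ax, base + s.median, 0.9, "red")
        if s.mean is not None:
            _draw_arrow(ax, base + s.mean, 0.8, "blue")
        if s.q25 is not None:
            span = np.mod(s.q75 - s.q25, 2.0 * np.pi)
            arc = base + s.q25 + np.linspace(0.0, span, 64)
            ax.plot(arc, np.full_like(arc, 0.6), color="lightgreen", lw=4,
                    solid_capstyle="round", zorder=2)
    ax.set_rticks([])
    ax.set_title("ECH")
    fig.savefig(out, dpi=150)
    plt.close(fig)
    ech_sidecar(cloud, partition).to_csv(str(out) + ".csv", index=False)
    return Path(out)


def render_map_overview(map_doc, calls, out="map.png"):
    """Somata, reference points and per-neuron called directions for one map.

    ``calls`` maps neuron id -> NeuronDirectionCall (or None for skipped
    neurons).
    """
    fig, ax = plt.subplots(figsize=(6, 6))
    if map_doc.contour:
        c = np.asarray(map_doc.contour + (map_doc.contour[0],))
        ax.plot(c[:, 0], c[:, 1], color="0.7", lw=1)
    for j, p in map_doc.reference_points.items():
        ax.scatter(*p, color=SECTOR_COLORS[j], marker="s", s=40)
        ax.annotate(j[0].upper(), p, textcoords="offset points", xytext=(4, 4))
    for rec in map_doc.neurons:
        if rec.soma is None:
            continue
        o = np.asarray(rec.soma)
        ax.scatter(*o, color="red", s=15, zorder=3)
        call = calls.get(rec.id)
        if call is not None and call.sector is not None:
            p_post = np.asarray(map_doc.reference_points["posterior"])
            base = math.atan2(*(p_post - o)[::-1])
            theta = base + call.median
            tip = o + 60.0 * np.array([math.cos(theta), math.sin(theta)])
            ax.annotate("", xy=tip, xytext=o,
                        arrowprops=dict(arrowstyle="-|>", color="red"))
        ax.annotate(rec.id, o, textcoords="offset points", xytext=(3, -8), fontsize=7)
    ax.set_aspect("equal")
    ax.set_title(f"map {map_doc.map_id}")
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)
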