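"""SWC morphology and map-document I/O, plus arc-length resampling.

A *map* is one horizontal brain section: its contour, the 2-D position of
every labeled neuron inside it, and four anatomical reference points
(posterior, anterior, dorsal, ventral) placed per brain-atlas convention.
Morphologies come in as standard 7-column SWC files; only basal dendrites
(SWC type code 3) are analyzed.

Dendritic mass is represented as a cloud of planar sample points spaced
exactly ``step`` micrometres apart in arc length along each unbranched
section (default 0.5 um), which makes total dendritic length per angular
sector proportional to a simple point count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import MapValidationError, SWCParseError

__all__ = [
    "BranchSet",
    "SegmentCloud",
    "NeuronRecord",
    "MapDocument",
    "read_swc",
    "write_swc",
    "read_map",
    "resample",
    "DIRECTIONS",
    "LAYERS",
]

DIRECTIONS = ("posterior", "dorsal", "anterior", "ventral")
LAYERS = ("II", "III", "IV", "Va", "Vb", "VI")

_SOMA_TYPE = 1
_BASAL_TYPE = 3


@dataclass
class BranchSet:
    """Basal-dendrite sections of one neuron, rooted at the soma.

    Each branch is an unbranched polyline (k, 3) whose first vertex is its
    attachment point (the soma for first-order dendrites, the parent branch
    point otherwise), so per-branch arc-length resampling never double
    counts shared wiring.
    """

    soma: np.ndarray  # (3,) soma center, um
    branches: list  # list of (k, 3) float arrays, um

    def total_length(self, planar=False):
        total = 0.0
        for b in self.branches:
            seg = np.diff(b[:, :2] if planar else b, axis=0)
            total += float(np.linalg.norm(seg, axis=1).sum())
        return total


@dataclass
class SegmentCloud:
    """Planar dendritic sample points at fixed arc-length spacing."""

    points: np.ndarray  # (n, 2) map-plane coordinates, um
    soma: np.ndarray  # (2,) map-plane soma center, um
    step: float  # arc-length spacing, um
    distances: np.ndarray = field(default=None)  # (n,) planar distance to soma

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.soma = np.asarray(self.soma, dtype=float).reshape(2)
        if self.distances is None:
            self.distances = np.linalg.norm(self.points - self.soma, axis=1)

    def __len__(self):
        return self.points.shape[0]

    @property
    def vectors(self):
        """Soma-to-point vectors (n, 2)."""
        return self.points - self.soma


class NeuronRecord(BaseModel):
    """One labeled neuron within a map."""

    model_config = ConfigDict(frozen=True)

    id: str
    layer: Literal["II", "III", "IV", "Va", "Vb", "VI"]
    swc: Optional[str] = None  # morphology path, relative to the map file
    soma: Optional[tuple[float, float]] = None  # map-plane position, um


class MapDocument(BaseModel):
    """One horizontal section: reference points, contour, neurons."""

    model_config = ConfigDict(frozen=True)

    map_id: str
    reference_points: dict[str, tuple[float, float]]
    neurons: tuple[NeuronRecord, ...]
    contour: Optional[tuple[tuple[float, float], ...]] = None
    base_dir: Optional[str] = None  # directory the document was read from

    @field_validator("reference_points")
    @classmethod
    def _four_directions(cls, v):
        missing = [d for d in DIRECTIONS if d not in v]
        if missing:
            raise ValueError(f"missing reference point(s): {', '.join(missing)}")
        extra = [k for k in v if k not in DIRECTIONS]
        if extra:
            raise ValueError(f"unknown direction key(s): {', '.join(extra)}")
        return v

    @model_validator(mode="after")
    def _neurons_ok(self):
        if len(self.neurons) < 1:
            raise ValueError("a map must contain at least one neuron")
        ids = [n.id for n in self.neurons]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate neuron id(s): {', '.join(sorted(dupes))}")
        return self

    def swc_path(self, neuron: NeuronRecord) -> Path:
        p = Path(neuron.swc)
        if not p.is_absolute() and self.base_dir:
            p = Path(self.base_dir) / p
        return p


def read_map(path) -> MapDocument:
    """Read and validate a map JSON document."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    raw.setdefault("base_dir", str(path.parent))
    try:
        return MapDocument(**raw)
    except (ValueError, TypeError) as exc:
        raise MapValidationError(f"{path}: {exc}") from exc


def read_swc(path) -> BranchSet:
    """Parse an SWC file, returning basal-dendrite (type 3) sections only.

    The soma center is the coordinate of the root type-1 node, or the
    centroid when the soma is traced as several type-1 nodes.  Apical
    dendrites, axon and any other type codes are dropped.
    """
    path = Path(path)
    nodes = {}  # id -> (type, xyz, parent)
    order = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 7:
                raise SWCParseError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                ntype = int(parts[1])
                xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
                float(parts[5])  # radius: validated, unused
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"{path}:{lineno}: {exc}") from exc
            if nid in nodes:
                raise SWCParseError(f"{path}:{lineno}: duplicate node id {nid}")
            nodes[nid] = (ntype, xyz, parent, lineno)
            order.append(nid)

    if not nodes:
        raise SWCParseError(f"{path}: empty SWC file")

    # Validate the parent forest (detect cycles / dangling parents).
    state = {}  # 0 visiting, 1 done
    for nid in order:
        chain = []
        cur = nid
        while cur != -1 and state.get(cur) != 1:
            if state.get(cur) == 0:
                lineno = nodes[cur][3]
                raise SWCParseError(f"{path}:{lineno}: cyclic parent pointers at node {cur}")
            if cur not in nodes:
                raise SWCParseError(f"{path}: node {chain[-1]} references missing parent {cur}")
            state[cur] = 0
            chain.append(cur)
            cur = nodes[cur][2]
            if cur != -1 and cur not in nodes:
                raise SWCParseError(
                    f"{path}:{nodes[chain[-1]][3]}: missing parent node {cur}"
                )
        for c in chain:
            state[c] = 1

    soma_ids = [i for i in order if nodes[i][0] == _SOMA_TYPE]
    if not soma_ids:
        raise SWCParseError(f"{path}: no soma (type 1) node found")
    soma = np.mean([nodes[i][1] for i in soma_ids], axis=0)

    children = {}
    for nid in order:
        children.setdefault(nodes[nid][2], []).append(nid)

    def n_children(nid):
        return len(children.get(nid, []))

    # Decompose basal dendrites into unbranched sections.  A section starts
    # at a basal node whose parent is the soma or a branch point, and its
    # polyline includes the attachment coordinate as first vertex.
    branches = []
    basal = set(i for i in order if nodes[i][0] == _BASAL_TYPE)
    for nid in order:
        if nid not in basal:
            continue
        parent = nodes[nid][2]
        starts_section = (
            parent == -1
            or parent not in basal
            or n_children(parent) > 1
        )
        if not starts_section:
            continue
        if parent == -1 or parent not in nodes:
            anchor = soma
        elif nodes[parent][0] == _SOMA_TYPE:
            anchor = soma
        else:
            anchor = nodes[parent][1]
        poly = [anchor]
        cur = nid
        while True:
            poly.append(nodes[cur][1])
            kids = [k for k in children.get(cur, []) if k in basal]
            if len(kids) == 1 and n_children(cur) == 1:
                cur = kids[0]
            else:
                break
        branches.append(np.asarray(poly, dtype=float))
    return BranchSet(soma=soma, branches=branches)


def write_swc(path, branchset: BranchSet, soma_radius=5.0, neurite_radius=0.4):
    """Write a BranchSet as a minimal SWC file (soma node + type-3 branches).

    First-order branches are parented to the soma node; the shared first
    vertex of each branch is not duplicated.  Deterministic formatting
    (fixed precision) so identical inputs give byte-identical files.
    """
    lines = []
    soma = branchset.soma
    # 9 decimals (sub-nm): keeps arc lengths stable enough that a written
    # arbor resamples to exactly the same point count when read back.
    lines.append(
        f"1 1 {soma[0]:.9f} {soma[1]:.9f} {soma[2]:.9f} {soma_radius:.3f} -1"
    )
    next_id = 2
    # Map from vertex coordinates (rounded) to node id, so daughter branches
    # can attach to their parent branch's node.
    coord_ids = {tuple(np.round(soma, 9)): 1}
    for poly in branchset.branches:
        anchor = tuple(np.round(poly[0], 9))
        parent = coord_ids.get(anchor, 1)
        for vtx in poly[1:]:
            lines.append(
                f"{next_id} 3 {vtx[0]:.9f} {vtx[1]:.9f} {vtx[2]:.9f} "
                f"{neurite_radius:.3f} {parent}"
            )
            coord_ids.setdefault(tuple(np.round(vtx, 9)), next_id)
            parent = next_id
            next_id += 1
    Path(path).write_text("\n".join(lines) + "\n")


def _resample_polyline(poly, step, planar=False):
    """Sample points at arc lengths k*step, k = 1..floor(L/step)."""
    seg = np.diff(poly[:, :2] if planar else poly, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    # floor with a relative guard: synthetic branches routinely end within
    # float noise of an exact multiple of the step, and the guard keeps the
    # count stable across write/read round trips
    n = int(np.floor(total / step + 1e-6))
    if n == 0:
        return np.empty((0, poly.shape[1]))
    targets = step * np.arange(1, n + 1)
    targets = np.minimum(targets, total)  # guard fp overshoot at the tip
    cols = [np.interp(targets, cum, poly[:, k]) for k in range(poly.shape[1])]
    return np.stack(cols, axis=1)


def resample(
    branchset: BranchSet,
    step: float = 0.5,
    drop_axis: str = "z",
    planar_arclength: bool = False,
    soma_xy=None,
) -> SegmentCloud:
    """Resample a basal arbor into a planar SegmentCloud.

    Arc length is measured along the 3-D polyline and the samples are then
    projected onto the map plane by dropping ``drop_axis`` (the sectioning
    axis, default z).  With ``planar_arclength=True`` arc length is instead
    measured on the already-projected polylines.  Branch tips with residual
    length < ``step`` contribute no point, so consecutive samples along any
    one branch are exactly ``step`` apart in arc length.

    ``soma_xy`` translates the cloud into map-frame coordinates: SWC
    coordinates are treated as soma-relative and the arbor is re-anchored
    at the given map-plane soma position.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    keep = {"x": [1, 2], "y": [0, 2], "z": [0, 1]}.get(drop_axis)
    if keep is None:
        raise ValueError(f"drop_axis must be one of x, y, z; got {drop_axis!r}")

    samples = []
    for poly in branchset.branches:
        pts = _resample_polyline(np.asarray(poly, float), step, planar=planar_arclength)
        if len(pts):
            samples.append(pts[:, keep])
    points = np.concatenate(samples, axis=0) if samples else np.empty((0, 2))
    soma2d = branchset.soma[keep]
    if soma_xy is not None:
        soma_xy = np.asarray(soma_xy, dtype=float)
        points = points - soma2d + soma_xy
        soma2d = soma_xy
    return SegmentCloud(points=points, soma=soma2d, step=step)
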