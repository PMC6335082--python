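"""Fisher-median per-neuron orientation and map-level tendency rules.

A neuron's main orientation is the sector containing the Fisher circular
median of all its sample-point angles; when the median falls exactly on a
sector boundary the circular mean direction decides instead (the median
alone is then "unclear").  At the map level the individual sector calls
are pooled into per-direction counts and a tendency label is derived from
percentage rules:

* oriented(j)        — > 80% of the neurons call sector j
* oriented(j1-j2)    — two contiguous sectors hold 100% of the neurons,
                       with at least 50% in one and 30% in the other
* partly(j1-j2)      — same 50/30 gate but the pair holds > 80%
* partly(j)          — > 60% call sector j
* undetermined       — none of the above

Full labels outrank partial ones and, at equal strength, pair labels
outrank single ones; comparisons are strict for the > rules and inclusive
for the "at least" 50/30 gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .circstats import circular_distance, fisher_median, mean_direction
from .dlrm import CONTIGUOUS_PAIRS, SHORT
from .errors import UndefinedMeanError
from .io import DIRECTIONS
from .sectors import SectorPartition

__all__ = [
    "NeuronDirectionCall", "MapTendency",
    "call_neuron", "map_tendency",
    "load_table1", "validate_table1", "parse_tendency_label",
]

log = logging.getLogger(__name__)

_LONG = {v: k for k, v in SHORT.items()}
# Canonical iteration order over contiguous pairs (deterministic output).
_PAIR_ORDER = (
    ("anterior", "ventral"),
    ("anterior", "dorsal"),
    ("dorsal", "posterior"),
    ("posterior", "ventral"),
)


@dataclass(frozen=True)
class NeuronDirectionCall:
    """Sector call for one neuron from its median (or fallback mean) direction."""

    median: float
    mean: float | None
    sector: str | None  # None when the call is unclear
    fallback_used: bool

    @property
    def unclear(self):
        return self.sector is None


@dataclass(frozen=True)
class MapTendency:
    """Group-level orientation tendency of one map."""

    counts: dict  # direction -> neuron count
    n: int
    kind: str  # "oriented" | "partly" | "undetermined"
    directions: tuple  # () for undetermined, 1 or 2 direction names otherwise

    @property
    def label(self) -> str:
        if self.kind == "undetermined":
            return "Undetermined"
        code = "-".join(SHORT[d] for d in self.directions)
        return code if self.kind == "oriented" else f"Partly {code}"


def call_neuron(angles, partition: SectorPartition, boundary_tol=1e-12) -> NeuronDirectionCall:
    """Orientation sector of one neuron via the Fisher median direction.

    The mean direction is used for support when the median is unclear,
    i.e. lies exactly on a sector boundary (within ``boundary_tol``).  If
    the mean is also on a boundary, or undefined, the call is unclear
    (sector None) and a warning is logged.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("no dendrite: empty angle set")
    med = fisher_median(angles)
    try:
        mu = mean_direction(angles)
    except UndefinedMeanError:
        mu = None
    bounds = np.asarray(partition.boundaries)

    def on_boundary(theta):
        return bool(np.min(circular_distance(bounds, theta)) <= boundary_tol)

    if not on_boundary(med):
        sector = str(partition.sector_of(med)[0])
        return NeuronDirectionCall(median=med, mean=mu, sector=sector, fallback_used=False)
    if mu is not None and not on_boundary(mu):
        sector = str(partition.sector_of(mu)[0])
        return NeuronDirectionCall(median=med, mean=mu, sector=sector, fallback_used=True)
    log.warning("orientation call unclear: median on a sector boundary and mean unusable")
    return NeuronDirectionCall(median=med, mean=mu, sector=None, fallback_used=True)


def map_tendency(counts, n=None) -> MapTendency:
    """Tendency label of one map from its per-direction neuron counts."""
    counts = {j: counts[j] for j in DIRECTIONS}
    total = sum(counts.values())
    if n is None:
        n = total
    if total != n or n < 1:
        raise ValueError(f"counts sum to {total}, expected n = {n} >= 1")
    frac = {j: counts[j] / n for j in DIRECTIONS}

    def pair_gate(j1, j2):
        hi, lo = max(frac[j1], frac[j2]), min(frac[j1], frac[j2])
        return hi >= 0.5 and lo >= 0.3

    # (1) fully oriented toward a single direction
    for j in DIRECTIONS:
        if frac[j] > 0.8:
            return MapTendency(counts=counts, n=n, kind="oriented", directions=(j,))
    # (2) fully oriented toward a contiguous pair (pair holds every neuron)
    for j1, j2 in _PAIR_ORDER:
        if frac[j1] + frac[j2] >= 1.0 and pair_gate(j1, j2):
            return MapTendency(counts=counts, n=n, kind="oriented", directions=(j1, j2))
    # (3) partly oriented toward a contiguous pair
    for j1, j2 in _PAIR_ORDER:
        if frac[j1] + frac[j2] > 0.8 and pair_gate(j1, j2):
            return MapTendency(counts=counts, n=n, kind="partly", directions=(j1, j2))
    # (4) partly oriented toward a single direction
    for j in DIRECTIONS:
        if frac[j] > 0.6:
            return MapTendency(counts=counts, n=n, kind="partly", directions=(j,))
    return MapTendency(counts=counts, n=n, kind="undetermined", directions=())


def parse_tendency_label(text: str):
    """Normalize a printed tendency label to (kind, direction frozenset)."""
    text = text.strip()
    if text.lower() == "undetermined":
        return ("undetermined", frozenset())
    kind = "oriented"
    if text.lower().startswith("partly"):
        kind = "partly"
        text = text[len("partly"):].strip()
    dirs = frozenset(_LONG[c] for c in text.split("-"))
    return (kind, dirs)


def load_table1() -> pd.DataFrame:
    """Packaged per-map Fisher-method count fixture (44 horizontal sections).

    Columns: map_id, layer, n_cells, P, D, A, V, tendency (the published
    group label for that map).
    """
    with resources.files("dendrorient.data").joinpath("table1_counts.csv").open() as fh:
        return pd.read_csv(fh)


def validate_table1(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run the tendency rule engine over the packaged per-map counts.

    Returns the fixture with ``engine_label`` and ``matches`` columns, for
    auditing the rule engine against the published labels map by map.
    """
    if table is None:
        table = load_table1()
    rows = []
    for _, row in table.iterrows():
        counts = {
            "posterior": int(row["P"]), "dorsal": int(row["D"]),
            "anterior": int(row["A"]), "ventral": int(row["V"]),
        }
        tendency = map_tendency(counts, int(row["n_cells"]))
        expected = parse_tendency_label(str(row["tendency"]))
        got = (tendency.kind, frozenset(tendency.directions))
        rows.append({
            **row,
            "engine_label": tendency.label,
            "engine_kind": tendency.kind,
            "matches": got == expected,
        })
    return pd.DataFrame(rows)
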