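"""Dendritic length ratio method (DLRM).

For neuron i and direction j, TL_ij is the fraction of the neuron's total
dendritic length (0.5 um sample points) falling in sector j and PS_ij the
fraction of the circle that sector occupies.  The ratio TL_ij / PS_ij
compares observed to expected dendritic mass: ratios above a threshold
t > 1 mark a growth-orientation preference for j; ratios in (1, t) mark a
weak (sub-threshold) preference.  Because sum_j PS_ij * ratio_ij = 1
identically, at most three directions can ever exceed any t > 1, so a
neuron's preferred set has size 0-3: undetermined, single, double
(contiguous or opposite) or triple orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import DIRECTIONS
from .sectors import SectorAssignment, SectorPartition

__all__ = [
    "SHORT", "CONTIGUOUS_PAIRS", "OPPOSITE_PAIRS", "CLASS_LABELS",
    "OrientationRatios", "NeuronOrientationCall",
    "compute_ratios", "classify_neuron", "class_label", "summarize_group",
]

SHORT = {"posterior": "P", "dorsal": "D", "anterior": "A", "ventral": "V"}
_ORDER = {"P": 0, "D": 1, "A": 2, "V": 3}

CONTIGUOUS_PAIRS = frozenset({
    frozenset({"anterior", "ventral"}),
    frozenset({"anterior", "dorsal"}),
    frozenset({"dorsal", "posterior"}),
    frozenset({"posterior", "ventral"}),
})
OPPOSITE_PAIRS = frozenset({
    frozenset({"anterior", "posterior"}),
    frozenset({"dorsal", "ventral"}),
})

# Canonical class columns for group summaries: four singles, six pairs,
# four triples, undetermined.
CLASS_LABELS = (
    "P", "D", "A", "V",
    "A-V", "A-D", "A-P", "D-P", "D-V", "P-V",
    "P-D-A", "P-D-V", "P-A-V", "D-A-V",
    "Und.",
)


@dataclass(frozen=True)
class OrientationRatios:
    """Per-direction TL, PS and TL/PS ratios for one neuron."""

    tl: dict
    ps: dict
    ratio: dict
    threshold: float

    def __post_init__(self):
        # sum_j PS_j * ratio_j == sum_j TL_j == 1 is an identity of the
        # construction; assert it so every downstream call inherits the
        # "at most 3 preferred directions" bound as a theorem.
        check = sum(self.ps[j] * self.ratio[j] for j in DIRECTIONS)
        assert abs(check - 1.0) < 1e-9, f"conservation violated: {check}"


@dataclass(frozen=True)
class NeuronOrientationCall:
    """DLRM orientation call for one neuron at one threshold."""

    preferred: frozenset  # directions with ratio > t (size 0-3)
    weak: frozenset  # directions with 1 < ratio < t
    type: str  # undetermined | single | contiguous | opposite | triple
    threshold: float


def compute_ratios(
    assignment: SectorAssignment,
    partition: SectorPartition,
    threshold: float,
) -> OrientationRatios:
    """TL, PS and TL/PS per direction from one neuron's sector counts."""
    if threshold <= 1.0:
        raise ValueError(f"threshold must exceed 1, got {threshold}")
    total = assignment.total
    if total == 0:
        raise ValueError("no dendrite: the segment cloud is empty")
    ps = partition.arc_fractions
    tl = {j: assignment.counts[j] / total for j in DIRECTIONS}
    ratio = {j: tl[j] / ps[j] for j in DIRECTIONS}
    return OrientationRatios(tl=tl, ps=ps, ratio=ratio, threshold=threshold)


def classify_neuron(ratios: OrientationRatios) -> NeuronOrientationCall:
    """Preferred/weak direction sets and orientation type at one threshold.

    Strict rules on both sides: ratio == t is not preferred and
    ratio == 1 is not weak.
    """
    t = ratios.threshold
    preferred = frozenset(j for j in DIRECTIONS if ratios.ratio[j] > t)
    weak = frozenset(j for j in DIRECTIONS if 1.0 < ratios.ratio[j] < t)
    k = len(preferred)
    assert k <= 3, "conservation forbids 4 preferred directions"
    if k == 0:
        kind = "undetermined"
    elif k == 1:
        kind = "single"
    elif k == 2:
        kind = "contiguous" if preferred in CONTIGUOUS_PAIRS else "opposite"
    else:
        kind = "triple"
    return NeuronOrientationCall(preferred=preferred, weak=weak, type=kind, threshold=t)


def class_label(preferred) -> str:
    """Canonical class column for a preferred set (e.g. {A, V} -> 'A-V').

    Singles use the direction letter; pairs use the canonical pair order;
    triples list members in P, D, A, V order; the empty set is 'Und.'.
    """
    codes = sorted((SHORT[j] for j in preferred), key=_ORDER.get)
    if not codes:
        return "Und."
    if len(codes) == 1:
        return codes[0]
    if len(codes) == 2:
        pair = frozenset(preferred)
        for lab in ("A-V", "A-D", "A-P", "D-P", "D-V", "P-V"):
            names = frozenset(
                j for j in DIRECTIONS if SHORT[j] in lab.split("-")
            )
            if names == pair:
                return lab
    return "-".join(codes)


def summarize_group(calls: pd.DataFrame, by="map_id") -> pd.DataFrame:
    """Frequency table of orientation classes per group and threshold.

    ``calls`` must hold one row per neuron per threshold with columns
    ``threshold``, ``class`` (a CLASS_LABELS value) and the grouping
    column(s).  Returns counts with one row per (group, threshold) and one
    column per class; class counts always sum to the group's neuron count.
    """
    keys = [by] if isinstance(by, str) else list(by)
    for col in keys + ["threshold", "class"]:
        if col not in calls.columns:
            raise ValueError(f"calls frame lacks required column {col!r}")
    per_group = calls.groupby(keys + ["threshold"], sort=True).size()
    table = (
        calls.groupby(keys + ["threshold", "class"], sort=True)
        .size()
        .unstack("class", fill_value=0)
        .reindex(columns=list(CLASS_LABELS), fill_value=0)
    )
    table["n_cells"] = per_group
    return table.reset_index()
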