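"""End-to-end analysis pipelines: maps in, per-neuron and per-map tables out."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from . import dlrm as _dlrm
from .fisher import call_neuron, map_tendency
from .io import DIRECTIONS, MapDocument, read_map, read_swc, resample
from .sectors import assign_sectors, build_partition

__all__ = ["RunConfig", "NeuronResult", "analyze_neuron", "analyze_map", "analyze_maps"]

log = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Pipeline parameters (defaults match the method's published settings)."""

    model_config = ConfigDict(frozen=True)

    step: float = 0.5  # um between dendritic sample points
    thresholds: tuple[float, ...] = (1.1, 1.2, 1.3)
    boundary_mode: str = "bisector"  # or "rays"
    planar_arclength: bool = False  # measure arc length after projection
    drop_axis: str = "z"

    @field_validator("step")
    @classmethod
    def _step_pos(cls, v):
        if v <= 0:
            raise ValueError("step must be > 0")
        return v

    @field_validator("thresholds")
    @classmethod
    def _t_gt_one(cls, v):
        if not v or any(t <= 1.0 for t in v):
            raise ValueError("all thresholds must exceed 1")
        return tuple(sorted(v))


@dataclass
class NeuronResult:
    """Everything computed for one neuron (kept for plotting)."""

    map_id: str
    neuron_id: str
    layer: str
    cloud: object
    partition: object
    assignment: object
    ratios: object  # OrientationRatios (threshold-independent TL/PS/ratio)
    calls: dict  # threshold -> NeuronOrientationCall
    direction_call: object  # NeuronDirectionCall (Fisher method)


def analyze_neuron(branchset, soma_xy, map_doc: MapDocument, cfg: RunConfig,
                   neuron_id="n", layer="II") -> NeuronResult:
    """Run the full per-neuron pipeline on one arbor."""
    cloud = resample(
        branchset, step=cfg.step, drop_axis=cfg.drop_axis,
        planar_arclength=cfg.planar_arclength, soma_xy=soma_xy,
    )
    partition = build_partition(cloud.soma, map_doc.reference_points,
                                mode=cfg.boundary_mode)
    assignment = assign_sectors(cloud, partition)
    ratios = _dlrm.compute_ratios(assignment, partition, cfg.thresholds[0])
    calls = {
        t: _dlrm.classify_neuron(
            _dlrm.compute_ratios(assignment, partition, t)
        )
        for t in cfg.thresholds
    }
    alpha = partition.angles_of(cloud.points[np.linalg.norm(cloud.vectors, axis=1) > 0])
    dcall = call_neuron(alpha, partition)
    return NeuronResult(
        map_id=map_doc.map_id, neuron_id=neuron_id, layer=layer,
        cloud=cloud, partition=partition, assignment=assignment,
        ratios=ratios, calls=calls, direction_call=dcall,
    )


def analyze_map(map_doc: MapDocument, cfg: RunConfig,
                arbors: Optional[dict] = None) -> list:
    """Analyze every neuron of one map.

    ``arbors`` optionally supplies in-memory BranchSets by neuron id;
    otherwise morphologies are read from the SWC paths in the document.
    Neurons that fail (missing file, empty arbor) are skipped with a
    warning.
    """
    results = []
    for rec in map_doc.neurons:
        try:
            if arbors is not None and rec.id in arbors:
                bset = arbors[rec.id]
            elif rec.swc is not None:
                bset = read_swc(map_doc.swc_path(rec))
            else:
                raise ValueError("no morphology available")
            soma_xy = rec.soma if rec.soma is not None else bset.soma[:2]
            results.append(
                analyze_neuron(bset, soma_xy, map_doc, cfg,
                               neuron_id=rec.id, layer=rec.layer)
            )
        except Exception as exc:  # keep going; the CLI reports skips
            log.warning("map %s neuron %s skipped: %s", map_doc.map_id, rec.id, exc)
    return results


def neuron_table(results) -> pd.DataFrame:
    """One row per neuron per threshold: TL, PS, ratios, preferred/weak/type."""
    rows = []
    for res in results:
        for t, call in res.calls.items():
            row = {
                "map_id": res.map_id, "neuron_id": res.neuron_id,
                "layer": res.layer, "threshold": t,
            }
            for j in DIRECTIONS:
                code = _dlrm.SHORT[j]
                row[f"TL_{code}"] = res.ratios.tl[j]
                row[f"PS_{code}"] = res.ratios.ps[j]
                row[f"ratio_{code}"] = res.ratios.ratio[j]
            row["preferred"] = _dlrm.class_label(call.preferred)
            row["weak"] = "+".join(sorted(_dlrm.SHORT[j] for j in call.weak))
            row["type"] = call.type
            row["class"] = _dlrm.class_label(call.preferred)
            rows.append(row)
    return pd.DataFrame(rows)


def fisher_table(results_by_map) -> pd.DataFrame:
    """Per-map Fisher-method counts and tendency label (one row per map)."""
    rows = []
    for map_id, results in results_by_map.items():
        counts = {j: 0 for j in DIRECTIONS}
        n = 0
        for res in results:
            if res.direction_call.sector is None:
                continue
            counts[res.direction_call.sector] += 1
            n += 1
        if n == 0:
            log.warning("map %s: no usable Fisher calls", map_id)
            continue
        tendency = map_tendency(counts, n)
        rows.append({
            "map_id": map_id, "n_cells": n,
            "n_P": counts["posterior"], "n_D": counts["dorsal"],
            "n_A": counts["anterior"], "n_V": counts["ventral"],
            "tendency": tendency.label,
        })
    return pd.DataFrame(rows)


def analyze_maps(paths, cfg: RunConfig):
    """Analyze several map documents from disk.

    Returns ``(neuron_df, dlrm_group_df, fisher_df, results_by_map)``.
    """
    results_by_map = {}
    for path in paths:
        doc = read_map(path)
        log.info("analyzing map %s (%d neurons)", doc.map_id, len(doc.neurons))
        results_by_map[doc.map_id] = analyze_map(doc, cfg)
    all_results = [r for rs in results_by_map.values() for r in rs]
    ndf = neuron_table(all_results)
    group = _dlrm.summarize_group(ndf, by="map_id") if len(ndf) else pd.DataFrame()
    fdf = fisher_table(results_by_map)
    return ndf, group, fdf, results_by_map
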