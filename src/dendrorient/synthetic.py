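"""Synthetic maps and basal arbors with known orientation structure.

The generator emulates the study's data geometry — horizontal sections
("maps") holding 6 +/- 2 labeled neurons each, with four anatomical
reference points — and grows planar basal arbors as tortuous random
walks: each primary branch takes its initial bearing from a von Mises
mixture (the orientation dial; kappa = 0 gives uniform, unoriented
arbors) and then wanders with wrapped-normal per-step heading jitter.
Every generated neuron carries its generating parameters and intended
orientation label, so classifier recovery is testable end to end without
any external data.

Map-frame convention: anterior = +x, posterior = -x, dorsal = +y,
ventral = -y (reference points may be jittered off these axes).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .circstats import circular_distance
from .dlrm import classify_neuron, compute_ratios
from .io import BranchSet, MapDocument, NeuronRecord, resample, write_swc
from .sectors import assign_sectors, build_partition

__all__ = [
    "BiasComponent", "SyntheticConfig", "GroundTruth",
    "axis_bearings", "generate_neuron", "generate_map", "recovery_experiment",
]

AXIS_BEARINGS = {
    "anterior": 0.0,
    "dorsal": math.pi / 2.0,
    "posterior": math.pi,
    "ventral": -math.pi / 2.0,
}


def axis_bearings():
    """Map-frame bearing of each anatomical axis (radians, atan2 convention)."""
    return dict(AXIS_BEARINGS)


class BiasComponent(BaseModel):
    """One von Mises component over initial branch bearings."""

    model_config = ConfigDict(frozen=True)

    mu: float | str  # absolute map-frame bearing (rad) or a direction name
    kappa: float = 0.0
    weight: float = 1.0

    @field_validator("kappa")
    @classmethod
    def _kappa_nonneg(cls, v):
        if v < 0:
            raise ValueError("kappa must be >= 0")
        return v

    @field_validator("weight")
    @classmethod
    def _weight_pos(cls, v):
        if v <= 0:
            raise ValueError("weight must be > 0")
        return v

    def resolve_mu(self) -> float:
        if isinstance(self.mu, str):
            return AXIS_BEARINGS[self.mu]
        return float(self.mu)


class SyntheticConfig(BaseModel):
    """Study-condition parameters for the generator.

    Defaults mirror the emulated dataset: 6 +/- 2 neurons per section,
    3-8 primary basal branches per neuron of ~100 um, gentle tortuosity
    (heading jitter sd 0.06 rad per 1 um growth step, path/chord ~ 1.1),
    and reference points ~2 mm from the section center.
    """

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_maps: int = 1
    neurons_per_map: Optional[int] = None  # fixed count override
    neurons_per_map_mean: float = 6.0
    neurons_per_map_sd: float = 2.0
    branches_range: tuple[int, int] = (3, 8)
    branch_length_mean: float = 100.0  # um
    branch_length_sd: float = 25.0  # um
    branch_length_min: float = 20.0  # um
    growth_step: float = 1.0  # um per random-walk step
    tortuosity: float = 0.06  # heading jitter sd, rad per step
    bifurcations_range: tuple[int, int] = (0, 2)
    bias: tuple[BiasComponent, ...] = (BiasComponent(mu=0.0, kappa=0.0),)
    uniform_fraction: float = 0.0  # fraction of neurons forced unoriented
    frame_radius: float = 2000.0  # um, soma-to-reference-point scale
    frame_jitter: float = 0.0  # um sd of reference-point placement noise
    contour_radius: float = 600.0  # um
    layer: str = "II"

    @field_validator("bias")
    @classmethod
    def _weights_normalizable(cls, v):
        if not v:
            raise ValueError("bias mixture needs at least one component")
        return v

    def mixture(self):
        mus = np.array([c.resolve_mu() for c in self.bias])
        kappas = np.array([c.kappa for c in self.bias])
        w = np.array([c.weight for c in self.bias], dtype=float)
        return mus, kappas, w / w.sum()


class GroundTruth:
    """Per-neuron generating parameters and intended orientation labels."""

    def __init__(self):
        self.rows = []

    def add(self, map_id, neuron_id, mus, kappas, weights, intended):
        self.rows.append({
            "map_id": map_id,
            "neuron_id": neuron_id,
            "mu": "+".join(f"{m:.4f}" for m in mus),
            "kappa": "+".join(f"{k:.3f}" for k in kappas),
            "weight": "+".join(f"{w:.3f}" for w in weights),
            "intended": intended,
        })

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["map_id", "neuron_id", "mu", "kappa", "weight", "intended"],
        )


def _nearest_axis(mu):
    return min(AXIS_BEARINGS, key=lambda j: circular_distance(AXIS_BEARINGS[j], mu))


def intended_label(mus, kappas, weights, min_kappa=2.0, min_weight=0.2):
    """Intended orientation from the generating mixture.

    Components too diffuse (kappa below ``min_kappa``) or too light carry
    no intended direction; with none left the neuron is 'undetermined'.
    """
    dirs = sorted({
        _nearest_axis(m)
        for m, k, w in zip(mus, kappas, weights)
        if k >= min_kappa and w >= min_weight
    })
    return "+".join(dirs) if dirs else "undetermined"


def _grow_branch(rng, start, bearing, length, cfg: SyntheticConfig):
    """Tortuous planar random-walk polyline from ``start`` (3-D, z kept)."""
    n_steps = max(1, int(round(length / cfg.growth_step)))
    jitter = rng.normal(0.0, cfg.tortuosity, size=n_steps)
    jitter[0] = 0.0  # first step exactly at the drawn bearing
    headings = bearing + np.cumsum(jitter)
    steps = cfg.growth_step * np.stack(
        [np.cos(headings), np.sin(headings), np.zeros(n_steps)], axis=1
    )
    return np.vstack([start, start + np.cumsum(steps, axis=0)])


def generate_neuron(rng, cfg: SyntheticConfig, soma=(0.0, 0.0, 0.0),
                    mixture=None) -> BranchSet:
    """Grow one synthetic basal arbor (soma-anchored sections)."""
    soma = np.asarray(soma, dtype=float)
    mus, kappas, weights = cfg.mixture() if mixture is None else mixture
    n_branches = int(rng.integers(cfg.branches_range[0], cfg.branches_range[1] + 1))
    branches = []
    for _ in range(n_branches):
        comp = int(rng.choice(len(weights), p=weights))
        bearing = float(rng.vonmises(mus[comp], kappas[comp]))
        length = max(cfg.branch_length_min,
                     float(rng.normal(cfg.branch_length_mean, cfg.branch_length_sd)))
        poly = _grow_branch(rng, soma, bearing, length, cfg)
        lo, hi = cfg.bifurcations_range
        n_bif = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        daughters = []
        attach = []
        for _ in range(n_bif):
            if len(poly) < 3:
                continue
            vtx = int(rng.integers(1, len(poly) - 1))
            seg = poly[vtx] - poly[vtx - 1]
            parent_heading = math.atan2(seg[1], seg[0])
            dh = float(rng.normal(0.0, 0.4))
            dlen = max(cfg.branch_length_min / 2.0,
                       float(rng.normal(cfg.branch_length_mean / 2.0,
                                        cfg.branch_length_sd / 2.0)))
            daughters.append(_grow_branch(rng, poly[vtx], parent_heading + dh, dlen, cfg))
            attach.append(vtx)
        # split the parent at attachment vertices so the branch list is a
        # proper section decomposition (matches what read_swc reconstructs)
        cuts = sorted(set(attach))
        prev = 0
        for c in cuts:
            branches.append(poly[prev : c + 1])
            prev = c
        branches.append(poly[prev:])
        branches.extend(daughters)
    return BranchSet(soma=soma, branches=branches)


def _contour(cfg, n_vertices=36):
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return [
        (round(cfg.contour_radius * math.cos(a), 3),
         round(cfg.contour_radius * math.sin(a), 3))
        for a in ang
    ]


def generate_map(cfg: SyntheticConfig, map_index=0, rng=None, out_dir=None):
    """Generate one synthetic map.

    Returns ``(map_doc, arbors, ground_truth)`` where ``arbors`` maps
    neuron id -> BranchSet in soma-relative (SWC) coordinates.  With
    ``out_dir`` set, SWC files and the map JSON are written there
    deterministically (same seed -> byte-identical files).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + map_index)
    map_id = f"sim{map_index + 1}{cfg.layer}"

    refs = {}
    for j, bearing in AXIS_BEARINGS.items():
        p = cfg.frame_radius * np.array([math.cos(bearing), math.sin(bearing)])
        if cfg.frame_jitter > 0:
            p = p + rng.normal(0.0, cfg.frame_jitter, size=2)
        refs[j] = (round(float(p[0]), 3), round(float(p[1]), 3))

    if cfg.neurons_per_map is not None:
        n_neurons = cfg.neurons_per_map
    else:
        n_neurons = max(1, int(round(rng.normal(cfg.neurons_per_map_mean,
                                                cfg.neurons_per_map_sd))))

    truth = GroundTruth()
    arbors = {}
    records = []
    for k in range(n_neurons):
        nid = f"n{k + 1}"
        r = 0.6 * cfg.contour_radius * math.sqrt(rng.uniform())
        phi = rng.uniform(-math.pi, math.pi)
        soma_xy = (round(r * math.cos(phi), 3), round(r * math.sin(phi), 3))
        if rng.uniform() < cfg.uniform_fraction:
            mixture = (np.array([0.0]), np.array([0.0]), np.array([1.0]))
        else:
            mixture = cfg.mixture()
        arbor = generate_neuron(rng, cfg, soma=(0.0, 0.0, 0.0), mixture=mixture)
        arbors[nid] = arbor
        truth.add(map_id, nid, *mixture, intended_label(*mixture))
        records.append(NeuronRecord(
            id=nid, layer=cfg.layer, soma=soma_xy,
            swc=f"{map_id}_{nid}.swc" if out_dir else None,
        ))

    doc = MapDocument(
        map_id=map_id,
        reference_points=refs,
        neurons=tuple(records),
        contour=tuple(_contour(cfg)),
        base_dir=str(out_dir) if out_dir else None,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in records:
            write_swc(out_dir / rec.swc, arbors[rec.id])
        payload = {
            "map_id": doc.map_id,
            "reference_points": {j: list(refs[j]) for j in sorted(refs)},
            "contour": [list(v) for v in doc.contour],
            "neurons": [
                {"id": r.id, "layer": r.layer, "swc": r.swc, "soma": list(r.soma)}
                for r in records
            ],
        }
        with open(out_dir / f"{map_id}.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        truth.frame().to_csv(out_dir / f"{map_id}_truth.csv", index=False)
    return doc, arbors, truth.frame()


def _classify_synthetic(arbor, refs, thresholds, step=0.5):
    """Run the DLRM pipeline on one in-memory arbor at several thresholds."""
    cloud = resample(arbor, step=step)
    partition = build_partition(cloud.soma, refs)
    assignment = assign_sectors(cloud, partition)
    out = {}
    for t in thresholds:
        out[t] = classify_neuron(compute_ratios(assignment, partition, t))
    return out


def recovery_experiment(
    kappas=(0.0, 2.0, 4.0, 8.0),
    thresholds=(1.1, 1.2, 1.3),
    n_replicates=50,
    n_branches=40,
    branch_length=100.0,
    mu_direction="anterior",
    seed=0,
    step=0.5,
) -> pd.DataFrame:
    """Monte-Carlo recovery of the generating orientation by the DLRM.

    For each bias strength kappa, ``n_replicates`` neurons are grown with
    all primary-branch bearings drawn von Mises around ``mu_direction``
    (kappa = 0: uniform, intended call 'undetermined'; kappa > 0:
    intended call single orientation toward that direction).  Accuracy is
    the fraction of replicates whose DLRM call at threshold t equals the
    intended call, with binomial standard errors.
    """
    if not len(kappas):
        raise ValueError("empty kappa grid")
    refs = {
        j: tuple(2000.0 * np.array([math.cos(b), math.sin(b)]))
        for j, b in AXIS_BEARINGS.items()
    }
    rows = []
    for ik, kappa in enumerate(kappas):
        rng = np.random.default_rng(seed + 1000 * ik)
        cfg = SyntheticConfig(
            branches_range=(n_branches, n_branches),
            branch_length_mean=branch_length,
            branch_length_sd=0.0,
            bifurcations_range=(0, 0),
            bias=(BiasComponent(mu=mu_direction, kappa=kappa),),
        )
        intended = (
            frozenset() if kappa < 2.0 else frozenset({mu_direction})
        )
        hits = {t: 0 for t in thresholds}
        for _ in range(n_replicates):
            arbor = generate_neuron(rng, cfg)
            calls = _classify_synthetic(arbor, refs, thresholds, step=step)
            for t in thresholds:
                if calls[t].preferred == intended:
                    hits[t] += 1
        for t in thresholds:
            acc = hits[t] / n_replicates
            rows.append({
                "kappa": kappa,
                "threshold": t,
                "accuracy": acc,
                "se": math.sqrt(max(acc * (1 - acc), 1e-12) / n_replicates),
                "n": n_replicates,
            })
    return pd.DataFrame(rows)
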