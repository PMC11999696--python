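"""Synthetic-data generators for every pipeline input.

Three generators emulate the statistical structure the analysis assumes:

* :func:`simulate_cell_map` — 1-D parasagittal maps with first-order Markov
  label copying of tunable strength κ (cell *i* copies cell *i−1*'s
  five-class label with probability κ, else draws from the configured
  frequencies), truncated-normal soma spacings, and an alternating
  gyrus/bank/sulcus segmentation plan.
* :func:`simulate_arbor` — stochastic binary branching trees with
  species-scaled size: cable is grown tip by tip under a per-cell total
  length budget, bifurcating with fixed probability at each segment end,
  with upward-biased directions capped at the molecular-layer thickness.
* :func:`simulate_spiny_branch` — spiny branch segments with per-type
  Poisson spine counts and per-type head-size distributions.

Every generator is deterministic under a fixed seed and emits exact
ground-truth bookkeeping alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import presets
from .classify import (
    THRESHOLDS, DendriteTrace, PrimaryDendriteFeatures,
)
from .io import Arbor
from .spines import SpineRecord, SpinyBranchSegment, sphere_volume

__all__ = [
    "MapSimConfig",
    "ArborSimConfig",
    "SpineSimConfig",
    "simulate_cell_map",
    "simulate_arbor",
    "simulate_spiny_branch",
    "sample_classifier_features",
    "human_map_config",
    "mouse_map_config",
    "human_arbor_config",
    "mouse_arbor_config",
    "human_spine_config",
    "mouse_spine_config",
]

FIVE_CLASSES = ("Normative", "V-Split", "H-Split", "V-Poly", "H-Poly")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float = math.inf, size=None) -> np.ndarray:
    """Normal draws clipped into [low, high] (simple clipping; the tails
    carry negligible mass for every preset used here)."""
    return np.clip(rng.normal(mean, sd, size=size), low, high)


# ======================================================================
# cell maps
# ======================================================================

@dataclass
class MapSimConfig:
    n_cells: int
    category_frequencies: dict = field(
        default_factory=lambda: dict(presets.HUMAN_CLASS_FREQUENCIES))
    copy_probability: float = presets.DEFAULT_COPY_PROBABILITY
    spacing_mean: float = presets.HUMAN_SOMA_SPACING_UM[0]
    spacing_sd: float = presets.HUMAN_SOMA_SPACING_UM[1]
    foliar_plan: tuple = presets.HUMAN_FOLIAR_PLAN
    lobules: tuple = presets.HUMAN_LOBULES
    hemisphere: str = "vermis"
    individual: str = "sim-1"
    species: str = "human"
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        freqs = np.array([self.category_frequencies.get(c, 0.0) for c in FIVE_CLASSES])
        if not math.isclose(freqs.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("category frequencies must sum to 1")
        if np.any(freqs < 0):
            raise ValueError("category frequencies must be >= 0")
        if not 0.0 <= self.copy_probability < 1.0:
            raise ValueError("copy probability must lie in [0, 1)")
        if self.spacing_mean <= 0:
            raise ValueError("spacing mean must be positive")


def simulate_cell_map(config: MapSimConfig,
                      rng: np.random.Generator | None = None):
    """Generate one ordered parasagittal cell map.

    Returns ``(DataFrame, ground_truth)`` where the ground truth records the
    generative parameters and the realised label counts.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    freqs = np.array([config.category_frequencies.get(c, 0.0) for c in FIVE_CLASSES])
    freqs = freqs / freqs.sum()

    spacing = _truncated_normal(
        rng, config.spacing_mean, config.spacing_sd,
        low=max(1.0, config.spacing_mean - 3 * config.spacing_sd), size=n - 1,
    )
    x = np.concatenate([[0.0], np.cumsum(spacing)])
    # small radial wobble of the monolayer
    y = rng.normal(0.0, 0.02 * config.spacing_mean, size=n)

    labels = np.empty(n, dtype=object)
    kappa = config.copy_probability
    labels[0] = rng.choice(FIVE_CLASSES, p=freqs)
    for i in range(1, n):
        if rng.random() < kappa:
            labels[i] = labels[i - 1]
        else:
            labels[i] = rng.choice(FIVE_CLASSES, p=freqs)

    morph = np.array(
        ["Normative" if l == "Normative" else l.split("-", 1)[1] for l in labels],
        dtype=object)
    orient = np.array(
        ["NA" if l == "Normative"
         else ("Vertical" if l.startswith("V") else "Horizontal") for l in labels],
        dtype=object)

    foliar = _foliar_from_plan(x, config.foliar_plan)
    lobule = _lobules_by_block(n, config.lobules)

    df = pd.DataFrame({
        "cell_id": [f"{config.individual}-{config.hemisphere}-{i:05d}" for i in range(n)],
        "x": x, "y": y,
        "morph_type": morph, "orientation": orient,
        "foliar": foliar, "lobule": lobule,
        "hemisphere": config.hemisphere,
        "individual": config.individual,
        "species": config.species,
    })
    counts = pd.Series(labels).value_counts().to_dict()
    truth = {
        "copy_probability": kappa,
        "category_frequencies": {c: float(f) for c, f in zip(FIVE_CLASSES, freqs)},
        "seed": config.seed,
        "n_cells": n,
        "realized_counts": {str(k): int(v) for k, v in counts.items()},
    }
    return df, truth


def _foliar_from_plan(x: np.ndarray, plan) -> np.ndarray:
    labels = [p[0] for p in plan]
    lengths = np.array([p[1] for p in plan], dtype=float)
    period = lengths.sum()
    edges = np.cumsum(lengths)
    pos = np.mod(x, period)
    idx = np.searchsorted(edges, pos, side="right")
    idx = np.clip(idx, 0, len(labels) - 1)
    return np.array([labels[i] for i in idx], dtype=object)


def _lobules_by_block(n: int, lobules) -> np.ndarray:
    k = len(lobules)
    block = np.minimum((np.arange(n) * k) // n, k - 1)
    return np.array([lobules[b] for b in block], dtype=object)


# ======================================================================
# arbors
# ======================================================================

@dataclass
class ArborSimConfig:
    species: str = "human"
    trunk_count_probs: dict = field(default_factory=lambda: {1: 0.55, 2: 0.35, 3: 0.10})
    total_length_mean: float = presets.HUMAN_TOTAL_LENGTH_UM[0]
    total_length_sd: float = presets.HUMAN_TOTAL_LENGTH_UM[1]
    segment_length_mean: float = 23.0
    segment_length_sd: float = 10.0
    bifurcation_prob: float = 0.45   # at each segment end; termination below
    termination_prob: float = 0.25
    taper_ratio: float = 0.96        # parent -> child diameter ratio
    trunk_diameter: float = 5.5
    min_diameter: float = 0.7
    height_cap: float = presets.HUMAN_MAX_HEIGHT_UM[0]
    lateral_spread: float = presets.HUMAN_MAX_WIDTH_UM[0] / 2.0
    eccentricity_mean_deg: float = 37.0
    eccentricity_sd_deg: float = 24.0
    soma_radius: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.height_cap <= 0 or self.total_length_mean <= 0:
            raise ValueError("height cap and target length must be positive")
        if self.segment_length_mean <= 0:
            raise ValueError("segment length must be positive")
        if not 0.0 <= self.bifurcation_prob <= 1.0:
            raise ValueError("bifurcation probability must lie in [0, 1]")
        if self.bifurcation_prob + self.termination_prob > 1.0:
            raise ValueError("bifurcation + termination probabilities exceed 1")
        tot = sum(self.trunk_count_probs.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-6):
            raise ValueError("trunk count probabilities must sum to 1")


def simulate_arbor(config: ArborSimConfig,
                   rng: np.random.Generator | None = None):
    """Grow one stochastic branching arbor.

    Returns ``(Arbor, bookkeeping)``; bookkeeping totals (cable length,
    structural branch count, trunk count) are computed from the emitted
    geometry itself, so they match any correct measurement exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    target = float(_truncated_normal(
        rng, config.total_length_mean, config.total_length_sd,
        low=0.2 * config.total_length_mean))

    xyz = [np.zeros(3)]
    radius = [config.soma_radius]
    structure = ["soma"]
    parent = [-1]

    trunks = int(rng.choice(list(config.trunk_count_probs),
                            p=list(config.trunk_count_probs.values())))
    tips: list[tuple[int, np.ndarray, float]] = []  # (node row, direction, diameter)
    for _ in range(trunks):
        # trunk nodes sit at the soma surface heading steeply upward
        theta = math.radians(_truncated_normal(rng, 65.0, 10.0, 20.0, 88.0))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        d = np.array([sign * math.cos(theta), math.sin(theta),
                      rng.normal(0.0, 0.05)])
        d /= np.linalg.norm(d)
        xyz.append(xyz[0] + d * 1e-9)  # zero-length attachment stub
        radius.append(config.trunk_diameter / 2.0)
        structure.append("dendrite")
        parent.append(0)
        tips.append((len(xyz) - 1, d, config.trunk_diameter))

    total = 0.0
    while total < target:
        if not tips:
            # regrow a collateral from a random existing dendrite node
            row = int(rng.integers(1, len(xyz)))
            tips.append((row, _new_direction(rng, config, xyz[row][1]),
                         max(config.min_diameter, 2.0 * radius[row])))
        i = int(rng.integers(len(tips)))
        row, d, diam = tips.pop(i)
        seg_len = float(_truncated_normal(
            rng, config.segment_length_mean, config.segment_length_sd, low=2.0))
        seg_len = min(seg_len, target - total)
        if seg_len <= 0:
            break
        d = _new_direction(rng, config, xyz[row][1], previous=d)
        # damp lateral drift beyond the configured spread
        if abs(xyz[row][0]) > config.lateral_spread and np.sign(d[0]) == np.sign(xyz[row][0]):
            d[0] = -d[0]
        # reflect the vertical component at the molecular-layer cap: keeps
        # the drawn cable length exact and y below the cap by induction
        if xyz[row][1] + d[1] * seg_len > config.height_cap:
            d[1] = -abs(d[1])
        p = xyz[row] + d * seg_len
        new_diam = max(config.min_diameter, diam * config.taper_ratio)
        xyz.append(p)
        radius.append(new_diam / 2.0)
        structure.append("dendrite")
        parent.append(row)
        new_row = len(xyz) - 1
        total += seg_len

        u = rng.random()
        dirn = (p - xyz[row])
        dirn = dirn / np.linalg.norm(dirn)
        if u < config.bifurcation_prob:
            tips.append((new_row, dirn, new_diam))
            tips.append((new_row, dirn, max(config.min_diameter,
                                            new_diam * config.taper_ratio)))
        elif u < config.bifurcation_prob + config.termination_prob:
            pass
        else:
            tips.append((new_row, dirn, new_diam))

    arbor = Arbor(
        node_id=np.arange(1, len(xyz) + 1),
        parent_id=np.array([p + 1 if p >= 0 else -1 for p in parent]),
        xyz=np.array(xyz),
        radius=np.array(radius),
        structure=np.array(structure, dtype=object),
        species=config.species,
        molecular_layer_thickness=config.height_cap,
    )
    bookkeeping = {
        "total_length": _structural_length(arbor),
        "n_branches": _structural_branch_count(arbor),
        "n_trunks": trunks,
        "target_length": target,
        "seed": config.seed,
    }
    return arbor, bookkeeping


def _new_direction(rng: np.random.Generator, config: ArborSimConfig,
                   height: float, previous: np.ndarray | None = None) -> np.ndarray:
    """Upward-biased direction with the configured eccentricity distribution;
    flattens out near the molecular-layer cap."""
    theta = math.radians(_truncated_normal(
        rng, config.eccentricity_mean_deg, config.eccentricity_sd_deg, -20.0, 89.0))
    if height > 0.92 * config.height_cap:
        theta = math.radians(_truncated_normal(rng, -5.0, 8.0, -30.0, 10.0))
    if previous is not None and previous[0] != 0:
        sign = math.copysign(1.0, previous[0])
        if rng.random() < 0.15:
            sign = -sign
    else:
        sign = 1.0 if rng.random() < 0.5 else -1.0
    d = np.array([sign * math.cos(theta), math.sin(theta), rng.normal(0.0, 0.08)])
    return d / np.linalg.norm(d)


def _structural_length(arbor: Arbor) -> float:
    """Exact cable bookkeeping: sum of edges into dendrite nodes."""
    dend = arbor.dendrite_mask
    rows = np.flatnonzero(dend & (arbor.parent_row >= 0))
    d = arbor.xyz[rows] - arbor.xyz[arbor.parent_row[rows]]
    return float(np.linalg.norm(d, axis=1).sum())


def _structural_branch_count(arbor: Arbor) -> int:
    """Number of maximal unbranched segments, counted from topology alone:
    dendrite nodes whose parent is not a dendrite node, or whose parent has
    two or more dendrite children, each start one segment."""
    dend = arbor.dendrite_mask
    n_dend_children = np.zeros(len(arbor), dtype=int)
    for r in np.flatnonzero(dend & (arbor.parent_row >= 0)):
        n_dend_children[arbor.parent_row[r]] += 1
    count = 0
    for r in np.flatnonzero(dend):
        pr = arbor.parent_row[r]
        if pr < 0 or not dend[pr] or n_dend_children[pr] >= 2:
            count += 1
    return count


# ======================================================================
# spiny branches
# ======================================================================

@dataclass
class SpineSimConfig:
    densities: dict = field(default_factory=lambda: dict(presets.HUMAN_SPINE_DENSITIES))
    head_diameter: dict = field(default_factory=lambda: dict(presets.HUMAN_HEAD_DIAMETER_UM))
    neck_length: tuple = presets.NECK_LENGTH_UM
    protrusion: tuple = presets.PROTRUSION_UM
    puncta: tuple = presets.CLUSTER_PUNCTA
    cluster_head_volume: tuple | None = presets.CLUSTER_HEAD_VOLUME_UM3
    branch_length: float = 30.0
    mean_dendrite_diameter: float = 1.0
    region: str = "intermediate"
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.densities.values()):
            raise ValueError("densities must be >= 0")
        if self.branch_length <= 0:
            raise ValueError("branch length must be positive")


def simulate_spiny_branch(config: SpineSimConfig,
                          rng: np.random.Generator | None = None) -> SpinyBranchSegment:
    """One spiny branch with Poisson(density·length) spines per type."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spines: list[SpineRecord] = []
    for t, dens in config.densities.items():
        count = int(rng.poisson(dens * config.branch_length))
        mu, sd = config.head_diameter[t]
        for _ in range(count):
            puncta = 1
            head_volume = None
            if t == "thin":
                diam = float(_truncated_normal(rng, mu, sd, 0.10, 0.499))
            elif t == "cluster":
                puncta = int(round(_truncated_normal(rng, *config.puncta, low=3.0)))
                # diameter scales linearly with puncta number: clusters
                # resize by gaining/losing discrete puncta
                diam = float(np.clip(
                    mu + presets.CLUSTER_DIAMETER_PUNCTA_SLOPE * (puncta - config.puncta[0])
                    + rng.normal(0.0, presets.CLUSTER_DIAMETER_RESIDUAL_SD),
                    0.50, 2.0))
                if config.cluster_head_volume is not None:
                    head_volume = float(_truncated_normal(
                        rng, *config.cluster_head_volume, low=0.02))
            else:
                diam = float(_truncated_normal(rng, mu, sd, 0.50 if t == "mushroom" else 0.10, 2.0))
            if t == "branched":
                puncta = 2  # one punctum per head
            spines.append(SpineRecord(
                spine_id=f"{t}-{len(spines)}",
                type=t,
                head_diameter=diam,
                neck_length=float(_truncated_normal(rng, *config.neck_length, low=0.05)),
                protrusion_distance=float(_truncated_normal(rng, *config.protrusion, low=0.2)),
                puncta_count=puncta,
                head_volume=head_volume,
            ))
    return SpinyBranchSegment(
        branch_id=f"sim-{config.seed}",
        length=config.branch_length,
        mean_dendrite_diameter=config.mean_dendrite_diameter,
        region=config.region,
        spines=spines,
    )


# ======================================================================
# classifier features inside rule regions
# ======================================================================

def sample_classifier_features(label: str, species: str,
                               rng: np.random.Generator) -> PrimaryDendriteFeatures:
    """Draw primary-dendrite features strictly inside the rule region of a
    five-class label, for classifier-recovery checks (no boundary sampling)."""
    if label not in FIVE_CLASSES:
        raise ValueError(f"unknown class {label!r}")
    th = THRESHOLDS[species]
    soma = float(rng.uniform(25.0, 35.0) if species == "human"
                 else rng.uniform(18.0, 22.0))
    window = th.bifurcation_window if th.bifurcation_window is not None else 2.0 * soma

    def vertical_trace() -> DendriteTrace:
        return DendriteTrace(
            parallel_run_length=float(rng.uniform(0.0, 0.5 * th.parallel_pair)),
            angle_at_threshold=float(rng.uniform(35.0, 85.0)),
            direction=int(rng.choice([1, -1])),
        )

    def horizontal_trace(direction: int, single: bool) -> DendriteTrace:
        lo = th.parallel_single if single else th.parallel_pair
        return DendriteTrace(
            parallel_run_length=float(rng.uniform(1.2 * lo, 2.5 * lo)),
            angle_at_threshold=float(rng.uniform(0.0, 25.0)),
            direction=direction,
        )

    if label == "Normative":
        return PrimaryDendriteFeatures(
            species=species, n_trunks=1, soma_diameter=soma,
            first_bifurcation_distance=float(rng.uniform(1.2, 3.0)) * window,
            bifurcation_symmetric=False,
            minor_branch_max_projection=float(rng.uniform(0.0, 0.6)) * th.minor_projection,
            dendrites=[vertical_trace()],
        )

    orient, morph = label.split("-", 1)
    n_trunks = 1 if morph == "Split" else int(rng.integers(2, 4))
    symmetric = bool(rng.random() < 0.5)
    minor = (float(rng.uniform(1.3, 2.5)) * th.minor_projection
             if not symmetric else float(rng.uniform(0.0, 0.6)) * th.minor_projection)
    if orient == "H":
        if rng.random() < 0.5:
            dendrites = [horizontal_trace(1, single=True), vertical_trace()]
        else:
            dendrites = [horizontal_trace(1, single=False),
                         horizontal_trace(-1, single=False)]
    else:
        dendrites = [vertical_trace(), vertical_trace()]
    return PrimaryDendriteFeatures(
        species=species, n_trunks=n_trunks, soma_diameter=soma,
        first_bifurcation_distance=float(rng.uniform(0.2, 0.9)) * window,
        bifurcation_symmetric=symmetric,
        minor_branch_max_projection=minor,
        dendrites=dendrites,
    )


# ======================================================================
# preset factories
# ======================================================================

def human_map_config(n_cells: int = 500, seed: int = 0, **kw) -> MapSimConfig:
    return MapSimConfig(n_cells=n_cells, seed=seed, **kw)


def mouse_map_config(n_cells: int = 500, seed: int = 0, **kw) -> MapSimConfig:
    defaults = dict(
        category_frequencies=dict(presets.MOUSE_CLASS_FREQUENCIES),
        spacing_mean=presets.MOUSE_SOMA_SPACING_UM[0],
        spacing_sd=presets.MOUSE_SOMA_SPACING_UM[1],
        foliar_plan=presets.MOUSE_FOLIAR_PLAN,
        lobules=presets.MOUSE_LOBULES,
        species="mouse",
    )
    defaults.update(kw)
    return MapSimConfig(n_cells=n_cells, seed=seed, **defaults)


def human_arbor_config(seed: int = 0, **kw) -> ArborSimConfig:
    return ArborSimConfig(seed=seed, **kw)


def mouse_arbor_config(seed: int = 0, **kw) -> ArborSimConfig:
    defaults = dict(
        species="mouse",
        trunk_count_probs={1: 0.75, 2: 0.22, 3: 0.03},
        total_length_mean=presets.MOUSE_TOTAL_LENGTH_UM[0],
        total_length_sd=presets.MOUSE_TOTAL_LENGTH_UM[1],
        segment_length_mean=8.5,
        segment_length_sd=4.0,
        trunk_diameter=3.5,
        height_cap=presets.MOUSE_MAX_HEIGHT_UM[0],
        lateral_spread=presets.MOUSE_MAX_WIDTH_UM[0] / 2.0,
        eccentricity_mean_deg=45.0,
        soma_radius=10.0,
    )
    defaults.update(kw)
    return ArborSimConfig(seed=seed, **defaults)


def human_spine_config(seed: int = 0, **kw) -> SpineSimConfig:
    return SpineSimConfig(seed=seed, **kw)


def mouse_spine_config(seed: int = 0, **kw) -> SpineSimConfig:
    defaults = dict(
        densities=dict(presets.MOUSE_SPINE_DENSITIES),
        head_diameter=dict(presets.MOUSE_HEAD_DIAMETER_UM),
    )
    defaults.update(kw)
    return SpineSimConfig(seed=seed, **defaults)
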