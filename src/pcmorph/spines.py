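"""Spine taxonomy, densities, volume fractions and the confocal optics helper.

Spines on Purkinje-cell spiny branchlets fall into four classes:

* ``thin`` — single smooth head with diameter < 0.5 µm,
* ``mushroom`` — single smooth head with diameter ≥ 0.5 µm (the 0.5 µm
  boundary itself is assigned to mushroom),
* ``branched`` — two heads emerging from a shared neck,
* ``cluster`` — a single head bearing three or more distinct puncta.

Densities are simple counts per µm of branch length, with no correction for
spines hidden along the optical axis.  A branched spine counts once toward
spine density; its per-head count is retained for synapse extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SPINE_TYPES",
    "SpineRecord",
    "SpinyBranchSegment",
    "OpticsSpec",
    "classify_spine",
    "sphere_volume",
    "spine_densities",
    "volume_fraction",
    "rayleigh_limit",
    "extrapolate_total_spines",
    "cluster_puncta_stats",
    "MUSHROOM_DIAMETER_UM",
    "CLUSTER_MIN_PUNCTA",
]

SPINE_TYPES = ("thin", "mushroom", "branched", "cluster")

MUSHROOM_DIAMETER_UM = 0.5   # thin/mushroom head-diameter boundary
CLUSTER_MIN_PUNCTA = 3       # puncta on one head that make a spine cluster


def sphere_volume(diameter: float) -> float:
    """(π/6)·d³ — default head volume from a head diameter."""
    return math.pi / 6.0 * diameter ** 3


@dataclass
class SpineRecord:
    spine_id: str
    type: str
    head_diameter: float          # µm; largest head for cluster/branched
    neck_length: float            # µm
    protrusion_distance: float    # µm, head centre from the dendrite surface
    puncta_count: int = 1
    head_volume: float | None = None

    def __post_init__(self):
        if self.type not in SPINE_TYPES:
            raise ValueError(f"unknown spine type {self.type!r}")
        if self.type == "cluster" and self.puncta_count < CLUSTER_MIN_PUNCTA:
            raise ValueError("cluster spines need >= 3 puncta")
        if self.head_volume is None:
            self.head_volume = sphere_volume(self.head_diameter)
        if self.head_volume <= 0:
            raise ValueError("head_volume must be positive")


@dataclass
class SpinyBranchSegment:
    branch_id: str
    length: float                   # µm
    mean_dendrite_diameter: float   # µm
    region: str = "intermediate"    # proximal / intermediate / distal
    spines: list[SpineRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("branch length must be positive")


def classify_spine(head_count: int,
                   head_diameters,
                   puncta_per_head=None) -> str:
    """Assign one of the four spine classes from measured head structure."""
    if head_count < 1:
        raise ValueError("a spine needs at least one head")
    if head_count >= 2:
        return "branched"
    diam = float(np.max(np.atleast_1d(head_diameters)))
    puncta = 1 if puncta_per_head is None else int(np.sum(np.atleast_1d(puncta_per_head)))
    if puncta >= CLUSTER_MIN_PUNCTA:
        return "cluster"
    return "mushroom" if diam >= MUSHROOM_DIAMETER_UM else "thin"


def spine_densities(segment: SpinyBranchSegment) -> dict[str, float]:
    """Spines per µm, per type and total; the total equals the type sum."""
    out = {t: 0.0 for t in SPINE_TYPES}
    for s in segment.spines:
        out[s.type] += 1.0
    for t in SPINE_TYPES:
        out[t] /= segment.length
    out["total"] = sum(out[t] for t in SPINE_TYPES)
    return out


def volume_fraction(segment: SpinyBranchSegment) -> float:
    """Spine-head volume as a percent of the perispinal shell volume.

    The shell is the cylinder of radius (mean dendrite radius + mean head
    protrusion distance) minus the dendrite cylinder itself:
    100·Σ head_volume / (π·L·((r+p)² − r²)).
    """
    if not segment.spines:
        return 0.0
    r = segment.mean_dendrite_diameter / 2.0
    if r <= 0:
        raise ValueError("mean dendrite radius must be positive")
    p = float(np.mean([s.protrusion_distance for s in segment.spines]))
    if p <= 0:
        raise ValueError("degenerate shell: zero mean protrusion with spines present")
    shell = math.pi * segment.length * ((r + p) ** 2 - r ** 2)
    total_head = float(np.sum([s.head_volume for s in segment.spines]))
    return 100.0 * total_head / shell


def rayleigh_limit(wavelength_nm: float, numerical_aperture: float) -> float:
    """Diffraction-limited minimum resolvable distance R = 0.61·λ/NA, in nm."""
    if wavelength_nm <= 0 or numerical_aperture <= 0:
        raise ValueError("wavelength and numerical aperture must be positive")
    return 0.61 * wavelength_nm / numerical_aperture


@dataclass(frozen=True)
class OpticsSpec:
    wavelength_nm: float
    numerical_aperture: float

    @property
    def limit_nm(self) -> float:
        return rayleigh_limit(self.wavelength_nm, self.numerical_aperture)


def extrapolate_total_spines(total_length_um: float, density_per_um: float) -> int:
    """Whole-cell spine count as total dendritic length × spine density."""
    if total_length_um < 0 or density_per_um < 0:
        raise ValueError("inputs must be non-negative")
    return int(round(total_length_um * density_per_um))


def cluster_puncta_stats(segments: list[SpinyBranchSegment]) -> dict:
    """Summary statistics of spine clusters pooled over branch segments.

    Returns mean puncta per cluster, mean cluster head volume, the OLS slope
    of cluster diameter on puncta number (None when fewer than two distinct
    puncta counts are available), and the density of clustered puncta per µm
    of branch length.
    """
    clusters = [s for seg in segments for s in seg.spines if s.type == "cluster"]
    total_len = sum(seg.length for seg in segments)
    if not clusters:
        return {
            "mean_puncta": None, "mean_head_volume": None,
            "diameter_puncta_slope": None, "clustered_puncta_per_um": 0.0,
        }
    puncta = np.array([s.puncta_count for s in clusters], dtype=float)
    diam = np.array([s.head_diameter for s in clusters], dtype=float)
    vol = np.array([s.head_volume for s in clusters], dtype=float)
    slope = None
    if len(np.unique(puncta)) >= 2:
        slope = float(stats.linregress(puncta, diam).slope)
    return {
        "mean_puncta": float(puncta.mean()),
        "mean_head_volume": float(vol.mean()),
        "diameter_puncta_slope": slope,
        "clustered_puncta_per_um": float(puncta.sum() / total_len),
    }
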