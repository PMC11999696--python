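"""Rule-based Purkinje-cell morphology, orientation and foliar classifiers.

Morphology classes
    * ``Poly`` — more than one primary trunk leaves the soma, regardless of
      relative size.
    * ``Split`` — a single trunk that bifurcates within the proximal window
      (two soma diameters in human, a fixed 40 µm in mouse) either
      symmetrically, or asymmetrically with the smaller daughter projecting
      far enough in the parasagittal axis (>200 µm human, >100 µm mouse) to
      reach prominence in its own right.
    * ``Normative`` — everything else: a single trunk with no proximal
      bifurcation, or one whose minor daughter stays near the main
      compartment.

Orientation (Split and Poly only)
    ``Horizontal`` when one primary dendrite ramifies parallel with the
    Purkinje-cell layer for >300 µm (human; >150 µm mouse), or two primary
    dendrites run in opposing directions for >150 µm each (human; >75 µm
    mouse); "parallel" means the dendrite sits at <30° from the layer plane
    at the species' threshold distance from the soma.  Otherwise
    ``Vertical``.

Foliar subregion
    ``Gyrus`` / ``Bank`` / ``Sulcus`` by whether the parasagittal pial
    length exceeds, equals (within a relative tolerance) or falls short of
    the granule-layer/white-matter border length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SpeciesThresholds",
    "THRESHOLDS",
    "DendriteTrace",
    "PrimaryDendriteFeatures",
    "FoliarRegionOutline",
    "classify_morphology",
    "classify_orientation",
    "classify_foliar",
    "bifurcation_symmetric_from_diameters",
    "PARALLEL_ANGLE_DEG",
]

PARALLEL_ANGLE_DEG = 30.0  # below this angle from the layer a dendrite is "parallel"


@dataclass(frozen=True)
class SpeciesThresholds:
    """All species-specific classifier constants, in µm."""

    bifurcation_window: float | None  # None -> 2 × measured soma diameter
    minor_projection: float           # asymmetric-split prominence distance
    parallel_single: float            # one-dendrite horizontal run
    parallel_pair: float              # per-dendrite run for an opposing pair
    adjacency_distance: float         # clustering neighbour threshold
    shell_width: float                # shell-analysis increment
    population_radius_min: float
    population_radius_max: float


THRESHOLDS = {
    "human": SpeciesThresholds(
        bifurcation_window=None, minor_projection=200.0,
        parallel_single=300.0, parallel_pair=150.0,
        adjacency_distance=1000.0, shell_width=500.0,
        population_radius_min=250.0, population_radius_max=10_000.0,
    ),
    # mouse somata are 18-22 µm, so the two-soma window is fixed at 40 µm;
    # spatial scales are 20% of human, matching the dendritic width ratio
    "mouse": SpeciesThresholds(
        bifurcation_window=40.0, minor_projection=100.0,
        parallel_single=150.0, parallel_pair=75.0,
        adjacency_distance=200.0, shell_width=100.0,
        population_radius_min=50.0, population_radius_max=2_000.0,
    ),
}


@dataclass
class DendriteTrace:
    """Per-primary-dendrite ramification summary used by the orientation rule."""

    parallel_run_length: float   # µm ramified parallel with the PC layer
    angle_at_threshold: float    # degrees from the layer plane at the species
                                 # threshold distance from the soma
    direction: int = 1           # +1 anterior / −1 posterior along the layer

    def __post_init__(self):
        if self.parallel_run_length < 0:
            raise ValueError("run length must be >= 0")
        if not 0.0 <= self.angle_at_threshold <= 90.0:
            raise ValueError("angle must lie in [0, 90] degrees")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class PrimaryDendriteFeatures:
    species: str
    n_trunks: int
    soma_diameter: float
    first_bifurcation_distance: float = math.inf   # inf if the trunk never splits
    bifurcation_symmetric: bool = False
    minor_branch_max_projection: float = 0.0
    dendrites: list[DendriteTrace] = field(default_factory=list)

    def __post_init__(self):
        if self.species not in THRESHOLDS:
            raise ValueError(f"unknown species {self.species!r}")
        if self.n_trunks < 1:
            raise ValueError("a Purkinje cell has at least one primary trunk")
        if self.soma_diameter <= 0:
            raise ValueError("soma diameter must be positive")
        if self.first_bifurcation_distance < 0 or self.minor_branch_max_projection < 0:
            raise ValueError("distances must be >= 0")


def classify_morphology(features: PrimaryDendriteFeatures) -> str:
    th = THRESHOLDS[features.species]
    if features.n_trunks > 1:
        return "Poly"
    window = (th.bifurcation_window if th.bifurcation_window is not None
              else 2.0 * features.soma_diameter)
    if features.first_bifurcation_distance <= window and (
        features.bifurcation_symmetric
        or features.minor_branch_max_projection > th.minor_projection
    ):
        return "Split"
    return "Normative"


def classify_orientation(features: PrimaryDendriteFeatures,
                         morphology: str | None = None) -> str:
    if morphology is None:
        morphology = classify_morphology(features)
    if morphology == "Normative":
        raise ValueError("orientation undefined for Normative cells")
    th = THRESHOLDS[features.species]
    parallel = [d for d in features.dendrites
                if d.angle_at_threshold < PARALLEL_ANGLE_DEG]
    # single-dendrite rule
    if any(d.parallel_run_length > th.parallel_single for d in parallel):
        return "Horizontal"
    # opposing-pair rule
    fwd = [d for d in parallel
           if d.direction > 0 and d.parallel_run_length > th.parallel_pair]
    bwd = [d for d in parallel
           if d.direction < 0 and d.parallel_run_length > th.parallel_pair]
    if fwd and bwd:
        return "Horizontal"
    return "Vertical"


def bifurcation_symmetric_from_diameters(d1: float, d2: float,
                                         ratio: float = 0.75) -> bool:
    """Optional numeric symmetry criterion for automated pipelines: a
    bifurcation is symmetric when the thinner daughter's diameter is at
    least ``ratio`` of the thicker's."""
    if d1 <= 0 or d2 <= 0:
        raise ValueError("daughter diameters must be positive")
    return min(d1, d2) / max(d1, d2) >= ratio


@dataclass(frozen=True)
class FoliarRegionOutline:
    pial_length: float
    gcl_wm_border_length: float

    def __post_init__(self):
        if self.pial_length <= 0 or self.gcl_wm_border_length <= 0:
            raise ValueError("outline lengths must be positive")


def classify_foliar(outline: FoliarRegionOutline, tolerance: float = 0.05) -> str:
    """Gyrus / Bank / Sulcus from the pial vs granule-layer border lengths.

    ``tolerance`` widens "equal" to a relative band because traced outline
    lengths are never exactly equal.
    """
    if not 0.0 <= tolerance < 1.0:
        raise ValueError("tolerance must lie in [0, 1)")
    rho = outline.pial_length / outline.gcl_wm_border_length
    if rho > 1.0 + tolerance:
        return "Gyrus"
    if rho < 1.0 - tolerance:
        return "Sulcus"
    return "Bank"
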