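"""Versioned generative constants for the human and mouse synthetic cohorts.

These are the study conditions every simulator emulates: cohort means of the
reconstruction and spine datasets (total dendritic length, branch counts,
arbor extents, per-type spine densities and head-size distributions) and the
demographic/spatial structure of the parasagittal cell maps.  Each simulator
preset targets these values generatively; the parameter-recovery tests check
that the measurement pipeline gets them back.

All lengths µm, densities per µm, volumes µm³.
"""

from __future__ import annotations

PRESETS_VERSION = "1.0"

# -- reconstruction cohort summary targets (mean, SD across cells) ---------

HUMAN_TOTAL_LENGTH_UM = (63_645.0, 4_572.0)
MOUSE_TOTAL_LENGTH_UM = (6_004.0, 831.0)
HUMAN_N_BRANCHES = (2_750.0, 247.0)
MOUSE_N_BRANCHES = (707.0, 118.0)
HUMAN_MAX_WIDTH_UM = (644.0, 126.0)
MOUSE_MAX_WIDTH_UM = (143.0, 31.0)
HUMAN_MAX_HEIGHT_UM = (366.0, 58.0)
MOUSE_MAX_HEIGHT_UM = (158.0, 22.0)

# -- spine cohort targets --------------------------------------------------

# per-type densities (spines/µm); mouse spine clusters are essentially
# absent (1 of 1380 spines), modelled as a zero rate
HUMAN_SPINE_DENSITIES = {
    "thin": 5.37, "mushroom": 0.49, "branched": 0.42, "cluster": 0.52,
}
MOUSE_SPINE_DENSITIES = {
    "thin": 4.56, "mushroom": 0.13, "branched": 0.49, "cluster": 0.0,
}
HUMAN_TOTAL_SPINE_DENSITY = sum(HUMAN_SPINE_DENSITIES.values())  # 6.80/µm
MOUSE_TOTAL_SPINE_DENSITY = sum(MOUSE_SPINE_DENSITIES.values())  # 5.18/µm

# head-diameter distributions (mean, SD) per type
HUMAN_HEAD_DIAMETER_UM = {
    "thin": (0.34, 0.07), "mushroom": (0.58, 0.07),
    "branched": (0.40, 0.08), "cluster": (0.93, 0.19),
}
MOUSE_HEAD_DIAMETER_UM = {
    "thin": (0.29, 0.06), "mushroom": (0.55, 0.05),
    "branched": (0.36, 0.07), "cluster": (0.93, 0.19),
}

CLUSTER_PUNCTA = (4.84, 1.75)          # puncta per spine cluster (mean, SD), >= 3
CLUSTER_HEAD_VOLUME_UM3 = (0.49, 0.42)  # measured spherical volume (mean, SD)

# cluster diameter grows linearly with puncta number (clusters resize by
# gaining or losing stereotypically sized puncta, not by puncta growth);
# diameter = mean + slope·(puncta − mean puncta) + residual
CLUSTER_DIAMETER_PUNCTA_SLOPE = 0.08   # µm per punctum
CLUSTER_DIAMETER_RESIDUAL_SD = 0.10    # µm

# neck length and head protrusion distance (mean, SD); protrusion is the
# head-centre distance from the dendrite surface
NECK_LENGTH_UM = (0.80, 0.30)
PROTRUSION_UM = (1.40, 0.40)

# -- cell-map demographic and spatial structure ----------------------------

# five-class frequencies; humans are overwhelmingly multi-branched while
# mice retain a large Normative fraction
HUMAN_CLASS_FREQUENCIES = {
    "Normative": 0.15, "V-Split": 0.25, "H-Split": 0.20,
    "V-Poly": 0.15, "H-Poly": 0.25,
}
MOUSE_CLASS_FREQUENCIES = {
    "Normative": 0.30, "V-Split": 0.28, "H-Split": 0.12,
    "V-Poly": 0.18, "H-Poly": 0.12,
}

# nearest-neighbour soma spacing along the layer (mean, SD); chosen so that
# matched runs reproduce the observed run-length scale (~2.6-3.1 cells over
# ~537 µm human / ~71 µm mouse) together with the copy probability below
HUMAN_SOMA_SPACING_UM = (300.0, 120.0)
MOUSE_SOMA_SPACING_UM = (35.0, 12.0)

# first-order Markov label copying strength; expected run size
# 1/(1 − κ) ≈ 2.5-3 cells at κ = 0.4 when neighbours stay within threshold
DEFAULT_COPY_PROBABILITY = 0.40

# alternating foliar segmentation plan: (label, parasagittal length)
HUMAN_FOLIAR_PLAN = (
    ("Gyrus", 3000.0), ("Bank", 4000.0), ("Sulcus", 2000.0), ("Bank", 4000.0),
)
MOUSE_FOLIAR_PLAN = (
    ("Gyrus", 600.0), ("Bank", 800.0), ("Sulcus", 400.0), ("Bank", 800.0),
)

HUMAN_LOBULES = ("L1-2", "L3", "L4", "L5", "L6", "L7", "L8", "L9", "L10")
MOUSE_LOBULES = ("L1-2", "L3", "L4-5", "L6", "L7", "L8", "L9", "L10")
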