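"""Readers and writers for the pipeline's three tabular inputs.

Single-neuron reconstructions travel as standard 7-column SWC
(``id type x y z radius parent``, ``#`` comments, coordinates and radii in
micrometres).  Cell maps — one Purkinje cell per row with its position along
the parasagittal layer, morphology class and anatomical labels — and spine
tables are plain CSV with a header.

Axis convention (configurable via :class:`AxisMap`): ``x`` runs
anterior→posterior along the Purkinje-cell layer (parasagittal), ``y`` is
radial depth from the soma toward the pia, ``z`` is mediolateral.  No
shrinkage factor or z-correction is applied on read; a correction hook is
exposed on :class:`Arbor` for users who need one, default off.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SWCError",
    "SchemaError",
    "AxisMap",
    "ArborNode",
    "Arbor",
    "read_swc",
    "write_swc",
    "read_cell_map",
    "write_cell_map",
    "validate_cell_map",
    "read_spine_table",
    "write_spine_table",
    "MORPH_TYPES",
    "ORIENTATIONS",
    "FOLIAR_LABELS",
    "HEMISPHERES",
    "SPECIES",
    "STRUCTURE_CODES",
]


class SWCError(ValueError):
    """Structural problem in an SWC reconstruction (orphan, cycle, no root)."""


class SchemaError(ValueError):
    """A delimited table is missing columns or carries unknown category labels."""


# SWC structure-type integers -> semantic labels; everything else -> unspecified
STRUCTURE_CODES = {1: "soma", 2: "axon", 3: "dendrite"}
_LABEL_CODES = {v: k for k, v in STRUCTURE_CODES.items()}

MORPH_TYPES = ("Normative", "Split", "Poly")
ORIENTATIONS = ("Vertical", "Horizontal", "NA")
FOLIAR_LABELS = ("Gyrus", "Bank", "Sulcus")
HEMISPHERES = ("left", "right", "vermis")
SPECIES = ("human", "mouse")

CELL_MAP_COLUMNS = (
    "cell_id", "x", "y", "morph_type", "orientation", "foliar",
    "lobule", "hemisphere", "individual", "species",
)

SPINE_COLUMNS = (
    "branch_id", "spine_id", "type", "head_diameter", "neck_length",
    "protrusion_distance", "puncta_count", "head_volume",
)


@dataclass(frozen=True)
class AxisMap:
    """Which SWC coordinate plays which anatomical role."""

    parasagittal: str = "x"
    radial: str = "y"
    mediolateral: str = "z"

    _IDX = {"x": 0, "y": 1, "z": 2}

    @property
    def parasagittal_idx(self) -> int:
        return self._IDX[self.parasagittal]

    @property
    def radial_idx(self) -> int:
        return self._IDX[self.radial]


@dataclass(frozen=True)
class ArborNode:
    node_id: int
    parent_id: int
    x: float
    y: float
    z: float
    radius: float
    structure_label: str = "dendrite"


class Arbor:
    """A rooted 3-D reconstruction with radii.

    Internally column-oriented (numpy arrays indexed 0..n-1 in declaration
    order) so the metric code can vectorise; ``node_id``/``parent_id`` keep
    the file's own identifiers.
    """

    def __init__(
        self,
        node_id: np.ndarray,
        parent_id: np.ndarray,
        xyz: np.ndarray,
        radius: np.ndarray,
        structure: np.ndarray,
        species: str | None = None,
        molecular_layer_thickness: float | None = None,
        axes: AxisMap = AxisMap(),
    ):
        self.node_id = np.asarray(node_id, dtype=np.int64)
        self.parent_id = np.asarray(parent_id, dtype=np.int64)
        self.xyz = np.asarray(xyz, dtype=float)
        self.radius = np.asarray(radius, dtype=float)
        self.structure = np.asarray(structure, dtype=object)
        self.species = species
        if molecular_layer_thickness is not None and molecular_layer_thickness <= 0:
            raise ValueError("molecular_layer_thickness must be positive")
        self.molecular_layer_thickness = molecular_layer_thickness
        self.axes = axes
        self._validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_nodes(cls, nodes: list[ArborNode], **kw) -> "Arbor":
        return cls(
            node_id=np.array([n.node_id for n in nodes]),
            parent_id=np.array([n.parent_id for n in nodes]),
            xyz=np.array([[n.x, n.y, n.z] for n in nodes], dtype=float),
            radius=np.array([n.radius for n in nodes], dtype=float),
            structure=np.array([n.structure_label for n in nodes], dtype=object),
            **kw,
        )

    def _validate(self) -> None:
        n = len(self.node_id)
        if n == 0:
            raise SWCError("empty reconstruction")
        if len(np.unique(self.node_id)) != n:
            raise SWCError("duplicate node ids")
        if np.any(self.radius < 0):
            raise SWCError("negative radius")
        id_to_row = {int(i): r for r, i in enumerate(self.node_id)}
        parent_row = np.full(n, -1, dtype=np.int64)
        roots = 0
        for r in range(n):
            pid = int(self.parent_id[r])
            if pid == -1:
                roots += 1
                continue
            if pid not in id_to_row:
                raise SWCError(
                    f"node {int(self.node_id[r])} references undeclared parent {pid}"
                )
            pr = id_to_row[pid]
            if pr >= r:
                # forward reference: either a cycle or out-of-order declaration
                raise SWCError(
                    f"node {int(self.node_id[r])} declared before its parent {pid}"
                )
            parent_row[r] = pr
        if roots != 1:
            raise SWCError(f"expected exactly one root, found {roots}")
        self.parent_row = parent_row
        self.root = int(np.flatnonzero(self.parent_row == -1)[0])
        # children adjacency
        ch: list[list[int]] = [[] for _ in range(n)]
        for r in range(n):
            if parent_row[r] >= 0:
                ch[parent_row[r]].append(r)
        self.children = ch

    # -- views ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.node_id)

    @property
    def soma_mask(self) -> np.ndarray:
        return self.structure == "soma"

    @property
    def dendrite_mask(self) -> np.ndarray:
        return self.structure == "dendrite"

    @property
    def soma_centroid(self) -> np.ndarray:
        m = self.soma_mask
        if m.any():
            return self.xyz[m].mean(axis=0)
        return self.xyz[self.root]

    @property
    def soma_diameter(self) -> float:
        """Soma diameter estimated as twice the largest soma-node radius."""
        m = self.soma_mask
        if m.any():
            return 2.0 * float(self.radius[m].max())
        return 2.0 * float(self.radius[self.root])

    def nodes(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_id,
                "parent_id": self.parent_id,
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
                "radius": self.radius,
                "structure": self.structure,
            }
        )

    def scaled(self, shrinkage_factor: float = 1.0, z_factor: float = 1.0) -> "Arbor":
        """Optional shrinkage / z correction hook; identity by default."""
        xyz = self.xyz.copy()
        xyz[:, :2] *= shrinkage_factor
        xyz[:, 2] *= z_factor
        return Arbor(
            self.node_id, self.parent_id, xyz, self.radius, self.structure,
            species=self.species,
            molecular_layer_thickness=self.molecular_layer_thickness,
            axes=self.axes,
        )


def read_swc(path, species: str | None = None,
             molecular_layer_thickness: float | None = None,
             axes: AxisMap = AxisMap()) -> Arbor:
    """Parse a 7-column SWC file into an :class:`Arbor` (units taken as µm)."""
    tab = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None,
        names=["node_id", "type", "x", "y", "z", "radius", "parent_id"],
        float_precision="round_trip",
    )
    if tab.shape[1] != 7:
        raise SWCError("SWC requires 7 whitespace-delimited columns")
    structure = np.array(
        [STRUCTURE_CODES.get(int(t), "unspecified") for t in tab["type"]],
        dtype=object,
    )
    return Arbor(
        node_id=tab["node_id"].to_numpy(np.int64),
        parent_id=tab["parent_id"].to_numpy(np.int64),
        xyz=tab[["x", "y", "z"]].to_numpy(float),
        radius=tab["radius"].to_numpy(float),
        structure=structure,
        species=species,
        molecular_layer_thickness=molecular_layer_thickness,
        axes=axes,
    )


def write_swc(arbor: Arbor, path) -> None:
    buf = _stdio.StringIO()
    for r in range(len(arbor)):
        code = _LABEL_CODES.get(str(arbor.structure[r]), 0)
        x, y, z = arbor.xyz[r]
        buf.write(
            f"{int(arbor.node_id[r])} {code} {x:.17g} {y:.17g} {z:.17g} "
            f"{arbor.radius[r]:.17g} {int(arbor.parent_id[r])}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# -- cell maps -------------------------------------------------------------

def validate_cell_map(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell map missing columns: {missing}")
    if df.empty:
        return df.reset_index(drop=True)
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise SchemaError(f"duplicate cell_id: {dup!r}")
    checks = {
        "morph_type": MORPH_TYPES,
        "orientation": ORIENTATIONS,
        "foliar": FOLIAR_LABELS,
        "hemisphere": HEMISPHERES,
        "species": SPECIES,
    }
    for col, allowed in checks.items():
        bad = set(df[col].unique()) - set(allowed)
        if bad:
            raise SchemaError(f"unknown {col} value(s): {sorted(map(str, bad))}")
    # Normative cells carry no orientation class
    norm = df["morph_type"] == "Normative"
    if (df.loc[norm, "orientation"] != "NA").any():
        raise SchemaError("Normative cells must have orientation 'NA'")
    if (df.loc[~norm, "orientation"] == "NA").any():
        raise SchemaError("Split/Poly cells must have a Vertical/Horizontal orientation")
    return df.reset_index(drop=True)


def read_cell_map(path) -> pd.DataFrame:
    """Load a cell-map CSV; rows keep the stored anterior→posterior order."""
    # keep_default_na: the literal orientation label "NA" must survive
    df = pd.read_csv(path, dtype={"cell_id": str, "lobule": str, "individual": str},
                     keep_default_na=False, na_values=[],
                     float_precision="round_trip")
    if df.empty and not set(CELL_MAP_COLUMNS) <= set(df.columns):
        # an empty file with header still validates; truly headerless is an error
        pass
    return validate_cell_map(df)


def write_cell_map(df: pd.DataFrame, path) -> None:
    validate_cell_map(df).to_csv(path, index=False)


# -- spine tables ----------------------------------------------------------

def read_spine_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SPINE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"spine table missing columns: {missing}")
    bad = set(df["type"].unique()) - {"thin", "mushroom", "branched", "cluster"}
    if bad:
        raise SchemaError(f"unknown spine type(s): {sorted(map(str, bad))}")
    return df


def write_spine_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
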