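"""Per-arbor morphometrics: branch decomposition, extents, eccentricity,
diameter profiles and Sholl analysis.

All metrics operate on :class:`pcmorph.io.Arbor`.  Dendritic length counts
every inter-node edge whose child node is a dendrite node (the stub from the
soma into the first dendrite node therefore belongs to the trunk segment);
soma-internal and axonal cable is excluded.  Branch order is centrifugal:
every trunk leaving the soma is order 1 and order increments at each branch
point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Arbor

__all__ = [
    "BranchSegment",
    "ShollProfile",
    "ArborSummary",
    "decompose_branches",
    "total_length",
    "arbor_extent_and_shape",
    "branch_eccentricity",
    "assign_region",
    "thin_caliber_threshold",
    "diameter_profile",
    "sholl_profile",
    "branch_height_profile",
    "summarize",
    "segments_table",
    "THIN_CALIBER_THRESHOLD_UM",
]

# Thin-caliber diameter cut (µm): log-normal mean + 1 SD of pooled branch
# mean diameters across the two species' reconstruction cohorts.
THIN_CALIBER_THRESHOLD_UM = 1.31

REGIONS = ("proximal", "intermediate", "distal")


@dataclass
class BranchSegment:
    """A maximal unbranched dendritic path between branch points / tips.

    ``rows`` are Arbor row indices; the first row is the junction the segment
    emerges from (a branch point, or the soma for a trunk) and contributes
    its position but not its cable.
    """

    segment_id: int
    rows: list[int]
    order: int
    length: float
    mean_diameter: float
    is_terminal: bool
    eccentricity_deg: float | None = None
    region: str | None = None


@dataclass
class ShollProfile:
    radii: np.ndarray            # shell upper edges, µm (shell k covers (k-1, k])
    length_per_shell: np.ndarray
    branch_count_per_shell: np.ndarray

    @property
    def cumulative_normalized(self) -> np.ndarray:
        tot = self.length_per_shell.sum()
        if tot == 0:
            return np.zeros_like(self.length_per_shell)
        return np.cumsum(self.length_per_shell) / tot


@dataclass
class ArborSummary:
    total_length: float
    n_branches: int
    n_terminal_branches: int
    max_order: int
    mean_order: float
    max_width: float
    max_height: float
    shape_index: float
    soma_diameter: float
    max_primary_diameter: float
    thin_fraction: float
    n_primary_dendrites: int


# -- branch decomposition --------------------------------------------------

def _edge_lengths(arbor: Arbor) -> np.ndarray:
    """Length of the edge into each node (0 for the root)."""
    n = len(arbor)
    out = np.zeros(n)
    has_parent = arbor.parent_row >= 0
    rows = np.flatnonzero(has_parent)
    d = arbor.xyz[rows] - arbor.xyz[arbor.parent_row[rows]]
    out[rows] = np.linalg.norm(d, axis=1)
    return out


def decompose_branches(arbor: Arbor) -> list[BranchSegment]:
    """Partition the dendritic tree into maximal unbranched segments.

    Every dendrite node belongs to exactly one segment; the sum of segment
    lengths equals :func:`total_length` exactly.
    """
    dend = arbor.dendrite_mask
    if not dend.any():
        return []
    edge_len = _edge_lengths(arbor)
    diam = 2.0 * arbor.radius

    def dendrite_children(r: int) -> list[int]:
        return [c for c in arbor.children[r] if dend[c]]

    # trunk starts: dendrite nodes whose parent is not a dendrite node
    starts = [
        r for r in range(len(arbor))
        if dend[r] and (arbor.parent_row[r] < 0 or not dend[arbor.parent_row[r]])
    ]
    segments: list[BranchSegment] = []
    # stack of (first dendrite node of segment, junction row, order)
    stack = [(s, arbor.parent_row[s], 1) for s in reversed(starts)]
    while stack:
        head, junction, order = stack.pop()
        rows = [junction] if junction >= 0 else []
        length = 0.0
        wsum = 0.0  # length-weighted diameter accumulator (edge midpoints)
        cur = head
        while True:
            rows.append(cur)
            l = edge_len[cur]
            pr = arbor.parent_row[cur]
            if pr >= 0:
                length += l
                # soma-junction edges take the child's caliber: soma girth is
                # not dendritic cable
                if dend[pr]:
                    wsum += l * 0.5 * (diam[cur] + diam[pr])
                else:
                    wsum += l * diam[cur]
            kids = dendrite_children(cur)
            if len(kids) == 1:
                cur = kids[0]
            else:
                break
        if length > 0:
            mean_diam = wsum / length
        else:
            mean_diam = float(np.mean(diam[[r for r in rows if dend[r]]]))
        kids = dendrite_children(cur)
        seg = BranchSegment(
            segment_id=len(segments),
            rows=rows,
            order=order,
            length=length,
            mean_diameter=mean_diam,
            is_terminal=len(kids) == 0,
        )
        segments.append(seg)
        for k in reversed(kids):
            stack.append((k, cur, order + 1))
    return segments


def total_length(arbor: Arbor) -> float:
    """Total dendritic cable length in µm."""
    edge_len = _edge_lengths(arbor)
    return float(edge_len[arbor.dendrite_mask].sum())


# -- extents ---------------------------------------------------------------

def arbor_extent_and_shape(arbor: Arbor) -> tuple[float, float, float]:
    """(max_width, max_height, shape_index).

    Width is the parasagittal extent and height the radial extent of the
    dendritic point cloud on raw coordinates.  The shape index is
    +100·(W/H − 1) when the arbor is wider than tall and −100·(H/W − 1)
    otherwise, so +76 means 76% greater width than height.
    """
    dend = arbor.dendrite_mask
    if not dend.any():
        raise ValueError("no dendrite nodes")
    px = arbor.xyz[dend, arbor.axes.parasagittal_idx]
    ry = arbor.xyz[dend, arbor.axes.radial_idx]
    width = float(px.max() - px.min())
    height = float(ry.max() - ry.min())
    if width == 0 or height == 0:
        raise ValueError("zero extent")
    if width >= height:
        shape = 100.0 * (width / height - 1.0)
    else:
        shape = -100.0 * (height / width - 1.0)
    return width, height, shape


# -- eccentricity ----------------------------------------------------------

def branch_eccentricity(vertices: np.ndarray) -> float | None:
    """Angle of a branch from the Purkinje-layer plane, degrees in [0, 90].

    ``vertices`` is an (n, 2) array of (parasagittal, radial) trace points.
    The branch origin is translated to (0, 0); branches projecting downward
    (negative mean radial displacement) are mirrored over the horizontal
    axis and leftward ones over the vertical axis, so only the inclination
    relative to the layer survives.  The slope is a through-origin
    least-squares fit b = Σxy/Σx²; perfectly vertical branches give 90°.

    Returns None when all vertices coincide (degenerate; excluded from
    aggregates upstream).
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("need at least two (x, y) vertices")
    v = v - v[0]
    if np.allclose(v, 0.0):
        return None
    if v[:, 1].mean() < 0:
        v[:, 1] = -v[:, 1]
    if v[:, 0].mean() < 0:
        v[:, 0] = -v[:, 0]
    sxx = float(np.sum(v[:, 0] ** 2))
    if sxx == 0.0:
        return 90.0
    b = float(np.sum(v[:, 0] * v[:, 1])) / sxx
    return float(np.clip(math.degrees(math.atan(b)), 0.0, 90.0))


def segment_eccentricity(segment: BranchSegment, arbor: Arbor) -> float | None:
    v = arbor.xyz[np.asarray(segment.rows)][
        :, [arbor.axes.parasagittal_idx, arbor.axes.radial_idx]
    ]
    return branch_eccentricity(v)


# -- molecular-layer region ------------------------------------------------

def assign_region(segment: BranchSegment, arbor: Arbor,
                  thickness: float | None = None) -> str:
    """Proximal / intermediate / distal third of the molecular-layer depth.

    Assignment is by the radial distance of the segment's cable midpoint from
    the soma, against the molecular-layer thickness (or the arbor's own
    radial height as proxy).  Bins are closed on their left edge: a midpoint
    exactly at one third is proximal.
    """
    if thickness is None:
        thickness = arbor.molecular_layer_thickness
    soma_r = arbor.soma_centroid[arbor.axes.radial_idx]
    if thickness is None:
        dend = arbor.dendrite_mask
        thickness = float(arbor.xyz[dend, arbor.axes.radial_idx].max() - soma_r)
    if thickness <= 0:
        raise ValueError("non-positive molecular-layer thickness")
    mid = _segment_midpoint(segment, arbor)
    h = mid[arbor.axes.radial_idx] - soma_r
    if h > thickness:
        warnings.warn("segment midpoint above molecular-layer thickness; "
                      "clamped to distal")
        return "distal"
    frac = h / thickness
    if frac <= 1.0 / 3.0:
        return "proximal"
    if frac <= 2.0 / 3.0:
        return "intermediate"
    return "distal"


def _segment_midpoint(segment: BranchSegment, arbor: Arbor) -> np.ndarray:
    """Point halfway along the segment's cable."""
    pts = arbor.xyz[np.asarray(segment.rows)]
    if len(pts) == 1:
        return pts[0]
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = steps.sum()
    if total == 0:
        return pts[0]
    target = total / 2.0
    acc = 0.0
    for i, s in enumerate(steps):
        if acc + s >= target:
            t = (target - acc) / s if s > 0 else 0.0
            return pts[i] + t * (pts[i + 1] - pts[i])
        acc += s
    return pts[-1]


# -- diameters -------------------------------------------------------------

def thin_caliber_threshold(diameters: np.ndarray) -> float:
    """Log-normal mean + 1 SD, exp(mean(ln d) + sd(ln d)), over pooled branch
    mean diameters (cross-species pool when both cohorts are supplied).
    Zero / non-positive diameters are excluded with a warning."""
    d = np.asarray(diameters, dtype=float)
    bad = d <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} non-positive diameters "
                      "from log statistics")
        d = d[~bad]
    if d.size == 0:
        raise ValueError("no positive diameters")
    ln = np.log(d)
    return float(np.exp(ln.mean() + ln.std(ddof=1 if ln.size > 1 else 0)))


def diameter_profile(arbor: Arbor,
                     segments: list[BranchSegment] | None = None,
                     threshold: float | None = None):
    """(max_primary_diameter, normalized_diameter_by_order, thin_fraction, threshold).

    Per-order mean segment diameter is normalised to the thickest primary
    dendrite.  The thin-caliber threshold defaults to the log-normal
    mean + 1 SD of this arbor's own segment mean diameters; pass the pooled
    cohort value (e.g. :data:`THIN_CALIBER_THRESHOLD_UM`) for cross-cell
    comparability.  ``thin_fraction`` is the percent of total dendritic
    length on segments thinner than the threshold.
    """
    if segments is None:
        segments = decompose_branches(arbor)
    if not segments:
        raise ValueError("arbor has no dendritic segments")
    d = np.array([s.mean_diameter for s in segments])
    l = np.array([s.length for s in segments])
    orders = np.array([s.order for s in segments])
    max_primary = _max_primary_diameter(arbor, segments)
    by_order = pd.Series(d).groupby(orders).mean()
    normalized = (by_order / max_primary).rename("normalized_diameter")
    normalized.index.name = "order"
    if threshold is None:
        threshold = thin_caliber_threshold(d)
    thin_fraction = 100.0 * float(l[d < threshold].sum() / l.sum())
    return max_primary, normalized, thin_fraction, threshold


def _max_primary_diameter(arbor: Arbor, segments: list[BranchSegment]) -> float:
    """Max node diameter on order-1 segments within two soma diameters."""
    soma_c = arbor.soma_centroid
    window = 2.0 * arbor.soma_diameter
    best = 0.0
    dend = arbor.dendrite_mask
    for s in segments:
        if s.order != 1:
            continue
        rows = [r for r in s.rows if dend[r]]
        pts = arbor.xyz[rows]
        near = np.linalg.norm(pts - soma_c, axis=1) <= window
        if near.any():
            best = max(best, float((2.0 * arbor.radius[rows])[near].max()))
    if best == 0.0 and segments:
        # degenerate window (e.g. zero soma radius): fall back to thickest
        # node of any primary segment
        for s in segments:
            if s.order == 1:
                rows = [r for r in s.rows if dend[r]]
                best = max(best, float((2.0 * arbor.radius[rows]).max()))
    return best


# -- Sholl -----------------------------------------------------------------

def sholl_profile(arbor: Arbor, step: float = 1.0,
                  center: np.ndarray | None = None,
                  segments: list[BranchSegment] | None = None) -> ShollProfile:
    """Dendritic length and branch counts in concentric 3-D shells.

    Shell k covers radial distances ((k−1)·step, k·step] from the soma
    centroid.  Each inter-node edge is split exactly at shell crossings
    (quadratic roots of |a + t·d|² = R²), so shell lengths sum to the total
    dendritic length to machine precision.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if center is None:
        center = arbor.soma_centroid
    if segments is None:
        segments = decompose_branches(arbor)
    dend = arbor.dendrite_mask

    # maximum radius over dendrite nodes
    if not dend.any():
        return ShollProfile(np.array([]), np.array([]), np.array([], dtype=int))
    rmax = float(np.linalg.norm(arbor.xyz[dend] - center, axis=1).max())
    n_shell = max(1, int(math.ceil(rmax / step - 1e-12)))
    length = np.zeros(n_shell)
    seg_shells: list[set[int]] = []

    for seg in segments:
        touched: set[int] = set()
        rows = seg.rows
        for i in range(1, len(rows)):
            pr, cr = rows[i - 1], rows[i]
            if not dend[cr]:
                continue  # junction edge from soma carries no dendritic cable
            a = arbor.xyz[pr] - center
            b = arbor.xyz[cr] - center
            _accumulate_edge(a, b, step, length, touched)
        seg_shells.append(touched)

    branch_count = np.zeros(n_shell, dtype=int)
    for touched in seg_shells:
        for k in touched:
            if k < n_shell:
                branch_count[k] += 1
    radii = step * np.arange(1, n_shell + 1)
    return ShollProfile(radii, length, branch_count)


def _accumulate_edge(a: np.ndarray, b: np.ndarray, step: float,
                     length: np.ndarray, touched: set) -> None:
    """Distribute the cable of edge a→b (coords relative to center) over shells."""
    d = b - a
    L = float(np.linalg.norm(d))
    if L == 0:
        k = _shell_index(float(np.linalg.norm(a)), step)
        touched.add(k)
        return
    A = float(d @ d)
    B = 2.0 * float(a @ d)
    C = float(a @ a)
    ra, rb = math.sqrt(C), math.sqrt(float(b @ b))
    lo_k = _shell_index(min(ra, rb), step)
    hi_k = _shell_index(max(ra, rb), step)
    ts = [0.0, 1.0]
    # radius along the edge is sqrt(At² + Bt + C); find crossings of each
    # shell boundary R in (0, 1)
    for k in range(lo_k, hi_k + 1):
        R = k * step
        c2 = C - R * R
        disc = B * B - 4.0 * A * c2
        if disc <= 0:
            continue
        sq = math.sqrt(disc)
        for t in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)):
            if 1e-12 < t < 1 - 1e-12:
                ts.append(t)
    ts = sorted(set(ts))
    for t0, t1 in zip(ts[:-1], ts[1:]):
        tm = 0.5 * (t0 + t1)
        rm = math.sqrt(max(A * tm * tm + B * tm + C, 0.0))
        k = _shell_index(rm, step)
        if k >= len(length):
            k = len(length) - 1
        length[k] += L * (t1 - t0)
        touched.add(k)


def _shell_index(r: float, step: float) -> int:
    """0-based index of the shell ((k−1)·step, k·step] containing radius r."""
    if r <= 0:
        return 0
    return max(0, int(math.ceil(r / step - 1e-9)) - 1)


# -- branch-point height histogram ----------------------------------------

def branch_height_profile(arbor: Arbor, n_bins: int = 10,
                          segments: list[BranchSegment] | None = None) -> np.ndarray:
    """Histogram of branch-point radial positions normalised to arbor height."""
    if segments is None:
        segments = decompose_branches(arbor)
    dend = arbor.dendrite_mask
    if not dend.any():
        return np.zeros(n_bins, dtype=int)
    soma_r = arbor.soma_centroid[arbor.axes.radial_idx]
    height = float(arbor.xyz[dend, arbor.axes.radial_idx].max() - soma_r)
    if height <= 0:
        return np.zeros(n_bins, dtype=int)
    # branch points = last node of non-terminal segments
    ys = [arbor.xyz[s.rows[-1], arbor.axes.radial_idx] - soma_r
          for s in segments if not s.is_terminal]
    if not ys:
        return np.zeros(n_bins, dtype=int)
    frac = np.clip(np.asarray(ys) / height, 0.0, 1.0)
    hist, _ = np.histogram(frac, bins=n_bins, range=(0.0, 1.0))
    return hist


# -- summary ---------------------------------------------------------------

def summarize(arbor: Arbor, thin_threshold: float | None = None) -> ArborSummary:
    segments = decompose_branches(arbor)
    if not segments:
        raise ValueError("arbor has no dendritic segments")
    width, height, shape = arbor_extent_and_shape(arbor)
    orders = np.array([s.order for s in segments])
    max_primary, _, thin_fraction, _ = diameter_profile(
        arbor, segments, threshold=thin_threshold
    )
    return ArborSummary(
        total_length=total_length(arbor),
        n_branches=len(segments),
        n_terminal_branches=sum(s.is_terminal for s in segments),
        max_order=int(orders.max()),
        mean_order=float(orders.mean()),
        max_width=width,
        max_height=height,
        shape_index=shape,
        soma_diameter=arbor.soma_diameter,
        max_primary_diameter=max_primary,
        thin_fraction=thin_fraction,
        n_primary_dendrites=int((orders == 1).sum()),
    )


def segments_table(arbor: Arbor,
                   segments: list[BranchSegment] | None = None) -> pd.DataFrame:
    """One CSV-ready row per branch segment with order, length, diameter,
    eccentricity and molecular-layer region."""
    if segments is None:
        segments = decompose_branches(arbor)
    rows = []
    for s in segments:
        ecc = segment_eccentricity(s, arbor)
        rows.append({
            "segment_id": s.segment_id,
            "order": s.order,
            "length": s.length,
            "mean_diameter": s.mean_diameter,
            "is_terminal": s.is_terminal,
            "eccentricity_deg": ecc,
            "region": assign_region(s, arbor),
        })
    return pd.DataFrame(rows)
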