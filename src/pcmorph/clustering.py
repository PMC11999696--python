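"""1-D spatial cell-type clustering statistics with permutation nulls.

Cells in a parasagittal map are ordered anterior→posterior along the
Purkinje-cell monolayer.  Three statistics quantify whether morphological
categories cluster beyond chance:

* **Adjacency scores** — each cell starts at −1; having any immediate
  neighbour within the species distance threshold (1000 µm human, 200 µm
  mouse) raises it to 0, and each neighbour that also *matches* adds +1
  (so 0, 1 or 2).  Maximal stretches of mutually matching adjacent cells
  form runs, summarised by cell count and parasagittal length.
* **Population match rates** — for every focal cell, the category mix of
  all cells within a radius; matching/nonmatching rates are compared to
  label-shuffled versions of the same map.
* **Shell match rates** — the same tally restricted to an annulus
  [k·w, (k+1)·w) around each cell, ignoring the core, isolating clustering
  at distance.

Shuffles permute the (morphology, orientation) label pair without
replacement — globally or within foliar strata — holding positions and all
other fields fixed, so every shuffle conserves the label multiset exactly.
Matching can require the full five-class identity (Normative, V-Split,
H-Split, V-Poly, H-Poly), the morphology type only, or the orientation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .classify import THRESHOLDS

__all__ = [
    "MATCH_MODES",
    "FIVE_CLASSES",
    "ShuffleSpec",
    "MatchRateProfile",
    "match_labels",
    "adjacency_scores",
    "cluster_runs",
    "shuffle_map",
    "shuffle_labels",
    "clustering_excess",
    "population_match_rates",
    "population_match_profile",
    "shell_match_profile",
    "count_rates",
    "demographics",
    "interhemisphere_difference",
    "default_distance_threshold",
]

MATCH_MODES = ("complete", "type_only", "orientation_only")
FIVE_CLASSES = ("Normative", "V-Split", "H-Split", "V-Poly", "H-Poly")


@dataclass(frozen=True)
class ShuffleSpec:
    mode: str = "global"          # "global" | "within_foliar"
    n_reps: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("global", "within_foliar"):
            raise ValueError(f"unknown shuffle mode {self.mode!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class MatchRateProfile:
    """Observed-minus-shuffled match/nonmatch rate elevations, in percentage
    points, per radius or shell."""

    radii: np.ndarray                 # outer radius (population) / shell outer edge
    matching: np.ndarray              # mean elevation over the five classes
    nonmatching: np.ndarray
    per_category: pd.DataFrame        # long: radius, category, match_elev, nonmatch_elev
    inner_radii: np.ndarray | None = None  # shell inner edges, shell variant only


def default_distance_threshold(species: str) -> float:
    return THRESHOLDS[species].adjacency_distance


# -- labels ----------------------------------------------------------------

def match_labels(df: pd.DataFrame, match_mode: str = "complete") -> np.ndarray:
    """Per-cell category label under the requested matching rule."""
    if match_mode not in MATCH_MODES:
        raise ValueError(f"unknown match mode {match_mode!r}")
    if match_mode == "type_only":
        return df["morph_type"].to_numpy(object)
    if match_mode == "orientation_only":
        return df["orientation"].to_numpy(object)
    lab = np.where(
        df["morph_type"].to_numpy(object) == "Normative",
        "Normative",
        pd.Series(df["orientation"].astype(str).str[0] + "-" + df["morph_type"].astype(str)).to_numpy(object),
    )
    return lab.astype(object)


def _positions(df: pd.DataFrame) -> np.ndarray:
    return df[["x", "y"]].to_numpy(float)


def _gaps(df: pd.DataFrame) -> np.ndarray:
    """Euclidean distance between consecutive cells along the layer."""
    pos = _positions(df)
    if len(pos) < 2:
        return np.zeros(0)
    return np.linalg.norm(np.diff(pos, axis=0), axis=1)


# -- adjacency -------------------------------------------------------------

def _scores_from(labels: np.ndarray, within: np.ndarray) -> np.ndarray:
    match = (labels[:-1] == labels[1:]) & within
    left_w = np.r_[False, within]
    right_w = np.r_[within, False]
    left_m = np.r_[False, match].astype(int)
    right_m = np.r_[match, False].astype(int)
    return np.where(left_w | right_w, left_m + right_m, -1)


def adjacency_scores(df: pd.DataFrame,
                     distance_threshold: float | None = None,
                     match_mode: str = "complete") -> pd.DataFrame:
    """Per-cell cluster score (−1, 0, 1 or 2) and run membership.

    The map must be in anterior→posterior order; the default distance
    threshold comes from the species column (1000 µm human, 200 µm mouse).
    """
    if distance_threshold is None:
        distance_threshold = _threshold_from_species(df)
    if distance_threshold <= 0:
        raise ValueError("distance threshold must be positive")
    labels = match_labels(df, match_mode)
    within = _gaps(df) <= distance_threshold
    score = _scores_from(labels, within)
    run_id = _run_ids(labels, within)
    out = df.copy()
    out["score"] = score
    out["run_id"] = run_id
    return out


def _threshold_from_species(df: pd.DataFrame) -> float:
    sp = df["species"].unique()
    if len(sp) != 1:
        raise ValueError("mixed-species map: pass distance_threshold explicitly")
    return default_distance_threshold(sp[0])


def _run_ids(labels: np.ndarray, within: np.ndarray) -> np.ndarray:
    """Run id per cell (−1 outside any run).  A run is a maximal stretch of
    >= 2 cells in which every adjacent pair is within threshold and matches;
    a sub-threshold gap terminates the run."""
    n = len(labels)
    pair_ok = (labels[:-1] == labels[1:]) & within
    run_id = np.full(n, -1, dtype=int)
    rid = 0
    i = 0
    while i < n - 1:
        if pair_ok[i]:
            j = i
            while j < n - 1 and pair_ok[j]:
                j += 1
            run_id[i:j + 1] = rid
            rid += 1
            i = j
        else:
            i += 1
    return run_id


def cluster_runs(scored: pd.DataFrame) -> pd.DataFrame:
    """Run table (run_id, n_cells, run_length_um) from an adjacency-scored map."""
    gaps = _gaps(scored)
    rows = []
    rid_col = scored["run_id"].to_numpy()
    for rid in np.unique(rid_col[rid_col >= 0]):
        idx = np.flatnonzero(rid_col == rid)
        rows.append({
            "run_id": int(rid),
            "n_cells": len(idx),
            "run_length_um": float(gaps[idx[0]:idx[-1]].sum()),
        })
    return pd.DataFrame(rows, columns=["run_id", "n_cells", "run_length_um"])


# -- shuffling -------------------------------------------------------------

def shuffle_labels(df: pd.DataFrame, rng: np.random.Generator,
                   mode: str = "global") -> pd.DataFrame:
    """One label shuffle: permute the (morph_type, orientation) pair without
    replacement, globally or within each foliar stratum; everything else
    (coordinates, foliar labels, lobules) stays fixed."""
    out = df.copy()
    mt = out["morph_type"].to_numpy(object)
    ori = out["orientation"].to_numpy(object)
    if mode == "global":
        perm = rng.permutation(len(out))
        out["morph_type"] = mt[perm]
        out["orientation"] = ori[perm]
    elif mode == "within_foliar":
        fol = out["foliar"].to_numpy(object)
        for stratum in pd.unique(fol):
            idx = np.flatnonzero(fol == stratum)
            perm = idx[rng.permutation(len(idx))]
            out.loc[out.index[idx], "morph_type"] = mt[perm]
            out.loc[out.index[idx], "orientation"] = ori[perm]
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return out


def shuffle_map(df: pd.DataFrame, spec: ShuffleSpec) -> list[pd.DataFrame]:
    """``spec.n_reps`` independent label shuffles, deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    return [shuffle_labels(df, rng, spec.mode) for _ in range(spec.n_reps)]


def _shuffled_label_sets(df: pd.DataFrame, spec: ShuffleSpec,
                         match_mode: str) -> list[np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_reps):
        out.append(match_labels(shuffle_labels(df, rng, spec.mode), match_mode))
    return out


# -- adjacency clustering excess ------------------------------------------

def clustering_excess(df: pd.DataFrame, spec: ShuffleSpec,
                      match_mode: str = "complete",
                      distance_threshold: float | None = None,
                      include_isolated: bool = False) -> float:
    """Observed minus shuffled-mean rate of nonzero cluster scores, in
    percentage points.

    The rate is the share of cells with score >= 1; its denominator is the
    cells with score >= 0 (``include_isolated=True`` divides by all cells
    instead).  Raises when every cell is isolated.
    """
    if distance_threshold is None:
        distance_threshold = _threshold_from_species(df)
    within = _gaps(df) <= distance_threshold
    obs = _nonzero_rate(match_labels(df, match_mode), within, include_isolated)
    if obs is None:
        raise ValueError("all cells isolated: clustering rate undefined")
    null = [
        _nonzero_rate(lab, within, include_isolated)
        for lab in _shuffled_label_sets(df, spec, match_mode)
    ]
    return 100.0 * (obs - float(np.mean(null)))


def _nonzero_rate(labels: np.ndarray, within: np.ndarray,
                  include_isolated: bool) -> float | None:
    score = _scores_from(labels, within)
    denom = len(score) if include_isolated else int((score >= 0).sum())
    if denom == 0:
        return None
    return float((score >= 1).sum() / denom)


# -- population / shell profiles ------------------------------------------

def _category_rates(mask: np.ndarray, labels: np.ndarray,
                    categories: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per focal category: mean fraction of in-mask neighbours that match /
    don't match the focal cell.  Cells with no neighbour in the mask are
    excluded from the average; categories with no valid focal cell give NaN.
    """
    onehot = labels[:, None] == categories[None, :]
    counts = mask.astype(float) @ onehot          # (n, k) neighbours per category
    tot = counts.sum(axis=1)
    valid = tot > 0
    match_rate = np.full(len(categories), np.nan)
    for j, cat in enumerate(categories):
        focal = (labels == cat) & valid
        if focal.any():
            match_rate[j] = float(np.mean(counts[focal, j] / tot[focal]))
    return match_rate, 1.0 - match_rate


def _profile(df: pd.DataFrame, masks: list[np.ndarray], radii: np.ndarray,
             spec: ShuffleSpec, match_mode: str,
             inner_radii: np.ndarray | None = None) -> MatchRateProfile:
    obs_labels = match_labels(df, match_mode)
    categories = np.array(sorted(pd.unique(obs_labels)), dtype=object)
    null_labels = _shuffled_label_sets(df, spec, match_mode)

    match_el = np.empty(len(masks))
    non_el = np.empty(len(masks))
    rows = []
    for i, mask in enumerate(masks):
        m_obs, n_obs = _category_rates(mask, obs_labels, categories)
        m_null = np.nanmean(
            [_category_rates(mask, lab, categories)[0] for lab in null_labels], axis=0
        )
        m_elev = 100.0 * (m_obs - m_null)
        n_elev = -m_elev  # nonmatch rate is the complement of the match rate
        match_el[i] = float(np.nanmean(m_elev))
        non_el[i] = float(np.nanmean(n_elev))
        for j, cat in enumerate(categories):
            rows.append({
                "radius": radii[i], "category": cat,
                "match_elevation": m_elev[j], "nonmatch_elevation": n_elev[j],
            })
    return MatchRateProfile(
        radii=radii, matching=match_el, nonmatching=non_el,
        per_category=pd.DataFrame(rows), inner_radii=inner_radii,
    )


def population_match_rates(df: pd.DataFrame, radius: float,
                           match_mode: str = "complete") -> pd.DataFrame:
    """Observed per-category match/nonmatch rates within one radius (no
    shuffling): for each focal category, the mean fraction of cells within
    ``radius`` of a focal cell that share / don't share its label."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    labels = match_labels(df, match_mode)
    categories = np.array(sorted(pd.unique(labels)), dtype=object)
    pos = _positions(df)
    dist = cdist(pos, pos)
    np.fill_diagonal(dist, np.inf)
    m, nm = _category_rates(dist <= radius, labels, categories)
    return pd.DataFrame({
        "category": categories, "match_rate": m, "nonmatch_rate": nm,
    })


def count_rates(counts: dict) -> dict:
    """Percent of total per category from raw counts (demographic tabulation)."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return {k: 100.0 * v / total for k, v in counts.items()}


def population_match_profile(df: pd.DataFrame, radii, spec: ShuffleSpec,
                             match_mode: str = "complete") -> MatchRateProfile:
    """Match-rate elevation of the whole population within each radius of
    every focal cell (focal cell excluded from its own tally)."""
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    pos = _positions(df)
    dist = cdist(pos, pos)
    np.fill_diagonal(dist, np.inf)
    masks = [dist <= r for r in radii]
    return _profile(df, masks, radii, spec, match_mode)


def shell_match_profile(df: pd.DataFrame, shell_width: float, n_shells: int,
                        spec: ShuffleSpec,
                        match_mode: str = "complete") -> MatchRateProfile:
    """Match-rate elevation in annular shells [k·w, (k+1)·w) around each
    cell, ignoring the core region, for k = 0..n_shells−1.

    Cells whose shell is empty are dropped from that shell's average; cells
    whose shell runs past the slice edge contribute a one-sided tally.
    """
    if shell_width <= 0 or n_shells < 1:
        raise ValueError("shell_width must be positive and n_shells >= 1")
    pos = _positions(df)
    dist = cdist(pos, pos)
    np.fill_diagonal(dist, np.inf)
    inner = shell_width * np.arange(n_shells)
    outer = inner + shell_width
    masks = [(dist >= lo) & (dist < hi) for lo, hi in zip(inner, outer)]
    return _profile(df, masks, outer, spec, match_mode, inner_radii=inner)


# -- demographics ----------------------------------------------------------

def demographics(df: pd.DataFrame, group_by: str = "lobule",
                 match_mode: str = "complete"):
    """Per-group category percentages plus a chi-squared test of independence
    on the underlying count table.  Empty groups are dropped."""
    labels = match_labels(df, match_mode)
    tab = pd.crosstab(df[group_by], pd.Series(labels, index=df.index, name="category"))
    tab = tab.loc[tab.sum(axis=1) > 0]
    if len(tab) < 2:
        raise ValueError("need at least two non-empty groups")
    pct = 100.0 * tab.div(tab.sum(axis=1), axis=0)
    counts = tab.loc[:, tab.sum(axis=0) > 0]
    chi2, p, dof, _ = stats.chi2_contingency(counts.to_numpy())
    return pct, float(chi2), float(p), int(dof)


def _class_percentages(df: pd.DataFrame) -> pd.Series:
    labels = pd.Series(match_labels(df, "complete"))
    pct = 100.0 * labels.value_counts(normalize=True)
    return pct.reindex(FIVE_CLASSES, fill_value=0.0)


def interhemisphere_difference(left: pd.DataFrame, right: pd.DataFrame,
                               reference_lobule: str = "L6") -> pd.DataFrame:
    """Per-lobule mean absolute demographic difference between hemispheres.

    For each (individual, lobule), the five-class percentage vectors are
    computed on each side and averaged as mean |left% − right%|; the
    normalized column divides by the individual's value in the reference
    lobule (NaN when that value is 0, flagged via the ``normalizable``
    column).  Symmetric in its two arguments.
    """
    rows = []
    for ind in sorted(set(left["individual"]) | set(right["individual"])):
        l_ind = left[left["individual"] == ind]
        r_ind = right[right["individual"] == ind]
        lobs = sorted(set(l_ind["lobule"]) & set(r_ind["lobule"]))
        if reference_lobule not in lobs:
            raise ValueError(
                f"reference lobule {reference_lobule!r} absent for individual {ind!r}"
            )
        raw = {}
        for lob in lobs:
            pl = _class_percentages(l_ind[l_ind["lobule"] == lob])
            pr = _class_percentages(r_ind[r_ind["lobule"] == lob])
            raw[lob] = float(np.mean(np.abs(pl.to_numpy() - pr.to_numpy())))
        ref = raw[reference_lobule]
        for lob in lobs:
            rows.append({
                "individual": ind, "lobule": lob,
                "mean_abs_diff_pct": raw[lob],
                "normalized_to_reference": raw[lob] / ref if ref > 0 else np.nan,
                "normalizable": ref > 0,
            })
    return pd.DataFrame(rows)
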