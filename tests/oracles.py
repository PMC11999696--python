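"""Independent brute-force O(n²) oracles for the clustering statistics.

Deliberately naive loop implementations, kept free of any code shared with
pcmorph.clustering so they can arbitrate it.
"""

import math

import numpy as np


def oracle_labels(df, match_mode):
    out = []
    for _, r in df.iterrows():
        if match_mode == "type_only":
            out.append(r["morph_type"])
        elif match_mode == "orientation_only":
            out.append(r["orientation"])
        elif r["morph_type"] == "Normative":
            out.append("Normative")
        else:
            out.append(r["orientation"][0] + "-" + r["morph_type"])
    return out


def _dist(df, i, j):
    return math.hypot(df["x"].iloc[i] - df["x"].iloc[j],
                      df["y"].iloc[i] - df["y"].iloc[j])


def oracle_scores(df, threshold, match_mode="complete"):
    lab = oracle_labels(df, match_mode)
    n = len(df)
    scores = []
    for i in range(n):
        neighbors = []
        if i > 0 and _dist(df, i - 1, i) <= threshold:
            neighbors.append(i - 1)
        if i < n - 1 and _dist(df, i, i + 1) <= threshold:
            neighbors.append(i + 1)
        if not neighbors:
            scores.append(-1)
        else:
            scores.append(sum(1 for j in neighbors if lab[j] == lab[i]))
    return scores


def oracle_runs(df, threshold, match_mode="complete"):
    """List of (n_cells, run_length) for maximal matched adjacent stretches."""
    lab = oracle_labels(df, match_mode)
    n = len(df)
    runs = []
    i = 0
    while i < n - 1:
        ok = lab[i] == lab[i + 1] and _dist(df, i, i + 1) <= threshold
        if ok:
            j = i
            length = 0.0
            while (j < n - 1 and lab[j] == lab[j + 1]
                   and _dist(df, j, j + 1) <= threshold):
                length += _dist(df, j, j + 1)
                j += 1
            runs.append((j - i + 1, length))
            i = j
        else:
            i += 1
    return runs


def oracle_population_rates(df, radius, match_mode="complete"):
    """{category: mean fraction of in-radius neighbours matching the focal
    cell}, averaging over focal cells that have at least one neighbour."""
    lab = oracle_labels(df, match_mode)
    n = len(df)
    per_cat: dict = {}
    for i in range(n):
        neigh = [j for j in range(n) if j != i and _dist(df, i, j) <= radius]
        if not neigh:
            continue
        frac = sum(1 for j in neigh if lab[j] == lab[i]) / len(neigh)
        per_cat.setdefault(lab[i], []).append(frac)
    return {c: float(np.mean(v)) for c, v in per_cat.items()}
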