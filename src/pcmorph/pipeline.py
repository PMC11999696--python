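"""End-to-end orchestration: simulate → measure → classify → cluster → report.

A :class:`RunConfig` carries every threshold the classifiers and clustering
statistics use (defaulted to the species constants in
:mod:`pcmorph.classify`), the simulation sizes, the shuffle count and the
master seed.  :func:`run` executes the stages, writes one CSV per result
table plus a JSON manifest (version, seed, thresholds, output hashes) under
the output directory, and is byte-deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, arbor as arbor_metrics, clustering, spines as spine_metrics, synth
from .classify import THRESHOLDS
from .io import write_cell_map, write_swc

log = logging.getLogger("pcmorph")

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    species: str = "human"
    n_arbors: int = 5
    n_branches: int = 15
    n_cells: int = 500
    n_shuffles: int = 20
    copy_probability: float | None = None   # None -> preset default
    match_mode: str = "complete"
    shell_width: float | None = None        # None -> species constant
    distance_threshold: float | None = None
    seed: int = 0
    out_dir: str = "results/run"
    write_swc_files: bool = False

    def thresholds(self) -> dict:
        th = THRESHOLDS[self.species]
        return {
            "distance_threshold": self.distance_threshold or th.adjacency_distance,
            "shell_width": self.shell_width or th.shell_width,
            "minor_projection": th.minor_projection,
            "parallel_single": th.parallel_single,
            "parallel_pair": th.parallel_pair,
            "bifurcation_window": th.bifurcation_window,
        }


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage = "setup"
    try:
        stage = "simulate-arbors"
        if config.species == "human":
            arbor_cfg = synth.human_arbor_config(seed=config.seed)
            spine_cfg = synth.human_spine_config(seed=config.seed)
            map_cfg = synth.human_map_config(config.n_cells, seed=config.seed)
        else:
            arbor_cfg = synth.mouse_arbor_config(seed=config.seed)
            spine_cfg = synth.mouse_spine_config(seed=config.seed)
            map_cfg = synth.mouse_map_config(config.n_cells, seed=config.seed)
        if config.copy_probability is not None:
            map_cfg = dataclasses.replace(map_cfg,
                                          copy_probability=config.copy_probability)

        summaries = []
        for i in range(config.n_arbors):
            arb, book = synth.simulate_arbor(arbor_cfg, rng)
            s = arbor_metrics.summarize(arb)
            row = asdict(s)
            row["arbor_id"] = i
            row["bookkeeping_length"] = book["total_length"]
            summaries.append(row)
            if config.write_swc_files:
                write_swc(arb, out / f"arbor_{i:03d}.swc")
        arbors_df = pd.DataFrame(summaries)
        arbors_df.to_csv(out / "arbor_summaries.csv", index=False)
        log.info("measured %d simulated arbors", config.n_arbors)

        stage = "simulate-spines"
        rows = []
        for i in range(config.n_branches):
            seg = synth.simulate_spiny_branch(spine_cfg, rng)
            d = spine_metrics.spine_densities(seg)
            d["branch_id"] = seg.branch_id + f"-{i}"
            d["volume_fraction_pct"] = spine_metrics.volume_fraction(seg)
            rows.append(d)
        spines_df = pd.DataFrame(rows)
        spines_df.to_csv(out / "spine_densities.csv", index=False)

        stage = "simulate-map"
        cmap, truth = synth.simulate_cell_map(map_cfg)
        write_cell_map(cmap, out / "cell_map.csv")

        stage = "cluster"
        spec = clustering.ShuffleSpec(n_reps=config.n_shuffles, seed=config.seed)
        scored = clustering.adjacency_scores(
            cmap, config.thresholds()["distance_threshold"], config.match_mode)
        scored.to_csv(out / "adjacency_scores.csv", index=False)
        runs = clustering.cluster_runs(scored)
        runs.to_csv(out / "cluster_runs.csv", index=False)
        excess = clustering.clustering_excess(
            cmap, spec, config.match_mode, config.thresholds()["distance_threshold"])

        stage = "demographics"
        pct, chi2, p, dof = clustering.demographics(cmap, "lobule")
        pct.to_csv(out / "demographics.csv")

        stage = "report"
        report = {
            "mean_total_length_um": float(arbors_df["total_length"].mean()),
            "mean_n_branches": float(arbors_df["n_branches"].mean()),
            "mean_total_spine_density_per_um": float(spines_df["total"].mean()),
            "clustering_excess_pct": float(excess),
            "mean_run_cells": float(runs["n_cells"].mean()) if len(runs) else None,
            "mean_run_length_um": float(runs["run_length_um"].mean()) if len(runs) else None,
            "demographics_chi2": chi2,
            "demographics_p": p,
            "demographics_dof": dof,
        }
        manifest = {
            "pcmorph_version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "thresholds": config.thresholds(),
            "map_ground_truth": truth,
            "report": report,
            "outputs": {
                p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception:
        log.error("pipeline failed in stage %r", stage)
        raise


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
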