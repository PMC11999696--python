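#!/usr/bin/env python
"""Generate the synthetic study cohorts for both species.

Writes, under results/cohorts/: per-species cell maps (CSV + ground-truth
JSON sidecars), 30 human / 30 mouse arbors as SWC with bookkeeping, and the
spiny-branch tables.  Everything downstream (02-05) consumes these files
through the package readers, exercising the full I/O path.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from pcmorph import synth
from pcmorph.io import write_cell_map, write_swc

OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"
SEED = 20_240_101
N_ARBORS = 30
N_BRANCHES = 50


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for species in ("human", "mouse"):
        # cell map
        map_cfg = (synth.human_map_config if species == "human"
                   else synth.mouse_map_config)(2000, seed=SEED)
        cmap, truth = synth.simulate_cell_map(map_cfg)
        write_cell_map(cmap, OUT / f"{species}_map.csv")
        (OUT / f"{species}_map.truth.json").write_text(json.dumps(truth, indent=2))

        # arbors
        arb_dir = OUT / f"{species}_arbors"
        arb_dir.mkdir(exist_ok=True)
        cfg = (synth.human_arbor_config if species == "human"
               else synth.mouse_arbor_config)(seed=SEED)
        rng = np.random.default_rng(SEED)
        books = []
        for i in range(N_ARBORS):
            arb, book = synth.simulate_arbor(cfg, rng)
            write_swc(arb, arb_dir / f"arbor_{i:03d}.swc")
            book["arbor_id"] = i
            books.append(book)
        pd.DataFrame(books).to_csv(arb_dir / "bookkeeping.csv", index=False)

        # spiny branches
        sp_cfg = (synth.human_spine_config if species == "human"
                  else synth.mouse_spine_config)(branch_length=30.0)
        rng = np.random.default_rng(SEED + 1)
        rows = []
        for i in range(N_BRANCHES):
            seg = synth.simulate_spiny_branch(sp_cfg, rng)
            for s in seg.spines:
                rows.append({
                    "branch_id": f"{species}-br{i:03d}", "spine_id": s.spine_id,
                    "type": s.type, "head_diameter": s.head_diameter,
                    "neck_length": s.neck_length,
                    "protrusion_distance": s.protrusion_distance,
                    "puncta_count": s.puncta_count, "head_volume": s.head_volume,
                    "branch_length": seg.length,
                    "mean_dendrite_diameter": seg.mean_dendrite_diameter,
                })
        pd.DataFrame(rows).to_csv(OUT / f"{species}_spines.csv", index=False)
        print(f"{species}: {len(cmap)} cells, {N_ARBORS} arbors, "
              f"{N_BRANCHES} spiny branches -> {OUT}")


if __name__ == "__main__":
    main()
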