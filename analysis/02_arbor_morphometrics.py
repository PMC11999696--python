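#!/usr/bin/env python
"""Arbor morphometrics on the simulated cohorts.

Reads the SWC files written by 01, measures every per-arbor quantity
(total length, branch counts and orders, extents and shape index, thin
fraction, Sholl profiles), verifies the measurements against the
simulators' exact bookkeeping, and prints the cross-species ratios.
Writes results/arbor_summaries.csv and results/sholl_long.csv.
"""

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from pcmorph.arbor import sholl_profile, summarize
from pcmorph.io import read_swc

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    rows, sholl_rows = [], []
    for species in ("human", "mouse"):
        arb_dir = ROOT / "cohorts" / f"{species}_arbors"
        book = pd.read_csv(arb_dir / "bookkeeping.csv")
        for i, swc in enumerate(sorted(arb_dir.glob("*.swc"))):
            arb = read_swc(swc, species=species)
            s = summarize(arb)
            row = asdict(s)
            row.update(species=species, arbor_id=i)
            # measurement must agree with the generator's exact bookkeeping
            assert abs(s.total_length - book.loc[i, "total_length"]) < 1e-6
            assert s.n_branches == book.loc[i, "n_branches"]
            rows.append(row)
            prof = sholl_profile(arb)
            for r, l, b in zip(prof.radii, prof.length_per_shell,
                               prof.branch_count_per_shell):
                sholl_rows.append({"species": species, "arbor_id": i,
                                   "radius_um": r, "length_um": l,
                                   "n_branches": b})
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "arbor_summaries.csv", index=False)
    pd.DataFrame(sholl_rows).to_csv(ROOT / "sholl_long.csv", index=False)

    h = df[df.species == "human"]
    m = df[df.species == "mouse"]
    print(f"human mean total length {h.total_length.mean():,.0f} µm "
          f"(mouse {m.total_length.mean():,.0f}) -> "
          f"ratio {h.total_length.mean() / m.total_length.mean():.1f}x")
    print(f"branch-count ratio {h.n_branches.mean() / m.n_branches.mean():.1f}x, "
          f"width ratio {h.max_width.mean() / m.max_width.mean():.1f}x, "
          f"height ratio {h.max_height.mean() / m.max_height.mean():.1f}x")
    print(f"human shape index {h.shape_index.mean():+.0f}% "
          f"(wider than tall), mouse {m.shape_index.mean():+.0f}%")
    print(f"thin-caliber fraction: human {h.thin_fraction.mean():.0f}%, "
          f"mouse {m.thin_fraction.mean():.0f}%")


if __name__ == "__main__":
    main()
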