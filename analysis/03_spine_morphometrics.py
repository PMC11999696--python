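#!/usr/bin/env python
"""Spine morphometrics on the simulated cohorts.

Reads the spine tables written by 01, rebuilds branch segments, and
computes: per-type and total densities by species, spine-to-surround
volume fractions, spine-cluster puncta statistics, the Rayleigh limit of
the imaging configuration, and the whole-cell spine-count extrapolations.
Writes results/spine_density_summary.csv.
"""

from pathlib import Path

import pandas as pd

from pcmorph.spines import (
    SpineRecord, SpinyBranchSegment, cluster_puncta_stats,
    extrapolate_total_spines, rayleigh_limit, spine_densities, volume_fraction,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_segments(path):
    df = pd.read_csv(path)
    segments = []
    for bid, g in df.groupby("branch_id"):
        spines = [SpineRecord(r.spine_id, r.type, r.head_diameter, r.neck_length,
                              r.protrusion_distance, int(r.puncta_count),
                              r.head_volume)
                  for r in g.itertuples()]
        segments.append(SpinyBranchSegment(
            bid, float(g["branch_length"].iloc[0]),
            float(g["mean_dendrite_diameter"].iloc[0]), spines=spines))
    return segments


def main():
    print(f"imaging: Rayleigh limit {rayleigh_limit(555, 1.4):.1f} nm "
          "(555 nm excitation, 1.4 NA)")
    rows = []
    arbors = pd.read_csv(ROOT / "arbor_summaries.csv")
    for species in ("human", "mouse"):
        segs = load_segments(ROOT / "cohorts" / f"{species}_spines.csv")
        dens = pd.DataFrame([spine_densities(s) for s in segs])
        vf = pd.Series([volume_fraction(s) for s in segs])
        mean_len = arbors.loc[arbors.species == species, "total_length"].mean()
        total_spines = extrapolate_total_spines(mean_len, dens["total"].mean())
        row = dens.mean().to_dict()
        row.update(species=species, volume_fraction_pct=vf.mean(),
                   extrapolated_spines_per_cell=total_spines)
        rows.append(row)
        print(f"{species}: total {dens['total'].mean():.2f}/µm "
              f"(thin {dens['thin'].mean():.2f}, mushroom {dens['mushroom'].mean():.2f}, "
              f"branched {dens['branched'].mean():.2f}, cluster {dens['cluster'].mean():.2f}); "
              f"spine/surround {vf.mean():.2f}%; "
              f"~{total_spines:,} spines per cell")
        if species == "human":
            cp = cluster_puncta_stats(segs)
            print(f"  spine clusters: {cp['mean_puncta']:.2f} puncta, "
                  f"head volume {cp['mean_head_volume']:.2f} µm³, "
                  f"diameter-vs-puncta slope {cp['diameter_puncta_slope']:.3f} µm/punctum, "
                  f"{cp['clustered_puncta_per_um']:.2f} clustered puncta/µm")
    pd.DataFrame(rows).to_csv(ROOT / "spine_density_summary.csv", index=False)


if __name__ == "__main__":
    main()
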