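#!/usr/bin/env python
"""Classifier verification and regional demographics.

First checks that the rule-based morphology/orientation classifiers recover
generating labels on features sampled inside each rule region, for both
species.  Then tabulates five-class demographics of the simulated maps
across lobules and foliar subregions with chi-squared tests, and the
climbing-fiber innervation rates from the observed 44-cell count table.
Writes results/demographics_by_lobule_<species>.csv.
"""

from pathlib import Path

import numpy as np

from pcmorph.classify import classify_morphology, classify_orientation
from pcmorph.clustering import count_rates, demographics
from pcmorph.io import read_cell_map
from pcmorph.synth import FIVE_CLASSES, sample_classifier_features

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    rng = np.random.default_rng(11)
    for species in ("human", "mouse"):
        hits = trials = 0
        for label in FIVE_CLASSES:
            for _ in range(200):
                f = sample_classifier_features(label, species, rng)
                morph = classify_morphology(f)
                got = (morph if morph == "Normative" else
                       classify_orientation(f, morph)[0] + "-" + morph)
                hits += got == label
                trials += 1
        print(f"{species}: classifier recovered {hits}/{trials} "
              "generating labels inside rule regions")

    for species in ("human", "mouse"):
        cmap = read_cell_map(ROOT / "cohorts" / f"{species}_map.csv")
        pct, chi2, p, dof = demographics(cmap, "lobule")
        pct.to_csv(ROOT / f"demographics_by_lobule_{species}.csv")
        print(f"{species}: demographics across {len(pct)} lobules, "
              f"chi2={chi2:.1f} (dof={dof}), p={p:.3g}")
        pct_f, chi2_f, p_f, _ = demographics(cmap, "foliar")
        print(f"  by foliar subregion: chi2={chi2_f:.1f}, p={p_f:.3g}")

    # climbing-fiber innervation tabulation from the observed counts
    rates = count_rates({"putative mono": 22, "absence multi": 11,
                         "putative multi": 6, "fully labeled multi": 5})
    print("innervation classes (44 co-labeled cells): "
          + ", ".join(f"{k} {v:.1f}%" for k, v in rates.items()))
    print(f"  -> multi-innervation floor {rates['fully labeled multi']:.1f}%, "
          f"putative+full {rates['putative multi'] + rates['fully labeled multi']:.1f}%")


if __name__ == "__main__":
    main()
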