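#!/usr/bin/env python
"""Layer-by-layer differential expression.

Filters low counts (mean >= 5 for coding, >= 2 for non-coding, in at
least one group), runs the conditional NB exact test with TMM-scaled
libraries, adjusts with Benjamini-Hochberg, and calls DE with strict
|log2FC| > 1 plus FDR < 0.05 (mRNA/lncRNA) or p < 0.05 (miRNA/circRNA).
Also writes sample PCA coordinates on log2(CPM+1).
"""

import argparse
from pathlib import Path

import yaml

from stressrna.config import RunConfig
from stressrna.diffexpr import filter_low_counts, pca, run_de
from stressrna.io import read_counts
from stressrna.types import LAYER_BIOTYPE, LAYERS

NAME = {"mRNA": "DEM", "miRNA": "DEMI", "lncRNA": "DEL", "circRNA": "DEC"}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig()
    design = yaml.safe_load((args.indir / "design.yaml").read_text())

    for layer in LAYERS:
        m = read_counts(args.indir / f"counts_{layer}.tsv", layer, design)
        fm = filter_low_counts(m, {t: LAYER_BIOTYPE[layer] for t in m.transcript_ids}, cfg)
        de = run_de(fm, cfg)
        de.reset_index().to_csv(args.outdir / f"de_{layer}.tsv", sep="\t", index=False)
        n_de = int((de["status"] != "ns").sum())
        up = int((de["status"] == "up").sum())
        print(f"{layer}: {len(m.transcript_ids)} -> {len(fm.transcript_ids)} "
              f"after filtering; {n_de} {NAME[layer]}s ({up} up, {n_de - up} down), "
              f"dispersion {de['dispersion'].iloc[0]:.3f}")
        if layer == "mRNA":
            coords, ratio = pca(fm)
            coords.to_csv(args.outdir / "pca_mRNA.tsv", sep="\t")
            print(f"  PCA: PC1 {ratio[0]:.1%}, PC2 {ratio[1]:.1%} of variance; "
                  "PC1 separates stress from control" if _separates(coords, design)
                  else "  PCA: groups not separated on PC1")


def _separates(coords, design) -> bool:
    pc1 = coords["PC1"]
    stress = [s for s in coords.index if design[s] == "stress"]
    control = [s for s in coords.index if design[s] == "control"]
    return (pc1[stress].max() < pc1[control].min()) or \
           (pc1[control].max() < pc1[stress].min())


if __name__ == "__main__":
    main()
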