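#!/usr/bin/env python
"""Functional enrichment of the differential mRNAs.

Over-representation (hypergeometric + BH) of the DEM list against the
gene-set collection, and GSEA on the signed significance ranking
(sign(log2FC) * -log10 p) with gene-set permutation NES/p.
"""

import argparse
from pathlib import Path

import pandas as pd

from stressrna.enrichment import gsea_table, ora, rank_metric, read_gmt


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    de = pd.read_csv(args.outdir / "de_mRNA.tsv", sep="\t").set_index("transcript_id")
    universe = sorted(de.index)
    dems = sorted(de.index[de["status"] != "ns"])
    gene_sets = read_gmt(args.indir / "gene_sets.gmt")

    ora_out = ora(dems, universe, gene_sets)
    ora_out.to_csv(args.outdir / "enrichment_ora_dem.tsv", sep="\t", index=False)
    top = ora_out.iloc[0]
    print(f"ORA over {len(gene_sets)} terms, query {len(dems)} DEMs of "
          f"{len(universe)}: top term {top['term_id']} "
          f"(k={int(top['k'])}/K={int(top['K'])}, gene ratio "
          f"{top['gene_ratio']:.2f}, FDR {top['fdr']:.2e})")

    ranked = rank_metric(de)
    gsea_out = gsea_table(ranked, gene_sets, n_perm=500, seed=args.seed)
    gsea_out.to_csv(args.outdir / "enrichment_gsea_dem.tsv", sep="\t", index=False)
    gtop = gsea_out.iloc[0]
    print(f"GSEA (500 permutations): top term {gtop['term_id']} "
          f"ES {gtop['es']:.2f}, NES {gtop['nes']:.2f}, p {gtop['p']:.3f}, "
          f"direction {gtop['direction']}")


if __name__ == "__main__":
    main()
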