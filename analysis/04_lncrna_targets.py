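#!/usr/bin/env python
"""lncRNA target assignment for the differential sets.

Builds cis (< 100 kb) and antisense (opposite-strand overlap) candidates
between DELs and DEMs from the annotation, treats remaining DEL x DEM
combinations as trans candidates, and emits pairs passing the Pearson
gate |r| > 0.9 with p < 0.05 on pooled log2(CPM+1), one mode per pair
(antisense > cis > trans).
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from stressrna.config import RunConfig
from stressrna.diffexpr import filter_low_counts, log_cpm
from stressrna.io import read_annotation, read_counts, read_fasta
from stressrna.regulation import (assign_targets, find_antisense_candidates,
                                  find_cis_candidates)
from stressrna.types import LAYER_BIOTYPE


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    args = ap.parse_args()
    cfg = RunConfig()
    design = yaml.safe_load((args.indir / "design.yaml").read_text())

    de_ids = {}
    expr_parts = []
    for layer in ("mRNA", "lncRNA"):
        de = pd.read_csv(args.outdir / f"de_{layer}.tsv", sep="\t").set_index("transcript_id")
        de_ids[layer] = sorted(de.index[de["status"] != "ns"])
        m = read_counts(args.indir / f"counts_{layer}.tsv", layer, design)
        fm = filter_low_counts(m, {t: LAYER_BIOTYPE[layer] for t in m.transcript_ids}, cfg)
        expr_parts.append(log_cpm(fm))
    expr = pd.concat(expr_parts)

    records = read_annotation(args.indir / "annotation.gtf")
    dels, dems = de_ids["lncRNA"], de_ids["mRNA"]
    cis_c = find_cis_candidates(records, dels, dems, cfg.cis_window_bp)
    anti_c = find_antisense_candidates(records, dels, dems)
    seqs = read_fasta(args.indir / "transcripts.fa")
    pairs = assign_targets(expr, dels, dems, cis_c, anti_c, cfg, sequences=seqs)

    df = pd.DataFrame([dataclasses.asdict(p) for p in pairs],
                      columns=["lnc_id", "target_gene_id", "mode", "r", "p",
                               "distance_bp", "duplex_score"])
    df.to_csv(args.outdir / "regulatory_pairs.tsv", sep="\t", index=False)

    print(f"{len(dels)} DELs x {len(dems)} DEMs: "
          f"{len(cis_c)} cis candidates, {len(anti_c)} antisense candidates")
    by_mode = df["mode"].value_counts().to_dict()
    print(f"emitted {len(df)} co-expressed pairs: "
          + ", ".join(f"{by_mode.get(m, 0)} {m}" for m in ("antisense", "cis", "trans")))
    anti = df[df["mode"] == "antisense"]
    if len(anti):
        print(f"  antisense duplex scores: best {anti['duplex_score'].min():.0f}, "
              f"median {anti['duplex_score'].median():.0f} "
              "(perfect 40-mer hybrid = -80)")


if __name__ == "__main__":
    main()
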