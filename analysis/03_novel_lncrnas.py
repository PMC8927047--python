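#!/usr/bin/env python
"""Novel lncRNA discovery.

Scores every lncRNA transcript with two coding-potential screens
(Fickett TESTCODE and longest-ORF coverage) and intersects them with the
known-transcript catalogue: novel = non-coding by both screens, no
catalogue hit, >= 200 nt. Also summarises expression by novelty class.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from stressrna.config import RunConfig
from stressrna.diffexpr import filter_low_counts, log_cpm
from stressrna.io import read_annotation, read_counts, read_fasta, read_id_list
from stressrna.novelty import call_novelty, expression_density_by_class


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig()

    seqs = read_fasta(args.indir / "transcripts.fa")
    known = read_id_list(args.indir / "known_ids.txt")
    lncs = [dataclasses.replace(r, sequence=seqs[r.transcript_id])
            for r in read_annotation(args.indir / "annotation.gtf")
            if r.biotype == "lncRNA"]
    calls = call_novelty(lncs, known, cfg)
    calls.reset_index().to_csv(args.outdir / "novelty.tsv", sep="\t", index=False)

    n_novel = int((calls["novelty"] == "novel").sum())
    print(f"{len(calls)} lncRNA transcripts: {n_novel} novel, "
          f"{int((calls['novelty'] == 'known').sum())} known, "
          f"{int((calls['novelty'] == 'coding').sum())} coding-like "
          f"({n_novel / len(calls):.1%} novel)")

    design = yaml.safe_load((args.indir / "design.yaml").read_text())
    m = read_counts(args.indir / "counts_lncRNA.tsv", "lncRNA", design)
    fm = filter_low_counts(m, {t: "lncRNA" for t in m.transcript_ids}, cfg)
    de_path = args.outdir / "de_lncRNA.tsv"
    status = None
    if de_path.exists():
        status = pd.read_csv(de_path, sep="\t").set_index("transcript_id")["status"]
    dens = expression_density_by_class(log_cpm(fm), calls["novelty"], design, status)
    dens.to_csv(args.outdir / "expression_density.tsv", sep="\t", index=False)
    if status is not None:
        for cls in ("known", "novel"):
            sub = dens[dens["class"] == cls]
            if len(sub):
                print(f"  {cls}: {int(sub['n_de'].iloc[0])} DELs of "
                      f"{int(sub['n_transcripts'].iloc[0])} expressed")


if __name__ == "__main__":
    main()
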