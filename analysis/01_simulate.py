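#!/usr/bin/env python
"""Generate the synthetic study dataset.

Four count layers (mRNA, miRNA, lncRNA, circRNA; 3 stress vs 3 control),
a GTF annotation on one synthetic chromosome, transcript/3'UTR/miRNA
FASTAs and a ground-truth record of everything planted: differential
transcripts, cis/antisense/trans lncRNA-gene pairs, miRNA seed sites and
ceRNA sponge modules. Downstream drivers read the files this writes.
"""

import argparse
from pathlib import Path

from stressrna.simulate import SimConfig, simulate_dataset, write_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    ds = simulate_dataset(SimConfig(), seed=args.seed)
    write_dataset(ds, args.outdir)

    t = ds.truth
    print(f"wrote dataset to {args.outdir} (seed {args.seed})")
    for layer, m in ds.matrices.items():
        planted = t.planted_de.get(layer, {})
        print(f"  {layer}: {m.counts.shape[0]} transcripts x "
              f"{m.counts.shape[1]} samples, {len(planted)} planted DE")
    print(f"  planted pairs: {len(t.planted_cis_pairs)} cis, "
          f"{len(t.planted_antisense_pairs)} antisense, "
          f"{len(t.planted_trans_pairs)} trans")
    print(f"  planted ceRNA triplets: {len(t.planted_triplets)} "
          f"({len({(a, b) for _, a, b in t.planted_triplets})} sponge pairs)")
    print(f"  novel lncRNAs: {len(t.novel_lnc_ids)} of "
          f"{sum(1 for r in ds.records if r.biotype == 'lncRNA')}")


if __name__ == "__main__":
    main()
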