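#!/usr/bin/env python
"""ceRNA network inference over the differential sets.

Predicts miRNA binding by seed matching (>= 7mer-m8) on 3'UTRs of
DEMs/DELs/DECs, keeps (miRNA, sponge) pairs with Pearson r < -0.9,
and links two sponges when they share miRNAs, are positively
co-expressed, and the shared-miRNA overlap passes the hypergeometric
test (p < 0.05, universe = DEMIs). Reports degrees (distinct shared
miRNAs), hubs (degree >= 5) and the common vs lncRNA-specific DEM split.
"""

import argparse
from pathlib import Path

import pandas as pd
import yaml

from stressrna.cerna import (build_network, mirna_target_sets, scan_all_sites,
                             specific_vs_common)
from stressrna.config import RunConfig
from stressrna.diffexpr import filter_low_counts, log_cpm
from stressrna.io import read_counts, read_fasta, write_edge_list
from stressrna.types import LAYER_BIOTYPE, LAYERS


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    args = ap.parse_args()
    cfg = RunConfig()
    design = yaml.safe_load((args.indir / "design.yaml").read_text())

    de_ids, expr_parts = {}, []
    for layer in LAYERS:
        de = pd.read_csv(args.outdir / f"de_{layer}.tsv", sep="\t").set_index("transcript_id")
        de_ids[layer] = sorted(de.index[de["status"] != "ns"])
        m = read_counts(args.indir / f"counts_{layer}.tsv", layer, design)
        fm = filter_low_counts(m, {t: LAYER_BIOTYPE[layer] for t in m.transcript_ids}, cfg)
        expr_parts.append(log_cpm(fm))
    expr = pd.concat(expr_parts)

    mirnas = read_fasta(args.indir / "mirnas.fa")
    utrs = read_fasta(args.indir / "utrs.fa")
    demis = de_ids["miRNA"]
    sponge_type = {t: ly for ly in ("mRNA", "lncRNA", "circRNA") for t in de_ids[ly]}
    sites = scan_all_sites({m: mirnas[m] for m in demis},
                           {t: utrs[t] for t in sponge_type if t in utrs})
    target_sets = mirna_target_sets(sites, cfg.min_site_class)
    net = build_network(target_sets, expr, sponge_type, cfg, universe_n=len(demis))
    write_edge_list(net, args.outdir / "cerna_edges.tsv")

    lnc_only, common = specific_vs_common(net)
    comp = net.composition()
    print(f"{len(demis)} DEMIs, {len(sites)} seed sites, "
          f"{sum(len(v) for v in target_sets.values())} gated miRNA-target pairs")
    print(f"network: {len(net.nodes)} nodes, {len(net.edges)} sponge edges, "
          f"{len(net.hubs)} hubs (degree >= {cfg.hub_degree})")
    if comp:
        print("composition: " + ", ".join(f"{t} {f:.1%}" for t, f in comp.items()))
    print(f"DEM partition: {len(common)} commonly regulated "
          f"(lncRNA and circRNA partners), {len(lnc_only)} lncRNA-specific")
    nodes = pd.DataFrame(
        [{"node": n, "type": net.node_types[n],
          "degree": net.degree_of.get(n, 0), "hub": n in set(net.hubs)}
         for n in net.nodes])
    nodes.to_csv(args.outdir / "cerna_nodes.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
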