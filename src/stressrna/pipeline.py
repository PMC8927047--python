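"""End-to-end orchestration: filter -> DE -> novelty -> lncRNA targets ->
ceRNA network -> enrichment, with a deterministic run manifest.

Stages communicate through the per-stage TSVs written under the output
directory, so any stage can be re-run from intermediates. The manifest
records the config hash, seed, per-file checksums and per-stage counts
(the four differential sets in the order DEM, DEMI, DEL, DEC).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cerna, diffexpr, enrichment, novelty, regulation
from .config import RunConfig
from .io import (read_annotation, read_counts, read_fasta, read_id_list,
                 write_results)
from .simulate import (Dataset, GroundTruth, SimConfig, simulate_dataset,
                       synthetic_gene_sets, write_dataset)
from .types import LAYER_BIOTYPE, LAYERS, CountMatrix


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    checksums: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(stage: str, **counts) -> None:
    kv = " ".join(f"{k}={v}" for k, v in counts.items())
    print(f"[stressrna] {stage}: {kv}", file=sys.stderr)


def _load_inputs(config: RunConfig) -> Dataset:
    """Read a dataset laid out as by :func:`stressrna.simulate.write_dataset`."""
    paths = config.paths
    base = Path(paths.get("indir", "."))

    def p(key: str, default: str) -> Path:
        path = Path(paths.get(key, base / default))
        if not path.exists():
            raise FileNotFoundError(f"missing input {key}: {path}")
        return path

    design = yaml.safe_load(p("design", "design.yaml").read_text())
    matrices = {}
    for layer in LAYERS:
        cpath = Path(paths.get(f"counts_{layer}", base / f"counts_{layer}.tsv"))
        if cpath.exists():
            matrices[layer] = read_counts(cpath, layer, design)
    if not matrices:
        raise FileNotFoundError(f"no counts_<layer>.tsv found under {base}")
    records = read_annotation(p("annotation", "annotation.gtf"))
    transcripts = read_fasta(p("transcripts", "transcripts.fa"))
    utrs = read_fasta(p("utrs", "utrs.fa"))
    mirnas = read_fasta(p("mirnas", "mirnas.fa"))
    known = read_id_list(p("known_ids", "known_ids.txt"))
    records = [dataclasses.replace(r, sequence=transcripts.get(r.transcript_id),
                                   known=r.transcript_id in known)
               for r in records]
    gmt_path = Path(paths.get("gene_sets", base / "gene_sets.gmt"))
    gene_sets = None
    if gmt_path.exists():
        from .enrichment import read_gmt
        gene_sets = read_gmt(gmt_path)
    return Dataset(records, matrices, transcripts, utrs, mirnas,
                   GroundTruth(), design, gene_sets)


def run_all(config: RunConfig | None = None, outdir: str | Path = "results/run",
            simulate: bool = False, sim_config: SimConfig | None = None,
            dataset: Dataset | None = None, seed: int | None = None,
            gene_sets: dict[str, list[str]] | None = None,
            n_perm: int = 200) -> RunManifest:
    """Run every stage and return the manifest.

    Inputs come from ``dataset`` if given, from the generator when
    ``simulate`` is true, else from paths in ``config.paths``.
    """
    cfg = config or RunConfig()
    seed = cfg.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if dataset is not None:
        ds = dataset
    elif simulate:
        ds = simulate_dataset(sim_config or SimConfig(), seed)
        write_dataset(ds, outdir / "sim")
    else:
        ds = _load_inputs(cfg)
    records_by_id = {r.transcript_id: r for r in ds.records}

    # ---- filter + DE per layer ----------------------------------------
    tables: dict[str, pd.DataFrame] = {}
    de_tables: dict[str, pd.DataFrame] = {}
    filtered: dict[str, CountMatrix] = {}
    stage_counts: dict = {}
    for layer, matrix in ds.matrices.items():
        biotype_of = {t: LAYER_BIOTYPE[layer] for t in matrix.transcript_ids}
        fm = diffexpr.filter_low_counts(matrix, biotype_of, cfg)
        filtered[layer] = fm
        de = diffexpr.run_de(fm, cfg)
        de_tables[layer] = de
        tables[f"de_{layer}"] = de.reset_index()
        stage_counts[f"n_input_{layer}"] = len(matrix.transcript_ids)
        stage_counts[f"n_filtered_{layer}"] = len(fm.transcript_ids)
        _log(f"diffexpr[{layer}]", kept=len(fm.transcript_ids),
             de=int((de["status"] != "ns").sum()))

    de_ids = {layer: sorted(t.index[t["status"] != "ns"])
              for layer, t in de_tables.items()}
    for name, layer in (("DEM", "mRNA"), ("DEMI", "miRNA"),
                        ("DEL", "lncRNA"), ("DEC", "circRNA")):
        stage_counts[f"n_{name}"] = len(de_ids.get(layer, []))

    # pooled log-CPM across layers for every correlation gate
    expr = pd.concat([diffexpr.log_cpm(m) for m in filtered.values()])

    # ---- novelty ------------------------------------------------------
    lnc_records = [r for r in ds.records if r.biotype == "lncRNA"
                   and (r.sequence or ds.transcripts.get(r.transcript_id))]
    lnc_records = [dataclasses.replace(r, sequence=r.sequence or ds.transcripts[r.transcript_id])
                   for r in lnc_records]
    known_ids = {r.transcript_id for r in ds.records if r.known}
    nov = novelty.call_novelty(lnc_records, known_ids, cfg)
    tables["novelty"] = nov.reset_index()
    if "lncRNA" in filtered:
        dens = novelty.expression_density_by_class(
            diffexpr.log_cpm(filtered["lncRNA"]), nov["novelty"],
            ds.design, de_tables["lncRNA"]["status"])
        tables["expression_density"] = dens
    stage_counts["n_novel_lncRNA"] = int((nov["novelty"] == "novel").sum())
    _log("novelty", novel=stage_counts["n_novel_lncRNA"], total=len(nov))

    # ---- lncRNA target assignment -------------------------------------
    dels = de_ids.get("lncRNA", [])
    dems = de_ids.get("mRNA", [])
    cis_c = regulation.find_cis_candidates(ds.records, dels, dems, cfg.cis_window_bp)
    anti_c = regulation.find_antisense_candidates(ds.records, dels, dems)
    pairs = regulation.assign_targets(expr, dels, dems, cis_c, anti_c, cfg,
                                      sequences=ds.transcripts)
    tables["regulatory_pairs"] = pd.DataFrame(
        [dataclasses.asdict(p) for p in pairs],
        columns=["lnc_id", "target_gene_id", "mode", "r", "p",
                 "distance_bp", "duplex_score"])
    stage_counts["n_regulatory_pairs"] = len(pairs)
    _log("regulation", cis_candidates=len(cis_c), antisense_candidates=len(anti_c),
         pairs=len(pairs))

    # ---- ceRNA network ------------------------------------------------
    demis = de_ids.get("miRNA", [])
    sponge_type = {t: ly for ly in ("mRNA", "lncRNA", "circRNA")
                   for t in de_ids.get(ly, [])}
    sites = cerna.scan_all_sites(
        {m: ds.mirnas[m] for m in demis if m in ds.mirnas},
        {t: ds.utrs[t] for t in sponge_type if t in ds.utrs})
    target_sets = cerna.mirna_target_sets(sites, cfg.min_site_class)
    universe_n = max(len(demis), 1)
    network = cerna.build_network(target_sets, expr, sponge_type, cfg,
                                  universe_n=universe_n)
    lnc_only, common = cerna.specific_vs_common(network)
    tables["cerna_nodes"] = pd.DataFrame(
        [{"node": n, "type": network.node_types[n],
          "degree": network.degree_of.get(n, 0),
          "edge_degree": network.edge_degree_of.get(n, 0),
          "hub": n in set(network.hubs)}
         for n in network.nodes],
        columns=["node", "type", "degree", "edge_degree", "hub"])
    stage_counts["n_cerna_edges"] = len(network.edges)
    stage_counts["n_cerna_hubs"] = len(network.hubs)
    stage_counts["n_common_dems"] = len(common)
    stage_counts["n_lnc_specific_dems"] = len(lnc_only)
    _log("cerna", edges=len(network.edges), hubs=len(network.hubs),
         common=len(common), specific=len(lnc_only))

    # ---- enrichment ---------------------------------------------------
    universe = sorted(filtered["mRNA"].transcript_ids) if "mRNA" in filtered else []
    if gene_sets is None:
        gene_sets = ds.gene_sets
    if gene_sets is None and universe:
        planted_up = sorted(t for t, e in ds.truth.planted_de.get("mRNA", {}).items()
                            if e > 0)
        gene_sets = synthetic_gene_sets(universe, planted_up, seed + 7)
    if gene_sets and universe:
        if dems:
            tables["enrichment_ora_dem"] = enrichment.ora(dems, universe, gene_sets)
        ranked = enrichment.rank_metric(de_tables["mRNA"])
        tables["enrichment_gsea_dem"] = enrichment.gsea_table(
            ranked, gene_sets, n_perm=n_perm, seed=seed + 11)
        targets = sorted({p.target_gene_id for p in pairs} & set(universe))
        if targets:
            tables["enrichment_ora_lnc_targets"] = enrichment.ora(
                targets, universe, gene_sets)
        for name, group in (("common", common), ("lnc_specific", lnc_only)):
            ids = sorted(set(group) & set(universe))
            if ids:
                tables[f"enrichment_ora_{name}"] = enrichment.ora(
                    ids, universe, gene_sets)
        _log("enrichment", terms=len(gene_sets))

    # ---- outputs + manifest -------------------------------------------
    summary = {"de_counts": {k: stage_counts[f"n_{k}"]
                             for k in ("DEM", "DEMI", "DEL", "DEC")},
               "stage_counts": stage_counts}
    written = write_results(tables, network, outdir, summary=summary)
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(
        config_hash=cfg_hash, seed=seed,
        checksums={name: _sha256(p) for name, p in sorted(written.items())},
        counts=stage_counts)
    manifest.save(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# ground-truth validation


def validate_against_truth(outdir: str | Path, truth_path: str | Path) -> dict:
    """Sensitivity/precision per planted structure class from a finished
    run directory and its ground-truth file."""
    outdir = Path(outdir)
    truth_path = Path(truth_path)
    if not truth_path.exists():
        raise FileNotFoundError(f"ground truth file not found: {truth_path}")
    truth = GroundTruth.from_json(truth_path.read_text())
    report: dict = {}

    # differential expression
    for layer in LAYERS:
        de_path = outdir / f"de_{layer}.tsv"
        planted = truth.planted_de.get(layer, {})
        if not de_path.exists():
            continue
        de = pd.read_csv(de_path, sep="\t").set_index("transcript_id")
        called = set(de.index[de["status"] != "ns"])
        cohort = {t for t, e in planted.items() if abs(e) == 2.0} or set(planted)
        if cohort:
            report[f"de_sensitivity_{layer}"] = \
                len(called & cohort) / len(cohort & set(de.index)) \
                if cohort & set(de.index) else 0.0
        report[f"de_false_discovery_{layer}"] = \
            (len(called - set(planted)) / len(called)) if called else 0.0

    # novelty
    nov_path = outdir / "novelty.tsv"
    if nov_path.exists() and truth.novel_lnc_ids:
        nov = pd.read_csv(nov_path, sep="\t").set_index("transcript_id")
        called = set(nov.index[nov["novelty"] == "novel"])
        planted = set(truth.novel_lnc_ids) & set(nov.index)
        report["novelty_sensitivity"] = len(called & planted) / len(planted) if planted else 0.0
        report["novelty_precision"] = len(called & planted) / len(called) if called else 0.0

    # regulatory pairs
    rp_path = outdir / "regulatory_pairs.tsv"
    if rp_path.exists():
        rp = pd.read_csv(rp_path, sep="\t")
        emitted = {(row.lnc_id, row.target_gene_id, row.mode)
                   for row in rp.itertuples()}
        for mode, planted in (("cis", truth.planted_cis_pairs),
                              ("antisense", truth.planted_antisense_pairs),
                              ("trans", truth.planted_trans_pairs)):
            if planted:
                hits = sum((l, g, mode) in emitted for l, g in planted)
                report[f"{mode}_pair_sensitivity"] = hits / len(planted)

    # ceRNA triplets
    edge_path = outdir / "cerna_edges.tsv"
    if edge_path.exists():
        ed = pd.read_csv(edge_path, sep="\t")
        edge_mirnas = {}
        for row in ed.itertuples():
            shared = set(str(row.shared_mirnas).split(",")) if pd.notna(row.shared_mirnas) else set()
            edge_mirnas[frozenset((row.nodeA, row.nodeB))] = shared
        if truth.planted_triplets:
            hits = sum(m in edge_mirnas.get(frozenset((a, b)), set())
                       for m, a, b in truth.planted_triplets)
            report["cerna_triplet_sensitivity"] = hits / len(truth.planted_triplets)
        planted_pairs = {frozenset((a, b)) for _m, a, b in truth.planted_triplets}
        report["cerna_false_edges"] = float(
            sum(1 for k in edge_mirnas if k not in planted_pairs))

    for k, v in report.items():
        if k != "cerna_false_edges" and not (0.0 <= v <= 1.0):
            raise AssertionError(f"report value out of range: {k}={v}")
    return report
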