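"""Synthetic four-layer RNA-seq data with planted ground truth.

Generates, fully deterministically under a seed:

* an annotation on one synthetic chromosome where a configurable
  fraction of lncRNAs sit within 100 kb of a coding gene (cis
  candidates), a fraction overlap a coding gene on the opposite strand
  (antisense candidates), and the rest are distal;
* negative-binomial count matrices for the four layers under a 3 vs 3
  stress/control design, with planted log2 effects and shared latent
  factors that induce the co-expression sign structure the downstream
  gates look for (positive between lncRNA/circRNA sponges and their
  partner genes, negative between a miRNA and its sponges);
* transcript, 3'UTR and mature-miRNA sequences where every planted
  (miRNA, sponge) pair has an exact 8mer seed site, non-target UTRs are
  scrubbed of seed matches for all generated miRNAs, coding transcripts
  carry a long ORF and novel lncRNAs are ORF-poor.

The generator's defaults are the study conditions the analyses are
validated under; see docs/methods.md for the rationale behind each.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import write_annotation, write_counts, write_fasta, write_id_list
from .novelty import fickett_score, orf_coverage
from .types import CountMatrix, TranscriptRecord

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# configuration and ground truth


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset (defaults = the
    conditions all recovery figures in this package refer to)."""

    n_coding: int = 2000
    n_lnc: int = 300
    n_mirna: int = 50
    n_circ: int = 100
    n_reps: int = 3
    # annotation structure
    cis_fraction: float = 0.10
    antisense_fraction: float = 0.10
    novel_fraction: float = 0.50
    gene_spacing_bp: int = 1_000_000
    # expression model
    dispersion: float = 0.1
    lib_sizes: dict = field(default_factory=lambda: {
        "mRNA": 200_000, "miRNA": 10_000, "lncRNA": 50_000, "circRNA": 20_000,
    })
    lib_depth_jitter: float = 0.10
    abundance_log2_sd: float = 1.5
    # planted plain differential expression (the sensitivity cohort)
    de_fraction: float = 0.10
    de_effect: float = 2.0
    de_min_mean: float = 50.0
    # planted structural pairs/triplets (strong coupling so the n=6
    # Pearson 0.9 gate is reachable)
    n_cis_pairs: int = 20
    n_antisense_pairs: int = 15
    n_trans_pairs: int = 20
    # ceRNA architecture: a module couples 2 mRNAs + 1 lncRNA + 1 circRNA
    # through a dedicated miRNA set (so module mRNAs are "commonly
    # regulated"); hub modules carry enough miRNAs to cross the hub
    # degree threshold; lnc-only pairs give lncRNA-specific mRNAs
    n_sponge_modules: int = 6
    n_hub_modules: int = 2
    n_lnc_only_pairs: int = 4
    mirnas_per_module: int = 2
    mirnas_per_hub_module: int = 5
    structural_effect: float = 5.0
    structural_mean: float = 300.0
    coupling_sd: float = 1.0
    # sequences
    utr_length: int = 200
    mrna_orf_codons: int = 200
    lnc_length: int = 600


@dataclass
class GroundTruth:
    """Bookkeeping of everything planted, for recovery scoring."""

    planted_de: dict = field(default_factory=dict)        # layer -> {tid: effect}
    planted_cis_pairs: list = field(default_factory=list)       # (lnc, gene)
    planted_antisense_pairs: list = field(default_factory=list)
    planted_trans_pairs: list = field(default_factory=list)
    planted_sites: dict = field(default_factory=dict)     # mirna -> [targets]
    planted_triplets: list = field(default_factory=list)  # (mirna, a, b)
    novel_lnc_ids: list = field(default_factory=list)
    cis_candidates: list = field(default_factory=list)    # (lnc, gene, gap)
    antisense_candidates: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(**{f.name: d[f.name] for f in dataclasses.fields(cls) if f.name in d})

    def de_cohort(self, layer: str, effect: float) -> list[str]:
        """Ids planted at |log2 effect| == ``effect`` in a layer."""
        return [t for t, e in self.planted_de.get(layer, {}).items()
                if abs(e) == effect]


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(n_coding: int, n_lnc: int, n_mirna: int, n_circ: int,
                        seed: int, cis_fraction: float = 0.10,
                        antisense_fraction: float = 0.10,
                        novel_fraction: float = 0.50,
                        gene_spacing_bp: int = 1_000_000,
                        ) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Lay out one synthetic chromosome and a ground-truth skeleton.

    Coding genes are spaced ``gene_spacing_bp`` apart so a lncRNA is
    within 100 kb of at most its designated partner. Returns the records
    and a :class:`GroundTruth` whose candidate lists are filled in.
    """
    for n in (n_coding, n_lnc, n_mirna, n_circ):
        if n < 0:
            raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    records: list[TranscriptRecord] = []
    chrom = "chr1"

    gene_start = {}
    gene_end = {}
    gene_strand = {}
    for i in range(n_coding):
        start = 500_000 + i * gene_spacing_bp
        length = int(rng.integers(1000, 3001))
        strand = "+" if rng.random() < 0.5 else "-"
        tid = f"mRNA_{i:04d}"
        gene_start[tid], gene_end[tid], gene_strand[tid] = start, start + length - 1, strand
        records.append(TranscriptRecord(tid, f"GENE_{i:04d}", "coding", chrom,
                                        start, start + length - 1, strand))

    n_cis = int(round(cis_fraction * n_lnc)) if n_coding else 0
    n_anti = int(round(antisense_fraction * n_lnc)) if n_coding else 0
    coding_ids = [f"mRNA_{i:04d}" for i in range(n_coding)]
    partners = list(rng.choice(n_coding, size=min(n_cis + n_anti, n_coding),
                               replace=False)) if n_coding else []
    n_novel = int(round(novel_fraction * n_lnc))

    for j in range(n_lnc):
        known = j >= n_novel
        tid = f"lnc_{j:04d}" if known else f"TCONS_{j:04d}"
        length = int(rng.integers(300, 2001))
        if j < n_cis and partners:
            g = coding_ids[partners[j % len(partners)]]
            gap = int(rng.integers(1_000, 90_001))
            if rng.random() < 0.5:
                start = gene_end[g] + gap + 1
            else:
                start = gene_start[g] - gap - length
            strand = "+" if rng.random() < 0.5 else "-"
            truth.cis_candidates.append([tid, g, gap])
        elif j < n_cis + n_anti and partners:
            g = coding_ids[partners[j % len(partners)]]
            start = gene_start[g] + int(rng.integers(0, max(1, gene_end[g] - gene_start[g] - 200)))
            strand = "-" if gene_strand[g] == "+" else "+"
            truth.antisense_candidates.append([tid, g])
        else:
            # distal: mid-gap, >= ~350 kb from every gene
            slot = int(rng.integers(0, max(1, n_coding - 1))) if n_coding > 1 else 0
            start = 500_000 + slot * gene_spacing_bp + gene_spacing_bp // 2 \
                + int(rng.integers(-50_000, 50_001))
            strand = "+" if rng.random() < 0.5 else "-"
        records.append(TranscriptRecord(tid, f"LNCG_{j:04d}", "lncRNA", chrom,
                                        start, start + length - 1, strand, known=known))
        if not known:
            truth.novel_lnc_ids.append(tid)

    for k in range(n_mirna):
        slot = int(rng.integers(0, max(1, n_coding - 1))) if n_coding > 1 else 0
        start = 500_000 + slot * gene_spacing_bp + gene_spacing_bp // 4 \
            + int(rng.integers(0, 10_000))
        records.append(TranscriptRecord(f"miR_{k:03d}", f"MIRG_{k:03d}", "miRNA",
                                        chrom, start, start + 79, "+"))

    for c in range(n_circ):
        if n_coding:
            host = coding_ids[int(rng.integers(0, n_coding))]
            start = gene_start[host]
            end = gene_end[host]
            strand = gene_strand[host]
        else:
            start, end, strand = 1_000 + c * 10_000, 1_000 + c * 10_000 + 999, "+"
        records.append(TranscriptRecord(f"circ_{c:03d}", f"CIRCG_{c:03d}", "circRNA",
                                        chrom, start, end, strand))
    return records, truth


# ---------------------------------------------------------------------------
# planting


def plant_structures(records: list[TranscriptRecord], truth: GroundTruth,
                     cfg: SimConfig, seed: int) -> dict:
    """Choose planted DE cohorts, pairs and triplets; fill in ``truth``.

    Returns the internal planting plan used by :func:`generate_counts`:
    per-transcript effects, per-transcript forced baseline means, and
    coupling groups (lists of (member, sign) sharing a latent factor).
    """
    rng = np.random.default_rng(seed)
    by_layer: dict[str, list[str]] = {"mRNA": [], "lncRNA": [], "miRNA": [], "circRNA": []}
    layer_of_biotype = {"coding": "mRNA", "lncRNA": "lncRNA", "miRNA": "miRNA", "circRNA": "circRNA"}
    for r in records:
        by_layer[layer_of_biotype[r.biotype]].append(r.transcript_id)

    effects: dict[str, float] = {}
    forced_mean: dict[str, float] = {}
    coupling_groups: list[list[tuple[str, float]]] = []
    used: set[str] = set()

    # alternate effect signs so each layer stays compositionally
    # balanced (up- and down-regulation in equal measure)
    _sign_state = [1.0]

    def sign() -> float:
        _sign_state[0] = -_sign_state[0]
        return _sign_state[0]

    # structural pairs: cis and antisense from annotation candidates
    for cand, store, n_want in (
        (truth.cis_candidates, truth.planted_cis_pairs, cfg.n_cis_pairs),
        (truth.antisense_candidates, truth.planted_antisense_pairs, cfg.n_antisense_pairs),
    ):
        pool = [c for c in cand if c[0] not in used and c[1] not in used]
        take = pool[: n_want]
        for entry in take:
            lnc, gene = entry[0], entry[1]
            s = sign()
            for tid in (lnc, gene):
                effects[tid] = s * cfg.structural_effect
                forced_mean[tid] = cfg.structural_mean
                used.add(tid)
            coupling_groups.append([(lnc, 1.0), (gene, 1.0)])
            store.append([lnc, gene])

    # trans pairs: distal lncRNAs x far-away genes
    cand_lnc = [t for t in by_layer["lncRNA"]
                if t not in used
                and t not in {c[0] for c in truth.cis_candidates}
                and t not in {c[0] for c in truth.antisense_candidates}]
    cand_gene = [t for t in by_layer["mRNA"] if t not in used]
    rng.shuffle(cand_lnc)
    rng.shuffle(cand_gene)
    for lnc, gene in zip(cand_lnc[: cfg.n_trans_pairs], cand_gene[: cfg.n_trans_pairs]):
        s = sign()
        for tid in (lnc, gene):
            effects[tid] = s * cfg.structural_effect
            forced_mean[tid] = cfg.structural_mean
            used.add(tid)
        coupling_groups.append([(lnc, 1.0), (gene, 1.0)])
        truth.planted_trans_pairs.append([lnc, gene])

    # ceRNA modules: sponges coupled through dedicated miRNA sets
    cand_lnc = [t for t in cand_lnc if t not in used]
    cand_gene = [t for t in by_layer["mRNA"] if t not in used]
    cand_circ = [t for t in by_layer["circRNA"] if t not in used]
    cand_mir = [t for t in by_layer["miRNA"] if t not in used]
    rng.shuffle(cand_gene)
    gene_i = lnc_i = circ_i = mir_i = 0
    n_modules = cfg.n_sponge_modules + cfg.n_hub_modules

    def plant_module(mrnas: list[str], lncs: list[str], circs: list[str],
                     mirnas: list[str]) -> None:
        s = sign()
        group: list[tuple[str, float]] = []
        sponges = mrnas + lncs + circs
        for tid in sponges:
            effects[tid] = s * cfg.structural_effect
            forced_mean[tid] = cfg.structural_mean
            used.add(tid)
            group.append((tid, 1.0))
        for m in mirnas:
            effects[m] = -s * cfg.structural_effect
            forced_mean[m] = cfg.structural_mean
            used.add(m)
            group.append((m, -1.0))
            truth.planted_sites.setdefault(m, []).extend(sponges)
            # triplets = every allowed sponge pairing sharing this miRNA
            for g in mrnas:
                for nc in lncs + circs:
                    truth.planted_triplets.append([m, g, nc])
        coupling_groups.append(group)

    for mod in range(n_modules):
        n_mir = (cfg.mirnas_per_hub_module if mod < cfg.n_hub_modules
                 else cfg.mirnas_per_module)
        if (gene_i + 2 > len(cand_gene) or lnc_i + 1 > len(cand_lnc)
                or circ_i + 1 > len(cand_circ) or mir_i + n_mir > len(cand_mir)):
            break
        plant_module(cand_gene[gene_i:gene_i + 2], [cand_lnc[lnc_i]],
                     [cand_circ[circ_i]], cand_mir[mir_i:mir_i + n_mir])
        gene_i += 2
        lnc_i += 1
        circ_i += 1
        mir_i += n_mir

    for _ in range(cfg.n_lnc_only_pairs):
        if (gene_i + 1 > len(cand_gene) or lnc_i + 1 > len(cand_lnc)
                or mir_i + cfg.mirnas_per_module > len(cand_mir)):
            break
        plant_module([cand_gene[gene_i]], [cand_lnc[lnc_i]], [],
                     cand_mir[mir_i:mir_i + cfg.mirnas_per_module])
        gene_i += 1
        lnc_i += 1
        mir_i += cfg.mirnas_per_module

    # plain DE cohorts at |effect| = de_effect (chosen later among
    # sufficiently expressed transcripts; marked here as count quotas)
    plan = {
        "effects": effects,
        "forced_mean": forced_mean,
        "coupling_groups": coupling_groups,
        "de_quota": {ly: int(round(cfg.de_fraction * len(by_layer[ly]))) for ly in by_layer},
        "by_layer": by_layer,
        "used": used,
    }
    return plan


# ---------------------------------------------------------------------------
# counts


def generate_counts(records: list[TranscriptRecord], truth: GroundTruth,
                    cfg: SimConfig, seed: int,
                    plan: dict | None = None) -> dict[str, CountMatrix]:
    """NB counts per layer: mu_gs = lib_s * q_g * 2^(effect_g.[s in stress]
    + coupling); dispersion ``cfg.dispersion``; deterministic under seed."""
    if cfg.dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    if plan is None:
        plan = plant_structures(records, truth, cfg, seed + 1)
    by_layer = plan["by_layer"]
    effects = plan["effects"]
    forced_mean = plan["forced_mean"]

    samples = [f"stress_{i + 1}" for i in range(cfg.n_reps)] + \
              [f"control_{i + 1}" for i in range(cfg.n_reps)]
    is_stress = np.array([1.0] * cfg.n_reps + [0.0] * cfg.n_reps)
    n_samples = 2 * cfg.n_reps

    # latent coupling factors: one value per (group, sample)
    coupling = {tid: np.zeros(n_samples) for g in plan["coupling_groups"] for tid, _ in g}
    for group in plan["coupling_groups"]:
        z = rng.normal(0.0, 1.0, size=n_samples)
        for tid, sgn in group:
            coupling[tid] = coupling[tid] + sgn * cfg.coupling_sd * z

    matrices: dict[str, CountMatrix] = {}
    for layer, ids in by_layer.items():
        if not ids:
            continue
        lib = cfg.lib_sizes[layer]
        depth = lib * rng.uniform(1 - cfg.lib_depth_jitter, 1 + cfg.lib_depth_jitter,
                                  size=n_samples)
        # relative abundances
        w = 2.0 ** rng.normal(0.0, cfg.abundance_log2_sd, size=len(ids))
        base = lib * w / w.sum()
        # force structural members to a high baseline
        for i, tid in enumerate(ids):
            if tid in forced_mean:
                base[i] = forced_mean[tid]
        # choose the plain DE cohort among well-expressed, unused transcripts
        eligible = [i for i, tid in enumerate(ids)
                    if tid not in plan["used"] and base[i] >= cfg.de_min_mean]
        quota = min(plan["de_quota"][layer], len(eligible))
        chosen = rng.choice(eligible, size=quota, replace=False) if quota else []
        for i in chosen:
            effects[ids[i]] = cfg.de_effect * (1.0 if rng.random() < 0.5 else -1.0)

        truth.planted_de[layer] = {tid: effects[tid] for tid in ids if tid in effects}

        eff = np.array([effects.get(tid, 0.0) for tid in ids])
        coup = np.vstack([coupling.get(tid, np.zeros(n_samples)) for tid in ids])
        log2_mu = (np.log2(np.maximum(base, 1e-9))[:, None]
                   + eff[:, None] * is_stress[None, :]
                   + coup
                   + np.log2(depth / lib)[None, :])
        mu = 2.0 ** log2_mu
        r = 1.0 / cfg.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        df = pd.DataFrame(counts, index=ids, columns=samples)
        matrices[layer] = CountMatrix(layer, df,
                                      {s: ("stress" if s.startswith("stress") else "control")
                                       for s in samples})
    return matrices


# ---------------------------------------------------------------------------
# sequences

_NONSTOP = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")]


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _scrub_cores(seq: str, cores: list[str], rng, max_iter: int = 200) -> str:
    """Replace any occurrence of a seed core until the sequence is clean."""
    for _ in range(max_iter):
        dirty = False
        for core in cores:
            pos = seq.find(core)
            if pos >= 0:
                seq = seq[:pos] + _random_seq(rng, len(core)) + seq[pos + len(core):]
                dirty = True
        if not dirty:
            return seq
    raise RuntimeError("could not scrub seed cores from sequence")


def _longest_orf(seq: str) -> tuple[int, int]:
    """(start, length in nt) of the longest complete forward-frame ORF."""
    best = (-1, 0)
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in ("TAA", "TAG", "TGA"):
                if i + 3 - start > best[1]:
                    best = (start, i + 3 - start)
                start = None
    return best


def _orf_poor(seq: str, rng, max_frac: float = 0.25) -> str:
    """Disrupt ORFs (mutate their start codon) until coverage < max_frac."""
    while True:
        start, length = _longest_orf(seq)
        if length / len(seq) < max_frac:
            return seq
        repl = "ACC" if seq[start:start + 3] == "ATG" else "ACC"
        seq = seq[:start] + repl + seq[start + 3:]


def generate_sequences(records: list[TranscriptRecord], truth: GroundTruth,
                       cfg: SimConfig, seed: int
                       ) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """(transcript sequences, 3'UTRs, mature miRNAs), deterministic.

    Planted (miRNA, target) pairs get one exact 8mer site in the
    target's UTR; every other UTR is scrubbed of 6mer-core matches for
    all generated miRNAs. Coding transcripts carry an ORF covering more
    than half their length; lncRNAs are kept below 25% ORF coverage
    (novel ones additionally re-drawn if their Fickett score looks
    coding-like).
    """
    rng = np.random.default_rng(seed)
    mirna_ids = sorted(r.transcript_id for r in records if r.biotype == "miRNA")

    # mature miRNAs with unique 6mer cores
    mirnas: dict[str, str] = {}
    cores: dict[str, str] = {}
    seen_cores: set[str] = set()
    for mid in mirna_ids:
        while True:
            seq = _random_seq(rng, 22)
            core = revcomp(seq[1:7])
            if core not in seen_cores:
                seen_cores.add(core)
                mirnas[mid] = seq
                cores[mid] = core
                break
    all_cores = [cores[m] for m in mirna_ids]

    site_of: dict[str, list[str]] = {}
    for m, targets in truth.planted_sites.items():
        # 8mer: reverse complement of miRNA nt 2-8, followed by A
        site = revcomp(mirnas[m][1:8]) + "A"
        for t in targets:
            site_of.setdefault(t, []).append(site)

    transcripts: dict[str, str] = {}
    utrs: dict[str, str] = {}
    anti_partner = {lnc: gene for lnc, gene in
                    (tuple(x[:2]) for x in truth.antisense_candidates)}

    coding_first = sorted(records, key=lambda r: r.biotype != "coding")
    for r in coding_first:
        tid = r.transcript_id
        if r.biotype == "miRNA":
            transcripts[tid] = mirnas[tid]
            continue
        if r.biotype == "coding":
            head = _scrub_cores(_random_seq(rng, 60), ["ATG"], rng)
            orf = "ATG" + "".join(rng.choice(_NONSTOP, size=cfg.mrna_orf_codons)) + "TAA"
            tail = _random_seq(rng, 60)
            transcripts[tid] = head + orf + tail
        else:  # lncRNA / circRNA: ORF-poor
            seq = _random_seq(rng, cfg.lnc_length)
            if r.biotype == "lncRNA" and tid in anti_partner and anti_partner[tid] in transcripts:
                # embed the reverse complement of a partner-mRNA window so
                # the duplex score flags the pair
                src = transcripts[anti_partner[tid]]
                start = int(rng.integers(0, len(src) - 60))
                ins = revcomp(src[start:start + 60])
                seq = seq[:100] + ins + seq[100 + 60:]
            seq = _orf_poor(seq, rng)
            if not r.known:
                while fickett_score(seq) >= 0.95 or orf_coverage(seq) >= 0.25:
                    seq = _orf_poor(_random_seq(rng, cfg.lnc_length), rng)
            transcripts[tid] = seq
        # 3'UTR for every sponge-capable transcript
        utr = _scrub_cores(_random_seq(rng, cfg.utr_length), all_cores, rng)
        placed: list[tuple[int, str]] = []
        for site in site_of.get(tid, []):
            while True:
                pos = int(rng.integers(0, len(utr) - len(site)))
                if any(pos < q + len(s) + 1 and q < pos + len(site) + 1
                       for q, s in placed):
                    continue  # keep planted sites non-overlapping
                cand = utr[:pos] + site + utr[pos + len(site):]
                wanted = {s for _, s in placed} | {site}
                stray = [c for c in all_cores if all(c not in s for s in wanted)]
                if all(c not in cand for c in stray) and \
                        all(s in cand for s in wanted):
                    utr = cand
                    placed.append((pos, site))
                    break
        utrs[tid] = utr
    return transcripts, utrs, mirnas


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class Dataset:
    records: list[TranscriptRecord]
    matrices: dict[str, CountMatrix]
    transcripts: dict[str, str]
    utrs: dict[str, str]
    mirnas: dict[str, str]
    truth: GroundTruth
    design: dict[str, str]
    gene_sets: dict | None = None


def synthetic_gene_sets(universe: list[str], planted: list[str], seed: int,
                        n_sets: int = 10, set_size: int = 30) -> dict[str, list[str]]:
    """Random same-size gene sets plus one set concentrated in the
    planted DE genes, so the enrichment stage has signal to find."""
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        sets[f"SET_RANDOM_{i:02d}"] = sorted(
            rng.choice(universe, size=min(set_size, len(universe)), replace=False))
    if planted:
        sets["SET_PLANTED_UP"] = sorted(
            rng.choice(planted, size=min(set_size, len(planted)), replace=False))
    return sets


def simulate_dataset(cfg: SimConfig | None = None, seed: int = 0) -> Dataset:
    """Generate annotation, counts and sequences in one deterministic call."""
    cfg = cfg or SimConfig()
    records, truth = generate_annotation(
        cfg.n_coding, cfg.n_lnc, cfg.n_mirna, cfg.n_circ, seed,
        cis_fraction=cfg.cis_fraction, antisense_fraction=cfg.antisense_fraction,
        novel_fraction=cfg.novel_fraction, gene_spacing_bp=cfg.gene_spacing_bp)
    plan = plant_structures(records, truth, cfg, seed + 1)
    matrices = generate_counts(records, truth, cfg, seed + 2, plan=plan)
    transcripts, utrs, mirnas = generate_sequences(records, truth, cfg, seed + 3)
    design = next(iter(matrices.values())).group_of if matrices else {}
    mrna_ids = sorted(r.transcript_id for r in records if r.biotype == "coding")
    # the planted set is directional (up-regulated members only): GSEA is
    # direction-sensitive, and a mixed-sign set self-cancels by design
    planted_up = sorted(t for t, e in truth.planted_de.get("mRNA", {}).items()
                        if e > 0)
    gene_sets = synthetic_gene_sets(mrna_ids, planted_up, seed + 7) \
        if mrna_ids else None
    return Dataset(records, matrices, transcripts, utrs, mirnas, truth,
                   dict(design), gene_sets)


def write_dataset(ds: Dataset, outdir: str | Path) -> None:
    """Write counts TSVs, GTF, FASTAs, known-id list, design and truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for layer, m in ds.matrices.items():
        write_counts(m, out / f"counts_{layer}.tsv")
    write_annotation(ds.records, out / "annotation.gtf")
    write_fasta(ds.transcripts, out / "transcripts.fa")
    write_fasta(ds.utrs, out / "utrs.fa")
    write_fasta(ds.mirnas, out / "mirnas.fa")
    novel = set(ds.truth.novel_lnc_ids)
    write_id_list([r.transcript_id for r in ds.records if r.transcript_id not in novel],
                  out / "known_ids.txt")
    (out / "ground_truth.json").write_text(ds.truth.to_json() + "\n")
    (out / "design.yaml").write_text(yaml.safe_dump(ds.design, sort_keys=True))
    if ds.gene_sets:
        from .enrichment import write_gmt
        write_gmt(ds.gene_sets, out / "gene_sets.gmt")
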