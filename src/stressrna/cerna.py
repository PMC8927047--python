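"""ceRNA network inference.

Sponges (mRNA, lncRNA, circRNA) compete for shared miRNAs. Binding is
predicted by canonical seed matching on 3'UTRs (site classes 6mer <
7mer-A1 < 7mer-m8 < 8mer); a (miRNA, sponge) pair must additionally be
strongly anti-correlated (Pearson r < -0.9 over pooled samples). A
sponge-sponge edge is emitted when the two share at least one surviving
miRNA, are positively co-expressed, and the shared-miRNA overlap is
significant under a hypergeometric tail test over the miRNA universe.
Node connectivity is the number of distinct shared miRNAs; nodes with
degree >= 5 are hubs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .simulate import revcomp
from .types import CeRNAEdge, CeRNANetwork

SITE_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
_CLASS_RANK = {c: i for i, c in enumerate(SITE_CLASSES)}


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    target_id: str
    site_class: str
    utr_position: int  # 1-based start of the site on the UTR


# ---------------------------------------------------------------------------
# seed matching


def find_seed_sites(mirna_seq: str, utr_seq: str, mirna_id: str = "",
                    target_id: str = "") -> list[SeedSite]:
    """All seed-complementary sites of a miRNA on a UTR.

    The 6mer core is the reverse complement of miRNA nt 2-7. A core
    match extends to 7mer-m8 when the UTR base 5' of the core pairs
    with miRNA nt 8, to 7mer-A1 when the base 3' of the core is an A
    (opposite miRNA nt 1), and to 8mer when both hold. Overlapping
    sites are all reported.
    """
    mirna = mirna_seq.upper().replace("U", "T")
    utr = utr_seq.upper().replace("U", "T")
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    core = revcomp(mirna[1:7])
    m8 = revcomp(mirna[7])  # complement of nt 8, sits 5' of the core
    sites: list[SeedSite] = []
    j = utr.find(core)
    while j >= 0:
        has_m8 = j >= 1 and utr[j - 1] == m8
        has_a1 = j + 6 < len(utr) and utr[j + 6] == "A"
        if has_m8 and has_a1:
            cls, start = "8mer", j - 1
        elif has_m8:
            cls, start = "7mer-m8", j - 1
        elif has_a1:
            cls, start = "7mer-A1", j
        else:
            cls, start = "6mer", j
        sites.append(SeedSite(mirna_id, target_id, cls, start + 1))
        j = utr.find(core, j + 1)
    return sites


def scan_all_sites(mirnas: dict[str, str], utrs: dict[str, str]) -> list[SeedSite]:
    """Seed sites of every miRNA on every UTR."""
    out: list[SeedSite] = []
    for mid, mseq in mirnas.items():
        for tid, useq in utrs.items():
            out.extend(find_seed_sites(mseq, useq, mid, tid))
    return out


def mirna_target_sets(sites: list[SeedSite], min_class: str = "7mer-m8"
                      ) -> dict[str, set[str]]:
    """Collapse sites to miRNA -> target-id sets, keeping targets with at
    least one site of class >= ``min_class``."""
    if min_class not in _CLASS_RANK:
        raise ValueError(f"unknown site class {min_class!r}")
    floor = _CLASS_RANK[min_class]
    out: dict[str, set[str]] = {}
    for s in sites:
        if _CLASS_RANK[s.site_class] >= floor:
            out.setdefault(s.mirna_id, set()).add(s.target_id)
    return out


# ---------------------------------------------------------------------------
# gates


def coexpression_gate(mirna_expr, target_expr, cut: float = -0.9
                      ) -> tuple[bool, float]:
    """Pass iff Pearson r is strictly below ``cut`` (default -0.9).

    Zero-variance input fails the gate with r = nan rather than
    propagating.
    """
    x = np.asarray(mirna_expr, dtype=float)
    y = np.asarray(target_expr, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return False, float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r < cut, r


def hypergeom_shared_test(targets_a: set, targets_b: set, universe_n: int) -> float:
    """P(X >= k) for the shared-miRNA overlap k = |a & b| under
    X ~ Hypergeometric(N = universe_n, K = |a|, n = |b|); symmetric."""
    K, n = len(targets_a), len(targets_b)
    k = len(set(targets_a) & set(targets_b))
    if universe_n < len(set(targets_a) | set(targets_b)):
        raise ValueError("universe smaller than the union of the two sets")
    if k > min(K, n):
        raise ValueError("overlap exceeds set sizes")
    return float(stats.hypergeom.sf(k - 1, universe_n, K, n))


# ---------------------------------------------------------------------------
# network


def build_network(target_sets: dict[str, set[str]], expression: pd.DataFrame,
                  type_of: dict[str, str], config: RunConfig | None = None,
                  universe_n: int | None = None) -> CeRNANetwork:
    """Assemble the ceRNA network.

    ``target_sets`` maps each (differential) miRNA to its predicted
    sponge targets; ``expression`` is pooled log2(CPM+1) indexed by id
    (miRNAs and sponges); ``type_of`` gives each sponge's node type
    (mRNA/lncRNA/circRNA). The miRNA universe for the hypergeometric
    test defaults to the number of miRNAs in ``target_sets``.
    """
    cfg = config or RunConfig()
    if universe_n is None:
        universe_n = len(target_sets)

    # per-sponge set of miRNAs surviving the anti-correlation gate
    mirnas_of: dict[str, set[str]] = {}
    for mid, targets in target_sets.items():
        if mid not in expression.index:
            continue
        mx = expression.loc[mid].to_numpy(dtype=float)
        for tid in targets:
            if tid not in expression.index:
                continue
            ok, _r = coexpression_gate(mx, expression.loc[tid].to_numpy(dtype=float),
                                       cut=cfg.cerna_corr_cut)
            if ok:
                mirnas_of.setdefault(tid, set()).add(mid)

    allowed = {("mRNA", "lncRNA"), ("mRNA", "circRNA")}
    if cfg.allow_lnc_circ_pairs:
        allowed.add(("lncRNA", "circRNA"))

    edges: list[CeRNAEdge] = []
    for a, b in combinations(sorted(mirnas_of), 2):
        ta, tb = type_of.get(a), type_of.get(b)
        if ta is None or tb is None:
            continue
        if (ta, tb) not in allowed and (tb, ta) not in allowed:
            continue
        if (ta, tb) not in allowed:  # canonical order: mRNA (or lncRNA) first
            a, b, ta, tb = b, a, tb, ta
        shared = mirnas_of[a] & mirnas_of[b]
        if not shared:
            continue
        r_ab = float(np.corrcoef(expression.loc[a].to_numpy(dtype=float),
                                 expression.loc[b].to_numpy(dtype=float))[0, 1])
        if not (r_ab > 0):
            continue
        p = hypergeom_shared_test(mirnas_of[a], mirnas_of[b], universe_n)
        if p >= cfg.cerna_p_cut:
            continue
        r_a = {m: float(np.corrcoef(expression.loc[m], expression.loc[a])[0, 1])
               for m in sorted(shared)}
        r_b = {m: float(np.corrcoef(expression.loc[m], expression.loc[b])[0, 1])
               for m in sorted(shared)}
        edges.append(CeRNAEdge(a, ta, b, tb, tuple(sorted(shared)), r_ab, p,
                               r_a, r_b))

    node_types: dict[str, str] = {}
    shared_by_node: dict[str, set[str]] = {}
    edge_degree: dict[str, int] = {}
    for e in edges:
        for node, t in ((e.node_a, e.type_a), (e.node_b, e.type_b)):
            node_types[node] = t
            shared_by_node.setdefault(node, set()).update(e.shared_mirnas)
            edge_degree[node] = edge_degree.get(node, 0) + 1
        for m in e.shared_mirnas:
            node_types[m] = "miRNA"
    degree = {n: len(s) for n, s in shared_by_node.items()}
    hubs = sorted(n for n, d in degree.items() if d >= cfg.hub_degree)
    return CeRNANetwork(edges, node_types, degree, edge_degree, hubs)


def specific_vs_common(network: CeRNANetwork) -> tuple[set[str], set[str]]:
    """Partition mRNA nodes by sponge-partner type.

    Returns (lncRNA-specific mRNAs, commonly regulated mRNAs): a gene
    with lncRNA partners only is specific; one with both lncRNA and
    circRNA partners is common.
    """
    partner_types: dict[str, set[str]] = {}
    for e in network.edges:
        for node, t, other_t in ((e.node_a, e.type_a, e.type_b),
                                 (e.node_b, e.type_b, e.type_a)):
            if t == "mRNA":
                partner_types.setdefault(node, set()).add(other_t)
    lnc_only = {g for g, ts in partner_types.items() if ts == {"lncRNA"}}
    common = {g for g, ts in partner_types.items() if {"lncRNA", "circRNA"} <= ts}
    return lnc_only, common
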