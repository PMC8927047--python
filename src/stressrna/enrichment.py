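"""Over-representation analysis and gene-set enrichment analysis.

ORA is the hypergeometric tail test of a query list against each gene
set, BH-adjusted across terms. GSEA is the weighted Kolmogorov-Smirnov
running-sum statistic: walking down the metric-ranked gene list, hits
increment proportionally to |metric|^p (normalised) and misses decrement
1/(N-K); ES is the maximum deviation from zero. The null is gene-set
label permutation (random same-size sets) — with three replicates per
group only ten phenotype permutations exist, far too few for an
empirical null. NES = ES / mean(|null ES| of the same sign); the
empirical p is one-tailed within the same-sign null pool and FDR is BH
across terms.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

P_FLOOR = 1e-300


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: term <tab> description <tab> member ids... (one set per line)."""
    sets: dict[str, list[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {ln[:60]!r}")
        members = list(dict.fromkeys(p for p in parts[2:] if p))
        sets[parts[0]] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, members in sets.items():
            fh.write("\t".join([term, term] + list(members)) + "\n")


# ---------------------------------------------------------------------------
# ORA


def ora(query_ids, universe_ids, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_ids`` in each set.

    p = P(X >= k), X ~ Hypergeom(N = |universe|, K = set size in
    universe, n = |query|); BH across terms. Query must be a subset of
    the universe.
    """
    universe = set(universe_ids)
    query = set(query_ids)
    offenders = sorted(query - universe)
    if offenders:
        raise ValueError(f"query ids outside the universe: {offenders[:10]}")
    N, n = len(universe), len(query)
    rows = []
    for term, members in gene_sets.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        k = len(in_universe & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N,
                     "gene_ratio": (k / n if n else 0.0), "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_adjust(df["p"].to_numpy())
    else:
        df["fdr"] = []
    return df.sort_values(["p", "term_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# GSEA


def rank_metric(de_table: pd.DataFrame) -> pd.Series:
    """Signed significance metric: sign(log2FC) * -log10(max(p, floor)),
    sorted for ranking with ties broken by id (lexicographic)."""
    m = np.sign(de_table["log2fc"].to_numpy()) * \
        -np.log10(np.maximum(de_table["p"].to_numpy(), P_FLOOR))
    s = pd.Series(m, index=de_table.index, name="metric")
    order = sorted(s.index, key=lambda i: (-s[i], i))
    return s.loc[order]


def _es_from_ranked(metric: np.ndarray, hit: np.ndarray, weight_p: float) -> float:
    """ES of one ordered hit pattern (max deviation of the running sum)."""
    n = metric.size
    k = int(hit.sum())
    if k == 0 or k == n:
        # degenerate: all (or no) genes in the set; a pure-hit walk
        # rises monotonically to 1
        return 1.0 if k else 0.0
    w = np.abs(metric) ** weight_p if weight_p > 0 else np.ones(n)
    hw = np.where(hit, w, 0.0)
    denom = hw.sum()
    if denom == 0:
        hw = hit.astype(float)
        denom = hw.sum()
    step = hw / denom - (~hit).astype(float) / (n - k)
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def gsea(ranked: pd.Series, gene_set, weight_p: float = 1.0,
         n_perm: int = 1000, seed: int = 0) -> dict:
    """Enrichment of ``gene_set`` in a ranked list (index = gene ids,
    values = metric, already sorted descending).

    Returns es, nes, p (empirical, same-sign null pool), n_hits.
    Deterministic under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    ids = list(ranked.index)
    metric = ranked.to_numpy(dtype=float)
    if not np.isfinite(metric).all():
        raise ValueError("ranking metric must be finite")
    members = set(gene_set) & set(ids)
    if not members:
        raise ValueError("gene set has no overlap with the ranked list")
    hit = np.fromiter((i in members for i in ids), dtype=bool, count=len(ids))
    es = _es_from_ranked(metric, hit, weight_p)

    rng = np.random.default_rng(seed)
    k = len(members)
    null = np.empty(n_perm)
    positions = np.arange(len(ids))
    for b in range(n_perm):
        perm_hit = np.zeros(len(ids), dtype=bool)
        perm_hit[rng.choice(positions, size=k, replace=False)] = True
        null[b] = _es_from_ranked(metric, perm_hit, weight_p)

    same = null[null >= 0] if es >= 0 else -null[null < 0]
    if same.size == 0:
        nes, p = float("nan"), 1.0 / (n_perm + 1)
    else:
        nes = abs(es) / same.mean() * (1.0 if es >= 0 else -1.0)
        p = (1 + int((same >= abs(es)).sum())) / (1 + same.size)
    return {"es": es, "nes": nes, "p": float(p), "n_hits": k}


def gsea_table(ranked: pd.Series, gene_sets: dict[str, list[str]],
               weight_p: float = 1.0, n_perm: int = 1000, seed: int = 0,
               min_overlap: int = 1) -> pd.DataFrame:
    """GSEA over a collection; BH FDR across terms on the empirical p."""
    rows = []
    for i, (term, members) in enumerate(sorted(gene_sets.items())):
        overlap = set(members) & set(ranked.index)
        if len(overlap) < min_overlap:
            continue
        res = gsea(ranked, members, weight_p=weight_p, n_perm=n_perm,
                   seed=seed + i)
        res["term_id"] = term
        res["direction"] = "up" if res["es"] >= 0 else "down"
        rows.append(res)
    df = pd.DataFrame(rows, columns=["term_id", "es", "nes", "p", "n_hits", "direction"])
    if len(df):
        df["fdr"] = bh_adjust(df["p"].to_numpy())
    else:
        df["fdr"] = []
    return df.sort_values(["p", "term_id"]).reset_index(drop=True)
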