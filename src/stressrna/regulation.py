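"""lncRNA target assignment: cis proximity, antisense duplex, trans co-expression.

Candidate (lncRNA, coding gene) pairs come from genomic structure —
cis: interval gap strictly below 100 kb on the same chromosome;
antisense: >=1 bp overlap on opposite strands; trans: every remaining
differential lncRNA x differential gene combination. Each candidate is
then gated on Pearson correlation of log2(CPM+1) across all samples
pooled (|r| > 0.9 and p < 0.05), and a pair qualifying under several
modes is reported once with priority antisense > cis > trans.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .config import RunConfig
from .types import RegulatoryPair, TranscriptRecord


# ---------------------------------------------------------------------------
# correlation


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p-value (df = n - 2).

    Returns (nan, nan) when either vector has zero variance — callers
    treat the pair as undefined and skip it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, _r_to_p(r, x.size)


def _r_to_p(r: float, n: int) -> float:
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlation_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-by-row Pearson r and p between two variable matrices.

    ``x`` (a x n) and ``y`` (b x n) hold one variable per row over the
    same n samples; returns (a x b) arrays. Zero-variance rows give nan.
    """
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc * xc).sum(axis=1))
    ys = np.sqrt((yc * yc).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc.T) / np.outer(xs, ys)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0
    return r, p


# ---------------------------------------------------------------------------
# structural candidates


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap in bp between two 1-based inclusive intervals (0 if overlapping)."""
    return max(0, max(start_a, start_b) - min(end_a, end_b) - 1)


def find_cis_candidates(records: list[TranscriptRecord], del_ids, dem_ids,
                        window_bp: int = 100_000) -> list[tuple[str, str, int]]:
    """All (DEL, DEM) pairs on one chromosome with gap strictly < window."""
    by_id = {r.transcript_id: r for r in records}
    out = []
    for lnc in del_ids:
        a = by_id.get(lnc)
        if a is None:
            continue
        for gene in dem_ids:
            b = by_id.get(gene)
            if b is None or b.chrom != a.chrom:
                continue
            gap = interval_gap(a.start, a.end, b.start, b.end)
            if gap < window_bp:
                out.append((lnc, gene, gap))
    return out


def find_antisense_candidates(records: list[TranscriptRecord], del_ids, dem_ids
                              ) -> list[tuple[str, str]]:
    """All (DEL, DEM) pairs overlapping >= 1 bp on opposite strands."""
    by_id = {r.transcript_id: r for r in records}
    out = []
    for lnc in del_ids:
        a = by_id.get(lnc)
        if a is None:
            continue
        for gene in dem_ids:
            b = by_id.get(gene)
            if b is None or b.chrom != a.chrom or b.strand == a.strand:
                continue
            if interval_gap(a.start, a.end, b.start, b.end) == 0 and \
                    max(a.start, b.start) <= min(a.end, b.end):
                out.append((lnc, gene))
    return out


# ---------------------------------------------------------------------------
# antisense duplex score

_PAIR_SCORE: dict[tuple[str, str], int] = {}
for _a, _b in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
    _PAIR_SCORE[(_a, _b)] = -2          # Watson-Crick
for _a, _b in (("G", "T"), ("T", "G")):
    _PAIR_SCORE[(_a, _b)] = -1          # G.U wobble (DNA alphabet)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_SCORE_MAT = np.full((4, 4), 3, dtype=float)  # mismatch +3
for (_a, _b), s in _PAIR_SCORE.items():
    _SCORE_MAT[_CODE[_a], _CODE[_b]] = s


def duplex_score(lnc_seq: str, mrna_seq: str, window: int = 40) -> float:
    """Best (minimum) ungapped antiparallel hybrid score over all
    window-length alignments: WC pair -2, G.U wobble -1, mismatch +3.

    A perfect window is -2*window; lower = more stable. This is a fast
    complementarity surrogate for minimum-free-energy duplex prediction.
    """
    if len(lnc_seq) < window or len(mrna_seq) < window:
        raise ValueError(
            f"sequences must be at least window={window} nt; "
            "use a smaller window for short transcripts")
    a = np.fromiter((_CODE[c] for c in lnc_seq.upper()), dtype=np.int64)
    b = np.fromiter((_CODE[c] for c in mrna_seq.upper()), dtype=np.int64)
    m = _SCORE_MAT[np.ix_(a, b)]
    # an antiparallel alignment pairs a[i+k] with b[j+w-1-k]: the cells
    # lie on one antidiagonal, so slide a length-w window along each
    best = np.inf
    flipped = m[:, ::-1]
    n1, n2 = flipped.shape
    w = window
    for d in range(-(n1 - w), n2 - w + 1):
        diag = np.diagonal(flipped, offset=d)
        if diag.size < w:
            continue
        c = np.concatenate(([0.0], np.cumsum(diag)))
        best = min(best, float(np.min(c[w:] - c[:-w])))
    return best


# ---------------------------------------------------------------------------
# assignment


def assign_targets(expression, del_ids, dem_ids,
                   cis_candidates, antisense_candidates,
                   config: RunConfig | None = None,
                   sequences: dict[str, str] | None = None,
                   ) -> list[RegulatoryPair]:
    """Gate all candidates on |r| > corr_cut and p < p_cut; emit each
    (lncRNA, gene) once with mode priority antisense > cis > trans.

    ``expression`` is a DataFrame of log2(CPM+1) indexed by transcript
    id over the pooled samples of both groups. Trans candidates are
    every DEL x DEM pair not already structural. When ``sequences`` are
    supplied, antisense pairs carry a duplex score, gated only if
    ``config.duplex_max`` is set.
    """
    cfg = config or RunConfig()
    del_ids = [t for t in del_ids if t in expression.index]
    dem_ids = [g for g in dem_ids if g in expression.index]
    if not del_ids or not dem_ids:
        return []
    li = {t: i for i, t in enumerate(del_ids)}
    gi = {g: i for i, g in enumerate(dem_ids)}
    r_mat, p_mat = correlation_matrix(
        expression.loc[del_ids].to_numpy(dtype=float),
        expression.loc[dem_ids].to_numpy(dtype=float))

    anti = {(l, g) for l, g in antisense_candidates}
    cis = {(l, g): d for l, g, d in cis_candidates}
    pairs: list[RegulatoryPair] = []
    for lnc in del_ids:
        for gene in dem_ids:
            r = r_mat[li[lnc], gi[gene]]
            p = p_mat[li[lnc], gi[gene]]
            if not np.isfinite(r) or abs(r) <= cfg.corr_cut or p >= cfg.p_cut:
                continue
            if (lnc, gene) in anti:
                mode, dist = "antisense", None
                score = None
                if sequences and lnc in sequences and gene in sequences:
                    w = min(40, len(sequences[lnc]), len(sequences[gene]))
                    score = duplex_score(sequences[lnc], sequences[gene], window=w)
                    if cfg.duplex_max is not None and score > cfg.duplex_max:
                        continue
                pairs.append(RegulatoryPair(lnc, gene, mode, float(r), float(p),
                                            duplex_score=score))
            elif (lnc, gene) in cis:
                pairs.append(RegulatoryPair(lnc, gene, "cis", float(r), float(p),
                                            distance_bp=cis[(lnc, gene)]))
            else:
                pairs.append(RegulatoryPair(lnc, gene, "trans", float(r), float(p)))
    return pairs
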