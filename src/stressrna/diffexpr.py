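"""Count filtering, TMM normalization, and exact-test differential expression.

The test is the classic two-group exact test for negative-binomial
counts: library sizes are pseudo-equalised to their geometric mean, each
gene's stress-group sum A is compared with its conditional distribution
given the overall sum T = A + B, where a sum of n iid NB(mean mu,
dispersion phi) variables is NB with size n/phi. The two-sided p-value
sums the probabilities of all outcomes no more likely than the observed
one. A common dispersion is estimated by maximising the within-group
conditional likelihood (which does not depend on the group means) unless
a value is supplied. As dispersion -> 0 the conditional law reduces to a
binomial split of the total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata
from sklearn.decomposition import PCA as _PCA
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .types import GROUPS, CountMatrix

# ---------------------------------------------------------------------------
# filtering


def filter_low_counts(matrix: CountMatrix, biotype_of: dict[str, str],
                      config: RunConfig | None = None) -> CountMatrix:
    """Drop transcripts whose group-wise mean raw count is below threshold
    (5 coding, 2 non-coding) in *both* groups; order is preserved."""
    cfg = config or RunConfig()
    thr = {}
    for t in matrix.transcript_ids:
        b = biotype_of.get(t)
        if b is None:
            raise ValueError(f"transcript {t!r} has no biotype")
        if b not in ("coding", "lncRNA", "miRNA", "circRNA"):
            raise ValueError(f"transcript {t!r}: unknown biotype {b!r}")
        thr[t] = cfg.filter_coding if b == "coding" else cfg.filter_noncoding
    thr_v = np.array([thr[t] for t in matrix.transcript_ids])
    means = np.column_stack(
        [matrix.counts[matrix.samples_in(g)].mean(axis=1).to_numpy() for g in GROUPS]
    )
    keep = (means >= thr_v[:, None]).any(axis=1)
    return CountMatrix(matrix.layer, matrix.counts.loc[keep], dict(matrix.group_of))


# ---------------------------------------------------------------------------
# normalization


def tmm_factors(matrix: CountMatrix | pd.DataFrame, logratio_trim: float = 0.30,
                abs_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference is the highest-depth sample. M (log2 ratio) and A
    (log2 abundance) values over genes positive in both samples are
    doubly trimmed (30% each tail of M, 5% each tail of A) and averaged
    with inverse asymptotic-variance weights; factors are rescaled to
    geometric mean 1.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    y = counts.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    lib = y.sum(axis=0)
    if np.any(lib == 0):
        bad = counts.columns[lib == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    ref = int(np.argmax(lib))
    yr, nr = y[:, ref], lib[ref]
    factors = np.ones(y.shape[1])
    for s in range(y.shape[1]):
        if s == ref:
            continue
        ys, ns = y[:, s], lib[s]
        ok = (ys > 0) & (yr > 0)
        if not ok.any():
            continue
        ps, pr = ys[ok] / ns, yr[ok] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        # delta-method variance of M (floored: a gene spanning a whole
        # library would otherwise get infinite weight)
        v = (ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        v = np.maximum(v, 1e-12)
        n = m.size
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_trim) + 1
        hi_a = n + 1 - lo_a
        rm, ra = rankdata(m), rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.any():
            f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
            if np.isfinite(f):
                factors[s] = 2.0 ** f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm")


def effective_lib_sizes(matrix: CountMatrix) -> pd.Series:
    """Raw depth x TMM factor per sample."""
    lib = matrix.counts.sum(axis=0)
    return lib * tmm_factors(matrix)


def cpm(matrix: CountMatrix, eff_lib: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million using effective (TMM-scaled) library sizes."""
    lib = effective_lib_sizes(matrix) if eff_lib is None else eff_lib
    return matrix.counts.div(lib, axis=1) * 1e6


def log_cpm(matrix: CountMatrix, eff_lib: pd.Series | None = None) -> pd.DataFrame:
    """log2(CPM + 1), the expression scale used for correlations and PCA."""
    return np.log2(cpm(matrix, eff_lib) + 1.0)


# ---------------------------------------------------------------------------
# exact test


def _pseudo_counts(matrix: CountMatrix, eff_lib: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Counts scaled to the geometric-mean effective library, split by group."""
    lib = eff_lib.to_numpy(dtype=float)
    geo = np.exp(np.mean(np.log(lib)))
    pseudo = matrix.counts.to_numpy(dtype=float) * (geo / lib)
    cols = list(matrix.counts.columns)
    idx = {g: [cols.index(s) for s in matrix.samples_in(g)] for g in GROUPS}
    return pseudo[:, idx["stress"]], pseudo[:, idx["control"]]


def estimate_common_dispersion(matrix: CountMatrix, eff_lib: pd.Series | None = None) -> float:
    """Common NB dispersion by maximum within-group conditional likelihood.

    For iid NB counts the distribution of a group's counts given their
    sum is free of the mean; summing that log-likelihood over genes and
    both groups yields a one-parameter profile maximised numerically.
    """
    if eff_lib is None:
        eff_lib = effective_lib_sizes(matrix)
    ps, pc = _pseudo_counts(matrix, eff_lib)
    groups = [np.round(ps), np.round(pc)]

    def neg_cll(log_phi: float) -> float:
        phi = np.exp(log_phi)
        r = 1.0 / phi
        total = 0.0
        for y in groups:
            n = y.shape[1]
            z = y.sum(axis=1)
            ll = (
                gammaln(y + r).sum(axis=1)
                - n * gammaln(r)
                - gammaln(z + n * r)
                + gammaln(n * r)
            )
            total += ll.sum()
        return -total

    res = minimize_scalar(neg_cll, bounds=(np.log(1e-6), np.log(10.0)), method="bounded")
    return float(np.exp(res.x))


def _exact_p(a: int, t: int, n1: int, n2: int, dispersion: float) -> float:
    """Two-sided conditional exact p for group-A sum ``a`` of total ``t``."""
    if t == 0:
        return 1.0
    x = np.arange(t + 1)
    if dispersion < 1e-8:
        # Poisson limit: binomial split of the total
        logw = (
            gammaln(t + 1) - gammaln(x + 1) - gammaln(t - x + 1)
            + x * np.log(n1 / (n1 + n2)) + (t - x) * np.log(n2 / (n1 + n2))
        )
    else:
        r1, r2 = n1 / dispersion, n2 / dispersion
        logw = (
            gammaln(x + r1) - gammaln(x + 1)
            + gammaln(t - x + r2) - gammaln(t - x + 1)
        )
    logp = logw - logsumexp(logw)
    mask = logp <= logp[a] + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def nb_exact_test(matrix: CountMatrix, dispersion: float | None = None,
                  eff_lib: pd.Series | None = None,
                  pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-transcript (log2fc, p) from the conditional NB exact test.

    ``log2fc`` is log2 of stress/control mean CPM with a pseudocount
    equivalent to ``pseudocount`` raw counts at the mean effective
    library size; an all-zero transcript gets log2fc 0 and p 1.
    """
    if dispersion is not None and dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if eff_lib is None:
        eff_lib = effective_lib_sizes(matrix)
    if dispersion is None:
        dispersion = estimate_common_dispersion(matrix, eff_lib)
    ps, pc = _pseudo_counts(matrix, eff_lib)
    n1, n2 = ps.shape[1], pc.shape[1]
    a = np.round(ps.sum(axis=1)).astype(int)
    b = np.round(pc.sum(axis=1)).astype(int)
    t = a + b
    pvals = np.array([_exact_p(ai, ti, n1, n2, dispersion) for ai, ti in zip(a, t)])

    cpm_df = cpm(matrix, eff_lib)
    m_s = cpm_df[matrix.samples_in("stress")].mean(axis=1).to_numpy()
    m_c = cpm_df[matrix.samples_in("control")].mean(axis=1).to_numpy()
    prior = pseudocount / float(eff_lib.mean()) * 1e6
    log2fc = np.log2((m_s + prior) / (m_c + prior))
    return pd.DataFrame(
        {
            "transcript_id": matrix.transcript_ids,
            "mean_cpm_stress": m_s,
            "mean_cpm_control": m_c,
            "log2fc": log2fc,
            "p": pvals,
            "dispersion": dispersion,
        }
    ).set_index("transcript_id")


# ---------------------------------------------------------------------------
# multiple testing and calling


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(table: pd.DataFrame, layer: str, config: RunConfig | None = None) -> pd.Series:
    """Assign up/down/ns per transcript.

    mRNA and lncRNA require FDR < 0.05; miRNA and circRNA use the raw
    p < 0.05 rule. All layers require strictly |log2FC| > 1; the sign of
    log2FC sets the direction.
    """
    cfg = config or RunConfig()
    crit = table["fdr"] < cfg.fdr_cut if layer in ("mRNA", "lncRNA") else table["p"] < cfg.p_cut
    sig = crit & (table["log2fc"].abs() > cfg.lfc_cut)
    status = np.where(~sig, "ns", np.where(table["log2fc"] > 0, "up", "down"))
    return pd.Series(status, index=table.index, name="status")


def run_de(matrix: CountMatrix, config: RunConfig | None = None,
           dispersion: float | None = None) -> pd.DataFrame:
    """Full DE table for one layer: exact test + BH + status."""
    cfg = config or RunConfig()
    table = nb_exact_test(matrix, dispersion=dispersion, pseudocount=cfg.pseudocount)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["layer"] = matrix.layer
    table["status"] = call_de(table, matrix.layer, cfg)
    return table


# ---------------------------------------------------------------------------
# PCA


def pca(matrix: CountMatrix, n_components: int = 2):
    """Sample-level PCA on log2(CPM+1), genes centred.

    Returns (coordinates DataFrame samples x PCs, explained variance
    ratio array). Deterministic up to component sign.
    """
    x = log_cpm(matrix).to_numpy().T  # samples x genes
    k = min(n_components, x.shape[0], x.shape[1])
    model = _PCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(coords, index=matrix.sample_ids, columns=cols),
        model.explained_variance_ratio_,
    )
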