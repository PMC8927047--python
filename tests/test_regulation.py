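import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stressrna.config import RunConfig
from stressrna.regulation import (assign_targets, duplex_score,
                                  find_antisense_candidates,
                                  find_cis_candidates, interval_gap,
                                  pearson_with_p)
from stressrna.simulate import revcomp
from stressrna.types import TranscriptRecord


def rec(tid, start, end, strand="+", biotype="lncRNA", chrom="chr1"):
    return TranscriptRecord(tid, f"G_{tid}", biotype, chrom, start, end, strand)


# ---------------------------------------------------------------------------
# Pearson


def test_pearson_exact_linearity():
    x = np.arange(6.0)
    r, p = pearson_with_p(x, 2 * x + 1)
    assert r == pytest.approx(1.0) and p == 0.0
    r, p = pearson_with_p(x, -x)
    assert r == pytest.approx(-1.0) and p == 0.0


def test_pearson_p_matches_t_distribution_oracle():
    """n=6, r=0.9: t = 0.9*sqrt(4/0.19) with 4 df, two-sided p ~ 0.0374."""
    # build a length-6 vector pair with sample r exactly 0.9:
    # y = 0.9*u + sqrt(1-0.81)*v with u || centred x, v orthogonal to u and 1
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    xc = x - x.mean()
    u = xc / np.linalg.norm(xc)
    v = np.array([1.0, -1.0, 0.0, 0.0, 1.0, -1.0])
    v = v - v @ u * u
    v -= v.mean()
    v /= np.linalg.norm(v)
    y = 0.9 * u + np.sqrt(1 - 0.81) * v
    r, p = pearson_with_p(x, y)
    assert r == pytest.approx(0.9, abs=1e-12)
    t = 0.9 * np.sqrt((6 - 2) / (1 - 0.81))
    assert p == pytest.approx(2 * stats.t.sf(t, df=4), abs=1e-12)
    assert p == pytest.approx(0.0145, abs=5e-4)
    # at n=5 (df 3) the same statistic gives the familiar ~0.0374
    t5 = 0.9 * np.sqrt((5 - 2) / (1 - 0.81))
    assert 2 * stats.t.sf(t5, df=3) == pytest.approx(0.0374, abs=5e-4)


def test_pearson_zero_variance_flagged_not_propagated():
    r, p = pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])
    assert np.isnan(r) and np.isnan(p)


# ---------------------------------------------------------------------------
# interval arithmetic


def test_cis_distance_hand_example():
    recs = [rec("L", 1_000, 2_000), rec("G", 90_000, 95_000, biotype="coding")]
    out = find_cis_candidates(recs, ["L"], ["G"])
    assert out == [("L", "G", 87_999)]


@pytest.mark.parametrize("gene_start,expected", [
    (102_000, True),    # gap 99,999 < 100,000
    (102_001, False),   # gap exactly 100,000: strict less-than
])
def test_cis_window_boundary(gene_start, expected):
    recs = [rec("L", 1_000, 2_000),
            rec("G", gene_start, gene_start + 1_000, biotype="coding")]
    out = find_cis_candidates(recs, ["L"], ["G"])
    assert bool(out) is expected


def test_overlap_counts_as_distance_zero():
    recs = [rec("L", 1_000, 2_000), rec("G", 1_500, 2_500, biotype="coding")]
    assert find_cis_candidates(recs, ["L"], ["G"]) == [("L", "G", 0)]


def test_cis_window_monotone(small_dataset):
    recs = small_dataset.records
    dels = [r.transcript_id for r in recs if r.biotype == "lncRNA"]
    dems = [r.transcript_id for r in recs if r.biotype == "coding"]
    wide = {(l, g) for l, g, _ in find_cis_candidates(recs, dels, dems, 100_000)}
    narrow = {(l, g) for l, g, _ in find_cis_candidates(recs, dels, dems, 10_000)}
    assert narrow <= wide


@settings(derandomize=True, max_examples=200)
@given(st.integers(1, 300), st.integers(1, 300), st.integers(1, 300), st.integers(1, 300))
def test_interval_gap_matches_per_bp_scan(s1, l1, s2, l2):
    e1, e2 = s1 + l1 - 1, s2 + l2 - 1
    bp1 = set(range(s1, e1 + 1))
    bp2 = set(range(s2, e2 + 1))
    if bp1 & bp2:
        expected = 0
    else:
        expected = min(abs(b - a) for a in (s1, e1) for b in (s2, e2)) - 1
    assert interval_gap(s1, e1, s2, e2) == expected


@pytest.mark.parametrize("lnc,gene,expected", [
    ((100, 500, "-"), (300, 900, "+"), True),    # overlap, opposite strands
    ((100, 500, "+"), (300, 900, "+"), False),   # same strand
    ((100, 500, "-"), (600, 900, "+"), False),   # disjoint
])
def test_antisense_candidates(lnc, gene, expected):
    recs = [rec("L", lnc[0], lnc[1], lnc[2]),
            rec("G", gene[0], gene[1], gene[2], biotype="coding")]
    out = find_antisense_candidates(recs, ["L"], ["G"])
    assert bool(out) is expected


# ---------------------------------------------------------------------------
# duplex score


def brute_force_duplex(a, b, w):
    score = {("A", "T"): -2, ("T", "A"): -2, ("G", "C"): -2, ("C", "G"): -2,
             ("G", "T"): -1, ("T", "G"): -1}
    best = np.inf
    for i in range(len(a) - w + 1):
        for j in range(len(b) - w + 1):
            s = sum(score.get((a[i + k], b[j + w - 1 - k]), 3) for k in range(w))
            best = min(best, s)
    return best


def test_duplex_perfect_reverse_complement_scores_minus_80():
    rng = np.random.default_rng(5)
    mrna = "".join(rng.choice(list("ACGT"), size=120))
    lnc = "".join(rng.choice(list("ACGT"), size=40)) + revcomp(mrna[30:70]) \
        + "".join(rng.choice(list("ACGT"), size=40))
    assert duplex_score(lnc, mrna, window=40) == -80.0


def test_duplex_matches_brute_force_scan():
    rng = np.random.default_rng(6)
    for _ in range(5):
        a = "".join(rng.choice(list("ACGT"), size=55))
        b = "".join(rng.choice(list("ACGT"), size=48))
        assert duplex_score(a, b, window=20) == brute_force_duplex(a, b, 20)


def test_duplex_random_sequences_rarely_perfect():
    rng = np.random.default_rng(7)
    scores = []
    for _ in range(100):
        a = "".join(rng.choice(list("ACGT"), size=200))
        b = "".join(rng.choice(list("ACGT"), size=200))
        scores.append(duplex_score(a, b, window=40))
    assert min(scores) > -80.0


def test_duplex_symmetry_and_window_error():
    rng = np.random.default_rng(8)
    a = "".join(rng.choice(list("ACGT"), size=60))
    b = "".join(rng.choice(list("ACGT"), size=60))
    assert duplex_score(a, b) == duplex_score(b, a)
    with pytest.raises(ValueError, match="window"):
        duplex_score("ACGT", b, window=40)


# ---------------------------------------------------------------------------
# target assignment


def _expr(rows):
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"s{i}" for i in range(6)])


def test_assign_targets_correlation_gates():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    noise = np.array([0.3, -0.2, 0.1, -0.1, 0.2, -0.3])
    expr = _expr({"L": x, "G_strong": x + 0.05 * noise, "G_weak": x + 8.0 * noise})
    pairs = assign_targets(expr, ["L"], ["G_strong", "G_weak"], [], [])
    emitted = {p.target_gene_id for p in pairs}
    assert "G_strong" in emitted          # r ~ 1, p << 0.05
    assert "G_weak" not in emitted        # r below the 0.9 gate


def test_assign_targets_mode_priority_antisense_over_cis():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    expr = _expr({"L": x, "G": 2 * x})
    pairs = assign_targets(expr, ["L"], ["G"],
                           cis_candidates=[("L", "G", 0)],
                           antisense_candidates=[("L", "G")])
    assert len(pairs) == 1 and pairs[0].mode == "antisense"


def test_assign_targets_trans_is_default_mode():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    expr = _expr({"L": x, "G": -x})
    pairs = assign_targets(expr, ["L"], ["G"], [], [])
    assert len(pairs) == 1 and pairs[0].mode == "trans" and pairs[0].r < -0.9


def test_emitted_pairs_respect_structural_predicates(small_dataset):
    """Every emitted cis/antisense pair re-validates against the GTF."""
    from stressrna import diffexpr
    from stressrna.pipeline import run_all
    import tempfile
    ds = small_dataset
    out = tempfile.mkdtemp()
    run_all(RunConfig(), outdir=out, dataset=ds, seed=7)
    rp = pd.read_csv(f"{out}/regulatory_pairs.tsv", sep="\t")
    by_id = {r.transcript_id: r for r in ds.records}
    for row in rp.itertuples():
        a, b = by_id[row.lnc_id], by_id[row.target_gene_id]
        gap = interval_gap(a.start, a.end, b.start, b.end)
        assert abs(row.r) > 0.9 and row.p < 0.05
        if row.mode == "cis":
            assert gap < 100_000 and gap == row.distance_bp
        elif row.mode == "antisense":
            assert gap == 0 and a.strand != b.strand
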