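import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stressrna.config import RunConfig
from stressrna.diffexpr import (bh_adjust, call_de, estimate_common_dispersion,
                                filter_low_counts, log_cpm, nb_exact_test, pca,
                                run_de, tmm_factors)
from stressrna.types import CountMatrix

from conftest import make_matrix

# ---------------------------------------------------------------------------
# filtering


@pytest.mark.parametrize(
    "biotype,stress,control,kept",
    [
        ("coding", [4, 5, 5], [5, 5, 4], False),   # means (4.67, 4.67): below 5 in both
        ("coding", [5, 5, 5], [0, 0, 0], True),    # meets 5 in one group
        ("lncRNA", [2, 2, 2], [1, 1, 1], True),    # non-coding threshold 2
        ("lncRNA", [1, 2, 2], [1, 1, 1], False),   # below 2 in both
    ],
)
def test_filter_group_mean_rule(biotype, stress, control, kept):
    m = make_matrix(np.array([stress + control]),
                    layer="mRNA" if biotype == "coding" else "lncRNA")
    out = filter_low_counts(m, {"g0": biotype})
    assert (len(out.transcript_ids) == 1) is kept


def test_filter_boundary_and_unknown_biotype():
    # g0 group means (4.67, 4.67): below 5 in both -> removed;
    # g1 means (5.0, 0.0): meets the threshold in one group -> retained
    m = make_matrix(np.array([[4, 5, 5, 5, 5, 4], [5, 5, 5, 0, 0, 0]]))
    m2 = filter_low_counts(m, {"g0": "coding", "g1": "coding"})
    assert m2.transcript_ids == ["g1"]
    with pytest.raises(ValueError, match="biotype"):
        filter_low_counts(m, {"g0": "coding", "g1": "protein"})


def test_filter_never_grows_and_preserves_order(small_dataset):
    m = small_dataset.matrices["mRNA"]
    out = filter_low_counts(m, {t: "coding" for t in m.transcript_ids})
    assert set(out.transcript_ids) <= set(m.transcript_ids)
    pos = {t: i for i, t in enumerate(m.transcript_ids)}
    assert [pos[t] for t in out.transcript_ids] == sorted(pos[t] for t in out.transcript_ids)


# ---------------------------------------------------------------------------
# TMM


def _tmm_fixture() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    mu = 2.0 ** rng.normal(5, 1.5, size=200)
    lib_scale = np.array([1.0, 2.0, 0.7, 1.3])
    counts = rng.poisson(mu[:, None] * lib_scale[None, :])
    counts[:10, 3] *= 8  # composition bias in s4
    return pd.DataFrame(counts, index=[f"g{i:03d}" for i in range(200)],
                        columns=["s1", "s2", "s3", "s4"])


def test_tmm_matches_reference_implementation():
    """Factors on a seeded 200-gene fixture, frozen from edgeR
    calcNormFactors(method='TMM', refColumn=highest depth)."""
    expected = [1.0435877985, 1.0568520458, 1.0497890183, 0.8636838314]
    got = tmm_factors(_tmm_fixture())
    assert np.allclose(got.to_numpy(), expected, atol=1e-9)


def test_tmm_identical_columns_give_unit_factors():
    col = np.arange(1, 101)
    m = make_matrix(np.column_stack([col] * 4))
    assert np.allclose(tmm_factors(m).to_numpy(), 1.0)


def test_tmm_depth_only_difference_keeps_factors_near_one():
    rng = np.random.default_rng(0)
    base = rng.poisson(2.0 ** rng.normal(6, 1, size=300))
    counts = np.column_stack([base, 2 * base, base, base])
    f = tmm_factors(make_matrix(counts))
    # depth is handled by library size; composition factors stay ~1
    assert np.allclose(f.to_numpy(), 1.0, atol=0.01)
    assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)


def test_tmm_rejects_all_zero_sample():
    counts = np.array([[1, 0], [2, 0], [3, 0], [4, 0]])
    with pytest.raises(ValueError, match="all-zero"):
        tmm_factors(pd.DataFrame(counts, columns=["a", "b"]))


# ---------------------------------------------------------------------------
# exact test


def test_balanced_equal_counts_give_p_one():
    m = make_matrix(np.array([[7, 7, 7, 7, 7, 7], [3, 4, 5, 5, 4, 3]]))
    tab = nb_exact_test(m, dispersion=0.1)
    assert np.allclose(tab["p"], 1.0)
    assert np.allclose(tab["log2fc"].iloc[0], 0.0, atol=1e-9)


def test_zero_dispersion_reduces_to_binomial_split():
    """dispersion -> 0, equal libraries, counts 10 vs 0: the conditional
    law is Binomial(10, 1/2); two-sided p doubles the extreme tail."""
    counts = np.zeros((40, 6), dtype=int)
    counts[:, :] = 5  # equalise libraries
    counts[0, :3] = [4, 3, 3]  # gene 0: 10 in stress, 0 in control
    counts[0, 3:] = 0
    m = make_matrix(counts)
    tab = nb_exact_test(m, dispersion=0.0)
    expected = 2 * stats.binom.pmf(0, 10, 0.5)  # both extremes equally likely
    assert np.isclose(tab["p"].iloc[0], expected, rtol=1e-6)


def test_all_zero_transcript_degenerates_cleanly():
    counts = np.array([[0, 0, 0, 0, 0, 0], [5, 6, 7, 5, 6, 7]])
    tab = nb_exact_test(make_matrix(counts), dispersion=0.1)
    assert tab["p"].iloc[0] == 1.0 and tab["log2fc"].iloc[0] == 0.0


def test_negative_dispersion_rejected(toy_matrix):
    with pytest.raises(ValueError, match="dispersion"):
        nb_exact_test(toy_matrix, dispersion=-0.1)


def test_common_dispersion_estimate_close_to_truth():
    rng = np.random.default_rng(3)
    phi = 0.1
    mu = 2.0 ** rng.normal(7, 1, size=800)
    counts = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu[:, None]),
                                   size=(800, 6))
    est = estimate_common_dispersion(make_matrix(counts))
    assert 0.07 < est < 0.14


# ---------------------------------------------------------------------------
# BH


def brute_force_bh(p):
    """Step-up BH straight from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_hand_example():
    out = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, [0.04, 0.04, 0.04, 0.04], atol=1e-12)


def test_bh_degenerate_inputs():
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                min_size=1, max_size=50))
def test_bh_matches_brute_force(pvals):
    assert np.allclose(bh_adjust(pvals), brute_force_bh(pvals), atol=1e-12)


# ---------------------------------------------------------------------------
# DE calling


@pytest.mark.parametrize(
    "layer,log2fc,p,fdr,expected",
    [
        ("mRNA", 1.2, 0.001, 0.04, "up"),
        ("mRNA", 1.0, 1e-6, 0.001, "ns"),     # strict |log2FC| > 1
        ("mRNA", 1.2, 0.01, 0.06, "ns"),      # FDR rule for mRNA
        ("lncRNA", -1.3, 0.01, 0.03, "down"),
        ("circRNA", -1.5, 0.03, 0.2, "down"),  # p rule, not FDR, for circRNA
        ("miRNA", 1.5, 0.06, 0.04, "ns"),      # p rule for miRNA
    ],
)
def test_call_de_layer_rules(layer, log2fc, p, fdr, expected):
    table = pd.DataFrame({"log2fc": [log2fc], "p": [p], "fdr": [fdr]},
                         index=["t"])
    assert call_de(table, layer).iloc[0] == expected


def test_run_de_fdr_monotone_in_p(small_dataset):
    tab = run_de(small_dataset.matrices["circRNA"])
    s = tab.sort_values("p")
    assert (np.diff(s["fdr"].to_numpy()) >= -1e-12).all()
    assert ((tab["fdr"] >= 0) & (tab["fdr"] <= 1)).all()
    up = tab[tab["status"] == "up"]
    dn = tab[tab["status"] == "down"]
    assert (up["log2fc"] > 0).all() and (dn["log2fc"] < 0).all()


# ---------------------------------------------------------------------------
# PCA


def test_pca_identical_samples_coincide():
    a = np.arange(1, 41)
    b = np.concatenate([a[20:], a[:20]])  # distinct profile, same depth
    m = make_matrix(np.column_stack([a, a, b, b]))
    coords, ratio = pca(m)
    assert np.allclose(coords.loc["s0"], coords.loc["s1"], atol=1e-8)
    assert (np.diff(ratio) <= 1e-12).all() and ratio.sum() <= 1 + 1e-9


def test_pca_separates_groups_with_strong_effect():
    from sklearn.metrics import silhouette_score
    rng = np.random.default_rng(4)
    mu = 2.0 ** rng.normal(6, 1, size=(500, 1)) * np.ones((1, 6))
    eff = np.ones((500, 6))
    de = rng.choice(500, size=100, replace=False)
    eff[de, :3] = 16.0  # planted effect 4 on 20% of genes
    counts = rng.poisson(mu * eff)
    m = make_matrix(counts)
    coords, _ = pca(m)
    labels = [m.group_of[s] for s in coords.index]
    assert silhouette_score(coords.to_numpy()[:, :1], labels) > 0
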