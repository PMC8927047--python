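from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from stressrna.cerna import (build_network, coexpression_gate, find_seed_sites,
                             hypergeom_shared_test, mirna_target_sets,
                             scan_all_sites, specific_vs_common)
from stressrna.config import RunConfig
from stressrna.simulate import revcomp
from stressrna.types import CeRNAEdge, CeRNANetwork

# ---------------------------------------------------------------------------
# seed matching

LET7A = "UGAGGUAGUAGGUUGUAUAGUU"  # nt 2-8 = GAGGUAG


def test_let7a_8mer_site():
    utr = "GGGG" + "CTACCTCA" + "GGGG"
    sites = find_seed_sites(LET7A, utr)
    assert len(sites) == 1
    s = sites[0]
    assert s.site_class == "8mer" and s.utr_position == 5


def test_site_class_hierarchy():
    core = revcomp(LET7A.replace("U", "T")[1:7])   # 6mer core on the UTR
    m8 = revcomp(LET7A.replace("U", "T")[7])
    assert [find_seed_sites(LET7A, u)[0].site_class for u in (
        "GG" + m8 + core + "A" + "GG",   # m8 match + A1 -> 8mer
        "GG" + m8 + core + "G" + "GG",   # m8 match only -> 7mer-m8
        "GG" + "G" + core + "A" + "GG",  # A1 only -> 7mer-A1
        "GG" + "G" + core + "G" + "GG",  # core only -> 6mer
    )] == ["8mer", "7mer-m8", "7mer-A1", "6mer"]


def test_no_core_match_gives_empty_list():
    assert find_seed_sites(LET7A, "A" * 50) == []


def test_tandem_sites_reported_at_distinct_positions():
    site = "CTACCTCA"
    sites = find_seed_sites(LET7A, site + site)
    assert len(sites) == 2
    assert sites[0].utr_position != sites[1].utr_position


def test_short_mirna_rejected():
    with pytest.raises(ValueError, match="8 nt"):
        find_seed_sites("ACGTACG", "ACGTACGTACGT")


def test_target_sets_respect_min_class():
    sites = find_seed_sites(LET7A, "GGG" + revcomp(LET7A.replace("U", "T")[1:7]) + "GGGG",
                            mirna_id="m", target_id="t")  # 6mer only
    assert mirna_target_sets(sites) == {}                 # default floor 7mer-m8
    assert mirna_target_sets(sites, min_class="6mer") == {"m": {"t"}}
    assert mirna_target_sets([]) == {}


# ---------------------------------------------------------------------------
# gates


@pytest.mark.parametrize("r_scale,expected", [(-1.0, True), (1.0, False)])
def test_coexpression_gate_sign(r_scale, expected):
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    ok, r = coexpression_gate(x, r_scale * x)
    assert ok is expected


def test_coexpression_gate_strict_boundary():
    # construct y with sample r exactly -0.9: must fail the strict gate
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    xc = x - x.mean()
    u = xc / np.linalg.norm(xc)
    v = np.array([1.0, -1.0, 0.0, 0.0, 1.0, -1.0])
    v = v - v @ u * u
    v -= v.mean()
    v /= np.linalg.norm(v)
    target = -0.9 + 1e-9  # one hair above the cut: must fail the strict gate
    y = target * u + np.sqrt(1 - target**2) * v
    ok, r = coexpression_gate(x, y)
    assert r == pytest.approx(-0.9, abs=1e-6) and not ok
    ok, _ = coexpression_gate(x, -0.95 * u + np.sqrt(1 - 0.9025) * v)
    assert ok


def test_coexpression_gate_zero_variance_fails_cleanly():
    ok, r = coexpression_gate([1, 1, 1, 1, 1, 1], [1, 2, 3, 4, 5, 6])
    assert not ok and np.isnan(r)


# ---------------------------------------------------------------------------
# hypergeometric shared-miRNA test


def enumerate_tail(N, K, n, k):
    """Brute force: enumerate all C(N, n) draws of the second set."""
    universe = list(range(N))
    first = set(range(K))
    total = hits = 0
    for draw in combinations(universe, n):
        total += 1
        if len(first & set(draw)) >= k:
            hits += 1
    return hits / total


def test_hypergeom_example_and_enumeration():
    a = {f"m{i}" for i in range(3)}
    b = {f"m{i}" for i in range(3)} | {"m9"}
    p = hypergeom_shared_test(a, b, universe_n=10)
    assert p == pytest.approx(7 / 210, abs=1e-12)  # C(3,3)*C(7,1)/C(10,4)
    assert p == pytest.approx(enumerate_tail(10, 3, 4, 3), abs=1e-12)


def test_hypergeom_matches_enumeration_exhaustively():
    rng = np.random.default_rng(0)
    for _ in range(25):
        N = int(rng.integers(4, 13))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        a = {f"m{i}" for i in range(K)}
        idx = rng.choice(N, size=n, replace=False)
        b = {f"m{i}" for i in idx}
        k = len(a & b)
        assert hypergeom_shared_test(a, b, N) == pytest.approx(
            enumerate_tail(N, K, n, k), abs=1e-12)
        assert hypergeom_shared_test(b, a, N) == pytest.approx(
            hypergeom_shared_test(a, b, N), abs=1e-12)


def test_hypergeom_degenerate_cases():
    assert hypergeom_shared_test({"a"}, {"b"}, 10) == pytest.approx(1.0)  # k=0
    full = {f"m{i}" for i in range(6)}
    assert hypergeom_shared_test(full, {"m0", "m1"}, 6) == pytest.approx(1.0)  # K=N
    with pytest.raises(ValueError, match="universe"):
        hypergeom_shared_test({"a", "b"}, {"c"}, 2)


# ---------------------------------------------------------------------------
# network


def _expr(rows):
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"s{i}" for i in range(6)])


def _toy_network(n_shared=2, universe=20):
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    rows = {"A": x, "B": x + 0.01}
    target_sets = {}
    for i in range(n_shared):
        rows[f"m{i}"] = -x + 0.01 * i
        target_sets[f"m{i}"] = {"A", "B"}
    expr = _expr(rows)
    types = {"A": "mRNA", "B": "lncRNA"}
    return build_network(target_sets, expr, types, universe_n=universe)


def test_network_edge_from_shared_anticonnected_mirnas():
    net = _toy_network()
    assert len(net.edges) == 1
    e = net.edges[0]
    assert set(e.shared_mirnas) == {"m0", "m1"}
    assert e.r_ab > 0 and e.hyper_p < 0.05
    assert all(r < -0.9 for r in e.mirna_r_a.values())
    assert net.degree_of == {"A": 2, "B": 2}


def test_hub_called_at_degree_five():
    net = _toy_network(n_shared=5, universe=40)
    assert net.degree_of["A"] == 5
    assert set(net.hubs) == {"A", "B"}
    net4 = _toy_network(n_shared=4, universe=40)
    assert net4.hubs == []  # boundary: degree 4 is not a hub


def test_empty_network_composition_is_empty():
    net = build_network({}, _expr({"A": np.arange(6.0)}), {"A": "mRNA"})
    assert net.edges == [] and net.composition() == {}


def test_mrna_mrna_pairs_excluded():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    expr = _expr({"A": x, "B": x + 0.01, "m0": -x, "m1": -x + 0.01})
    net = build_network({"m0": {"A", "B"}, "m1": {"A", "B"}}, expr,
                        {"A": "mRNA", "B": "mRNA"}, universe_n=20)
    assert net.edges == []


def test_specific_vs_common_partition():
    edges = [
        CeRNAEdge("g1", "mRNA", "l1", "lncRNA", ("m1",), 0.9, 0.01),
        CeRNAEdge("g2", "mRNA", "l1", "lncRNA", ("m1",), 0.9, 0.01),
        CeRNAEdge("g2", "mRNA", "c1", "circRNA", ("m2",), 0.9, 0.01),
    ]
    net = CeRNANetwork(edges, {}, {}, {}, [])
    lnc_only, common = specific_vs_common(net)
    assert lnc_only == {"g1"} and common == {"g2"}
    assert lnc_only.isdisjoint(common)


def test_planted_module_recovered_and_evidence_revalidates(small_dataset):
    """End-to-end on the small fixture: planted triplets appear as edges
    whose stored evidence recomputes from raw inputs."""
    from stressrna import diffexpr
    ds = small_dataset
    expr = pd.concat([diffexpr.log_cpm(m) for m in ds.matrices.values()])
    demis = sorted(ds.truth.planted_de["miRNA"])
    sponge_ids = {t for m in ("mRNA", "lncRNA", "circRNA")
                  for t in ds.matrices[m].transcript_ids}
    sites = scan_all_sites({m: ds.mirnas[m] for m in demis},
                           {t: u for t, u in ds.utrs.items() if t in sponge_ids})
    tsets = mirna_target_sets(sites)
    type_of = {}
    for layer in ("mRNA", "lncRNA", "circRNA"):
        for t in ds.matrices[layer].transcript_ids:
            type_of[t] = layer
    net = build_network(tsets, expr, type_of, universe_n=len(demis))
    edge_map = {frozenset((e.node_a, e.node_b)): e for e in net.edges}
    hits = sum(m in edge_map[frozenset((a, b))].shared_mirnas
               for m, a, b in ds.truth.planted_triplets
               if frozenset((a, b)) in edge_map)
    assert hits / len(ds.truth.planted_triplets) > 0.5
    for e in net.edges:
        for m in e.shared_mirnas:
            # site really exists in both UTRs
            assert any(s.site_class in ("7mer-m8", "8mer")
                       for s in find_seed_sites(ds.mirnas[m], ds.utrs[e.node_a]))
            # stored correlations recompute from expression
            r = np.corrcoef(expr.loc[m], expr.loc[e.node_a])[0, 1]
            assert r == pytest.approx(e.mirna_r_a[m], abs=1e-12) and r < -0.9
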