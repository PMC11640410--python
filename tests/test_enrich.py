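import itertools
import math

import numpy as np
import pytest

from mirmeta import enrich


def brute_force_upper_tail(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all n-subsets of the universe."""
    universe = list(range(N))
    term = set(universe[:K])
    total = hits = 0
    for combo in itertools.combinations(universe, n):
        total += 1
        if len(term & set(combo)) >= k:
            hits += 1
    return hits / total


def _collection(terms, universe=None):
    return enrich.GeneSetCollection(terms=terms, universe=universe or set())


def test_hypergeom_hand_example():
    # N=10, K=5, n=4, k=4: C(5,4)/C(10,4) = 5/210
    universe = {f"g{i}" for i in range(10)}
    term = ("T", "t", "BP", frozenset({f"g{i}" for i in range(5)}))
    coll = _collection([term], universe)
    res = enrich.hypergeom_enrich({"g0", "g1", "g2", "g3"}, coll)
    assert res["p"].iloc[0] == pytest.approx(5 / 210, abs=1e-12)
    assert res["k"].iloc[0] == 4


def test_hypergeom_matches_exhaustive_enumeration():
    for N in range(2, 13):
        for K in range(1, N + 1):
            for n in range(1, N + 1):
                for k in range(0, min(K, n) + 1):
                    expected = brute_force_upper_tail(N, K, n, k)
                    got = enrich.upper_tail_p(N, K, n, k)
                    assert math.isclose(got, expected, rel_tol=1e-9, abs_tol=1e-12), (
                        N, K, n, k,
                    )


def test_hypergeom_saturation_and_k0():
    universe = {f"g{i}" for i in range(8)}
    terms = [("T1", "", "BP", frozenset({"g0", "g1"})),
             ("T2", "", "BP", frozenset({"g5", "g6", "g7"}))]
    coll = _collection(terms, universe)
    res = enrich.hypergeom_enrich(universe, coll)  # query = universe
    assert (res["k"] == res["K"]).all()
    assert np.allclose(res["p"], 1.0)
    res2 = enrich.hypergeom_enrich({"g2", "g3"}, coll)
    assert res2.set_index("term_id").loc["T1", "p"] == pytest.approx(1.0)  # k = 0


def test_query_outside_universe_dropped_and_empty_query_errors():
    universe = {"a", "b", "c", "d"}
    coll = _collection([("T", "", "BP", frozenset({"a", "b"}))], universe)
    res = enrich.hypergeom_enrich({"a", "zzz"}, coll)
    assert res["n"].iloc[0] == 1
    with pytest.raises(ValueError, match="empty"):
        enrich.hypergeom_enrich({"zzz"}, coll)


def test_correction_methods():
    universe = {f"g{i}" for i in range(20)}
    terms = [(f"T{j}", "", "BP", frozenset({f"g{j}", f"g{j+1}"})) for j in range(5)]
    coll = _collection(terms, universe)
    q = {"g0", "g1", "g2"}
    bon = enrich.hypergeom_enrich(q, coll, method="bonferroni")
    assert np.allclose(bon["adj_p"], np.minimum(bon["p"] * 5, 1.0))
    bh = enrich.hypergeom_enrich(q, coll, method="bh")
    assert (bh["adj_p"] >= bh["p"] - 1e-15).all()
    holm = enrich.hypergeom_enrich(q, coll, method="holm")
    # rows align (same sort key); Holm step-down never exceeds plain Bonferroni
    assert (holm["term_id"] == bon["term_id"]).all()
    assert (holm["adj_p"] <= bon["adj_p"] + 1e-12).all()


def test_kappa_membership_values():
    universe = {f"g{i}" for i in range(4)}
    assert enrich.cohen_kappa_membership({"g0", "g1"}, {"g0", "g1"}, universe) == 1.0
    # hand po/pe: A={g0}, B=empty: po=3/4, pe=3/4 -> kappa 0
    assert enrich.cohen_kappa_membership({"g0"}, set(), universe) == pytest.approx(0.0)
    # symmetry
    a, b = {"g0", "g1"}, {"g1", "g2"}
    assert enrich.cohen_kappa_membership(a, b, universe) == pytest.approx(
        enrich.cohen_kappa_membership(b, a, universe)
    )


def test_kappa_matches_sklearn():
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(3)
    universe = [f"g{i}" for i in range(30)]
    for _ in range(20):
        a = {g for g in universe if rng.random() < 0.3}
        b = {g for g in universe if rng.random() < 0.4}
        va = np.array([g in a for g in universe], dtype=int)
        vb = np.array([g in b for g in universe], dtype=int)
        if (va == vb).all():
            continue
        expected = cohen_kappa_score(va, vb)
        got = enrich.cohen_kappa_membership(a, b, set(universe))
        assert got == pytest.approx(expected, abs=1e-12)


def test_kappa_grouping_identical_terms_and_unattainable_threshold():
    universe = {f"g{i}" for i in range(10)}
    genes = frozenset({"g0", "g1", "g2"})
    terms = [("A", "", "BP", genes), ("B", "", "BP", genes),
             ("C", "", "BP", frozenset({"g7", "g8"}))]
    coll = _collection(terms, universe)
    res = enrich.hypergeom_enrich({"g0", "g1", "g2"}, coll, method="bonferroni")
    grouped = enrich.kappa_group(res, coll, threshold=0.96, significant_only=False)
    by_term = grouped.set_index("term_id")["group_id"]
    assert by_term["A"] == by_term["B"]           # identical terms share a group
    assert by_term["C"] != by_term["A"]
    singles = enrich.kappa_group(res, coll, threshold=1.01, significant_only=False)
    assert singles["group_id"].nunique() == 3     # every term its own group
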