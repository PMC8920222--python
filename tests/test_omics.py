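import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import radsen as rs
from radsen.omics import (
    DeregEntry,
    DeregulationList,
    GeneSet,
    bh_fdr,
    classify_overlap,
    compare_enrichment,
    fisher_enrichment,
    merge_layers,
)


def hypergeom_tail_bruteforce(M, n, N, k):
    """P(X >= k) by exhaustive summation of the hypergeometric pmf."""
    denom = math.comb(M, N)
    return sum(
        math.comb(n, j) * math.comb(M - n, N - j)
        for j in range(k, min(n, N) + 1)
    ) / denom


def bh_stepup_by_hand(p):
    """Step-up q_i = min_{j>=i}(p_(j) m / j), mapped back to input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [p[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = [0.0] * m
    for rank, idx in enumerate(order):
        q[idx] = min(q_sorted[rank], 1.0)
    return q


def _dl(cond, pairs, layer="merged"):
    return DeregulationList.from_pairs(cond, layer, pairs)


class TestMergeLayers:
    def test_disjoint_union(self):
        t = _dl("c", [(f"T{i}", 1) for i in range(5)], "transcript")
        p = _dl("c", [(f"P{i}", -1) for i in range(3)], "protein")
        merged = merge_layers(t, p)
        assert len(merged) == 8 and merged.layer == "merged"

    def test_idempotent_on_identical_lists(self):
        t = _dl("c", [("A", 1), ("B", -1)], "transcript")
        p = _dl("c", [("A", 1), ("B", -1)], "protein")
        merged = merge_layers(t, p)
        assert merged.directions == t.directions
        assert not any(e.conflict for e in merged.entries)

    def test_discordant_identifier_kept_once_and_flagged(self):
        t = _dl("c", [("A", 1), ("X", 1)], "transcript")
        p = _dl("c", [("A", -1), ("Y", -1)], "protein")
        merged = merge_layers(t, p)
        entries = {e.identifier: e for e in merged.entries}
        assert set(entries) == {"A", "X", "Y"}
        assert entries["A"].conflict and not entries["X"].conflict

    def test_larger_magnitude_wins_on_conflict(self):
        t = DeregulationList("c", "transcript", (DeregEntry("A", 1, 0.5),))
        p = DeregulationList("c", "protein", (DeregEntry("A", -1, -2.0),))
        merged = merge_layers(t, p)
        assert merged.entries[0].direction == -1
        assert merged.entries[0].conflict

    def test_condition_mismatch_rejected(self):
        with pytest.raises(ValueError):
            merge_layers(_dl("a", [("X", 1)], "transcript"),
                         _dl("b", [("X", 1)], "protein"))


class TestClassifyOverlap:
    def test_isodose_2gy_structure(self):
        """9 shared proteins of the ~2 Gy comparison split 2 up/3 down/4 contra."""
        a, b, _, _ = rs.generate_omics(rs.isodose_overlap_scenario("2Gy", seed=0))
        ov = classify_overlap(a, b)
        assert (ov.n_up_both, ov.n_down_both, ov.n_contra) == (2, 3, 4)
        assert (ov.n_unique_a, ov.n_unique_b) == (121, 52)
        assert ov.up_both == frozenset({"ACTN1", "CAPN2"})
        assert ov.down_both == frozenset({"IDH2", "PPIB", "PDIA4"})
        assert ov.contra == frozenset({"AHNAK", "ITGB1", "MCAM", "PRCP"})

    def test_self_comparison(self):
        a = _dl("c", [("A", 1), ("B", -1), ("C", 1)])
        ov = classify_overlap(a, a)
        assert ov.n_contra == 0 and ov.n_unique_a == ov.n_unique_b == 0
        assert ov.n_up_both + ov.n_down_both == 3

    def test_global_sign_flip_makes_everything_contra(self):
        a = _dl("a", [("A", 1), ("B", -1), ("C", 1)])
        b = _dl("b", [("A", -1), ("B", 1), ("C", -1)])
        ov = classify_overlap(a, b)
        assert (ov.n_up_both, ov.n_down_both, ov.n_contra) == (0, 0, 3)

    @given(st.lists(st.tuples(st.integers(0, 30), st.sampled_from([-1, 1]),
                              st.sampled_from([-1, 1])), max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_counts_partition_common_set_and_contra_is_symmetric(self, spec):
        ids = {f"G{i}": (da, db) for i, da, db in spec}
        if not ids:
            return
        a = _dl("a", [(g, d[0]) for g, d in ids.items()])
        b = _dl("b", [(g, d[1]) for g, d in ids.items()])
        ov, vo = classify_overlap(a, b), classify_overlap(b, a)
        assert ov.n_up_both + ov.n_down_both + ov.n_contra == len(ov.common_ids)
        assert ov.n_contra == vo.n_contra
        assert (ov.n_up_both, ov.n_down_both) == (vo.n_up_both, vo.n_down_both)

    def test_case_insensitive_matching(self):
        a = _dl("a", [("Actn1", 1)])
        b = _dl("b", [("ACTN1", 1)])
        assert classify_overlap(a, b).n_up_both == 1


class TestFisherEnrichment:
    def test_worked_example(self):
        # universe 20, query 4, set of 5 fully hit except one possible draw:
        # P(X>=4) = C(5,4)C(15,0)/C(20,4) + ... = 5/4845 + 0 ... computed below
        universe = [f"G{i}" for i in range(20)]
        query = universe[:4]
        gs = GeneSet("S", frozenset(universe[:5]))
        row = fisher_enrichment(query, [gs], universe)[0]
        assert row.hits == 4
        assert row.p_value == pytest.approx(hypergeom_tail_bruteforce(20, 5, 4, 4))
        assert row.p_value == pytest.approx(5 / 4845)  # C(5,4)C(15,0)/C(20,4)

    def test_matches_bruteforce_on_all_small_instances(self):
        """Exhaustive oracle sweep over every composition with universe <= 25."""
        for M in range(2, 26):
            universe = [f"G{i}" for i in range(M)]
            for N in range(1, M + 1):
                query = universe[:N]
                sets, expected = [], []
                for n in range(1, M + 1):
                    for k in range(0, min(n, N) + 1):
                        if n - k > M - N:
                            continue  # not enough non-query ids available
                        members = universe[:k] + universe[N: N + (n - k)]
                        sets.append(GeneSet(f"n{n}k{k}", frozenset(members)))
                        expected.append(hypergeom_tail_bruteforce(M, n, N, k))
                rows = fisher_enrichment(query, sets, universe)
                got = {r.set_name: r.p_value for r in rows}
                for gs, exp in zip(sets, expected):
                    assert got[gs.name] == pytest.approx(exp, rel=1e-12, abs=1e-15)

    def test_disjoint_set_has_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        gs = GeneSet("S", frozenset(universe[10:14]))
        row = fisher_enrichment(universe[:4], [gs], universe)[0]
        assert row.hits == 0 and row.p_value == pytest.approx(1.0)

    def test_saturated_query_has_p_one(self):
        universe = [f"G{i}" for i in range(10)]
        gs = GeneSet("S", frozenset(universe[:5]))
        row = fisher_enrichment(universe, [gs], universe)[0]
        assert row.hits == 5 and row.p_value == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="STRAY"):
            fisher_enrichment(["STRAY"], [GeneSet("S", frozenset(["A"]))], ["A"])

    def test_rows_sorted_by_p(self):
        universe = [f"G{i}" for i in range(30)]
        sets = [GeneSet("hit", frozenset(universe[:5])),
                GeneSet("miss", frozenset(universe[20:25]))]
        rows = fisher_enrichment(universe[:5], sets, universe)
        assert [r.set_name for r in rows] == ["hit", "miss"]
        assert rows[0].p_value <= rows[1].p_value


class TestBenjaminiHochberg:
    def test_worked_four_p_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_tied_inputs(self):
        assert bh_fdr([0.2]) == [pytest.approx(0.2)]
        assert bh_fdr([0.3, 0.3, 0.3]) == pytest.approx([0.3] * 3)

    def test_matches_hand_stepup_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 12)).tolist()
            assert bh_fdr(p) == pytest.approx(bh_stepup_by_hand(p), rel=1e-12)

    def test_permutation_equivariance_and_floor(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=8)
        perm = rng.permutation(8)
        q = np.array(bh_fdr(p.tolist()))
        qp = np.array(bh_fdr(p[perm].tolist()))
        assert np.allclose(q[perm], qp)
        assert np.all(q >= p.min() - 1e-15)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(2, 20))
            q = np.array(bh_fdr(p.tolist()))
            assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCompareEnrichment:
    def _rows(self, spec):
        return [rs.EnrichmentRow(name, 10, 3, frozenset(), p, q)
                for name, p, q in spec]

    def test_identical_inputs_all_shared(self):
        rows = self._rows([("A", 0.001, 0.01), ("B", 0.5, 0.5)])
        parts = compare_enrichment(rows, rows, fdr_cut=0.05)
        assert parts["shared"] == {"A"}
        assert not parts["unique_a"] and not parts["unique_b"]

    def test_disjoint_passing_sets(self):
        names = ["A", "B", "C", "D", "E"]
        a = self._rows([(n, 0.01, 0.01 if n in "ABC" else 0.9) for n in names])
        b = self._rows([(n, 0.01, 0.01 if n in "DE" else 0.9) for n in names])
        parts = compare_enrichment(a, b, 0.05)
        assert not parts["shared"]
        assert len(parts["unique_a"]) + len(parts["unique_b"]) == 5

    def test_different_collections_rejected(self):
        with pytest.raises(ValueError):
            compare_enrichment(self._rows([("A", 0.1, 0.1)]),
                               self._rows([("B", 0.1, 0.1)]))


class TestDeregEntryValidation:
    def test_direction_from_magnitude_sign(self):
        assert DeregEntry("g1", 0, -1.2).direction == -1
        assert DeregEntry("g2", 0, 0.4).direction == 1

    def test_explicit_direction_wins_with_warning(self):
        with pytest.warns(UserWarning):
            e = DeregEntry("g1", 1, -2.0)
        assert e.direction == 1

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            _dl("c", [("A", 1), ("a", -1)])  # case-insensitive duplicate
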