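import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import regnet as rn
from regnet.enrichment import MirPathConfig


def enumerate_hypergeom_tail(k, K, n, N):
    """Exhaustive oracle: fraction of n-subsets of [N] with >= k of the K successes."""
    hits = total = 0
    successes = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeom:
    def test_zero_overlap_gives_one(self):
        assert rn.hypergeom_upper(0, 5, 5, 10) == 1.0

    def test_full_overlap_closed_form(self):
        assert rn.hypergeom_upper(5, 5, 5, 10) == pytest.approx(1 / math.comb(10, 5), rel=1e-12)

    def test_matches_exhaustive_enumeration_small_universe(self):
        rng = random.Random(19)
        for _ in range(25):
            N = rng.randint(4, 12)
            K = rng.randint(1, N)
            n = rng.randint(1, N)
            k = rng.randint(0, min(K, n))
            want = enumerate_hypergeom_tail(k, K, n, N)
            assert rn.hypergeom_upper(k, K, n, N) == pytest.approx(want, abs=1e-12)

    def test_bound_violations_are_errors(self):
        for bad in [(6, 5, 5, 10), (-1, 5, 5, 10), (0, 11, 5, 10), (0, 5, 11, 10)]:
            with pytest.raises(ValueError):
                rn.hypergeom_upper(*bad)


class TestBH:
    def test_single_p_unchanged(self):
        assert rn.bh_adjust([0.037]) == [pytest.approx(0.037)]

    def test_hand_computed_step_up(self):
        assert rn.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_ps_stay_equal(self):
        assert rn.bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            rn.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_never_decreases_and_preserves_ranking(self, ps):
        adj = rn.bh_adjust(ps)
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        assert all(a <= 1.0 + 1e-12 for a in adj)
        order = sorted(range(len(ps)), key=lambda i: ps[i])
        ranked = [adj[i] for i in order]
        assert all(x <= y + 1e-12 for x, y in zip(ranked, ranked[1:]))


class TestFisher:
    def test_single_p_identity(self):
        for p in (0.5, 0.05, 1e-6):
            assert rn.fisher_combine([p])[2] == pytest.approx(p, rel=1e-9)

    def test_all_ones_give_one(self):
        x2, df, p = rn.fisher_combine([1.0, 1.0])
        assert x2 == 0.0 and df == 4 and p == pytest.approx(1.0)

    def test_two_p05_closed_form(self):
        # chi2(4) upper tail has closed form exp(-x/2) * (1 + x/2)
        x2, df, p = rn.fisher_combine([0.05, 0.05])
        assert x2 == pytest.approx(-4 * math.log(0.05), rel=1e-9)
        assert x2 == pytest.approx(11.9829, abs=1e-4)
        want = math.exp(-x2 / 2) * (1 + x2 / 2)
        assert p == pytest.approx(want, rel=1e-9)
        assert p == pytest.approx(0.01747, abs=1e-5)

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            rn.fisher_combine([])

    def test_combined_p_decreases_with_more_significant_copies(self):
        # replicated small p-values strengthen the combined evidence; note
        # this holds for small alpha only (two copies of p=0.3 combine to
        # 0.307 — Fisher's method can weaken marginal evidence)
        ps = [rn.fisher_combine([0.05] * m)[2] for m in range(1, 8)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert rn.fisher_combine([0.3, 0.3])[2] > 0.3


class TestMirPath:
    def _one_mirna_setup(self):
        universe = [f"g{i}" for i in range(40)]
        targets = {f"g{i}": 0.9 for i in range(20)}
        pathways = rn.GeneSetCollection.from_sets(
            {"P1": [f"g{i}" for i in range(20)]}, universe=universe
        )
        return targets, pathways

    def test_pathway_equal_to_target_set_closed_form(self):
        targets, pathways = self._one_mirna_setup()
        (res,) = rn.mirpath_analyze({"miR-x": targets}, pathways)
        want = rn.hypergeom_upper(20, 20, 20, 40)
        assert res.p_raw == pytest.approx(want, rel=1e-9)  # Fisher of one p is that p
        assert res.k == 20 and res.n_mirnas == 1

    def test_cutoff_above_all_scores_gives_p_one(self):
        targets, pathways = self._one_mirna_setup()
        cfg = MirPathConfig(target_score_cutoff=0.95)
        (res,) = rn.mirpath_analyze({"miR-x": targets}, pathways, cfg)
        assert res.p_raw == 1.0

    def test_union_mode_pools_targets(self):
        universe = [f"g{i}" for i in range(40)]
        pathways = rn.GeneSetCollection.from_sets(
            {"P1": [f"g{i}" for i in range(10)]}, universe=universe
        )
        targets = {
            "a": {f"g{i}": 0.9 for i in range(5)},
            "b": {f"g{i}": 0.9 for i in range(5, 10)},
        }
        (res,) = rn.mirpath_analyze(targets, pathways, MirPathConfig(combine_method="union"))
        assert res.k == 10 and res.n == 10
        assert res.p_raw == pytest.approx(rn.hypergeom_upper(10, 10, 10, 40), rel=1e-9)
        assert res.combined_p is None

    def test_max_targets_truncation_keeps_best_scores(self):
        universe = [f"g{i}" for i in range(30)]
        pathways = rn.GeneSetCollection.from_sets(
            {"P1": [f"g{i}" for i in range(5)]}, universe=universe
        )
        scores = {f"g{i}": 0.8 + 0.001 * i for i in range(30)}
        cfg = MirPathConfig(max_targets_per_mirna=10)
        (res,) = rn.mirpath_analyze({"m": scores}, pathways, cfg)
        # the 10 best-scoring targets are g20..g29, disjoint from the pathway
        assert res.k == 0 and res.p_raw == 1.0

    def test_planted_multi_mirna_design_ranks_first(self):
        coll, query, truth = rn.gen_annotations(planted_fold=5, seed=3)
        planted = sorted(truth.extras["planted_term_members"])
        rng = np.random.default_rng(3)
        targets = {}
        for mi in range(3):
            member_part = list(rng.choice(planted, size=60, replace=False))
            other = sorted(coll.universe - set(planted))
            back_part = list(rng.choice(other, size=60, replace=False))
            targets[f"miR-{mi}"] = {g: 0.9 for g in member_part + back_part}
        results = rn.mirpath_analyze(targets, coll)
        assert results[0].term == truth.planted_term
        assert results[0].p_adjusted < 0.05

    def test_unknown_genes_dropped_not_fatal(self):
        targets, pathways = self._one_mirna_setup()
        targets["not-a-gene"] = 0.99
        (res,) = rn.mirpath_analyze({"miR-x": targets}, pathways)
        assert res.n == 20

    def test_empty_targets_mapping_is_error(self):
        _, pathways = self._one_mirna_setup()
        with pytest.raises(ValueError):
            rn.mirpath_analyze({}, pathways)


class TestGOAnnotate:
    def test_query_equal_to_term_ranks_first(self):
        universe = [f"g{i}" for i in range(20)]
        coll = rn.GeneSetCollection.from_sets(
            {"A": universe[:5], "B": universe[5:15]}, universe=universe
        )
        res = rn.go_annotate(universe[:5], coll)
        assert res[0].term == "A"
        assert res[0].p_raw < res[1].p_raw

    def test_bh_is_monotone_across_result_table(self):
        coll, query, _ = rn.gen_annotations(planted_fold=5, seed=8)
        res = rn.go_annotate(query, coll)
        ordered = sorted(res, key=lambda r: r.p_raw)
        adj = [r.p_adjusted for r in ordered]
        assert all(x <= y + 1e-12 for x, y in zip(adj, adj[1:]))
        assert all(r.p_adjusted >= r.p_raw - 1e-12 for r in res)

    def test_planted_term_recovered(self):
        coll, query, truth = rn.gen_annotations(planted_fold=5, seed=3)
        res = {r.term: r for r in rn.go_annotate(query, coll)}
        assert res[truth.planted_term].p_adjusted < 0.05

    def test_raw_p_values_calibrated_under_null(self):
        # a discrete test's p-values are uniform exactly at their attained
        # values (P(P <= p) = p there); evaluating the ECDF anywhere else
        # picks up the atom sizes, so calibration is checked on the support
        coll, _, _ = rn.gen_annotations(n_terms=20, seed=55)
        rng = np.random.default_rng(56)
        genes = sorted(coll.universe)
        N = len(coll.universe)
        draws = {t: [] for t in coll.sets}
        for _ in range(1000):
            q = set(rng.choice(genes, size=50, replace=False))
            for t, (_, members) in coll.sets.items():
                draws[t].append(rn.hypergeom_upper(len(q & members), len(members), 50, N))
        for ps in draws.values():  # each term has its own attained support
            ps = np.sort(ps)
            n = len(ps)
            deviation = max(
                abs(np.searchsorted(ps, v, side="right") / n - v) for v in np.unique(ps)
            )
            assert deviation < 0.05


class TestGMT:
    def test_round_trip(self, tmp_path):
        coll, _, _ = rn.gen_annotations(n_genes=200, n_terms=5, term_size_range=(10, 30), seed=1)
        p = tmp_path / "sets.gmt"
        rn.write_gmt(coll, p)
        back = rn.read_gmt(p, universe=coll.universe)
        assert back.sets == coll.sets

    def test_malformed_line_is_error(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("TERM_ONLY\tdesc\n")
        with pytest.raises(ValueError):
            rn.read_gmt(p)
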