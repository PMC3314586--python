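"""Slim construction, cumulative weights, filtering, grouping, Total Score."""

import math

import numpy as np
import pytest

from semgo.engine import (
    EngineConfig,
    EngineError,
    annotate,
    build_goslim,
    filter_terms,
    group_by_similarity,
    internal_confidence,
    noncumulative_internal_confidence,
    score_namespace,
    total_score,
)
from semgo.evidence import WeightedTermSet
from semgo.ontology import lin_similarity

from conftest import (
    MF,
    corpus_from_counts,
    graph_from_stanzas,
    random_dag_stanzas,
    single_linkage_oracle,
    slim_w_oracle,
)


@pytest.fixture
def figure_style_graph():
    """Two branches under the root: node2 with children B and C, where C
    also hangs under a second parent (node4), plus an unrelated branch."""
    return graph_from_stanzas([
        ("GO:0000001", MF, []),                    # root
        ("GO:0000002", MF, ["GO:0000001"]),        # node 2
        ("GO:0000004", MF, ["GO:0000001"]),        # node 4 (second parent of C)
        ("GO:0000005", MF, ["GO:0000002"]),        # B
        ("GO:0000006", MF, ["GO:0000002", "GO:0000004"]),  # C
        ("GO:0000007", MF, ["GO:0000001"]),        # unrelated light branch
    ])


class TestBuildGoslim:
    def test_single_chain_propagation(self, chain_graph):
        slim = build_goslim({"GO:0000003": 4.0}, chain_graph)
        assert slim.W == {
            "GO:0000003": 4.0, "GO:0000002": 4.0, "GO:0000001": 4.0
        }
        assert slim.slim_terms == {"GO:0000003", "GO:0000002", "GO:0000001"}

    def test_internal_node_sums_children_and_reconstructed_parent_inherits(
        self, figure_style_graph
    ):
        # retrieved: B and C; node 2 cumulates both, node 4 (reconstructed
        # from C alone) inherits exactly C's weight and adds none of its own
        w_b, w_c = 7.0, 3.0
        slim = build_goslim(
            {"GO:0000005": w_b, "GO:0000006": w_c}, figure_style_graph
        )
        assert slim.W["GO:0000002"] == pytest.approx(w_b + w_c)
        assert slim.W["GO:0000004"] == pytest.approx(w_c)
        assert slim.W["GO:0000001"] == pytest.approx(w_b + w_c)
        # pruned: the unrelated branch is not in the slim
        assert "GO:0000007" not in slim.slim_terms

    def test_diamond_matches_definition_oracle(self, diamond_graph):
        weights = {"GO:0000004": 2.0, "GO:0000002": 1.5}
        slim = build_goslim(weights, diamond_graph)
        assert slim.W == pytest.approx(slim_w_oracle(diamond_graph, weights))

    def test_empty_input_gives_empty_slim(self, chain_graph):
        slim = build_goslim({}, chain_graph)
        assert slim.is_empty()

    def test_mixed_namespaces_rejected(self):
        graph = graph_from_stanzas([
            ("GO:0000001", MF, []),
            ("GO:0000002", "biological_process", []),
        ])
        with pytest.raises(EngineError):
            build_goslim({"GO:0000001": 1.0, "GO:0000002": 1.0}, graph)

    def test_zero_spread_zscore_defined_as_zero(self, chain_graph):
        slim = build_goslim({"GO:0000003": 4.0}, chain_graph)
        assert slim.sigma == 0.0
        assert all(z == 0.0 for z in slim.Z.values())

    def test_zscore_standardises_cumulative_weights(self, figure_style_graph):
        slim = build_goslim(
            {"GO:0000005": 7.0, "GO:0000006": 3.0}, figure_style_graph
        )
        ws = np.array([slim.W[t] for t in sorted(slim.slim_terms)])
        mean = slim.W["GO:0000001"] / len(slim.slim_terms)
        sigma = ws.std()
        for t in slim.slim_terms:
            assert slim.Z[t] == pytest.approx((slim.W[t] - mean) / sigma)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_and_monotonicity_random(self, seed):
        rng = np.random.default_rng(200 + seed)
        graph = graph_from_stanzas(random_dag_stanzas(rng, int(rng.integers(4, 13))))
        terms = sorted(graph.terms)
        k = int(rng.integers(1, min(6, len(terms)) + 1))
        chosen = rng.choice(terms, size=k, replace=False)
        weights = {t: float(rng.uniform(0.5, 20)) for t in chosen}
        slim = build_goslim(weights, graph)
        assert slim.root_weight == pytest.approx(sum(weights.values()))
        for child, parent in graph.graph.edges:
            if child in slim.slim_terms:
                assert slim.W[parent] >= slim.W[child] - 1e-12
        assert slim.W == pytest.approx(slim_w_oracle(graph, weights))


class TestConfidences:
    def test_root_internal_confidence_is_one(self, chain_graph):
        slim = build_goslim({"GO:0000003": 4.0}, chain_graph)
        assert internal_confidence(slim, "GO:0000001") == 1.0

    def test_single_chain_all_ones(self, chain_graph):
        slim = build_goslim({"GO:0000003": 4.0}, chain_graph)
        assert all(
            internal_confidence(slim, t) == pytest.approx(1.0)
            for t in slim.slim_terms
        )

    def test_disjoint_branch_ratios(self, figure_style_graph):
        slim = build_goslim(
            {"GO:0000005": 3.0, "GO:0000004": 1.0}, figure_style_graph
        )
        assert internal_confidence(slim, "GO:0000005") == pytest.approx(0.75)
        assert internal_confidence(slim, "GO:0000004") == pytest.approx(0.25)
        assert noncumulative_internal_confidence(slim, "GO:0000005") == pytest.approx(0.75)
        assert noncumulative_internal_confidence(slim, "GO:0000004") == pytest.approx(0.25)

    def test_reconstructed_ancestor_has_zero_noncumulative(self, chain_graph):
        slim = build_goslim({"GO:0000003": 4.0}, chain_graph)
        assert noncumulative_internal_confidence(slim, "GO:0000002") == 0.0
        assert noncumulative_internal_confidence(slim, "GO:0000003") == 1.0


class TestGrouping:
    def test_singleton_group(self, chain_graph):
        corpus = corpus_from_counts(chain_graph, {"GO:0000003": 2, "GO:0000001": 6})
        slim = build_goslim({"GO:0000003": 4.0}, chain_graph)
        groups = group_by_similarity(slim, chain_graph, corpus)
        assert len(groups) == 1
        assert groups[0].members == {"GO:0000003"}
        assert groups[0].GrS == pytest.approx(internal_confidence(slim, "GO:0000003"))

    def test_identical_ancestry_pair_groups_together(self, chain_graph):
        # mid subsumes leaf and shares its cumulative count, so lin = 1
        corpus = corpus_from_counts(chain_graph, {"GO:0000003": 2, "GO:0000001": 6})
        slim = build_goslim({"GO:0000002": 1.0, "GO:0000003": 1.0}, chain_graph)
        sim = lin_similarity(chain_graph, corpus, "GO:0000002", "GO:0000003")
        assert sim == pytest.approx(1.0)
        groups = group_by_similarity(slim, chain_graph, corpus)
        assert len(groups) == 1
        assert groups[0].members == {"GO:0000002", "GO:0000003"}

    def test_chaining_merges_transitively(self, monkeypatch):
        """Three terms with pairwise similarities {0.9, 0.9, 0.2} end in one
        group through the chain, matching the 3-element partition oracle."""
        graph = graph_from_stanzas([
            ("GO:0000001", MF, []),
            ("GO:0000002", MF, ["GO:0000001"]),
            ("GO:0000003", MF, ["GO:0000001"]),
            ("GO:0000004", MF, ["GO:0000001"]),
        ])
        corpus = corpus_from_counts(graph, {"GO:0000002": 1, "GO:0000001": 7})
        sims = {
            frozenset({"GO:0000002", "GO:0000003"}): 0.9,
            frozenset({"GO:0000003", "GO:0000004"}): 0.9,
            frozenset({"GO:0000002", "GO:0000004"}): 0.2,
        }
        monkeypatch.setattr(
            "semgo.engine.lin_similarity",
            lambda g, c, a, b, **kw: sims[frozenset({a, b})],
        )
        slim = build_goslim(
            {"GO:0000002": 1.0, "GO:0000003": 1.0, "GO:0000004": 1.0}, graph
        )
        groups = group_by_similarity(slim, graph, corpus, sim_threshold=0.7)
        oracle = single_linkage_oracle(
            sorted(slim.input_terms),
            lambda a, b: sims[frozenset({a, b})] >= 0.7,
        )
        assert [g.members for g in groups] == oracle
        assert len(groups) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_partition_matches_naive_closure_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        graph = graph_from_stanzas(random_dag_stanzas(rng, int(rng.integers(5, 13))))
        terms = sorted(graph.terms)
        counts = {t: int(rng.integers(0, 4)) for t in terms}
        counts[terms[0]] += 1
        corpus = corpus_from_counts(graph, counts)
        k = int(rng.integers(2, min(6, len(terms)) + 1))
        chosen = sorted(rng.choice(terms, size=k, replace=False))
        slim = build_goslim({t: float(rng.uniform(1, 5)) for t in chosen}, graph)
        threshold = float(rng.uniform(0.2, 0.9))
        groups = group_by_similarity(slim, graph, corpus, sim_threshold=threshold)
        oracle = single_linkage_oracle(
            chosen,
            lambda a, b: lin_similarity(graph, corpus, a, b) >= threshold,
        )
        assert sorted((g.members for g in groups), key=min) == oracle
        # partition property
        assert set().union(*(g.members for g in groups)) == set(chosen)
        assert sum(len(g.members) for g in groups) == len(chosen)
        # group scores are member sums
        for g in groups:
            assert g.GrS == pytest.approx(
                sum(internal_confidence(slim, m) for m in g.members)
            )
            assert g.GrS_nc == pytest.approx(
                sum(noncumulative_internal_confidence(slim, m) for m in g.members)
            )


class TestFilterAndScore:
    @pytest.fixture
    def two_branch(self, figure_style_graph):
        corpus = corpus_from_counts(
            figure_style_graph,
            {"GO:0000005": 1, "GO:0000006": 1, "GO:0000007": 4, "GO:0000001": 2},
        )
        slim = build_goslim(
            {"GO:0000005": 40.0, "GO:0000006": 35.0, "GO:0000007": 2.0},
            figure_style_graph,
        )
        groups = group_by_similarity(slim, figure_style_graph, corpus)
        return figure_style_graph, corpus, slim, groups

    def test_vacuous_thresholds_keep_all(self, two_branch):
        _, _, slim, groups = two_branch
        kept = filter_terms(
            slim, groups, z_threshold=-math.inf, grs_threshold=0.0
        )
        assert kept == slim.input_terms

    def test_single_term_filtered_by_high_thresholds(self, chain_graph):
        corpus = corpus_from_counts(chain_graph, {"GO:0000003": 1, "GO:0000001": 7})
        slim = build_goslim({"GO:0000003": 4.0}, chain_graph)
        groups = group_by_similarity(slim, chain_graph, corpus)
        assert filter_terms(slim, groups, z_threshold=0.5) == set()
        assert filter_terms(slim, groups, grs_threshold=1.5) == set()

    def test_light_branch_discarded_at_intermediate_thresholds(self, two_branch):
        # heavy branch terms (40, 35) survive; the light branch (2) has
        # negative Z and a group score below threshold, so it is discarded
        _, _, slim, groups = two_branch
        kept = filter_terms(slim, groups, z_threshold=0.0, grs_threshold=0.2)
        assert "GO:0000007" not in kept
        assert {"GO:0000005", "GO:0000006"} <= kept

    def test_filter_monotone_in_both_thresholds(self, two_branch):
        _, _, slim, groups = two_branch
        base = filter_terms(slim, groups, z_threshold=-1.0, grs_threshold=0.0)
        for z in (-0.5, 0.0, 0.5):
            for grs in (0.1, 0.3, 0.9):
                assert filter_terms(
                    slim, groups, z_threshold=z, grs_threshold=grs
                ) <= base

    def test_total_score_direct_substitution(self, two_branch):
        graph, corpus, slim, groups = two_branch
        group_of = {m: g for g in groups for m in g.members}
        t = "GO:0000005"
        from semgo.ontology import information_content

        expected = (
            information_content(corpus, graph, t)
            * noncumulative_internal_confidence(slim, t) ** 2
            / group_of[t].GrS_nc
            * slim.input_weights[t]
        )
        got = total_score(slim, group_of[t], corpus, graph, t)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_singleton_group_ratio_collapses(self, chain_graph):
        corpus = corpus_from_counts(chain_graph, {"GO:0000003": 1, "GO:0000001": 7})
        slim = build_goslim({"GO:0000003": 4.0}, chain_graph)
        groups = group_by_similarity(slim, chain_graph, corpus)
        from semgo.ontology import information_content

        ic = information_content(corpus, chain_graph, "GO:0000003")
        # InC_nc = GrS_nc so TS = IC * InC_nc * w
        assert total_score(
            slim, groups[0], corpus, chain_graph, "GO:0000003"
        ) == pytest.approx(ic * 1.0 * 4.0)

    def test_root_scores_zero(self, chain_graph):
        corpus = corpus_from_counts(chain_graph, {"GO:0000003": 8})
        slim = build_goslim({"GO:0000001": 2.0, "GO:0000003": 4.0}, chain_graph)
        groups = group_by_similarity(slim, chain_graph, corpus)
        group_of = {m: g for g in groups for m in g.members}
        assert total_score(
            slim, group_of["GO:0000001"], corpus, chain_graph, "GO:0000001"
        ) == 0.0


class TestAnnotate:
    def test_empty_input_empty_output(self, chain_graph):
        corpus = corpus_from_counts(chain_graph, {"GO:0000003": 1})
        assert annotate({}, chain_graph, corpus) == []

    def test_chain_end_to_end(self, chain_graph):
        corpus = corpus_from_counts(chain_graph, {"GO:0000003": 1, "GO:0000001": 7})
        wts = WeightedTermSet("p1", {"GO:0000003": 50.0})
        anns = annotate([wts], chain_graph, corpus)
        assert [a.term for a in anns] == ["GO:0000003"]
        a = anns[0]
        assert a.is_representative
        assert a.TS == pytest.approx(-math.log(1 / 8) * 1.0 * 1.0 * 50.0)
        # TS recomputable from the reported fields
        assert a.TS == pytest.approx(a.IC * a.InC_nc * (a.InC_nc / a.GrS_nc) * a.w)

    def test_scale_equivariance(self, figure_style_graph):
        corpus = corpus_from_counts(
            figure_style_graph,
            {"GO:0000005": 1, "GO:0000006": 2, "GO:0000007": 3, "GO:0000001": 2},
        )
        weights = {"GO:0000005": 40.0, "GO:0000006": 25.0, "GO:0000007": 30.0}
        cfg = EngineConfig(z_threshold=-math.inf, grs_threshold=0.0)
        base = annotate(
            [WeightedTermSet("p", dict(weights))], figure_style_graph, corpus, cfg
        )
        c = 7.5
        scaled = annotate(
            [WeightedTermSet("p", {t: w * c for t, w in weights.items()})],
            figure_style_graph, corpus, cfg,
        )
        assert [a.term for a in base] == [a.term for a in scaled]
        for b, s in zip(base, scaled):
            assert s.TS == pytest.approx(b.TS * c, rel=1e-9)
            assert s.InC == pytest.approx(b.InC, rel=1e-9)
            assert s.InC_nc == pytest.approx(b.InC_nc, rel=1e-9)
            assert s.Z == pytest.approx(b.Z, rel=1e-9, abs=1e-12)
            assert s.GrS == pytest.approx(b.GrS, rel=1e-9)
            assert s.group_id == b.group_id

    def test_representative_is_group_max_ts(self, figure_style_graph):
        corpus = corpus_from_counts(
            figure_style_graph,
            {"GO:0000005": 1, "GO:0000006": 1, "GO:0000001": 6},
        )
        cfg = EngineConfig(z_threshold=-math.inf, grs_threshold=0.0)
        anns = annotate(
            [WeightedTermSet("p", {"GO:0000005": 10.0, "GO:0000006": 6.0})],
            figure_style_graph, corpus, cfg,
        )
        by_group = {}
        for a in anns:
            by_group.setdefault(a.group_id, []).append(a)
        for members in by_group.values():
            top = max(members, key=lambda a: a.TS)
            assert top.is_representative
            assert sum(m.is_representative for m in members) == 1

    def test_representatives_only_mode(self, figure_style_graph):
        corpus = corpus_from_counts(
            figure_style_graph,
            {"GO:0000005": 1, "GO:0000006": 1, "GO:0000001": 6},
        )
        cfg = EngineConfig(
            z_threshold=-math.inf, grs_threshold=0.0, representatives_only=True
        )
        anns = annotate(
            [WeightedTermSet("p", {"GO:0000005": 10.0, "GO:0000006": 6.0})],
            figure_style_graph, corpus, cfg,
        )
        assert all(a.is_representative for a in anns)

    def test_output_sorted_by_ts_descending(self, figure_style_graph):
        corpus = corpus_from_counts(
            figure_style_graph,
            {"GO:0000005": 1, "GO:0000006": 2, "GO:0000007": 1, "GO:0000001": 4},
        )
        cfg = EngineConfig(z_threshold=-math.inf, grs_threshold=0.0)
        anns = annotate(
            [WeightedTermSet(
                "p", {"GO:0000005": 9.0, "GO:0000006": 7.0, "GO:0000007": 8.0}
            )],
            figure_style_graph, corpus, cfg,
        )
        ts = [a.TS for a in anns]
        assert ts == sorted(ts, reverse=True)
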