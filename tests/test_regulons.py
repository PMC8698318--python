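"""Clustering, enrichment statistics, regulon inference and the TF network."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from osteostage import (ConsensusKAgglomerative, ExpressionSimConfig,
                        bh_adjust, build_tf_network, classify_switch,
                        cluster_quality_scores, hypergeom_pvalue,
                        infer_regulons, name_regulon, select_partition,
                        simulate_expression, zscore_genes)
from osteostage.regulons import Regulon


def hypergeom_oracle(N, K, n, k):
    """Exhaustive upper-tail probability from the counting definition."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


def bh_oracle(pvalues):
    """Brute-force step-up definition: adj_i = min over tail of p*m/rank."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestZScore:
    def test_hand_row(self):
        z, _ = zscore_genes(pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"]))
        assert np.allclose(z.loc["g"], [-1.0, 0.0, 1.0])

    def test_constant_row_flagged_degenerate(self):
        z, degenerate = zscore_genes(
            pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]],
                         index=["flat", "ok"]))
        assert list(degenerate) == ["flat"]
        assert list(z.index) == ["ok"]

    def test_single_condition_raises(self):
        with pytest.raises(ValueError):
            zscore_genes(pd.DataFrame([[1.0]]))


class TestClusterQuality:
    def test_silhouette_hand_example(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        q = cluster_quality_scores(X, [0, 0, 1, 1])
        assert q.silhouette == pytest.approx(0.990, abs=1e-3)

    def test_true_partition_beats_merged_alternatives(self):
        # 6 points in 3 tight, well-separated pairs: the true partition has
        # a lower DB index than every partition obtained by merging true
        # clusters (brute force over the merges of the 3-cluster solution)
        X = np.array([[0.0], [0.2], [4.0], [4.2], [10.0], [10.2]])
        true_labels = [0, 0, 1, 1, 2, 2]
        db_true = cluster_quality_scores(X, true_labels).davies_bouldin
        merges = [[0, 0, 0, 0, 1, 1],   # merge clusters 0 and 1
                  [0, 0, 1, 1, 0, 0],   # merge clusters 0 and 2
                  [0, 0, 1, 1, 1, 1]]   # merge clusters 1 and 2
        for labels in merges:
            assert db_true < cluster_quality_scores(X, labels).davies_bouldin

    def test_random_labels_on_iid_data_near_zero_silhouette(self):
        rng = np.random.default_rng(0)
        sils = []
        for _ in range(20):
            X = rng.normal(size=(60, 4))
            labels = rng.integers(0, 3, size=60)
            sils.append(cluster_quality_scores(X, labels).silhouette)
        assert abs(np.mean(sils)) < 0.1

    def test_single_cluster_raises(self):
        with pytest.raises(ValueError):
            cluster_quality_scores(np.zeros((4, 2)), [0, 0, 0, 0])


class TestPartitionSelection:
    def test_three_planted_groups_select_k3(self):
        rng = np.random.default_rng(5)
        centers = rng.normal(0, 2, size=(3, 6))
        X = np.vstack([c + rng.normal(0, 0.05, size=(15, 6))
                       for c in centers])
        partition = select_partition(pd.DataFrame(X))
        assert len(set(partition.values())) == 3

    def test_selection_invariant_to_uniform_scaling(self):
        rng = np.random.default_rng(8)
        centers = rng.normal(0, 2, size=(4, 5))
        X = np.vstack([c + rng.normal(0, 0.1, size=(12, 5))
                       for c in centers])
        a = ConsensusKAgglomerative().fit(X)
        b = ConsensusKAgglomerative().fit(X * 37.0)
        assert a.k_ == b.k_
        assert (a.labels_ == b.labels_).all()

    def test_planted_k8_recovered_within_one(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            centers = rng.normal(0, 1.5, size=(8, 12))
            X = np.vstack([c + rng.normal(0, 0.15, size=(10, 12))
                           for c in centers])
            k = ConsensusKAgglomerative().fit(X).k_
            hits += k in (7, 8, 9)
        assert hits == 10

    def test_too_few_genes_raises(self):
        with pytest.raises(ValueError):
            ConsensusKAgglomerative(k_min=3).fit(np.zeros((3, 2)))


class TestEnrichmentStats:
    def test_hypergeom_hand_values(self):
        assert hypergeom_pvalue(10, 5, 4, 0) == 1.0
        assert hypergeom_pvalue(10, 5, 4, 4) == pytest.approx(5 / 210,
                                                              abs=1e-12)
        assert hypergeom_pvalue(8, 8, 8, 8) == pytest.approx(1.0)

    def test_hypergeom_matches_enumeration_up_to_n20(self):
        for N in range(1, 21):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert abs(hypergeom_pvalue(N, K, n, k)
                                   - hypergeom_oracle(N, K, n, k)) < 1e-12

    def test_hypergeom_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 12, 4, 2)
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 5, 4, 5)

    def test_bh_hand_value_and_single_p(self):
        adj, sig = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)
        assert sig.all()
        adj1, _ = bh_adjust([0.07])
        assert adj1[0] == pytest.approx(0.07)

    def test_bh_matches_brute_force_definition(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 9))
            adj, _ = bh_adjust(p)
            assert np.allclose(adj, bh_oracle(p), atol=1e-12)

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestSwitchClassification:
    @pytest.mark.parametrize("activity, expected", [
        ([-1.0, 0.0, 1.0], "up"),
        ([1.0, 0.0, -1.0], "down"),
        ([0.0, 2.0, 0.2], "transient"),
        ([0.0, 0.1, 0.0], "flat"),
    ])
    def test_rules(self, activity, expected):
        assert classify_switch(activity) == expected

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            classify_switch([0.0, 1.0])


class TestNaming:
    @pytest.mark.parametrize("reg, n, expected", [
        ("E2F8", 123, "E2F8.123"),
        ("ZNF521", 45, "ZNF521.45"),
        ("X", 2, "X.2"),
    ])
    def test_names(self, reg, n, expected):
        assert name_regulon(reg, n) == expected

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            name_regulon("", 3)
        with pytest.raises(ValueError):
            name_regulon("A", 0)


class TestInference:
    def test_noise_free_planted_regulon_recovered_exactly(self):
        cfg = ExpressionSimConfig(n_genes=80, planted_regulons=4,
                                  decoy_regulators=3, noise_sd=0.0, seed=0)
        tpm, de, prior_df, tfs, metabolic, truth = simulate_expression(cfg)
        from osteostage import call_response_genes
        response = call_response_genes(de)
        z, _ = zscore_genes(np.log2(tpm + 1.0))
        prior = {reg: set(sub["target"])
                 for reg, sub in prior_df.groupby("regulator")}
        regulons = infer_regulons(z, response, prior)
        found = {r.regulator: r for r in regulons}
        assert set(found) == set(truth.regulons)
        for reg, r in found.items():
            assert sorted(r.targets) == sorted(truth.regulons[reg])
            assert r.correlation > 0.99
            assert r.direction == truth.directions[reg]

    def test_recovery_with_noise(self, expression_study):
        truth = expression_study["truth"]
        found = {r.regulator: r for r in expression_study["est"].regulons_}
        tp = set(found) & set(truth.regulons)
        precision = len(tp) / len(found)
        recall = len(tp) / len(truth.regulons)
        assert precision >= 0.9 and recall >= 0.9
        jaccards = [
            len(set(found[r].targets) & set(truth.regulons[r]))
            / len(set(found[r].targets) | set(truth.regulons[r]))
            for r in tp
        ]
        assert np.mean(jaccards) >= 0.8

    def test_decoy_regulators_rejected(self, expression_study):
        truth = expression_study["truth"]
        found = {r.regulator for r in expression_study["est"].regulons_}
        assert not (found & set(truth.decoy_regulators))

    def test_correlation_gate_holds_post_hoc(self, expression_study):
        est = expression_study["est"]
        for r in est.regulons_:
            assert r.correlation > est.r_threshold

    def test_invariant_to_gene_order(self, expression_study):
        z = expression_study["z"]
        shuffled = z.sample(frac=1.0, random_state=1)
        regulons = infer_regulons(shuffled, expression_study["response"],
                                  expression_study["prior"])
        base = {r.regulator: set(r.targets)
                for r in expression_study["est"].regulons_}
        new = {r.regulator: set(r.targets) for r in regulons}
        assert base == new

    def test_regulon_names_match_target_counts(self, expression_study):
        for r in expression_study["est"].regulons_:
            assert r.name == f"{r.regulator}.{len(r.targets)}"


class TestTFNetwork:
    def _regulon(self, reg, targets, direction="up"):
        idx = ["a", "b", "c"]
        series = pd.Series([0.0, 0.5, 1.0], index=idx)
        return Regulon(regulator=reg, targets=list(targets), correlation=0.9,
                       activity=series, activity_by_time=series,
                       direction=direction)

    def test_single_edge(self):
        G = build_tf_network([self._regulon("A", ["B", "g1"])], {"A", "B"})
        assert list(G.edges) == [("A", "B")]
        assert G.nodes["A"]["n_targets"] == 2
        assert G.nodes["A"]["direction"] == "up"

    def test_no_tf_targets_yields_no_edges(self):
        G = build_tf_network([self._regulon("A", ["g1", "g2"])], {"A"})
        assert G.number_of_edges() == 0

    def test_planted_cascade_recovered(self):
        from osteostage import PlantedRegulon, call_response_genes

        # cascade A -> B -> C with transcriptional delay: A switches first,
        # its targets (including TF B) follow, then B's targets (including
        # TF C); an unrelated late regulon D widens the population
        cfg = ExpressionSimConfig(
            n_genes=120,
            planted_regulons=[
                PlantedRegulon("A", ["B"] + [f"G{i:04d}" for i in range(8)],
                               "up", 3.0, switch_day=5.0, switch_width=2.5,
                               target_switch_day=11.0),
                PlantedRegulon("B", ["C"] + [f"G{i:04d}" for i in range(8, 16)],
                               "up", 3.0, switch_day=11.0, switch_width=2.5,
                               target_switch_day=17.0),
                PlantedRegulon("D", [f"G{i:04d}" for i in range(16, 26)],
                               "up", 3.0, switch_day=23.0, switch_width=2.5),
            ],
            decoy_regulators=0, noise_sd=0.05, seed=0)
        tpm, de, prior_df, tfs, metabolic, truth = simulate_expression(cfg)
        response = call_response_genes(de)
        z, _ = zscore_genes(np.log2(tpm + 1.0))
        prior = {reg: set(sub["target"])
                 for reg, sub in prior_df.groupby("regulator")}
        regulons = infer_regulons(z, response, prior)
        G = build_tf_network(regulons, set(tfs) | {"C"})
        assert G.has_edge("A", "B")
        assert G.has_edge("B", "C")
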