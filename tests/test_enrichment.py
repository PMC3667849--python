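"""Gene scores, quantile normalization, network enrichment and its null."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_expression, random_network
from pathcarc.enrichment import (
    EnrichmentResult,
    ExpressionMatrix,
    GeneScoreTable,
    PathwaySkipped,
    feature_vector,
    gene_scores,
    p_to_z,
    pathway_feature_matrix,
    permutation_pvalue,
    quantile_normalize,
    read_expression_tsv,
    sepea_nt3_score,
    sepea_score,
    write_expression_tsv,
)
from pathcarc.pathways import PathwayNetwork, node_weights, pairwise_distances


def expr_from_values(values, groups):
    genes = [f"g{i}" for i in range(len(values))]
    samples = [f"s{i}" for i in range(len(values[0]))]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.Series(groups, index=samples),
    )


class TestQuantileNormalize:
    def test_two_sample_rank_means(self):
        m = expr_from_values([[1, 4], [2, 5], [3, 6]], ["treated", "control"])
        out = quantile_normalize(m).values.to_numpy()
        assert out[:, 0].tolist() == [2.5, 3.5, 4.5]
        assert out[:, 1].tolist() == [2.5, 3.5, 4.5]

    def test_identical_columns_fixed_point(self):
        m = expr_from_values([[1, 1], [5, 5], [3, 3]], ["treated", "control"])
        out = quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out, m.values.to_numpy())

    def test_ties_get_mean_of_reference_span(self):
        # column 0 has a tie spanning ranks 1-2; reference = mean of sorted cols
        m = expr_from_values([[1, 10], [1, 20], [5, 30]], ["treated", "control"])
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)
        assert out[0, 0] == out[1, 0] == pytest.approx(ref[:2].mean())
        assert out[2, 0] == pytest.approx(ref[2])

    def test_column_multisets_become_identical(self, rng):
        vals = rng.normal(size=(20, 5))
        m = expr_from_values(vals, ["treated"] * 2 + ["control"] * 3)
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_single_sample_unchanged_with_warning(self):
        m = expr_from_values([[1.0], [2.0]], ["treated"])
        with pytest.warns(UserWarning, match="single sample"):
            out = quantile_normalize(m)
        assert out is m


def pooled_t_oracle(xt, xc):
    """Textbook pooled two-sample t, computed independently."""
    nt, nc = len(xt), len(xc)
    sp2 = ((nt - 1) * np.var(xt, ddof=1) + (nc - 1) * np.var(xc, ddof=1)) / (nt + nc - 2)
    return abs((np.mean(xt) - np.mean(xc)) / math.sqrt(sp2 * (1 / nt + 1 / nc)))


class TestGeneScores:
    def test_identical_groups_score_zero(self):
        m = expr_from_values(
            [[1, 2, 1, 2], [4, 4, 4, 4]], ["treated", "treated", "control", "control"]
        )
        table = gene_scores(m)
        assert table.get("g0") == 0.0
        assert table.get("g1") == 0.0

    def test_zero_variance_unequal_means_scores_table_max(self, rng):
        vals = rng.normal(size=(10, 6))
        vals[0] = [2, 2, 2, 0, 0, 0]  # degenerate: zero variance, unequal means
        m = expr_from_values(vals, ["treated"] * 3 + ["control"] * 3)
        table = gene_scores(m)
        finite = [table.get(f"g{i}") for i in range(1, 10)]
        assert table.get("g0") == pytest.approx(max(finite))

    def test_matches_textbook_oracle(self, rng):
        vals = rng.normal(size=(50, 7))
        m = expr_from_values(vals, ["treated"] * 3 + ["control"] * 4)
        table = gene_scores(m)
        for i in range(50):
            assert table.get(f"g{i}") == pytest.approx(
                pooled_t_oracle(vals[i, :3], vals[i, 3:])
            )

    def test_missing_group_raises_with_name(self):
        m = expr_from_values([[1, 2, 3]], ["treated", "treated", "treated"])
        with pytest.raises(ValueError, match="control"):
            gene_scores(m)


def direct_sepea_oracle(net, weights, dist, score_of):
    """Brute-force double-loop evaluation of the enrichment score."""
    nodes = sorted(net.nodes & set(score_of))
    s = {v: score_of[v] for v in nodes}
    first = sum(weights.weights[v] * s[v] for v in nodes) / sum(
        weights.weights[v] for v in nodes
    )
    num = den = 0.0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            d = dist.get(u, v)
            k = 0.0 if math.isinf(d) else 1.0 / (1.0 + d)
            num += s[u] * s[v] * k
            den += s[u] * s[v]
    second = 1.0 + num / den if den > 0 else 1.0
    return first * second


class TestSepeaScore:
    def test_equal_pair_at_distance_one(self):
        net = PathwayNetwork("P", "m", frozenset("AB"), frozenset([("A", "B")]))
        w = node_weights(net)
        d = pairwise_distances(net)
        c = 0.8
        table = GeneScoreTable({"A": c, "B": c}, frozenset("AB"))
        assert sepea_score(net, w, d, table) == pytest.approx(1.5 * c)

    def test_single_measured_node_convention(self, chain_net, chain_weights, chain_dist):
        table = GeneScoreTable({"B": 0.7}, frozenset(["B", "x", "y"]))
        assert sepea_score(chain_net, chain_weights, chain_dist, table) == pytest.approx(0.7)

    def test_matches_direct_summation_on_random_pathways(self, rng):
        for _ in range(30):
            net = random_network(rng, 6, p_edge=0.4)
            w = node_weights(net)
            d = pairwise_distances(net)
            score_of = {v: float(rng.uniform(0, 3)) for v in net.nodes}
            universe = set(score_of) | {f"extra{i}" for i in range(10)}
            table = GeneScoreTable(score_of, frozenset(universe))
            assert sepea_score(net, w, d, table) == pytest.approx(
                direct_sepea_oracle(net, w, d, score_of)
            )

    def test_no_measured_nodes_skips(self, chain_net, chain_weights, chain_dist):
        table = GeneScoreTable({"z": 1.0}, frozenset(["z"]))
        with pytest.raises(PathwaySkipped):
            sepea_score(chain_net, chain_weights, chain_dist, table)

    def test_mass_toward_terminus_raises_score(self, rng):
        # directed chain: moving score mass from the source to the terminus
        # must increase the enrichment score (terminus carries more weight)
        names = [f"n{i}" for i in range(5)]
        net = PathwayNetwork("P", "m", frozenset(names), frozenset(zip(names, names[1:])))
        w, d = node_weights(net), pairwise_distances(net)
        universe = frozenset(names)
        for _ in range(20):
            base = {v: float(rng.uniform(0.2, 2.0)) for v in names}
            moved = dict(base)
            mass = 0.5 * base[names[0]]
            moved[names[0]] -= mass
            moved[names[-1]] += mass
            lo = sepea_score(net, w, d, GeneScoreTable(base, universe))
            hi = sepea_score(net, w, d, GeneScoreTable(moved, universe))
            assert hi > lo


class TestSepeaNt3:
    def test_full_chain_coverage(self, chain_net, chain_weights, chain_dist):
        # pairs AB (d=1), BC (d=1), AC (d=2): 1 * (1 + (1/2 + 1/3 + 1/2)/3) = 13/9
        score = sepea_nt3_score(
            chain_net, chain_weights, chain_dist, {"A", "B", "C"}, {"A", "B", "C", "x"}
        )
        assert score == pytest.approx(13 / 9)

    def test_empty_intersection_skips(self, chain_net, chain_weights, chain_dist):
        with pytest.raises(PathwaySkipped):
            sepea_nt3_score(chain_net, chain_weights, chain_dist, {"q"}, {"A", "B", "C", "q"})

    def test_singleton_overlap_is_weight_share(self, chain_net, chain_weights, chain_dist):
        score = sepea_nt3_score(
            chain_net, chain_weights, chain_dist, {"C"}, {"A", "B", "C"}
        )
        w = chain_weights.weights
        assert score == pytest.approx(w["C"] / sum(w.values()))


class TestPToZ:
    def test_half_maps_to_zero(self):
        assert p_to_z(0.5) == 0.0

    def test_quantile_oracle(self):
        assert p_to_z(stats.norm.sf(2.0)) == pytest.approx(2.0)

    def test_smaller_p_larger_z(self):
        assert p_to_z(0.001) > p_to_z(0.01) > p_to_z(0.5) > p_to_z(0.9)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.0001, math.inf])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            p_to_z(bad)


class TestPermutationPValue:
    @pytest.fixture
    def setup(self, rng):
        net = random_network(rng, 6, p_edge=0.4, pathway_id="P")
        return net, node_weights(net), pairwise_distances(net)

    def test_all_scores_equal_gives_p_one_and_clamped_z(self, setup):
        net, w, d = setup
        universe = set(net.nodes) | {f"u{i}" for i in range(40)}
        table = GeneScoreTable({g: 1.0 for g in universe}, frozenset(universe))
        res = permutation_pvalue(net, w, d, table, K=199, seed=0)
        assert res.p_value == 1.0
        # z computed from p clamped to 1 - 1/(K+1)
        assert res.z == pytest.approx(stats.norm.isf(1.0 - 1.0 / 200))

    def test_dominant_pathway_reaches_p_floor(self, setup):
        net, w, d = setup
        universe = sorted(set(net.nodes) | {f"u{i}" for i in range(500)})
        scores = {g: 0.001 for g in universe}
        for g in net.nodes:
            scores[g] = 50.0  # all mass on the pathway: no null draw can match
        table = GeneScoreTable(scores, frozenset(universe))
        res = permutation_pvalue(net, w, d, table, K=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.z == pytest.approx(stats.norm.isf(1 / 1000))

    def test_p_invariant_under_positive_rescaling(self, setup, rng):
        net, w, d = setup
        universe = sorted(set(net.nodes) | {f"u{i}" for i in range(60)})
        scores = {g: float(rng.uniform(0, 2)) for g in universe}
        t1 = GeneScoreTable(scores, frozenset(universe))
        t2 = GeneScoreTable({g: 7.3 * s for g, s in scores.items()}, frozenset(universe))
        r1 = permutation_pvalue(net, w, d, t1, K=500, seed=7)
        r2 = permutation_pvalue(net, w, d, t2, K=500, seed=7)
        assert r1.p_value == r2.p_value

    def test_deterministic_given_seed(self, setup, rng):
        net, w, d = setup
        universe = sorted(set(net.nodes) | {f"u{i}" for i in range(60)})
        table = GeneScoreTable(
            {g: float(rng.uniform(0, 2)) for g in universe}, frozenset(universe)
        )
        r1 = permutation_pvalue(net, w, d, table, K=300, seed=3)
        r2 = permutation_pvalue(net, w, d, table, K=300, seed=3)
        assert (r1.p_value, r1.z) == (r2.p_value, r2.z)

    def test_small_k_rejected(self, setup):
        net, w, d = setup
        table = GeneScoreTable({g: 1.0 for g in net.nodes}, frozenset(net.nodes))
        with pytest.raises(ValueError, match="K"):
            permutation_pvalue(net, w, d, table, K=50)

    def test_nt3_mode_p_floor(self, setup):
        net, w, d = setup
        universe = sorted(set(net.nodes) | {f"u{i}" for i in range(800)})
        # gene set exactly = pathway nodes: observed is the densest possible hit
        res = permutation_pvalue(
            net, w, d,
            GeneScoreTable({}, frozenset(universe)),
            K=499, seed=2, gene_set=set(net.nodes),
        )
        assert res.p_value <= 5 / 500


class TestFeatureVector:
    def res(self, pid, z):
        return EnrichmentResult(pid, 1.0, 0.5, z, 100)

    def test_panel_order_and_skip_imputation(self):
        vec = feature_vector(["P1", "P2"], {"P1": self.res("P1", 1.2), "P2": None})
        np.testing.assert_array_equal(vec, [1.2, 0.0])

    def test_empty_panel(self):
        assert feature_vector([], {}).size == 0

    def test_result_order_irrelevant(self):
        results = {"P2": self.res("P2", -0.5), "P1": self.res("P1", 1.0)}
        np.testing.assert_array_equal(feature_vector(["P1", "P2"], results), [1.0, -0.5])


class TestBatchFeatureMatrix:
    def test_batch_matches_single_pathway_distribution(self, rng):
        # the batch builder and the per-pathway API share the same null model;
        # p-values for a strong signal must agree closely
        nets = {
            f"P{i}": random_network(rng, 8, 0.35, pathway_id=f"P{i}", prefix=f"P{i}_")
            for i in range(4)
        }
        universe = sorted({v for n in nets.values() for v in n.nodes} | {f"u{i}" for i in range(80)})
        scores = {g: float(rng.uniform(0, 1)) for g in universe}
        for g in nets["P0"].nodes:
            scores[g] = 8.0
        table = GeneScoreTable(scores, frozenset(universe))
        weights = {p: node_weights(n) for p, n in nets.items()}
        dists = {p: pairwise_distances(n) for p, n in nets.items()}
        X = pathway_feature_matrix(
            nets, weights, dists, {"chem": table}, ["P0", "P1", "P2", "P3"], K=400, seed=5
        )
        single = permutation_pvalue(nets["P0"], weights["P0"], dists["P0"], table, K=400, seed=5)
        assert X.loc["chem", "P0"] == pytest.approx(single.z, abs=0.2)
        assert X.loc["chem", "P0"] > 2.0
        assert abs(X.loc["chem", "P1"]) < 2.5

    def test_expression_round_trip(self, tmp_path, rng):
        m = make_expression(rng, n_genes=8)
        write_expression_tsv(m, tmp_path / "e.tsv", tmp_path / "g.tsv")
        back = read_expression_tsv(tmp_path / "e.tsv", tmp_path / "g.tsv")
        np.testing.assert_allclose(back.values.to_numpy(), m.values.to_numpy())
        assert list(back.groups) == list(m.groups)
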