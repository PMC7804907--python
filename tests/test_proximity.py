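import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_closest, build_interactome, random_interactome
from netprox import fixtures
from netprox.graphio import DrugTargetSet, GeneSet, load_interactome
from netprox.proximity import (
    DegreeBins,
    DistanceCache,
    closest_distance,
    closest_distance_detail,
    degree_matched_sample,
    overlap_metrics,
    pair_seed,
    proximity_z,
    screen,
    write_screen,
)


class TestClosestDistance:
    def test_identical_singleton_sets(self, path5):
        assert closest_distance(path5, {"N1"}, {"N1"}) == 0.0

    def test_identical_sets_are_distance_zero(self, path5):
        assert closest_distance(path5, {"N1", "N3"}, {"N1", "N3"}) == 0.0

    def test_path_graph_hand_value(self, path5):
        # A={1}: min to {4,5} is 3; B={4}: 3; B={5}: 4 -> (3+3+4)/3
        assert closest_distance(path5, {"N1"}, {"N4", "N5"}) == pytest.approx(10 / 3)

    def test_matches_floyd_warshall_oracle_on_random_graph(self):
        rng = np.random.default_rng(42)
        inter = random_interactome(rng, 12, 0.3)
        nodes = sorted(inter.nodes)
        a = set(nodes[:4])
        b = set(nodes[3:8])
        expected = brute_force_closest(inter, a, b)
        assert closest_distance(inter, a, b) == pytest.approx(expected)

    def test_symmetry(self, path5):
        a, b = {"N1", "N2"}, {"N4", "N5"}
        assert closest_distance(path5, a, b) == closest_distance(path5, b, a)

    def test_unreachable_genes_excluded_and_counted(self):
        inter = build_interactome([("A", "B"), ("X", "Y")])
        d, n_a, n_b = closest_distance_detail(inter, {"A", "X"}, {"B"})
        # X has no finite distance to B: drop from sum and normalizer
        assert (d, n_a, n_b) == (pytest.approx(2 / 2), 1, 0)

    def test_empty_input_vs_unmapped_distinguished(self, path5):
        with pytest.raises(ValueError, match="empty input"):
            closest_distance(path5, set(), {"N1"})
        with pytest.raises(ValueError, match="map"):
            closest_distance(path5, {"ZZZ"}, {"N1"})

    def test_fully_disconnected_pair_is_error(self):
        inter = build_interactome([("A", "B"), ("X", "Y")])
        with pytest.raises(ValueError, match="finite"):
            closest_distance(inter, {"A"}, {"X"})

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_oracle_on_small_random_graphs(self, seed):
        """Property sweep: exact agreement with an all-pairs oracle on graphs
        up to 25 nodes, for random overlapping / identical / disjoint sets."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 26))
        inter = random_interactome(rng, n, float(rng.uniform(0.1, 0.5)))
        nodes = sorted(inter.nodes)
        a = set(rng.choice(nodes, size=int(rng.integers(1, n)), replace=False))
        if rng.random() < 0.2:
            b = set(a)
        else:
            b = set(rng.choice(nodes, size=int(rng.integers(1, n)), replace=False))
        expected = brute_force_closest(inter, a, b)
        if expected is None:
            with pytest.raises(ValueError):
                closest_distance(inter, a, b)
        else:
            assert closest_distance(inter, a, b) == pytest.approx(expected)

    def test_gene_at_distance_zero_contributes_nothing(self, path5):
        # adding to A a gene already in B contributes a 0 term itself and can
        # only shrink other genes' nearest-neighbor terms
        # hand value: N1->3, N4->0 | N4->0, N5->1  => 4/4
        assert closest_distance(path5, {"N1", "N4"}, {"N4", "N5"}) == pytest.approx(1.0)
        base = closest_distance(path5, {"N1"}, {"N4", "N5"})
        assert closest_distance(path5, {"N1", "N4"}, {"N4", "N5"}) <= base


class TestDegreeMatchedSample:
    def test_template_of_all_nodes_returns_all_nodes(self, ba500):
        sample = degree_matched_sample(ba500, ba500.nodes, rng=0)
        assert sample == ba500.nodes

    def test_sample_size_preserved(self, ba500):
        rng = np.random.default_rng(5)
        nodes = sorted(ba500.nodes)
        for size in (1, 10, 50):
            template = set(rng.choice(nodes, size=size, replace=False))
            assert len(degree_matched_sample(ba500, template, rng)) == size

    def test_mean_degree_matches_template(self, ba500):
        """Monte-Carlo: over 1000 samples the mean degree of the samples
        tracks the template's mean degree within 3 standard errors."""
        rng = np.random.default_rng(11)
        bins = DegreeBins(ba500, min_bin_size=100)
        nodes = sorted(ba500.nodes)
        template = set(rng.choice(nodes, size=30, replace=False))
        t_mean = np.mean([ba500.degree(g) for g in template])
        means = np.array([
            np.mean([ba500.degree(g) for g in bins.sample_like(template, rng)])
            for _ in range(1000)
        ])
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - t_mean) <= 3 * se + 1e-9

    def test_small_graph_bins_merge_to_one(self, path5):
        bins = DegreeBins(path5, min_bin_size=100)
        assert len(bins.bins) == 1
        sample = degree_matched_sample(path5, {"N1", "N3"}, rng=0)
        assert len(sample) == 2 and sample <= path5.nodes

    def test_template_gene_outside_graph_is_error(self, path5):
        with pytest.raises(ValueError, match="not in the graph"):
            degree_matched_sample(path5, {"QQQ"}, rng=0)


class TestOverlapMetrics:
    @pytest.mark.parametrize(
        "a,b,c,j",
        [
            ({"x", "y"}, {"y", "z"}, 0.5, 1 / 3),
            ({"x", "y"}, {"x", "y"}, 1.0, 1.0),
            ({"x"}, {"y"}, 0.0, 0.0),
        ],
    )
    def test_hand_values(self, a, b, c, j):
        assert overlap_metrics(a, b) == (pytest.approx(c), pytest.approx(j))

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            overlap_metrics(set(), {"x"})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.sets(st.integers(0, 30), min_size=1, max_size=15),
        st.sets(st.integers(0, 30), min_size=1, max_size=15),
    )
    def test_jaccard_never_exceeds_overlap(self, a, b):
        c, j = overlap_metrics(a, b)
        assert 0 <= j <= c <= 1


class TestProximityZ:
    def test_self_pair_is_minimum_of_statistic(self, ba500):
        hub = max(ba500.nodes, key=ba500.degree)
        neigh = ba500.neighbors(hub)
        res = proximity_z(ba500, neigh, neigh, n_perm=100, rng_seed=0)
        assert res.d_observed == 0.0
        assert res.z < 0

    def test_reproducible_bit_for_bit(self, ba500):
        rng = np.random.default_rng(2)
        nodes = sorted(ba500.nodes)
        a = set(rng.choice(nodes, size=8, replace=False))
        b = set(rng.choice(nodes, size=20, replace=False))
        r1 = proximity_z(ba500, a, b, n_perm=50, rng_seed=123)
        r2 = proximity_z(ba500, a, b, n_perm=50, rng_seed=123)
        assert r1 == r2

    def test_significance_flag_definition(self, screen_fixture):
        inter = load_interactome(screen_fixture["graph"])
        drugs, sets = fixtures.screen_fixture_objects(screen_fixture)
        df = screen(inter, drugs, sets, n_perm=200, rng_seed=3)
        expected = (df["z"] < -1.5) & (df["p"] < 0.05)
        assert (df["significant"] == expected).all()

    def test_degenerate_null_flagged(self):
        # both templates cover every node, so each permutation resamples the
        # full node set: every permuted distance is 0 -> sd 0 -> z = 0, flagged
        inter = build_interactome(
            [(f"N{i}", f"N{j}") for i in range(4) for j in range(i + 1, 4)]
        )
        res = proximity_z(inter, inter.nodes, inter.nodes, n_perm=20, rng_seed=0)
        assert res.degenerate_null and res.z == 0.0

    def test_null_self_calibration(self, ba500):
        """Degree-matched random pairs should give mean z near 0."""
        rng = np.random.default_rng(9)
        bins = DegreeBins(ba500, min_bin_size=100)
        cache = DistanceCache(ba500)
        nodes = sorted(ba500.nodes)
        zs = []
        for rep in range(200):
            a = degree_matched_sample(ba500, set(rng.choice(nodes, 10, replace=False)), rng, bins)
            b = degree_matched_sample(ba500, set(rng.choice(nodes, 30, replace=False)), rng, bins)
            res = proximity_z(
                ba500, a, b, n_perm=200, rng_seed=int(rng.integers(2**31)),
                cache=cache, bins=bins,
            )
            zs.append(res.z)
        assert abs(np.mean(zs)) <= 0.3

    def test_planted_module_recovered(self, screen_fixture):
        inter = load_interactome(screen_fixture["graph"])
        drugs, sets = fixtures.screen_fixture_objects(screen_fixture)
        planted_drug = next(d for d in drugs if d.drug_id == "DRUG0")
        planted_set = next(s for s in sets if s.set_id == "MOD0")
        res = proximity_z(
            inter, planted_drug.targets, planted_set.genes, n_perm=1000, rng_seed=0
        )
        assert res.z < -1.5 and res.p < 0.05 and res.significant

    def test_monotone_p_across_n_perm(self, screen_fixture):
        """A clearly separated planted pair stays on the significant side of
        0.05 as the permutation count grows."""
        inter = load_interactome(screen_fixture["graph"])
        drugs, sets = fixtures.screen_fixture_objects(screen_fixture)
        a = next(d for d in drugs if d.drug_id == "DRUG0").targets
        b = next(s for s in sets if s.set_id == "MOD0").genes
        for n_perm in (200, 500, 1000):
            res = proximity_z(inter, a, b, n_perm=n_perm, rng_seed=4)
            assert res.p < 0.05 and res.z < -1.5


class TestScreen:
    def test_single_pair_matches_direct_call(self, ba500):
        rng = np.random.default_rng(6)
        nodes = sorted(ba500.nodes)
        drug = DrugTargetSet("D1", frozenset(rng.choice(nodes, 5, replace=False)))
        gs = GeneSet("S1", "set", frozenset(rng.choice(nodes, 12, replace=False)))
        df = screen(ba500, [drug], [gs], n_perm=100, rng_seed=77)
        direct = proximity_z(
            ba500, drug.targets, gs.genes, n_perm=100,
            rng_seed=pair_seed(77, "D1", "S1"), drug_id="D1", set_id="S1",
        )
        row = df.iloc[0]
        assert row["z"] == direct.z
        assert row["p"] == direct.p
        assert row["d_observed"] == direct.d_observed

    def test_row_order_independence(self, ba500):
        rng = np.random.default_rng(8)
        nodes = sorted(ba500.nodes)
        drugs = [
            DrugTargetSet(f"D{i}", frozenset(rng.choice(nodes, 5, replace=False)))
            for i in range(3)
        ]
        sets = [GeneSet("S1", "s", frozenset(rng.choice(nodes, 10, replace=False)))]
        df_fwd = screen(ba500, drugs, sets, n_perm=50, rng_seed=5)
        df_rev = screen(ba500, list(reversed(drugs)), sets, n_perm=50, rng_seed=5)
        merged = df_fwd.set_index("drug_id")[["z", "p"]].join(
            df_rev.set_index("drug_id")[["z", "p"]], rsuffix="_rev"
        )
        assert (merged["z"] == merged["z_rev"]).all()
        assert (merged["p"] == merged["p_rev"]).all()

    def test_planted_screen_flags_exactly_one_pair(self, screen_fixture):
        inter = load_interactome(screen_fixture["graph"])
        drugs, sets = fixtures.screen_fixture_objects(screen_fixture)
        df = screen(inter, drugs, sets, n_perm=1000, rng_seed=1)
        sig = df[df["significant"]]
        assert [(r["drug_id"], r["set_id"]) for _, r in sig.iterrows()] == [("DRUG0", "MOD0")]
        assert sig.iloc[0]["drug_n_significant"] == 1

    def test_same_seed_rerun_byte_identical(self, ba500, tmp_path):
        rng = np.random.default_rng(10)
        nodes = sorted(ba500.nodes)
        drugs = [DrugTargetSet("D1", frozenset(rng.choice(nodes, 5, replace=False)))]
        sets = [GeneSet("S1", "s", frozenset(rng.choice(nodes, 10, replace=False)))]
        paths = []
        for i in (1, 2):
            df = screen(ba500, drugs, sets, n_perm=100, rng_seed=99)
            p = tmp_path / f"run{i}.tsv"
            write_screen(df, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_unmappable_pair_skipped_and_reported(self, path5):
        drugs = [
            DrugTargetSet("DIN", frozenset({"N1"})),
            DrugTargetSet("DOUT", frozenset({"ZZZ"})),
        ]
        sets = [GeneSet("S1", "s", frozenset({"N4"}))]
        df = screen(path5, drugs, sets, n_perm=20, rng_seed=0)
        assert list(df["drug_id"]) == ["DIN"]
        skipped = df.attrs["skipped"]
        assert len(skipped) == 1
        assert skipped[0]["drug_id"] == "DOUT"
        assert skipped[0]["n_targets_unmapped"] == 1

    def test_output_column_order_documented(self, path5):
        drugs = [DrugTargetSet("D", frozenset({"N1"}))]
        sets = [GeneSet("S", "s", frozenset({"N4"}))]
        df = screen(path5, drugs, sets, n_perm=10, rng_seed=0)
        assert list(df.columns[:2]) == ["drug_id", "set_id"]
        assert "error" in df.columns and "drug_n_significant" in df.columns
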