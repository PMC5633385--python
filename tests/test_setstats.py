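import math
import random

import networkx as nx
import pytest

from clusterkin.formats_io import Cluster, ClusterCollection
from clusterkin.model import TaxonSet
from clusterkin.setstats import (
    RepresentationTestResult,
    cooccurrence_graph,
    log2fc_percentile,
    rarefaction_curve,
    representation_test,
    size_histogram_and_powerlaw,
    volcano_table,
)

from .oracles import mwu_exact_two_sided


def _cluster_from_counts(cid, counts):
    members = {}
    k = 0
    for p, c in counts.items():
        if c:
            members[p] = tuple(f"{p}_{cid}_{k + j}" for j in range(c))
            k += c
    return Cluster(cid, members)


class TestRarefaction:
    def test_toy_endpoint_is_nonsingleton_count(self, toy3):
        ts = TaxonSet("all", "all", frozenset({"A", "B", "C"}))
        res = rarefaction_curve(toy3.clusters, ts, reps=10, seed=5)
        assert all(v == 4 for v in res.curve[3])  # OG0, OG1, OG2, OG4

    def test_single_proteome_set(self, toy3):
        ts = TaxonSet("TAXON", "C", frozenset({"C"}))
        res = rarefaction_curve(toy3.clusters, ts, reps=3, seed=0)
        assert list(res.curve) == [1]
        # C appears in nonsingletons OG0 and OG4 only
        assert all(v == 2 for v in res.curve[1])

    def test_curves_nondecreasing_within_repetition(self, bundle):
        ts = TaxonSet("all", "all", frozenset(bundle.attrs.proteomes))
        res = rarefaction_curve(bundle.clusters, ts, reps=5, seed=3)
        ks = sorted(res.curve)
        for rep in range(5):
            values = [res.curve[k][rep] for k in ks]
            assert values == sorted(values)

    def test_endpoint_identity_every_repetition(self, bundle):
        for level, members in bundle.attrs.levels("habitat").items():
            ts = TaxonSet("habitat", level, frozenset(members))
            res = rarefaction_curve(bundle.clusters, ts, reps=8, seed=1)
            expected = sum(1 for c in bundle.clusters
                           if c.size > 1 and c.proteomes & ts.proteomes)
            assert all(v == expected for v in res.curve[len(ts)])

    def test_seed_determinism(self, bundle):
        ts = TaxonSet("all", "all", frozenset(bundle.attrs.proteomes))
        a = rarefaction_curve(bundle.clusters, ts, reps=6, seed=42)
        b = rarefaction_curve(bundle.clusters, ts, reps=6, seed=42)
        c = rarefaction_curve(bundle.clusters, ts, reps=6, seed=43)
        assert a.curve == b.curve
        assert a.curve != c.curve


SET_A = TaxonSet("g", "a", frozenset({"A1", "A2", "A3"}))
SET_B = TaxonSet("g", "b", frozenset({"B1", "B2", "B3"}))


def _rep(counts_a, counts_b, method="mwu"):
    counts = dict(zip(sorted(SET_A.proteomes), counts_a))
    counts.update(zip(sorted(SET_B.proteomes), counts_b))
    return representation_test(_cluster_from_counts("X", counts),
                               SET_A, SET_B, method)


class TestRepresentationTest:
    def test_exact_mwu_p_point_one(self):
        res = _rep([1, 1, 2], [5, 6, 7])
        assert res.pvalue == pytest.approx(0.1, abs=1e-12)
        # and against the independent enumeration oracle
        assert mwu_exact_two_sided([1, 1, 2], [5, 6, 7]) == \
            pytest.approx(0.1, abs=1e-12)

    def test_log2fc_closed_form(self):
        res = _rep([1, 1, 2], [5, 6, 7])
        assert res.log2fc == pytest.approx(math.log2((4 / 3) / 6), abs=1e-9)
        assert res.log2fc == pytest.approx(-2.1699, abs=1e-4)

    def test_identical_counts_degenerate(self):
        two_a = TaxonSet("g", "a", frozenset({"A1", "A2"}))
        two_b = TaxonSet("g", "b", frozenset({"B1", "B2"}))
        cluster = _cluster_from_counts(
            "X", {"A1": 2, "A2": 2, "B1": 2, "B2": 2})
        res = representation_test(cluster, two_a, two_b)
        assert res.log2fc == 0.0
        assert res.pvalue == 1.0

    def test_swap_flips_log2fc_and_keeps_p(self):
        res_ab = _rep([1, 1, 2], [5, 6, 7])
        counts = dict(zip(sorted(SET_A.proteomes), [1, 1, 2]))
        counts.update(zip(sorted(SET_B.proteomes), [5, 6, 7]))
        res_ba = representation_test(_cluster_from_counts("X", counts),
                                     SET_B, SET_A)
        assert res_ba.log2fc == pytest.approx(-res_ab.log2fc)
        assert res_ba.pvalue == pytest.approx(res_ab.pvalue)

    def test_absent_side_skipped(self):
        res = _rep([1, 2, 1], [0, 0, 0])
        assert res is None

    def test_zero_counts_carry_depletion_signal(self):
        res = _rep([2, 2, 2], [0, 0, 1])
        assert res.counts_b == (0, 0, 1)
        assert res.mean_b == pytest.approx(1 / 3)

    def test_small_set_pvalue_na(self):
        one = TaxonSet("g", "a", frozenset({"A1"}))
        res = representation_test(
            _cluster_from_counts("X", {"A1": 2, "B1": 1, "B2": 3}),
            one, TaxonSet("g", "b", frozenset({"B1", "B2"})))
        assert res.pvalue is None

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown test method"):
            _rep([1, 1, 2], [5, 6, 7], method="bayes")

    @pytest.mark.parametrize("method", ["welch", "student"])
    def test_t_variants_run(self, method):
        res = _rep([1, 1, 2], [5, 6, 7], method=method)
        assert 0.0 < res.pvalue < 0.05

    def test_asymptotic_close_to_exact_for_n8(self):
        """Normal approximation with continuity correction stays within
        0.02 of full enumeration at n1 = n2 = 8."""
        rng = random.Random(4)
        for _ in range(5):
            pooled = rng.sample(range(1, 100), 16)
            a, b = pooled[:8], pooled[8:]
            import scipy.stats as stats
            asym = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic",
                                      use_continuity=True).pvalue
            exact = mwu_exact_two_sided(a, b)
            assert abs(asym - exact) < 0.02


class TestVolcano:
    def _result(self, cid, log2fc, p):
        return RepresentationTestResult(cid, "a", "b", (1,), (1,),
                                        1.0, 1.0, log2fc, p, "mwu")

    def test_rows_sorted_by_pvalue(self, tmp_path):
        results = [self._result("c1", 0.5, 0.2),
                   self._result("c2", 1.0, 0.04),
                   self._result("c3", -2.0, 0.005)]
        out = volcano_table(results, tmp_path / "v.tsv")
        assert [r.cluster_id for r in out] == ["c3", "c2", "c1"]
        rows = (tmp_path / "v.tsv").read_text().splitlines()[1:]
        assert [r.split("\t")[0] for r in rows] == ["c3", "c2", "c1"]

    def test_constant_fold_changes_pin_percentile(self):
        results = [self._result(f"c{i}", 1.25, 0.5) for i in range(10)]
        assert log2fc_percentile(results) == pytest.approx(1.25)

    def test_percentile_of_uniform_grid(self):
        # |log2fc| on the 100-point grid 0.02, 0.04, ..., 2.00: the 95th
        # percentile under linear interpolation is 1.901
        results = [self._result(f"c{i}", 0.02 * (i + 1), 0.5)
                   for i in range(100)]
        assert log2fc_percentile(results) == pytest.approx(1.901, abs=1e-9)

    def test_plot_written(self, tmp_path):
        results = [self._result(f"c{i}", (-1) ** i * (0.1 + i / 10),
                                0.05 / (i + 1)) for i in range(20)]
        volcano_table(results, tmp_path / "v.tsv", tmp_path / "v.png")
        assert (tmp_path / "v.png").stat().st_size > 0


class TestSizeHistogram:
    def test_exact_power_law_recovered(self):
        hist = size_histogram_and_powerlaw({1: 16, 2: 4, 4: 1})
        assert hist.gamma == pytest.approx(2.0, abs=1e-9)

    def test_toy_histogram(self, toy3):
        hist = size_histogram_and_powerlaw(toy3.clusters)
        assert dict(hist.counts) == {1: 2, 2: 2, 3: 2}

    def test_breakdown_by_proteome_count(self, toy3):
        hist = size_histogram_and_powerlaw(toy3.clusters)
        assert hist.by_proteome_count[3] == {3: 2}
        assert hist.by_proteome_count[2] == {1: 1, 2: 1}
        assert sum(hist.counts.values()) == len(toy3.clusters)

    def test_single_size_no_fit(self):
        hist = size_histogram_and_powerlaw({5: 7})
        assert hist.powerlaw is None


class TestCooccurrence:
    def test_toy_weights(self, toy3):
        g = cooccurrence_graph(toy3.clusters)
        assert g["A"]["B"]["weight"] == 3
        assert g["A"]["C"]["weight"] == 2
        g2 = cooccurrence_graph(toy3.clusters, exclude_universal=True)
        assert g2["A"]["B"]["weight"] == 1
        assert not g2.has_edge("A", "C")

    def test_singletons_contribute_no_edges(self, toy3):
        g = cooccurrence_graph(toy3.clusters)
        assert g.degree("C") == 2  # edges to A and B only, via OG0/OG4

    def test_weight_bounded_by_shared_cluster_counts(self, bundle):
        g = cooccurrence_graph(bundle.clusters)
        n_with = {p: sum(1 for c in bundle.clusters if p in c.proteomes)
                  for p in bundle.attrs.proteomes}
        for u, v, w in g.edges.data("weight"):
            assert w <= min(n_with[u], n_with[v])

    def test_graphml_round_trip(self, toy3, tmp_path):
        g = cooccurrence_graph(toy3.clusters)
        nx.write_graphml(g, tmp_path / "g.graphml")
        g2 = nx.read_graphml(tmp_path / "g.graphml")
        assert g2["A"]["B"]["weight"] == 3
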