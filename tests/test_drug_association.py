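import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmclust import (
    CellLineClustering,
    DrugResponseTable,
    cluster_drug_association,
    compare_partitions,
    pseudo_f,
    robust_associations,
    transform_sensitivity,
)
from pharmclust.concordance import ClusterMatch
from pharmclust.drug_association import AssociationResult, SensitivityVector


def vector(values, drug="d", samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or tuple(f"s{i}" for i in range(len(values)))
    return SensitivityVector(drug_id=drug, sample_ids=tuple(samples),
                             values=values, source_metric="ic50_uM")


def pseudo_f_oracle(values, labels):
    """Plain-Python variance decomposition, standard CH degrees of freedom."""
    groups = {}
    for v, l in zip(values, labels):
        groups.setdefault(l, []).append(v)
    n, k = len(values), len(groups)
    grand = sum(values) / n
    between = sum(len(g) * (sum(g) / len(g) - grand) ** 2
                  for g in groups.values())
    within = sum((v - sum(g) / len(g)) ** 2
                 for g in groups.values() for v in g)
    return (between / (k - 1)) / (within / (n - k))


class TestTransform:
    def test_ic50_one_micromolar_maps_to_six(self):
        table = DrugResponseTable(
            values=pd.DataFrame([[1.0, 0.01]], index=["d"], columns=["s1", "s2"]),
            metric="ic50_uM", orientation="high_is_resistant",
        )
        (v,) = transform_sensitivity(table)
        assert v.values[0] == pytest.approx(6.0)
        assert v.values[1] == pytest.approx(8.0)

    def test_mean_viability_complement(self):
        table = DrugResponseTable(
            values=pd.DataFrame([[0.25]], index=["d"], columns=["s"]),
            metric="mean_viability", orientation="high_is_resistant",
        )
        (v,) = transform_sensitivity(table)
        assert v.values[0] == pytest.approx(0.75)

    def test_auc_flip_only_when_resistant_oriented(self):
        values = pd.DataFrame([[0.2]], index=["d"], columns=["s"])
        keep = transform_sensitivity(DrugResponseTable(
            values=values, metric="auc", orientation="high_is_sensitive"))
        flip = transform_sensitivity(DrugResponseTable(
            values=values, metric="auc", orientation="high_is_resistant"))
        assert keep[0].values[0] == pytest.approx(0.2)
        assert flip[0].values[0] == pytest.approx(0.8)

    def test_nonpositive_ic50_rejected(self):
        table = DrugResponseTable(
            values=pd.DataFrame([[0.0]], index=["d"], columns=["s"]),
            metric="ic50_uM", orientation="high_is_resistant",
        )
        with pytest.raises(ValueError, match="'d'"):
            transform_sensitivity(table)

    def test_missing_stays_missing(self):
        table = DrugResponseTable(
            values=pd.DataFrame([[1.0, np.nan]], index=["d"],
                                columns=["s1", "s2"]),
            metric="ic50_uM", orientation="high_is_resistant",
        )
        (v,) = transform_sensitivity(table)
        assert np.isnan(v.values[1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-30, 40), min_size=2, max_size=10, unique=True))
    def test_strictly_decreasing_in_ic50(self, tenth_log_ic50s):
        ic50s = [10.0 ** (e / 10.0) for e in tenth_log_ic50s]
        table = DrugResponseTable(
            values=pd.DataFrame([sorted(ic50s)], index=["d"],
                                columns=[f"s{i}" for i in range(len(ic50s))]),
            metric="ic50_uM", orientation="high_is_resistant",
        )
        (v,) = transform_sensitivity(table)
        assert (np.diff(v.values) < 0).all()


class TestPseudoF:
    def test_hand_decomposition(self):
        # between-SS 100, within-SS 1, N=4, K=2
        v = vector([0, 1, 10, 11])
        part = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        rep = pseudo_f(v, part)
        assert rep.pseudo_f == pytest.approx(200.0)
        assert rep.pseudo_f_as_printed == pytest.approx(50.0)
        assert (rep.n, rep.k) == (4, 2)

    def test_no_separation_is_zero(self):
        v = vector([5, 5, 5, 5])
        rep = pseudo_f(v, {"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        assert rep.pseudo_f == 0.0

    def test_perfect_separation_flagged_infinite(self):
        v = vector([0, 0, 10, 10])
        rep = pseudo_f(v, {"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        assert rep.infinite and np.isinf(rep.pseudo_f)

    def test_single_group_rejected(self):
        v = vector([1, 2, 3])
        with pytest.raises(ValueError, match="2 groups"):
            pseudo_f(v, {"s0": "A", "s1": "A", "s2": "A"})

    def test_missing_dropped_listwise(self):
        v = vector([0, 1, np.nan, 10, 11])
        part = {f"s{i}": l for i, l in enumerate("AABBB")}
        rep = pseudo_f(v, part)
        assert rep.n == 4

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(6, 40)
            k = rng.integers(2, 5)
            labels = rng.integers(0, k, size=n)
            labels[:k] = np.arange(k)  # every group non-empty
            values = rng.normal(0, 3, size=n)
            v = vector(values)
            part = {f"s{i}": str(l) for i, l in enumerate(labels)}
            rep = pseudo_f(v, part)
            expected = pseudo_f_oracle(list(values), list(labels))
            assert abs(rep.pseudo_f - expected) <= 1e-10 * max(1, abs(expected))

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=20)
        labels = rng.integers(0, 3, size=20)
        labels[:3] = [0, 1, 2]
        part = {f"s{i}": str(l) for i, l in enumerate(labels)}
        base = pseudo_f(vector(values), part).pseudo_f
        shifted = pseudo_f(vector(values + 100), part).pseudo_f
        scaled = pseudo_f(vector(values * 7.5), part).pseudo_f
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)


def planted_vectors(truth_labels, effect_map, rng, n_drugs=8):
    """Drug vectors whose affected group is shifted by the mapped effect."""
    samples = tuple(truth_labels)
    vectors = []
    for d in range(n_drugs):
        group, shift = effect_map[d % len(effect_map)]
        mu = {s: (shift if truth_labels[s] == group else 0.0) for s in samples}
        values = np.array([mu[s] + rng.normal() for s in samples])
        vectors.append(vector(values, drug=f"d{d}", samples=samples))
    return vectors


class TestComparePartitions:
    def _setup(self, align="cluster", seed=0):
        rng = np.random.default_rng(seed)
        n = 120
        samples = [f"s{i}" for i in range(n)]
        cluster = {s: f"C{rng.integers(4)}" for s in samples}
        tissue = {s: f"T{rng.integers(4)}" for s in samples}
        labels = cluster if align == "cluster" else tissue
        effects = [(f"{'C' if align == 'cluster' else 'T'}{g}", 2.0)
                   for g in range(4)]
        vectors = planted_vectors(labels, effects, rng)
        clustering = CellLineClustering(
            sample_ids=tuple(samples),
            labels=tuple(cluster[s] for s in samples),
        )
        return vectors, clustering, tissue

    def test_cluster_aligned_effects_favor_clustering(self):
        vectors, clustering, tissue = self._setup("cluster")
        df = compare_partitions(vectors, clustering, tissue)
        assert df["clustering_wins"].mean() >= 0.8

    def test_tissue_aligned_effects_reverse_the_outcome(self):
        vectors, clustering, tissue = self._setup("tissue")
        df = compare_partitions(vectors, clustering, tissue)
        assert df["clustering_wins"].mean() <= 0.2

    def test_single_drug_t_test_not_applicable(self):
        vectors, clustering, tissue = self._setup("cluster")
        df = compare_partitions(vectors[:1], clustering, tissue)
        assert len(df) == 1
        assert np.isnan(df.attrs["paired_t"])


class TestAssociation:
    def _clustering(self, n, rng, k=4):
        samples = [f"s{i}" for i in range(n)]
        labels = [f"C{rng.integers(k)}" for _ in samples]
        return CellLineClustering(sample_ids=tuple(samples),
                                  labels=tuple(labels))

    def test_planted_shift_called_with_correct_phenotype(self):
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            cl = self._clustering(100, rng)
            members = set(cl.members("C0"))
            values = np.array([
                2.0 + rng.normal() if s in members else rng.normal()
                for s in cl.sample_ids
            ])
            res = cluster_drug_association(
                [vector(values, samples=cl.sample_ids)], cl)
            called = {(r.cluster, r.phenotype) for r in res
                      if r.adjusted_p < 0.05}
            hits += ("C0", "sensitive") in called
        assert hits / n_rep >= 0.95

    def test_null_data_rarely_significant(self):
        n_sig = n_tests = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            cl = self._clustering(60, rng)
            vectors = [vector(rng.normal(size=60), drug=f"d{j}",
                              samples=cl.sample_ids) for j in range(5)]
            res = cluster_drug_association(vectors, cl)
            n_tests += len(res)
            n_sig += sum(r.adjusted_p < 0.05 for r in res)
        assert n_sig / n_tests <= 0.05

    def test_undersized_cluster_skipped(self):
        samples = tuple(f"s{i}" for i in range(20))
        labels = ("tiny", "tiny") + ("big",) * 18
        cl = CellLineClustering(sample_ids=samples, labels=labels)
        rng = np.random.default_rng(0)
        res = cluster_drug_association(
            [vector(rng.normal(size=20), samples=samples)], cl)
        assert {r.cluster for r in res} == set()  # both sides undersized

    def test_phenotype_sign_contract(self):
        with pytest.raises(ValueError, match="sign"):
            AssociationResult(drug_id="d", cluster="c", t_statistic=2.0,
                              p_value=0.01, adjusted_p=0.02,
                              phenotype="resistant", n_in=5, n_out=5)


class TestRobust:
    def _assoc(self, drug, cluster, t, q=0.01):
        return AssociationResult(
            drug_id=drug, cluster=cluster, t_statistic=t, p_value=q / 2,
            adjusted_p=q, phenotype="sensitive" if t > 0 else "resistant",
            n_in=10, n_out=30,
        )

    def _identity_match(self, labels):
        return ClusterMatch(mapping={l: l for l in labels},
                            unmatched_a=(), unmatched_b=(),
                            overlap={(l, l): 10 for l in labels})

    def test_identical_inputs_intersect_fully(self):
        res = [self._assoc("d1", "C1", 3.0), self._assoc("d2", "C2", -2.5),
               self._assoc("d3", "C1", 1.0, q=0.5)]
        df = robust_associations(res, res, self._identity_match(["C1", "C2"]))
        assert set(df["drug_id"]) == {"d1", "d2"}

    def test_opposite_signs_excluded(self):
        a = [self._assoc("d1", "C1", 3.0)]
        b = [self._assoc("d1", "C1", -3.0)]
        df = robust_associations(a, b, self._identity_match(["C1"]))
        assert df.empty

    def test_unmatched_clusters_counted(self):
        a = [self._assoc("d1", "C9", 3.0)]
        b = [self._assoc("d1", "C1", 3.0)]
        df = robust_associations(a, b, self._identity_match(["C1"]))
        assert df.empty
        assert df.attrs["n_unmatched"] == 1

    def test_mapped_relabeling(self):
        a = [self._assoc("d1", "A1", 3.0)]
        b = [self._assoc("d1", "B7", 2.0)]
        match = ClusterMatch(mapping={"A1": "B7"}, unmatched_a=(),
                             unmatched_b=(), overlap={("A1", "B7"): 10})
        df = robust_associations(a, b, match)
        assert list(df["cluster_b"]) == ["B7"]
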