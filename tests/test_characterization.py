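import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pharmclust import (
    CellLineClustering,
    GeneModule,
    MutationMatrix,
    call_breast_subtypes,
    classify_emt,
    differential_expression,
    gsea_enrichment_score,
    mutation_enrichment,
    preranked_gsea,
)

from conftest import expr_from_array


def fisher_tail_oracle(a, b, c, d):
    """One-tailed (enrichment) Fisher p by hypergeometric enumeration.

    Table rows: (mutated, unmutated) x (in cluster, out of cluster) =
    [[a, b], [c, d]].  p = P(X >= a) for X hypergeometric with
    population a+b+c+d, successes a+c, draws a+b.
    """
    n = a + b + c + d
    successes = a + c
    draws = a + b
    p = 0.0
    for x in range(a, min(successes, draws) + 1):
        if draws - x > n - successes:
            continue
        p += (math.comb(successes, x) * math.comb(n - successes, draws - x)
              / math.comb(n, draws))
    return p


def bh_oracle(pvals):
    """Sorted-definition BH: adjusted_i = min over j >= i of p_(j) * m / j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = running
    return adjusted


def es_oracle(scores, member):
    """Brute-force weighted running-sum enrichment score (w = 1)."""
    hit_total = sum(abs(s) for s, m in zip(scores, member) if m)
    n_miss = sum(1 for m in member if not m)
    running, best = 0.0, 0.0
    for s, m in zip(scores, member):
        if m:
            running += (abs(s) / hit_total) if hit_total > 0 else 1.0 / (
                len(scores) - n_miss)
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def clustering_for(samples, members):
    labels = ["in" if s in members else "out" for s in samples]
    return CellLineClustering(sample_ids=tuple(samples), labels=tuple(labels))


class TestDifferentialExpression:
    def test_planted_shift_ranks_first(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            arr = rng.normal(0, 1, size=(30, 24))
            arr[5, :8] += 3.0  # gene g5 up in the first 8 samples
            expr = expr_from_array(arr)
            cl = clustering_for(expr.sample_ids, set(expr.sample_ids[:8]))
            res = differential_expression(expr, cl, "in")
            assert res[0].gene_id == "g5"
            assert res[0].t_statistic > 0

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(1)
        expr = expr_from_array(rng.normal(0, 1, size=(600, 40)))
        cl = clustering_for(expr.sample_ids, set(expr.sample_ids[:20]))
        res = differential_expression(expr, cl, "in")
        ks = stats.kstest([r.p_value for r in res], "uniform")
        assert ks.pvalue > 0.01

    def test_ranking_is_permutation(self):
        rng = np.random.default_rng(2)
        expr = expr_from_array(rng.normal(size=(15, 12)))
        cl = clustering_for(expr.sample_ids, set(expr.sample_ids[:5]))
        res = differential_expression(expr, cl, "in")
        assert sorted(r.rank for r in res) == list(range(15))
        ts = [r.t_statistic for r in sorted(res, key=lambda r: r.rank)]
        assert ts == sorted(ts, reverse=True)

    def test_tiny_cluster_rejected(self):
        rng = np.random.default_rng(3)
        expr = expr_from_array(rng.normal(size=(5, 10)))
        cl = clustering_for(expr.sample_ids, {expr.sample_ids[0]})
        with pytest.raises(ValueError, match="insufficient replicates"):
            differential_expression(expr, cl, "in")


class TestGsea:
    def test_es_matches_brute_force_top_block(self):
        scores = np.array([5.0, 5.0, 5.0, -1, -1, -1, -1, -1, -1, -1])
        member = np.array([True] * 3 + [False] * 7)
        assert gsea_enrichment_score(scores, member) == pytest.approx(
            es_oracle(scores, member)
        )

    def test_es_matches_brute_force_random_lists(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 21)
            scores = rng.normal(0, 2, size=n)
            member = np.zeros(n, dtype=bool)
            member[rng.choice(n, size=rng.integers(1, n), replace=False)] = True
            assert gsea_enrichment_score(scores, member) == pytest.approx(
                es_oracle(scores, member), abs=1e-12
            )

    def test_null_module_placement_rarely_significant(self):
        rng = np.random.default_rng(5)
        n = 60
        scores = np.sort(rng.normal(size=n))[::-1]
        from pharmclust.characterization import DeResult
        ranked = [DeResult(gene_id=f"g{i}", t_statistic=float(s),
                           p_value=0.5, cluster="c", rank=i)
                  for i, s in enumerate(scores)]
        n_sig = 0
        n_rep = 50
        for rep in range(n_rep):
            genes = frozenset(
                f"g{i}" for i in rng.choice(n, size=10, replace=False)
            )
            res = preranked_gsea(ranked, GeneModule("m", genes),
                                 n_permutations=200, seed=rep)
            n_sig += res.p_value <= 0.05
        assert n_sig / n_rep <= 0.10

    def test_module_equal_to_whole_list_rejected(self):
        from pharmclust.characterization import DeResult
        ranked = [DeResult(f"g{i}", float(-i), 0.5, "c", i) for i in range(5)]
        with pytest.raises(ValueError):
            preranked_gsea(ranked, GeneModule("m", frozenset(
                f"g{i}" for i in range(5))), n_permutations=10)

    def test_direction_follows_sign(self):
        from pharmclust.characterization import DeResult
        ranked = [DeResult(f"g{i}", float(10 - i), 0.5, "c", i)
                  for i in range(10)]
        top = preranked_gsea(ranked, GeneModule("m", frozenset(["g0", "g1"])),
                             n_permutations=50, seed=0)
        bottom = preranked_gsea(ranked, GeneModule("m", frozenset(["g8", "g9"])),
                                n_permutations=50, seed=0)
        assert top.es > 0 and top.direction == "up"
        assert bottom.es < 0 and bottom.direction == "down"


class TestMutationEnrichment:
    def _build(self, in_mut, out_mut, n_in=5, n_out=5):
        samples = [f"s{i}" for i in range(n_in + n_out)]
        row = [1] * in_mut + [0] * (n_in - in_mut) + \
              [1] * out_mut + [0] * (n_out - out_mut)
        mut = MutationMatrix(pd.DataFrame([row], index=["TP53"],
                                          columns=samples))
        cl = clustering_for(samples, set(samples[:n_in]))
        return mut, cl

    def test_fully_enriched_cluster(self):
        mut, cl = self._build(in_mut=5, out_mut=0)
        res = [r for r in mutation_enrichment(mut, cl) if r.cluster == "in"]
        assert res[0].p_value == pytest.approx(1 / 252)

    def test_zero_mutations_everywhere(self):
        mut, cl = self._build(in_mut=0, out_mut=0)
        assert all(r.p_value == 1.0 for r in mutation_enrichment(mut, cl))

    def test_balanced_rates_not_enriched(self):
        mut, cl = self._build(in_mut=2, out_mut=2)
        res = [r for r in mutation_enrichment(mut, cl) if r.cluster == "in"]
        assert res[0].p_value > 0.5

    def test_p_matches_hypergeometric_oracle_all_small_tables(self):
        """scipy's one-sided Fisher agrees with tail enumeration for every
        2x2 table with margins at most 12."""
        for n_in in range(1, 13):
            for n_out in range(1, 13 - 0):
                if n_in + n_out > 12:
                    continue
                for a in range(n_in + 1):
                    for c in range(n_out + 1):
                        table = [[a, n_in - a], [c, n_out - c]]
                        _, p = stats.fisher_exact(table, alternative="greater")
                        assert p == pytest.approx(
                            fisher_tail_oracle(a, n_in - a, c, n_out - c),
                            abs=1e-12,
                        )

    def test_bh_adjustment_matches_sorted_definition(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(30)]
        mut = MutationMatrix(pd.DataFrame(
            rng.integers(0, 2, size=(6, 30)), index=[f"m{i}" for i in range(6)],
            columns=samples,
        ))
        cl = CellLineClustering(
            sample_ids=tuple(samples),
            labels=tuple(rng.choice(["a", "b", "c"], size=30)),
        )
        res = mutation_enrichment(mut, cl)
        expected = bh_oracle([r.p_value for r in res])
        for r, e in zip(res, expected):
            assert r.adjusted_p == pytest.approx(min(e, 1.0), abs=1e-12)


class TestEmt:
    def _signature_expr(self, up_shift, down_shift, seed=0, n=30):
        rng = np.random.default_rng(seed)
        up = [f"up{i}" for i in range(8)]
        down = [f"dn{i}" for i in range(12)]
        arr = rng.normal(0, 1, size=(20, n))
        arr[:8, :10] += up_shift      # first 10 samples
        arr[8:, :10] += down_shift
        expr = expr_from_array(arr, genes=up + down)
        return expr, set(up), set(down)

    def test_planted_mesenchymal_block(self):
        expr, up, down = self._signature_expr(2.0, -2.0)
        calls = {c.sample_id: c.label for c in classify_emt(expr, up, down)}
        mes = [calls[f"s{i}"] for i in range(10)]
        assert mes.count("mesenchymal") >= 9

    def test_planted_epithelial_block(self):
        expr, up, down = self._signature_expr(-2.0, 2.0)
        calls = {c.sample_id: c.label for c in classify_emt(expr, up, down)}
        epi = [calls[f"s{i}"] for i in range(10)]
        assert epi.count("epithelial") >= 9

    def test_flat_expression_is_neither(self):
        rng = np.random.default_rng(1)
        up = [f"up{i}" for i in range(25)]
        down = [f"dn{i}" for i in range(25)]
        expr = expr_from_array(rng.normal(0, 1, size=(50, 30)),
                               genes=up + down)
        calls = classify_emt(expr, set(up), set(down))
        assert all(c.label == "neither" for c in calls)

    def test_low_signature_coverage_rejected(self):
        expr = expr_from_array(np.random.default_rng(0).normal(size=(2, 10)),
                               genes=["up0", "dn0"])
        with pytest.raises(ValueError, match="signature"):
            classify_emt(expr, {"up0", "upX", "upY"}, {"dn0", "dnX", "dnY"})


class TestBreastSubtypes:
    def _bimodal(self, rng, n, frac_high, lo=3.0, hi=8.0, sd=0.5):
        high = rng.random(n) < frac_high
        return np.where(high, rng.normal(hi, sd, n), rng.normal(lo, sd, n)), high

    def test_mixture_recovery(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 80
            esr1, esr1_high = self._bimodal(rng, n, 0.5)
            pgr = rng.normal(3, 0.5, n)
            erbb2 = rng.normal(3, 0.5, n)
            expr = expr_from_array(np.vstack([esr1, pgr, erbb2]),
                                   genes=["ESR1", "PGR", "ERBB2"])
            with pytest.warns(UserWarning):
                calls = call_breast_subtypes(expr, seed=0)
            labels = np.array([c.label for c in calls])
            expected = np.where(esr1_high, "ER+Her2-", "TN")
            assert (labels == expected).mean() >= 0.95

    def test_all_unimodal_low_gives_triple_negative(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(3, 0.4, size=(3, 40))
        expr = expr_from_array(arr, genes=["ESR1", "PGR", "ERBB2"])
        with pytest.warns(UserWarning):
            calls = call_breast_subtypes(expr, seed=0)
        assert all(c.label == "TN" for c in calls)

    def test_erbb2_takes_precedence(self):
        rng = np.random.default_rng(2)
        n = 60
        esr1, _ = self._bimodal(rng, n, 0.5)
        erbb2, erbb2_high = self._bimodal(rng, n, 0.5)
        pgr = rng.normal(3, 0.5, n)
        expr = expr_from_array(np.vstack([esr1, pgr, erbb2]),
                               genes=["ESR1", "PGR", "ERBB2"])
        with pytest.warns(UserWarning):
            calls = call_breast_subtypes(expr, seed=0)
        for c, high in zip(calls, erbb2_high):
            if high:
                assert c.label == "Her2+"
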