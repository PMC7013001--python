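import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pathpass.aucpath import PassMatrix
from pathpass.differential import (DifferentialResult, EnrichmentCounts,
                                   dag_enrichment, differential_across_datasets,
                                   hypergeometric_enrichment, regulation_sets,
                                   ttest_features)
from pathpass.expression import ExpressionMatrix, Label, SampleLabels
from pathpass.pathways import Pathway


def make_pass(values, samples):
    return PassMatrix(data=pd.DataFrame(
        values, index=[f"f{i}" for i in range(len(values))], columns=samples,
        dtype=float))


def two_class_labels(n_a, n_b):
    mapping = {f"A{i}": Label.CLASS_A for i in range(n_a)}
    mapping.update({f"B{i}": Label.CLASS_B for i in range(n_b)})
    return SampleLabels(mapping), list(mapping)


def welch_oracle(a, b):
    """Textbook Welch statistic: t = (mean_a - mean_b) / sqrt(s2a/na + s2b/nb)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    return (a.mean() - b.mean()) / math.sqrt(se2)


class TestTtestFeatures:
    def test_identical_groups_give_null_result(self):
        labels, samples = two_class_labels(4, 4)
        row = [0.2, 0.4, 0.6, 0.8] * 2
        (res,) = ttest_features(make_pass([row], samples), labels)
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_welch_statistic_matches_textbook_oracle(self):
        labels, samples = two_class_labels(4, 4)
        a, b = [0.1, 0.2, 0.3, 0.4], [0.3, 0.4, 0.5, 0.6]
        (res,) = ttest_features(make_pass([a + b], samples), labels)
        assert res.t_statistic == pytest.approx(welch_oracle(a, b), abs=1e-12)
        # the classic (1,2,3,4) vs (3,4,5,6) example on the raw scale
        assert welch_oracle([1, 2, 3, 4], [3, 4, 5, 6]) == pytest.approx(-2.191, abs=5e-4)

    def test_constant_equal_groups_give_p_one(self):
        labels, samples = two_class_labels(3, 3)
        (res,) = ttest_features(make_pass([[0.5] * 6], samples), labels)
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_constant_unequal_groups_hit_floor(self):
        labels, samples = two_class_labels(3, 3)
        # 0.75 / 0.25 are binary-exact, so both group variances are exactly 0
        (res,) = ttest_features(make_pass([[0.75] * 3 + [0.25] * 3], samples), labels)
        assert res.p_value > 0.0 and res.p_value < 1e-300
        assert math.isinf(res.t_statistic) and res.t_statistic > 0

    def test_missing_features_skipped(self):
        labels, samples = two_class_labels(3, 3)
        values = np.array([[0.5] * 6, [0.2, 0.4, 0.6, 0.3, 0.5, 0.7]], dtype=float)
        values[0, 0] = np.nan
        results = ttest_features(make_pass(values, samples), labels)
        assert [r.feature_id for r in results] == ["f1"]

    def test_too_few_samples_rejected(self):
        labels, samples = two_class_labels(1, 4)
        with pytest.raises(ValueError, match=">= 2 samples"):
            ttest_features(make_pass([[0.5] * 5], samples), labels)

    def test_null_pvalues_are_uniform(self):
        """Kolmogorov-Smirnov check on 2000 null features (12 vs 12 samples)."""
        rng = np.random.default_rng(2024)
        labels, samples = two_class_labels(12, 12)
        values = np.clip(rng.normal(0.5, 0.12, size=(2000, 24)), 0, 1)
        results = ttest_features(make_pass(values, samples), labels)
        pvals = np.array([r.p_value for r in results])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestAcrossDatasets:
    def res(self, fid, p):
        return DifferentialResult(feature_id=fid, t_statistic=0.0, p_value=p,
                                  mean_class_a=0.5, mean_class_b=0.5)

    def test_must_be_significant_everywhere(self):
        datasets = [[self.res("f1", 0.01)] for _ in range(4)]
        datasets.append([self.res("f1", 0.2)])
        assert differential_across_datasets(datasets, 0.05) == set()
        assert differential_across_datasets(datasets[:4], 0.05) == {"f1"}

    def test_vacuous_threshold_returns_all_shared(self):
        datasets = [[self.res("f1", 0.9), self.res("f2", 0.99)]] * 2
        assert differential_across_datasets(datasets, 1.0) == {"f1", "f2"}

    def test_single_dataset_identity(self):
        ds = [self.res("f1", 0.01), self.res("f2", 0.5)]
        assert differential_across_datasets([ds], 0.05) == {"f1"}

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_in_alpha(self, a1, a2):
        rng = np.random.default_rng(5)
        datasets = [[self.res(f"f{i}", p) for i, p in enumerate(rng.uniform(size=20))]
                    for _ in range(3)]
        lo, hi = sorted([a1, a2])
        assert differential_across_datasets(datasets, lo) <= \
            differential_across_datasets(datasets, hi)


class TestHypergeometric:
    def test_empty_overlap_gives_one(self):
        assert hypergeometric_enrichment(10, 4, 3, 0) == 1.0

    def test_small_case_matches_subset_enumeration(self):
        # N=10, M=4, n=3, m=3: enumerate all C(10,3) draws
        special = set(range(4))
        draws = list(itertools.combinations(range(10), 3))
        frac = sum(1 for d in draws if len(special & set(d)) >= 3) / len(draws)
        assert frac == pytest.approx(1 / 30)
        assert hypergeometric_enrichment(10, 4, 3, 3) == pytest.approx(frac, abs=1e-12)

    def test_all_genes_special_gives_certainty(self):
        assert hypergeometric_enrichment(8, 8, 3, 3) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        for N, M, n, m in [(5, 6, 2, 1), (5, 3, 6, 1), (5, 3, 3, 4)]:
            with pytest.raises(ValueError, match="inconsistent"):
                hypergeometric_enrichment(N, M, n, m)

    def test_matches_exact_combinatorics_small_N(self):
        for N in range(1, 13):
            for M in range(N + 1):
                for n in range(N + 1):
                    for m in range(max(0, n - (N - M)), min(M, n) + 1):
                        num = sum(math.comb(M, i) * math.comb(N - M, n - i)
                                  for i in range(m))
                        denom = math.comb(N, n)
                        expected = (denom - num) / denom
                        assert hypergeometric_enrichment(N, M, n, m) == pytest.approx(
                            expected, abs=1e-12)

    def test_counts_record_and_neg_log10(self):
        c = EnrichmentCounts(N=10, M=4, n=3, m=3)
        assert c.p_value == pytest.approx(1 / 30)
        assert c.neg_log10_p == pytest.approx(-math.log10(1 / 30))
        with pytest.raises(ValueError):
            EnrichmentCounts(N=10, M=4, n=3, m=4)


class TestDagEnrichment:
    def test_counts_from_feature_ids(self):
        p1 = Pathway(id="P1", name="", genes=frozenset("abcd"),
                     edges=frozenset({("a", "b"), ("b", "c")}))
        p2 = Pathway(id="P2", name="", genes=frozenset("defg"),
                     edges=frozenset({("d", "e"), ("e", "f")}))
        counts = dag_enrichment([p1, p2], dag_genes={"a", "b", "z"},
                                differential_feature_ids={"P1|edge", "P1|node"})
        assert (counts.N, counts.M, counts.n, counts.m) == (7, 2, 4, 2)

    def test_unknown_pathway_in_features_rejected(self):
        p1 = Pathway(id="P1", name="", genes=frozenset("abc"),
                     edges=frozenset({("a", "b"), ("b", "c")}))
        with pytest.raises(ValueError, match="unknown pathways"):
            dag_enrichment([p1], {"a"}, {"P9|edge"})


class TestRegulationSets:
    def cohort(self, shift_a=0.0, shift_b=0.0, seed=0):
        rng = np.random.default_rng(seed)
        genes = ["g1", "g2"]
        ref = rng.normal(8, 0.3, size=(2, 10))
        a = rng.normal(8, 0.3, size=(2, 10))
        b = rng.normal(8, 0.3, size=(2, 10))
        a[0] += shift_a  # shift only g1
        b[0] += shift_b
        data = pd.DataFrame(np.hstack([ref, a, b]), index=genes,
                            columns=[f"R{i}" for i in range(10)]
                            + [f"A{i}" for i in range(10)]
                            + [f"B{i}" for i in range(10)])
        mapping = {c: Label.REFERENCE for c in data.columns[:10]}
        mapping.update({c: Label.CLASS_A for c in data.columns[10:20]})
        mapping.update({c: Label.CLASS_B for c in data.columns[20:]})
        return ExpressionMatrix(data=data), SampleLabels(mapping), genes

    def test_identical_distributions_stay_out(self):
        expr, labels, genes = self.cohort()
        sets = regulation_sets(expr, labels, genes, alpha=0.001)
        assert not (sets.up_a | sets.down_a | sets.up_b | sets.down_b)

    def test_strong_shift_lands_in_correct_set(self):
        expr, labels, genes = self.cohort(shift_a=1.5)  # +5 sigma in class A only
        sets = regulation_sets(expr, labels, genes, alpha=0.01)
        assert "g1" in sets.up_a
        assert "g1" not in (sets.up_b | sets.down_b)
        down = self.cohort(shift_a=-1.5, seed=1)
        sets2 = regulation_sets(down[0], down[1], down[2], alpha=0.01)
        assert "g1" in sets2.down_a

    def test_alpha_zero_empties_everything(self):
        expr, labels, genes = self.cohort(shift_a=3.0, shift_b=-3.0)
        sets = regulation_sets(expr, labels, genes, alpha=0.0)
        assert not (sets.up_a | sets.down_a | sets.up_b | sets.down_b)

    def test_up_down_disjoint_and_overlap_summary(self):
        expr, labels, genes = self.cohort(shift_a=2.0, shift_b=2.0)
        sets = regulation_sets(expr, labels, genes, alpha=0.05)
        assert not (sets.up_a & sets.down_a) and not (sets.up_b & sets.down_b)
        summary = sets.overlap_summary()
        assert summary["shared_same_direction"] >= 1
        assert sum(summary.values()) >= 1
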