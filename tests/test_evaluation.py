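"""Occurrence/differential scoring, Procrustes, and permutation nulls."""

import itertools
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mimet.diffstats import Thresholds
from mimet.evaluation import (
    NullDistribution,
    compare_pipelines_signed_rank,
    null_coverage,
    null_differential,
    occurrence_from_abundance,
    procrustes_compare,
    procrustes_m12sq,
    set_metrics,
)

from conftest import make_table

universe = st.sets(st.integers(0, 30))


class TestSetMetrics:
    def test_hand_counted_example(self):
        m = set_metrics({"a", "b", "c", "d"}, {"c", "d", "e"})
        assert (m.precision, m.recall) == (0.5, 2 / 3)
        assert m.f1 == pytest.approx(4 / 7)

    def test_perfect_and_disjoint(self):
        assert set_metrics({"a"}, {"a"}).f1 == 1.0
        assert set_metrics({"a"}, {"b"}).f1 == 0.0

    def test_both_empty_warns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            m = set_metrics(set(), set())
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(predicted=universe, measured=universe)
    def test_matches_confusion_matrix_brute_force(self, predicted, measured):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = set_metrics(predicted, measured)
        tp = sum(1 for x in predicted if x in measured)
        fp = sum(1 for x in predicted if x not in measured)
        fn = sum(1 for x in measured if x not in predicted)
        assert (m.tp, m.fp, m.fn) == (tp, fp, fn)
        if tp + fp:
            assert m.precision == pytest.approx(tp / (tp + fp))
        if m.precision + m.recall:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall)
            )
        assert m.f1 <= max(m.precision, m.recall) + 1e-12
        assert (m.f1 == 1.0) == (predicted == measured != set())


class TestOccurrence:
    def test_matches_brute_force_prevalence_scan(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(size=(8, 20)) * (rng.uniform(size=(8, 20)) > 0.8)
        table = make_table(values, features=[f"cpd:{i}" for i in range(8)])
        got = occurrence_from_abundance(table, 0.05)
        expected = {
            f for f, row in zip(table.features, values)
            if (np.abs(row) > 1e-12).mean() >= 0.05
        }
        assert got == expected

    def test_empty_table(self):
        assert occurrence_from_abundance(make_table(np.empty((0, 4)))) == set()

    def test_signed_scores_count_as_present(self):
        table = make_table(-np.ones((1, 5)), features=["cpd:x"])
        assert occurrence_from_abundance(table) == {"cpd:x"}


class TestProcrustes:
    def test_self_comparison_is_exact_fit(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.normal(size=(6, 12)))
        res = procrustes_compare(table, table, n_perm=19, seed=0)
        assert res.m12_squared == pytest.approx(0.0, abs=1e-10)
        assert res.correlation == pytest.approx(1.0)

    def test_similarity_transform_invariance(self):
        rng = np.random.default_rng(2)
        d, n = 6, 15
        pts = rng.normal(size=(n, d))
        # random rotation via QR, then scale + translate
        q, _ = np.linalg.qr(rng.normal(size=(d, d)))
        moved = 3.1 * pts @ q + 7.0
        a = make_table(pts.T, features=[f"cpd:{i}" for i in range(d)])
        b = make_table(moved.T, features=[f"cpd:{i}" for i in range(d)])
        res = procrustes_compare(a, b, n_perm=19, seed=0)
        assert res.m12_squared == pytest.approx(0.0, abs=1e-10)

    def test_independent_matrices_near_one_not_significant(self):
        rng = np.random.default_rng(0)
        a = make_table(rng.normal(size=(4, 30)))
        b = make_table(rng.normal(size=(4, 30)))
        res = procrustes_compare(a, b, n_perm=199, seed=0)
        assert res.m12_squared > 0.7
        assert res.p_value > 0.05

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(3)
        a = make_table(rng.normal(size=(5, 10)))
        b = make_table(rng.normal(size=(5, 10)))
        r_ab = procrustes_compare(a, b, n_perm=9, seed=0)
        r_ba = procrustes_compare(b, a, n_perm=9, seed=0)
        assert r_ab.m12_squared == pytest.approx(r_ba.m12_squared, abs=1e-8)

    def test_too_few_shared_samples(self):
        a = make_table(np.ones((2, 3)))
        with pytest.raises(ValueError, match=">= 4"):
            procrustes_compare(a, a, n_perm=9)

    def test_matches_vegan_symmetric_procrustes(self, tmp_path):
        """Cross-check m12^2 against vegan::procrustes (symmetric) in R."""
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(10, 4)), rng.normal(size=(10, 4))
        np.savetxt(tmp_path / "x.tsv", x)
        np.savetxt(tmp_path / "y.tsv", y)
        script = (
            'suppressMessages(library(vegan));'
            f'x <- as.matrix(read.table("{tmp_path}/x.tsv"));'
            f'y <- as.matrix(read.table("{tmp_path}/y.tsv"));'
            'cat(sprintf("%.12f", procrustes(x, y, symmetric=TRUE)$ss))'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        assert procrustes_m12sq(x, y) == pytest.approx(float(out.stdout), abs=1e-9)


class TestNullCoverage:
    def test_dictionary_equals_measured_forces_f1_one(self):
        measured = {f"cpd:{i}" for i in range(10)}
        nulls = null_coverage(measured, k=10, measured=measured, n_null=20, seed=0)
        assert np.allclose(nulls["f1"].replicates, 1.0)

    def test_disjoint_measured_forces_zero(self):
        dictionary = {f"cpd:a{i}" for i in range(20)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nulls = null_coverage(dictionary, 5, {"cpd:zzz"}, n_null=20, seed=0)
        assert np.allclose(nulls["f1"].replicates, 0.0)

    def test_hypergeometric_mean_precision(self):
        dictionary = {f"cpd:{i}" for i in range(100)}
        measured = {f"cpd:{i}" for i in range(10)}
        nulls = null_coverage(dictionary, 10, measured, n_null=400, seed=1)
        # E[precision] = |measured in dict| / |dict| = 0.1
        assert np.mean(nulls["precision"].replicates) == pytest.approx(0.1, abs=0.03)

    def test_k_larger_than_dictionary_rejected(self):
        with pytest.raises(ValueError, match="exceeds dictionary"):
            null_coverage({"cpd:a"}, 2, {"cpd:a"})

    def test_empirical_p_grid_with_99_replicates(self):
        dist = NullDistribution(np.linspace(0, 1, 99), observed=0.5)
        p = dist.empirical_p
        assert p in {i / 100 for i in range(1, 101)}


class TestNullDifferential:
    def test_mode_validation(self, strong_cohort, synth_ref):
        funcs, metab, _ = strong_cohort
        groups = funcs.groups("case", "control")
        with pytest.raises(ValueError, match="shuffle-genes mode needs"):
            null_differential("shuffle-genes", metab, groups)
        with pytest.raises(ValueError, match="needs `pred`"):
            null_differential("shuffle-metabolites", metab, groups)
        with pytest.raises(ValueError, match="unknown mode"):
            null_differential("bogus", metab, groups)

    def test_observed_matches_manually_chained_pipeline(self, strong_cohort, synth_ref):
        from mimet.diffstats import (
            diff_metabolites_ttest, nb_wald_diff_functions,
            prevalence_filter, significant_features,
        )
        from mimet.evaluation import set_metrics
        from mimet.predict import mangosteen_differential

        funcs, metab, _ = strong_cohort
        groups = funcs.groups("case", "control")
        th = Thresholds()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nulls = null_differential(
                "shuffle-genes", metab, groups, funcs=funcs, ref=synth_ref,
                thresholds=th, n_null=5, seed=0,
            )
            measured = significant_features(diff_metabolites_ttest(
                prevalence_filter(metab, th.prevalence_metabolites), groups, th.alpha_fdr
            ))
            flagged = significant_features(nb_wald_diff_functions(
                prevalence_filter(funcs, th.prevalence_functions), groups, th.alpha_fdr
            ))
            expected = set_metrics(mangosteen_differential(flagged, synth_ref), measured)
        assert nulls["f1"].observed == pytest.approx(expected.f1)
        assert nulls["precision"].observed == pytest.approx(expected.precision)

    def test_shuffled_metabolite_labels_score_lower(self, strong_cohort):
        funcs, metab, _ = strong_cohort
        groups = funcs.groups("case", "control")
        # predicted matrix = the measured table itself: a perfect predictor
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nulls = null_differential(
                "shuffle-metabolites", metab, groups, pred=metab,
                predicted_test="ttest", n_null=19, seed=0,
            )
        assert nulls["f1"].observed == 1.0
        assert nulls["f1"].empirical_p <= 0.05


class TestSignedRank:
    def test_identical_pipelines_undefined(self):
        table = pd.DataFrame([[0.1, 0.2, 0.3]] * 2, index=["a", "b"])
        out = compare_pipelines_signed_rank(table)
        assert np.isnan(out.loc["a", "b"])

    def test_six_positive_differences_exact_p(self):
        table = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6], [0, 0, 0, 0, 0, 0]], index=["a", "b"], dtype=float
        )
        out = compare_pipelines_signed_rank(table)
        assert out.loc["a", "b"] == pytest.approx(2 / 64)

    def test_enumeration_oracle_on_random_differences(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=8)
        table = pd.DataFrame([d, np.zeros(8)], index=["a", "b"])
        p = compare_pipelines_signed_rank(table).loc["a", "b"]
        # exhaustive sign-assignment enumeration of the signed-rank statistic
        ranks = pd.Series(np.abs(d)).rank().to_numpy()
        w_obs = ranks[d > 0].sum()
        mean_w = ranks.sum() / 2
        hits = total = 0
        for signs in itertools.product([0, 1], repeat=len(d)):
            w = sum(r for r, s in zip(ranks, signs) if s)
            total += 1
            if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
                hits += 1
        assert p == pytest.approx(hits / total)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(rng.uniform(size=(2, 7)), index=["a", "b"])
        out = compare_pipelines_signed_rank(table)
        assert out.loc["a", "b"] == out.loc["b", "a"]
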