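"""Differential-abundance statistics against independent oracles."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mimet.diffstats import (
    Thresholds,
    _nb_irls,
    bh_adjust,
    diff_metabolites_ranksum,
    diff_metabolites_ttest,
    import_differential,
    nb_wald_diff_functions,
    prevalence_filter,
    significant_features,
    size_factors,
)

from conftest import make_table


def bh_oracle(p):
    """Independent step-up implementation: sort, cummin from the largest."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def two_group_meta(n_case, n_ctrl):
    idx = [f"s{i}" for i in range(n_case + n_ctrl)]
    return pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=idx)


class TestPrevalenceFilter:
    def test_exactly_at_threshold_kept(self):
        values = np.zeros((1, 20))
        values[0, 0] = 5.0  # 1/20 = exactly 5%
        table = make_table(values)
        assert prevalence_filter(table, 0.05).features == table.features

    def test_never_detected_removed(self):
        table = make_table(np.zeros((1, 10)))
        assert prevalence_filter(table, 0.05).features == []

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(size=(10, 12)) * (rng.uniform(size=(10, 12)) > 0.6)
        table = make_table(values)
        kept = prevalence_filter(table, 0.25).features
        expected = [
            f for f, row in zip(table.features, values)
            if (np.abs(row) > 1e-12).sum() / 12 >= 0.25
        ]
        assert kept == expected

    def test_signed_matrix_uses_absolute_presence(self):
        table = make_table([[-3.0, 0.0, 0.0, 0.0]])
        assert prevalence_filter(table, 0.25).features == table.features


class TestBHAdjust:
    def test_hand_worked_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_independent_oracle(self, pvals):
        assert np.allclose(bh_adjust(pvals), bh_oracle(pvals))

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1).all()


class TestSizeFactors:
    def test_doubled_sample_closed_form(self):
        table = make_table([[10.0, 20.0], [4.0, 8.0]])
        sf = size_factors(table)
        assert np.allclose(sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_samples_unit_factors(self):
        table = make_table([[5.0, 5.0, 5.0], [2.0, 2.0, 2.0]])
        assert np.allclose(size_factors(table).to_numpy(), 1.0)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(2)
        values = rng.integers(1, 200, size=(8, 4)).astype(float)
        table = make_table(values)
        gm = np.exp(np.mean(np.log(values), axis=1))
        raw = np.median(values / gm[:, None], axis=0)
        expected = raw / np.exp(np.mean(np.log(raw)))  # geometric mean 1
        assert np.allclose(size_factors(table).to_numpy(), expected)

    def test_error_mentions_pseudocount(self):
        table = make_table([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(table)


class TestNBWald:
    def test_irls_matches_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n = 24
        case = np.arange(n) < 12
        s = np.exp(rng.normal(0, 0.2, n))
        k = rng.negative_binomial(5, 5 / (5 + 40 * s), size=(5, n)).astype(float)
        alpha = np.full(5, 0.2)
        b0, b1, se = _nb_irls(k, s, case, alpha)
        X = np.column_stack([np.ones(n), case.astype(float)])
        for i in range(5):
            fit = sm.GLM(
                k[i], X, family=sm.families.NegativeBinomial(alpha=alpha[i]),
                offset=np.log(s),
            ).fit()
            assert b1[i] == pytest.approx(fit.params[1], abs=1e-6)
            assert se[i] == pytest.approx(fit.bse[1], abs=1e-6)

    def test_planted_fold_changes_recovered(self, strong_cohort):
        funcs, _, truth = strong_cohort
        groups = funcs.groups("case", "control")
        filtered = prevalence_filter(funcs, 0.05)
        diff = nb_wald_diff_functions(filtered, groups, alpha=0.2)
        flagged = significant_features(diff)
        planted = set(truth.planted)
        assert len(flagged & planted) >= 0.9 * len(planted)
        # direction convention: case-enriched functions get positive log2fc
        up = [f for f, fc in truth.planted.items() if fc > 1 and f in diff.index]
        assert (diff.loc[up, "log2fc"] > 0).all()

    def test_case_deficit_flagged_negative(self):
        rng = np.random.default_rng(0)
        values = rng.integers(50, 150, size=(6, 20)).astype(float)
        values[0, :10] = 0.0  # absent in every case sample
        table = make_table(values)
        diff = nb_wald_diff_functions(table, two_group_meta(10, 10), alpha=0.2)
        assert diff.iloc[0]["significant"]
        assert diff.iloc[0]["log2fc"] < 0

    def test_requires_two_per_group(self):
        table = make_table([[1.0, 2.0, 3.0]])
        groups = pd.Series(["case", "control", "control"], index=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="two samples"):
            nb_wald_diff_functions(table, groups)


class TestImportDifferential:
    def test_threshold_scan(self, tmp_path):
        path = tmp_path / "deseq.tsv"
        rows = [(f"ko:K{i}", p) for i, p in enumerate([0.1, 0.3, 0.2, 0.01])]
        path.write_text(
            "feature_id\tpadj\n" + "".join(f"{f}\t{p}\n" for f, p in rows)
        )
        got = import_differential(path, alpha=0.2)
        assert got == {f for f, p in rows if p <= 0.2}

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("feature_id\tpadj\n")
        assert import_differential(path) == set()

    def test_missing_column_names_expected_header(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tp\nx\t0.1\n")
        with pytest.raises(ValueError, match="feature_id.*padj"):
            import_differential(path)


class TestTTest:
    def test_identical_groups_not_flagged(self):
        rng = np.random.default_rng(3)
        row = rng.uniform(1, 2, size=10)
        table = make_table(np.vstack([np.concatenate([row, row])]))
        diff = diff_metabolites_ttest(table, two_group_meta(10, 10), alpha=0.2)
        assert not diff["significant"].any()
        assert diff["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_matches_hand_pooled_t_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([10.0, 20.0, 15.0])
        table = make_table([np.concatenate([a, b])], features=["cpd:x"])
        diff = diff_metabolites_ttest(table, two_group_meta(3, 3), alpha=0.2)
        la, lb = np.log(a), np.log(b)
        sp = np.sqrt((la.var(ddof=1) * 2 + lb.var(ddof=1) * 2) / 4)
        t = (la.mean() - lb.mean()) / (sp * np.sqrt(2 / 3))
        p = 2 * stats.t.sf(abs(t), df=4)
        assert diff["stat"].iloc[0] == pytest.approx(t)
        assert diff["pvalue"].iloc[0] == pytest.approx(p)
        assert diff["log2fc"].iloc[0] == pytest.approx((la.mean() - lb.mean()) / np.log(2))

    def test_imputation_contract(self):
        values = np.array([[0.0, 4.0, 2.0, 8.0, 0.0, 6.0]])
        table = make_table(values)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # no all-zero warning expected
            diff = diff_metabolites_ttest(table, two_group_meta(3, 3), alpha=0.2)
        # zeros imputed with the row's min nonzero (2.0) before logging:
        # recompute expected t with the imputed vector
        imputed = np.log([2.0, 4.0, 2.0, 8.0, 2.0, 6.0])
        la, lb = imputed[:3], imputed[3:]
        sp = np.sqrt((la.var(ddof=1) + lb.var(ddof=1)) / 2)
        t = (la.mean() - lb.mean()) / (sp * np.sqrt(2 / 3))
        assert diff["stat"].iloc[0] == pytest.approx(t)

    def test_all_zero_metabolite_excluded_with_warning(self):
        table = make_table([[0.0] * 6, [1.0, 2, 3, 4, 5, 6]],
                           features=["cpd:z", "cpd:x"])
        with pytest.warns(UserWarning, match="all-zero"):
            diff = diff_metabolites_ttest(table, two_group_meta(3, 3))
        assert list(diff.index) == ["cpd:x"]

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(1, 5, size=(3, 12))
        meta = two_group_meta(6, 6)
        base = diff_metabolites_ttest(make_table(values), meta)
        scaled = diff_metabolites_ttest(make_table(values * 137.0), meta)
        assert np.allclose(base["stat"], scaled["stat"])
        assert np.allclose(base["pvalue"], scaled["pvalue"])


class TestRankSum:
    def exact_two_sided_p(self, a, b):
        """Enumerate all group assignments of the pooled values."""
        pooled = np.concatenate([a, b])
        n_a = len(a)
        obs = stats.rankdata(pooled)[:n_a].sum()
        mean = n_a * (len(pooled) + 1) / 2
        count = total = 0
        for combo in itertools.combinations(range(len(pooled)), n_a):
            ranks = stats.rankdata(pooled)[list(combo)].sum()
            total += 1
            if abs(ranks - mean) >= abs(obs - mean) - 1e-9:
                count += 1
        return count / total

    def test_fully_separated_triples(self):
        table = make_table([[1.0, 2, 3, 4, 5, 6]])
        diff = diff_metabolites_ranksum(table, two_group_meta(3, 3))
        assert diff["pvalue"].iloc[0] == pytest.approx(0.1)
        assert diff["pvalue"].iloc[0] == pytest.approx(
            self.exact_two_sided_p(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        )

    def test_matches_enumeration_oracle_on_random_data(self):
        rng = np.random.default_rng(6)
        for _ in range(3):
            a, b = rng.normal(size=4), rng.normal(size=5) + 0.5
            table = make_table([np.concatenate([a, b])])
            diff = diff_metabolites_ranksum(table, two_group_meta(4, 5))
            assert diff["pvalue"].iloc[0] == pytest.approx(self.exact_two_sided_p(a, b))

    def test_all_tied_gives_p_one(self):
        table = make_table([[2.0] * 8])
        diff = diff_metabolites_ranksum(table, two_group_meta(4, 4))
        assert diff["pvalue"].iloc[0] == 1.0

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(4, 14))
        meta = two_group_meta(7, 7)
        base = diff_metabolites_ranksum(make_table(values), meta)
        flipped = diff_metabolites_ranksum(make_table(-values), meta)
        assert np.allclose(base["pvalue"], flipped["pvalue"])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(4, 30))
        meta = two_group_meta(15, 15)
        base = diff_metabolites_ranksum(make_table(values), meta)
        warped = diff_metabolites_ranksum(make_table(np.exp(values)), meta)
        assert np.allclose(base["pvalue"], warped["pvalue"])


def test_thresholds_defaults_and_validation():
    th = Thresholds()
    assert (th.alpha_fdr, th.prevalence_functions, th.n_null) == (0.2, 0.05, 99)
    with pytest.raises(ValueError):
        Thresholds(alpha_fdr=1.5)
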