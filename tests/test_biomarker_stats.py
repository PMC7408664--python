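"""CD45-normalized scoring, rank tests, FDR, ROC/AUC, panel fit, correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ctcsig as cs
from ctcsig.synthgen import QpcrDataset


def make_qpcr(records, ct_floor=40.0):
    """records: (sample, group, gene, [ct replicates])"""
    rows = [
        (s, g, gene, w + 1, ct)
        for s, g, gene, cts in records
        for w, ct in enumerate(cts)
    ]
    return QpcrDataset(
        data=pd.DataFrame(rows, columns=["sample_id", "group", "gene", "well", "ct"]),
        ct_floor=ct_floor,
    )


def mw_enumeration_oracle(x, y):
    """Exact two-sided p by enumerating all rank assignments (untied data)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return (xs[:, None] > ys[None, :]).sum()

    u_obs = (x[:, None] > y[None, :]).sum()
    mean_u = n1 * len(y) / 2.0
    dev = abs(u_obs - mean_u)
    total = hits = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(idx) - mean_u) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total


class TestNormalizeCt:
    def test_stated_formula(self):
        d = make_qpcr([
            ("s1", "patient", "CD45", [25.0, 25.0]),
            ("s1", "patient", "HOXB13", [30.0, 30.0]),
        ])
        scores = cs.normalize_ct(d)
        assert scores.loc["s1", "HOXB13"] == pytest.approx(-5.0)  # (40-30)-(40-25)

    def test_gene_equal_reference_scores_zero(self):
        d = make_qpcr([
            ("s1", "patient", "CD45", [28.0, 28.0]),
            ("s1", "patient", "QKI", [28.0, 28.0]),
        ])
        assert cs.normalize_ct(d).loc["s1", "QKI"] == pytest.approx(0.0)

    def test_floor_case(self):
        d = make_qpcr([
            ("s1", "patient", "CD45", [25.0, 25.0]),
            ("s1", "patient", "MAOA", [40.0, 40.0]),
        ])
        assert cs.normalize_ct(d).loc["s1", "MAOA"] == pytest.approx(-15.0)

    def test_replicates_averaged_before_normalization(self):
        d = make_qpcr([
            ("s1", "patient", "CD45", [24.0, 26.0]),
            ("s1", "patient", "SDK1", [29.0, 31.0]),
        ])
        assert cs.normalize_ct(d).loc["s1", "SDK1"] == pytest.approx(-5.0)

    def test_missing_gene_is_missing_not_zero(self):
        d = make_qpcr([
            ("s1", "patient", "CD45", [25.0]),
            ("s1", "patient", "QKI", [30.0]),
            ("s2", "control", "CD45", [25.0]),
        ])
        scores = cs.normalize_ct(d)
        assert np.isnan(scores.loc["s2", "QKI"])

    def test_sample_without_cd45_named_in_error(self):
        d = make_qpcr([
            ("s1", "patient", "CD45", [25.0]),
            ("s1", "patient", "QKI", [30.0]),
            ("weird", "control", "QKI", [31.0]),
        ])
        with pytest.raises(cs.DataError, match="weird"):
            cs.normalize_ct(d)


class TestMannWhitney:
    def test_worked_example_fully_separated(self):
        u, p = cs.mannwhitney_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2 * 1/C(6,3)

    def test_identical_multisets_give_p_one(self):
        _, p = cs.mannwhitney_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_constant_groups(self):
        u, p = cs.mannwhitney_test([5, 5], [5, 5, 5])
        assert p == 1.0 and u == 3.0  # all ties: U = n1*n2/2

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        for n1, n2 in [(3, 4), (6, 7), (5, 5), (2, 8)]:
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            u, p = cs.mannwhitney_test(x, y, mode="exact")
            u_ref, p_ref = mw_enumeration_oracle(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_auto_switches_to_normal_for_large_or_tied(self):
        rng = np.random.default_rng(32)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 20)
        u, p = cs.mannwhitney_test(x, y, mode="auto")
        _, p_norm = cs.mannwhitney_test(x, y, mode="normal")
        assert p == p_norm
        # cross-group tie forces the tie-corrected normal path even at small n
        _, p_tied = cs.mannwhitney_test([1.0, 2.0], [2.0, 3.0], mode="auto")
        assert 0 <= p_tied <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(cs.DataError):
            cs.mannwhitney_test([], [1.0])


class TestBhFdr:
    def test_worked_example(self):
        q = cs.bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05, 0.9])
        np.testing.assert_allclose(q, [0.06, 0.06, 0.06, 0.06, 0.06, 0.9], atol=1e-12)

    def test_single_and_equal_ps(self):
        assert cs.bh_fdr([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(cs.bh_fdr([0.04] * 5), [0.04] * 5, atol=1e-12)

    def test_empty(self):
        assert cs.bh_fdr([]).size == 0

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=25), st.randoms())
    def test_permutation_invariance_and_monotone(self, ps, rnd):
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        q = cs.bh_fdr(ps)
        q_perm = cs.bh_fdr([ps[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-12)
        order = np.argsort(ps, kind="stable")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        assert (q >= np.asarray(ps) - 1e-12).all() and (q <= 1 + 1e-12).all()


class TestRocAuc:
    def test_perfect_separation(self):
        r = cs.roc_auc([3, 4, 5, 0, 1, 2], ["patient"] * 3 + ["control"] * 3)
        assert r.auc == 1.0
        assert r.points["tpr"].iloc[-1] == 1.0 and r.points["fpr"].iloc[-1] == 1.0

    def test_null_labels_near_half(self):
        rng = np.random.default_rng(33)
        scores = rng.normal(0, 1, 3000)
        labels = np.where(rng.random(3000) < 0.5, "patient", "control")
        assert abs(cs.roc_auc(scores, labels).auc - 0.5) < 0.05

    def test_auc_equals_u_over_n1n2(self):
        rng = np.random.default_rng(34)
        for _ in range(200):
            n1, n2 = rng.integers(2, 15, 2)
            x = np.round(rng.normal(1, 2, n1), 1)  # rounding induces ties
            y = np.round(rng.normal(0, 2, n2), 1)
            u, _ = cs.mannwhitney_test(x, y, mode="normal")
            scores = np.concatenate([x, y])
            labels = ["patient"] * n1 + ["control"] * n2
            assert cs.roc_auc(scores, labels).auc == pytest.approx(
                u / (n1 * n2), abs=1e-12
            )

    def test_delong_ci_brackets_auc(self):
        rng = np.random.default_rng(35)
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 25)])
        labels = ["patient"] * 30 + ["control"] * 25
        r = cs.roc_auc(scores, labels)
        assert 0 <= r.ci_low <= r.auc <= r.ci_high <= 1

    def test_single_class_rejected(self):
        with pytest.raises(cs.DataError):
            cs.roc_auc([1, 2], ["patient", "patient"])


class TestPanelLogistic:
    def test_separable_data_flagged_auc_one(self):
        x = np.linspace(-2, 2, 30)
        scores = pd.DataFrame({"g": x}, index=[f"s{i}" for i in range(30)])
        labels = np.where(x > 0, "patient", "control")
        with pytest.warns(UserWarning, match="separation"):
            model = cs.fit_panel_logistic(scores, labels)
        assert model.separation and model.auc == 1.0

    def test_coefficients_match_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(36)
        X = rng.normal(0, 1, (300, 2))
        logits = 0.5 + 1.2 * X[:, 0] - 0.8 * X[:, 1]
        y = rng.random(300) < 1 / (1 + np.exp(-logits))
        scores = pd.DataFrame(X, columns=["g1", "g2"])
        labels = np.where(y, "patient", "control")
        model = cs.fit_panel_logistic(scores, labels)
        ref = sm.GLM(y.astype(float), sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            [model.intercept, *model.coefficients], ref.params, atol=1e-6
        )
        assert model.converged and not model.separation

    def test_null_panel_auc_near_half(self):
        rng = np.random.default_rng(37)
        scores = pd.DataFrame(rng.normal(0, 1, (400, 3)), columns=list("abc"))
        labels = np.where(rng.random(400) < 0.5, "patient", "control")
        assert abs(cs.fit_panel_logistic(scores, labels).auc - 0.5) < 0.12

    def test_preconditions(self):
        with pytest.raises(cs.DataError):
            cs.fit_panel_logistic(
                pd.DataFrame({"g": [1.0, 2.0, 3.0]}), ["patient"] * 3
            )  # one class only
        with pytest.raises(cs.DataError):
            cs.fit_panel_logistic(
                pd.DataFrame({"g1": [1.0, 2.0, 3.0], "g2": [0.0, 1.0, 0.5]}),
                ["patient", "control", "patient"],
            )  # 3 complete cases < genes + 2


class TestPearson:
    def test_exact_linearity(self):
        x = np.arange(1.0, 8.0)
        r, p = cs.pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r2, _ = cs.pearson_corr(x, -x)
        assert r2 == pytest.approx(-1.0)

    def test_hand_computed_fixture(self):
        r, p = cs.pearson_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6, abs=1e-12)
        assert 0 < p < 1

    def test_zero_variance_rejected(self):
        with pytest.raises(cs.DataError):
            cs.pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDichotomize:
    def test_median_split(self):
        labels, cut = cs.dichotomize(pd.Series([1.0, 2.0, 3.0, 4.0]), "median")
        assert cut == 2.5
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_percentile70_nearest_rank(self):
        labels, cut = cs.dichotomize(pd.Series(np.arange(1.0, 11.0)), "p70")
        assert cut == 7.0
        assert (labels == "low").sum() == 7 and (labels == "high").sum() == 3

    def test_fixed_published_cut(self):
        s = pd.Series([-5.0, -3.9, -3.8, -2.0], index=list("abcd"))
        labels, cut = cs.dichotomize(s, -3.8)
        assert cut == -3.8
        assert labels.tolist() == ["low", "low", "low", "high"]

    def test_all_equal_warns_all_low(self):
        with pytest.warns(UserWarning, match="all scores equal"):
            labels, _ = cs.dichotomize(pd.Series([2.0, 2.0, 2.0]), "median")
        assert (labels == "low").all()


class TestMarkerTable:
    def test_synthetic_cohort_recovers_effects(self, qpcr_cohort):
        _, d = qpcr_cohort
        scores = cs.normalize_ct(d)
        table = cs.marker_test_table(scores, d.groups())
        assert (table["q_value"] >= table["p_value"] - 1e-15).all()
        assert table["auc"].between(0, 1).all()
        validated = table.loc[list(cs.VALIDATED_GENES)]
        assert (validated["q_value"] < 0.05).all()
        assert table.loc["ARL4A", "q_value"] > 0.05
        assert (validated["median_patient"] > validated["median_control"]).all()
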