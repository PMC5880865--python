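"""Group-statistics battery: split-plot ANOVA, post-hocs, χ², correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasl.stats import (chi_square, dichotomize_drug_use, drug_use_table,
                         mixed_anova, mixed_anova_arrays, oneway_anova,
                         pearson_r, run_battery, sidak_adjust)
from phasl.synthetic import CohortSpec, simulate_cohort


def micro_table():
    """2 groups x 2 subjects worked example."""
    return pd.DataFrame({
        "group": ["A", "A", "B", "B"],
        "cbf_pre_roi": [10.0, 12.0, 10.0, 12.0],
        "cbf_post_roi": [8.0, 10.0, 10.0, 11.0],
    })


def oracle_mixed_f(pre, post, groups):
    """Independent sequential-RSS linear-model oracle for the split-plot
    design: projections onto nested design matrices (intercept -> group ->
    subject -> +time -> +group x time)."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    groups = np.asarray(groups)
    N = len(pre)
    y = np.concatenate([pre, post])
    subj = np.tile(np.arange(N), 2)
    time = np.repeat([0, 1], N)
    grp = np.tile(groups, 2)
    labels = np.unique(groups)
    k = len(labels)

    def dummies(codes, levels):
        return np.column_stack([(codes == lv).astype(float) for lv in levels])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    ones = np.ones((2 * N, 1))
    Xg = np.column_stack([ones, dummies(grp, labels)])
    Xs = np.column_stack([ones, dummies(subj, np.arange(N))])
    Xst = np.column_stack([Xs, time.astype(float)[:, None]])
    inter = np.column_stack([(grp == lv).astype(float) * time for lv in labels])
    Xsti = np.column_stack([Xst, inter])

    rss0, rss_g, rss_s = rss(ones), rss(Xg), rss(Xs)
    rss_st, rss_sti = rss(Xst), rss(Xsti)
    ss_group, ss_subj = rss0 - rss_g, rss_g - rss_s
    ss_time, ss_inter, ss_err = rss_s - rss_st, rss_st - rss_sti, rss_sti
    f_group = (ss_group / (k - 1)) / (ss_subj / (N - k))
    f_time = (ss_time / 1) / (ss_err / (N - k))
    f_inter = (ss_inter / (k - 1)) / (ss_err / (N - k))
    return f_group, f_time, f_inter


class TestMixedAnova:
    def test_worked_micro_example(self):
        res = mixed_anova(micro_table(), "roi")
        np.testing.assert_allclose(res["group"].f, 0.36, atol=1e-10)
        np.testing.assert_allclose(res["challenge"].f, 25.0, atol=1e-10)
        np.testing.assert_allclose(res["interaction"].f, 9.0, atol=1e-10)
        assert (res["group"].df, res["challenge"].df) == (1, 1)
        assert res.effects["subjects_within"].df == 2

    def test_no_change_gives_zero_challenge_ss(self, rng):
        n = 12
        pre = rng.normal(60, 10, size=n)
        groups = np.repeat(["A", "B", "C"], 4)
        res = mixed_anova_arrays(pre, pre.copy(), groups)
        assert res["challenge"].ss == pytest.approx(0.0, abs=1e-12)
        assert res["challenge"].f == pytest.approx(0.0, abs=1e-10)

    def test_stratum_ss_add_to_total(self, rng):
        for _ in range(10):
            sizes = rng.integers(2, 8, size=3)
            groups = np.repeat(["A", "B", "C"], sizes)
            n = len(groups)
            pre = rng.normal(60, 10, size=n)
            post = pre + rng.normal(-3, 5, size=n)
            res = mixed_anova_arrays(pre, post, groups)
            parts = sum(res.effects[e].ss for e in
                        ("group", "subjects_within", "challenge",
                         "interaction", "residual"))
            np.testing.assert_allclose(parts, res.ss_total, atol=1e-8)

    def test_agrees_with_linear_model_oracle(self, rng):
        worst = 0.0
        for _ in range(100):
            k = int(rng.integers(2, 4))
            n_per = int(rng.integers(3, 7))
            groups = np.repeat([f"g{i}" for i in range(k)], n_per)
            pre = rng.normal(60, 10, size=len(groups))
            post = pre + rng.normal(-2, 4, size=len(groups))
            res = mixed_anova_arrays(pre, post, groups)
            fg, ft, fi = oracle_mixed_f(pre, post, groups)
            worst = max(worst, abs(res["group"].f - fg),
                        abs(res["challenge"].f - ft),
                        abs(res["interaction"].f - fi))
        assert worst < 1e-8

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        groups = np.repeat(["A", "B", "C"], 8)
        pre = rng.normal(60, 10, size=24)
        post = pre + rng.normal(-3, 5, size=24)
        res = mixed_anova_arrays(pre, post, groups)
        d = pd.DataFrame({
            "subj": np.tile(np.arange(24), 2),
            "grp": np.tile(groups, 2),
            "time": np.repeat(["pre", "post"], 24),
            "y": np.concatenate([pre, post]),
        })
        pg = pingouin.mixed_anova(data=d, dv="y", within="time",
                                  between="grp", subject="subj")
        np.testing.assert_allclose(res["group"].f,
                                   pg.loc[pg.Source == "grp", "F"].item(),
                                   rtol=1e-8)
        np.testing.assert_allclose(res["interaction"].f,
                                   pg.loc[pg.Source == "Interaction", "F"].item(),
                                   rtol=1e-8)

    def test_complete_case_handling(self):
        t = simulate_cohort(CohortSpec(seed=1))
        assert t["cbf_post_acc"].isna().sum() == 1
        res = mixed_anova(t, "acc")
        assert sum(res.n_per_group.values()) == len(t) - 1

    def test_small_group_error_names_group(self):
        t = pd.DataFrame({"group": ["A", "A", "B"],
                          "cbf_pre_roi": [1.0, 2.0, 3.0],
                          "cbf_post_roi": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="'B'"):
            mixed_anova(t, "roi")

    def test_sidak_contrasts_present(self):
        t = simulate_cohort(CohortSpec(seed=2))
        res = mixed_anova(t, "striatum")
        assert len(res.contrasts) == 3
        for c in res.contrasts:
            assert c.p_sidak >= c.p_unadjusted - 1e-15


class TestOnewayAnova:
    def test_hand_computed_example(self):
        res = oneway_anova([1, 2, 3, 4, 5, 6],
                           ["a", "a", "a", "b", "b", "b"])
        np.testing.assert_allclose(res["group"].f, 13.5, atol=1e-12)
        assert res["group"].df == 1 and res.effects["residual"].df == 4

    def test_zero_within_variance_is_error(self):
        with pytest.raises(ValueError, match="F undefined"):
            oneway_anova([1, 1, 2, 2], ["a", "a", "b", "b"])

    def test_orthogonal_covariate_leaves_f_close(self, rng):
        n = 30
        groups = np.repeat(["a", "b", "c"], 10)
        y = rng.normal(0, 1, size=n) + (groups == "a") * 1.5
        cov = rng.normal(size=n)
        cov = cov - cov.mean()
        # orthogonalize against group dummies
        for g in ("a", "b", "c"):
            sel = groups == g
            cov[sel] -= cov[sel].mean()
        plain = oneway_anova(y, groups)
        adj = oneway_anova(y, groups, covariates=cov)
        np.testing.assert_allclose(adj["group"].f, plain["group"].f, rtol=0.15)

    def test_singular_covariate_design_raises(self):
        y = [1.0, 2.0, 3.0, 4.0]
        groups = ["a", "a", "b", "b"]
        cov = np.column_stack([[1, 1, 1, 1], [2, 2, 2, 2]])  # collinear
        with pytest.raises(ValueError, match="singular"):
            oneway_anova(y, groups, covariates=cov)


class TestSidak:
    def test_closed_form(self):
        np.testing.assert_allclose(sidak_adjust(0.02, 3), 1 - 0.98 ** 3,
                                   rtol=1e-12)
        np.testing.assert_allclose(sidak_adjust(0.02, 3), 0.058808, atol=1e-6)

    def test_single_comparison_unchanged(self):
        assert sidak_adjust(0.3, 1) == pytest.approx(0.3)

    def test_endpoints(self):
        assert sidak_adjust(0.0, 5) == 0.0
        assert sidak_adjust(1.0, 5) == 1.0

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0, 1), st.integers(1, 20))
    def test_adjustment_never_decreases(self, p, m):
        adj = sidak_adjust(p, m)
        assert 0.0 <= adj <= 1.0 and adj >= p - 1e-12


class TestPearson:
    def test_perfect_linear(self):
        r, p = pearson_r([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_hand_computed(self):
        r, _ = pearson_r([1, 2, 3], [2, 1, 3])
        assert r == pytest.approx(0.5)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_affine_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1, _ = pearson_r(x, y)
        r2, _ = pearson_r(3 * x - 7, 0.5 * y + 2)
        assert r1 == pytest.approx(r2)


class TestDrugUse:
    def test_cutoff_boundaries(self):
        rec = pd.DataFrame({
            "cannabis_per_week": [1.0, 1.5],
            "mdma_lifetime": [10, 11],
            "cocaine_lifetime": [11, 10],
            "amphetamine_lifetime": [0, 100],
        })
        out = dichotomize_drug_use(rec)
        assert list(out["cannabis_user"]) == [False, True]
        assert list(out["mdma_user"]) == [False, True]
        assert list(out["cocaine_user"]) == [True, False]
        assert list(out["amphetamine_user"]) == [False, True]

    def test_missing_field_excluded(self):
        rec = pd.DataFrame({"cannabis_per_week": [2.0, np.nan]})
        out = dichotomize_drug_use(rec)
        assert out["cannabis_user"][0] is True or out["cannabis_user"][0] == True  # noqa: E712
        assert pd.isna(out["cannabis_user"][1])
        assert out["mdma_user"].isna().all()


class TestChiSquare:
    def test_equal_proportions_zero(self):
        chi2, df, p = chi_square([[10, 10], [20, 20], [5, 5]])
        assert chi2 == pytest.approx(0.0)
        assert df == 2 and p == pytest.approx(1.0)

    def test_cocaine_contingency_hand_value(self):
        # users/non-users per group reconstructed from 0%/24%/19% of 26/29/26
        chi2, df, p = chi_square([[0, 26], [7, 22], [5, 21]])
        assert chi2 == pytest.approx(6.92, abs=0.02)
        assert df == 2
        assert p == pytest.approx(0.032, abs=0.002)

    def test_doubling_cells_doubles_statistic(self):
        t = np.array([[3, 7], [6, 4], [5, 5]])
        c1, _, _ = chi_square(t)
        c2, _, _ = chi_square(2 * t)
        assert c2 == pytest.approx(2 * c1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square([[0, 0], [5, 5]])


class TestBattery:
    def test_full_battery_structure(self):
        t = simulate_cohort(CohortSpec(seed=8))
        out = run_battery(t)
        assert set(out["rois"]) == {"striatum", "thalamus", "acc"}
        for roi in out["rois"].values():
            assert "mixed_anova" in roi and "baseline_anova" in roi
        assert set(out["drug_use"]) == {"cannabis", "mdma", "cocaine",
                                        "amphetamine"}

    def test_drug_table_counts(self):
        t = simulate_cohort(CohortSpec(seed=9))
        tab = drug_use_table(t, "cannabis")
        assert tab.sum() == len(t)

    def test_covariate_adjustment_runs(self):
        t = simulate_cohort(CohortSpec(seed=10))
        out = run_battery(t, covariates=["age", "adhd_rs"])
        for roi in out["rois"].values():
            assert "baseline_anova_adjusted" in roi
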