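"""Composite (DCMS) machinery: ranks, robust covariance, score, fit, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sweepscan.dcms import (
    DcmsConfig,
    dcms_score,
    exhaustive_mcd,
    fast_mcd,
    fit_normal_pvalues,
    qvalues,
    rank_to_pvalue,
    robust_correlation,
    storey_pi0,
)


class TestRankToPvalue:
    def test_right_tail_counting(self):
        np.testing.assert_allclose(
            rank_to_pvalue(np.array([3.0, 1, 2]), "right"), [1 / 3, 1, 2 / 3]
        )

    def test_left_tail_mirror(self):
        np.testing.assert_allclose(
            rank_to_pvalue(np.array([3.0, 1, 2]), "left"), [1, 1 / 3, 2 / 3]
        )

    def test_ties_at_maximum(self):
        p = rank_to_pvalue(np.array([5.0, 5.0, 1.0, 2.0]), "right")
        assert p[0] == p[1] == pytest.approx(2 / 4)

    def test_missing_propagates(self):
        p = rank_to_pvalue(np.array([1.0, np.nan, 2.0]), "right")
        assert np.isnan(p[1]) and not np.isnan(p[0])

    def test_constant_vector_warns_all_one(self):
        with pytest.warns(UserWarning, match="constant"):
            p = rank_to_pvalue(np.full(5, 2.0), "right")
        assert (p == 1.0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_tail_overlap_identity(self, seed):
        """p_left + p_right >= 1 + 1/n (each side counts the tie block)."""
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(size=30), 1)  # rounding forces ties
        pl = rank_to_pvalue(x, "left")
        pr = rank_to_pvalue(x, "right")
        assert (pl + pr >= 1 + 1 / len(x) - 1e-12).all()


class TestFastMcd:
    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_minimum_determinant(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(8, 13))
        x = rng.normal(size=(n, 2))
        x[: max(1, n // 5)] += 8  # gross outliers
        _, _, rows = fast_mcd(x, alpha=0.75, seed=trial, n_starts=200)
        det_best, rows_best = exhaustive_mcd(x, alpha=0.75)
        sub = x[rows]
        det_got = float(np.linalg.det(np.cov(sub, rowvar=False)))
        assert det_got == pytest.approx(det_best, rel=1e-9)

    def test_recovers_known_correlation(self):
        rng = np.random.default_rng(7)
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        x = rng.multivariate_normal([0, 0], cov, size=5000)
        _, c, _ = fast_mcd(x, alpha=0.75, seed=1, n_starts=50)
        r = c[0, 1] / np.sqrt(c[0, 0] * c[1, 1])
        assert r == pytest.approx(0.8, abs=0.05)

    def test_duplicate_statistic_gives_unit_correlation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=500)
        panel = pd.DataFrame({"x": a, "y": a.copy(), "z": rng.normal(size=500)})
        corr = robust_correlation(panel, ["x", "y", "z"], 500, 0.75, seed=0)
        assert corr.loc["x", "y"] == pytest.approx(1.0, abs=1e-6)

    def test_too_few_rows_rejected(self):
        panel = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="complete rows"):
            robust_correlation(panel, ["x", "y"], 10, 0.75, seed=0)


class TestDcmsScore:
    def _corr(self, r, names=("a", "b")):
        return pd.DataFrame(
            [[1.0, r], [r, 1.0]], index=list(names), columns=list(names)
        )

    def test_single_statistic_p_half_is_zero(self):
        corr = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        score = dcms_score(pd.DataFrame({"a": [0.5]}), corr)
        assert score[0] == pytest.approx(0.0)

    def test_perfectly_correlated_pair(self):
        # r=1 -> w=2 each; p=0.1 both -> log10(9)
        score = dcms_score(pd.DataFrame({"a": [0.1], "b": [0.1]}), self._corr(1.0))
        assert score[0] == pytest.approx(np.log10(9), abs=1e-12)

    def test_independent_pair_doubles_signal(self):
        score = dcms_score(pd.DataFrame({"a": [0.1], "b": [0.1]}), self._corr(0.0))
        assert score[0] == pytest.approx(2 * np.log10(9), abs=1e-12)

    def test_missing_p_gives_missing_score(self):
        score = dcms_score(
            pd.DataFrame({"a": [0.1, np.nan], "b": [0.1, 0.2]}), self._corr(0.0)
        )
        assert np.isnan(score[1]) and not np.isnan(score[0])

    def test_monotone_in_each_p(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.05, 0.95, size=(50, 2))
        corr = self._corr(0.3)
        s0 = dcms_score(pd.DataFrame(base, columns=["a", "b"]), corr)
        bumped = base.copy()
        bumped[:, 0] *= 0.5  # decrease p of one statistic
        s1 = dcms_score(pd.DataFrame(bumped, columns=["a", "b"]), corr)
        assert (s1 >= s0 - 1e-12).all()


class TestNormalFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1.7, 2.3, size=10_000)
        _, mu, sigma = fit_normal_pvalues(x)
        assert mu == pytest.approx(1.7, abs=0.05)
        assert sigma == pytest.approx(2.3, abs=0.05)

    def test_center_value_p_half(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=5000)
        x[0] = 0.0
        p, mu, sigma = fit_normal_pvalues(x)
        assert p[0] == pytest.approx(sps.norm.sf((0 - mu) / sigma))
        assert abs(p[0] - 0.5) < 0.02

    def test_robust_to_one_percent_contamination(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0, size=10_000)
        xc = x.copy()
        xc[:100] = 500.0
        _, mu0, s0 = fit_normal_pvalues(x)
        _, mu1, s1 = fit_normal_pvalues(xc)
        assert abs(mu1 - mu0) < 0.05 * max(1, abs(mu0)) + 0.02
        assert abs(s1 - s0) / s0 < 0.05
        # a plain moment fit is wrecked by the same contamination
        assert abs(xc.std() - 1.0) > 0.5

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_normal_pvalues(np.full(200, 1.0))


class TestQvalues:
    def test_bh_hand_worked(self):
        q = qvalues(np.array([0.01, 0.02, 0.03, 0.04]), method="bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_uniform_null_pi0_near_one(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=10_000)
        assert storey_pi0(p) == pytest.approx(1.0, abs=0.1)

    def test_all_ones(self):
        assert (qvalues(np.ones(30)) == 1.0).all()

    def test_monotone_in_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=500)
        q = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_small_n_falls_back_to_bh(self):
        with pytest.warns(UserWarning, match="BH"):
            q = qvalues(np.array([0.1, 0.5, 0.9]), method="storey")
        assert np.isfinite(q).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            qvalues(np.array([0.0, 0.5]))


class TestLibraryCrossChecks:
    def test_mcd_correlation_agrees_with_sklearn(self):
        """Independent route: scikit-learn's MinCovDet on clean Gaussian
        data should give nearly the same robust correlation."""
        from sklearn.covariance import MinCovDet

        rng = np.random.default_rng(11)
        cov = np.array([[1.0, 0.6, 0.0], [0.6, 1.0, 0.2], [0.0, 0.2, 1.0]])
        x = rng.multivariate_normal(np.zeros(3), cov, size=3000)
        _, c_ours, _ = fast_mcd(x, alpha=0.75, seed=0, n_starts=100)
        sk = MinCovDet(support_fraction=0.75, random_state=0).fit(x)
        def to_corr(c):
            sd = np.sqrt(np.diag(c))
            return c / np.outer(sd, sd)
        np.testing.assert_allclose(
            to_corr(c_ours), to_corr(sk.covariance_), atol=0.05
        )

    def test_bh_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        p = rng.uniform(size=200) ** 2
        ours = qvalues(p, method="bh")
        _, theirs, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestDcmsConfig:
    def test_alpha_bounds(self):
        with pytest.raises(ValueError, match="mcd_alpha"):
            DcmsConfig(mcd_alpha=0.3)

    def test_threshold_order(self):
        with pytest.raises(ValueError, match="q_strong"):
            DcmsConfig(q_boundary=0.005, q_strong=0.01)

    def test_default_tails(self):
        cfg = DcmsConfig()
        assert cfg.tails == {
            "h2h1": "right",
            "h12": "right",
            "fst_smoothed": "right",
            "pi_smoothed": "left",
            "tajimas_d": "left",
        }
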