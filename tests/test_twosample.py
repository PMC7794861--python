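"""Two-sample estimators against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from ivmr import (MREstimate, TwoSampleMR, cochran_q, ivw, mr_egger,
                  scale_per_doubling, to_odds_ratio, wald_ratio,
                  weighted_median)


def make_set(gamma, se_gamma, Gamma, se_Gamma):
    return pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(len(gamma))],
        "gamma": gamma, "se_gamma": se_gamma,
        "Gamma": Gamma, "se_Gamma": se_Gamma,
    })


@pytest.fixture(scope="module")
def random_set():
    rng = np.random.default_rng(11)
    j = 10
    return make_set(rng.normal(0.1, 0.03, j), rng.uniform(0.005, 0.02, j),
                    rng.normal(0.005, 0.004, j), rng.uniform(0.002, 0.01, j))


class TestWaldRatio:
    def test_formula_arithmetic(self):
        est = wald_ratio(0.1, 0.01, 0.002, 0.001)
        assert est.beta == pytest.approx(0.02)
        assert est.se == pytest.approx(0.01)

    def test_null_outcome_effect(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.001).beta == 0.0

    def test_zero_gamma_rejected(self):
        with pytest.raises(ValueError, match="instrument"):
            wald_ratio(0.0, 0.01, 0.1, 0.01)

    def test_second_order_se_dominates_and_matches_bootstrap(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            g = rng.uniform(0.2, 0.5)
            sg = rng.uniform(0.005, 0.02)
            G = rng.normal(0, 0.05)
            sG = rng.uniform(0.005, 0.02)
            first = wald_ratio(g, sg, G, sG)
            second = wald_ratio(g, sg, G, sG, second_order=True)
            assert second.se >= first.se
            draws = rng.normal(G, sG, 100_000) / rng.normal(g, sg, 100_000)
            assert second.se == pytest.approx(draws.std(), rel=0.05)


class TestIVW:
    def test_single_snp_reduces_to_wald(self, random_set):
        one = random_set.iloc[[3]]
        est = ivw(one)
        ref = wald_ratio(*one[["gamma", "se_gamma", "Gamma",
                               "se_Gamma"]].iloc[0])
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_identical_snps_average(self):
        j = 4
        s = make_set([0.1] * j, [0.01] * j, [0.005] * j, [0.002] * j)
        est = ivw(s)
        assert est.beta == pytest.approx(0.05)
        single = wald_ratio(0.1, 0.01, 0.005, 0.002)
        assert est.se == pytest.approx(single.se / np.sqrt(j))

    def test_matches_wls_through_origin_oracle(self, random_set):
        est = ivw(random_set)
        w = 1.0 / random_set["se_Gamma"] ** 2
        res = sm.WLS(random_set["Gamma"], random_set[["gamma"]],
                     weights=w).fit()
        assert est.beta == pytest.approx(res.params.iloc[0], rel=1e-10)
        # fixed-effect SE is the WLS SE with residual scale forced to 1
        se_oracle = float(np.sqrt(1.0 / np.sum(w * random_set["gamma"] ** 2)))
        assert est.se == pytest.approx(se_oracle, rel=1e-12)

    def test_random_mode_never_tighter_than_fixed(self, random_set):
        fixed = ivw(random_set, mode="fixed")
        mre = ivw(random_set, mode="multiplicative_random")
        assert mre.se >= fixed.se

    def test_allele_flip_invariance(self, random_set):
        # flipping both gamma and Gamma signs (allele relabeling) is a no-op
        flipped = random_set.copy()
        flipped[["gamma", "Gamma"]] *= -1
        assert ivw(flipped).beta == pytest.approx(ivw(random_set).beta)

    def test_single_snp_random_mode_falls_back(self, random_set):
        with pytest.warns(RuntimeWarning, match="falls back"):
            ivw(random_set.iloc[[0]], mode="multiplicative_random")


class TestEgger:
    def test_matches_wls_with_intercept_oracle(self, random_set):
        slope, intercept = mr_egger(random_set)
        w = 1.0 / random_set["se_Gamma"] ** 2
        X = sm.add_constant(random_set["gamma"])
        res = sm.WLS(random_set["Gamma"], X, weights=w).fit()
        assert slope.beta == pytest.approx(res.params["gamma"], rel=1e-10)
        assert intercept.beta == pytest.approx(res.params["const"], rel=1e-10)
        # SEs: statsmodels scales by RSS/(J-2); ours floors that factor at 1
        j = len(random_set)
        rss = float((w * res.resid**2).sum())
        factor = np.sqrt(max(1.0, rss / (j - 2)) / (rss / (j - 2)))
        assert slope.se == pytest.approx(res.bse["gamma"] * factor, rel=1e-8)

    def test_gamma_orientation_invariance(self, random_set):
        flipped = random_set.copy()
        flipped.loc[::2, ["gamma", "Gamma"]] *= -1
        s1, i1 = mr_egger(random_set)
        s2, i2 = mr_egger(flipped)
        assert s1.beta == pytest.approx(s2.beta)
        assert i1.beta == pytest.approx(i2.beta)

    def test_requires_three_instruments(self, random_set):
        with pytest.raises(ValueError, match="insufficient"):
            mr_egger(random_set.iloc[:2])


class TestWeightedMedian:
    def test_constant_ratios_recovered(self):
        s = make_set([0.1, 0.2, 0.4], [0.01] * 3, [0.03, 0.06, 0.12],
                     [0.01, 0.02, 0.03])
        est = weighted_median(s, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.3)

    def test_equal_weights_odd_count_is_plain_median(self):
        gamma = np.array([0.1] * 5)
        Gamma = np.array([0.01, 0.03, 0.02, 0.05, 0.04])
        s = make_set(gamma, [0.01] * 5, Gamma, [0.01] * 5)
        est = weighted_median(s, n_boot=200, seed=0)
        assert est.beta == pytest.approx(np.median(Gamma / gamma))

    def test_matches_bruteforce_interpolation_oracle(self, random_set):
        est = weighted_median(random_set, n_boot=200, seed=1)
        ratios = (random_set["Gamma"] / random_set["gamma"]).to_numpy()
        w = (random_set["gamma"] ** 2
             / random_set["se_Gamma"] ** 2).to_numpy()
        order = np.argsort(ratios)
        r, ww = ratios[order], w[order] / w.sum()
        cum = 0.0
        oracle = r[-1]
        for i in range(len(r)):
            prev, cum = cum, cum + ww[i]
            mid = cum - ww[i] / 2
            if mid >= 0.5:
                if i == 0:
                    oracle = r[0]
                else:
                    mid_prev = prev - ww[i - 1] / 2
                    frac = (0.5 - mid_prev) / (mid - mid_prev)
                    oracle = r[i - 1] + frac * (r[i] - r[i - 1])
                break
        assert est.beta == pytest.approx(oracle, rel=1e-10)

    def test_bootstrap_reps_guardrails(self, random_set):
        with pytest.raises(ValueError):
            weighted_median(random_set, n_boot=1)
        with pytest.warns(RuntimeWarning, match="n_boot"):
            weighted_median(random_set, n_boot=50, seed=0)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        s = make_set([0.1, 0.2], [0.01] * 2, [0.02, 0.04], [0.01, 0.01])
        het = cochran_q(s)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.pvalue == pytest.approx(1.0)

    def test_hand_computed_three_snp_set(self):
        # ratios 0.1, 0.2, 0.3 with weights gamma^2/se_Gamma^2 = 100, 400, 100
        s = make_set([0.1, 0.2, 0.1], [0.01] * 3, [0.01, 0.04, 0.03],
                     [0.01, 0.01, 0.01])
        pooled = ivw(s)
        # beta_pooled = (100*.1 + 400*.2 + 100*.3)/600 = 0.2
        assert pooled.beta == pytest.approx(0.2)
        # Q = 100*(0.1-0.2)^2 + 400*0 + 100*(0.3-0.2)^2 = 2.0
        het = cochran_q(s, pooled)
        assert het.q == pytest.approx(2.0)
        assert het.df == 2

    def test_chi_square_distribution_under_homogeneity(self):
        # strong instruments, common true ratio: Q ~ chi2(J-1)
        rng = np.random.default_rng(8)
        j, reps = 20, 300
        gamma = rng.uniform(0.3, 0.6, j)
        se_G = np.full(j, 0.01)
        qs = []
        for _ in range(reps):
            ghat = rng.normal(gamma, 0.001)
            Ghat = rng.normal(0.1 * gamma, se_G)
            s = make_set(ghat, np.full(j, 0.001), Ghat, se_G)
            qs.append(cochran_q(s).q)
        mean_q = np.mean(qs)
        mc_se = np.std(qs, ddof=1) / np.sqrt(reps)
        assert abs(mean_q - (j - 1)) < 3 * mc_se


class TestScales:
    def _binary_est(self, beta=1.0, se=0.2):
        return MREstimate.from_beta_se("ivw_fixed", beta, se, 5,
                                       exposure_type="binary")

    def test_per_doubling_is_ln2_rescale(self):
        est = self._binary_est(beta=1.0)
        d = scale_per_doubling(est)
        assert d.beta == pytest.approx(np.log(2))
        assert d.scale == "per_doubling"
        width = (est.ci_high - est.ci_low) * np.log(2)
        assert d.ci_high - d.ci_low == pytest.approx(width)
        assert scale_per_doubling(self._binary_est(beta=0.0)).beta == 0.0

    def test_per_doubling_requires_binary_exposure(self):
        cont = MREstimate.from_beta_se("ivw_fixed", 0.1, 0.02, 5,
                                       exposure_type="continuous")
        with pytest.raises(ValueError, match="binary"):
            scale_per_doubling(cont)
        with pytest.raises(ValueError, match="per-unit"):
            scale_per_doubling(scale_per_doubling(self._binary_est()))

    def test_odds_ratio_round_trip(self):
        est = MREstimate.from_beta_se("ivw_fixed", np.log(1.02), 0.01, 5)
        rep = to_odds_ratio(est)
        assert rep["or"] == pytest.approx(1.02, rel=1e-12)
        assert rep["estimate"] is est

    @given(beta=st.floats(-2, 2), se=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_log_or_identity(self, beta, se):
        est = MREstimate.from_beta_se("wald", beta, se, 1)
        assert np.log(to_odds_ratio(est)["or"]) == pytest.approx(beta,
                                                                 abs=1e-12)
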