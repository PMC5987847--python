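"""Split-sample summary-statistic MR estimators and their robustness
properties."""

import numpy as np
import pandas as pd
import pytest

from edumr.results import MRResult
from edumr.twosample import (
    Egger,
    IVW,
    SummaryStats,
    WeightedMedian,
    egger,
    ivw,
    method_concordance,
    split_sample,
    wald_ratio,
    weighted_median,
    weighted_mode,
)


def make_ss(beta_exp, beta_out, se_exp=0.01, se_out=0.05, **tags):
    bx = np.asarray(beta_exp, float)
    by = np.asarray(beta_out, float)
    L = len(bx)
    df = pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(L)],
            "ea": "A",
            "oa": "G",
            "beta_exp": bx,
            "se_exp": np.broadcast_to(se_exp, L).astype(float),
            "beta_out": by,
            "se_out": np.broadcast_to(se_out, L).astype(float),
            "n_exp": 5000,
            "n_out": 5000,
        }
    )
    return SummaryStats(df, **tags)


def simulated_ss(rng, n_var=69, beta=-0.27, pleio=None, se_exp=0.002, se_out=0.02):
    """Summary stats drawn from their sampling distributions with known
    causal slope and optional per-variant pleiotropic offsets."""
    bx_true = np.abs(rng.normal(0.05, 0.02, n_var)) + 0.01
    delta = np.zeros(n_var) if pleio is None else pleio
    bx = rng.normal(bx_true, se_exp)
    by = rng.normal(beta * bx_true + delta, se_out)
    return make_ss(bx, by, se_exp=se_exp, se_out=se_out)


class TestSplitSample:
    def test_partition_properties(self, rng):
        df = pd.DataFrame({"participant_id": [f"p{i}" for i in range(11)]})
        a, b = split_sample(df, seed=3)
        assert abs(len(a) - len(b)) <= 1
        ids = set(a["participant_id"]) | set(b["participant_id"])
        assert ids == set(df["participant_id"])
        assert set(a["participant_id"]) & set(b["participant_id"]) == set()

    def test_deterministic_given_seed(self):
        df = pd.DataFrame({"participant_id": range(10)})
        a1, _ = split_sample(df, seed=5)
        a2, _ = split_sample(df, seed=5)
        pd.testing.assert_frame_equal(a1, a2)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_sample(pd.DataFrame({"x": [1, 2, 3]}), seed=0)

    def test_half_estimates_uncorrelated_on_null_trait(self):
        rng = np.random.default_rng(17)
        slopes_a, slopes_b = [], []
        for _ in range(200):
            d = rng.binomial(2, 0.3, 300).astype(float)
            y = rng.normal(0, 1, 300)
            df = pd.DataFrame({"d": d, "y": y})
            a, b = split_sample(df, rng)
            slopes_a.append(np.polyfit(a["d"], a["y"], 1)[0])
            slopes_b.append(np.polyfit(b["d"], b["y"], 1)[0])
        r = np.corrcoef(slopes_a, slopes_b)[0, 1]
        assert abs(r) < 0.15

    def test_same_sample_tags_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            make_ss([0.1], [0.05], exposure_sample="A", outcome_sample="A")


class TestWaldRatio:
    def test_basic_ratio(self):
        est, _ = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est == pytest.approx(0.5)

    def test_sign_and_scale_of_se(self):
        est, se = wald_ratio(-0.1, 0.01, 0.05, 0.01)
        assert est == pytest.approx(-0.5)
        assert se == pytest.approx(0.1)

    def test_zero_exposure_association_flagged(self):
        est, se = wald_ratio(0.0, 0.01, 0.05, 0.01)
        assert np.isnan(est) and np.isnan(se)

    def test_first_order_se_brackets_monte_carlo(self):
        # strong instrument (|bx|/se_zx = 20): the delta-method SE should
        # agree with the simulated ratio SD within 10%
        rng = np.random.default_rng(5)
        bx, se_zx, by, se_zy = 1.0, 0.05, 0.5, 0.1
        draws = rng.normal(by, se_zy, 200_000) / rng.normal(bx, se_zx, 200_000)
        _, se = wald_ratio(bx, se_zx, by, se_zy)
        assert se == pytest.approx(np.std(draws), rel=0.10)


class TestIVW:
    def test_single_variant_equals_wald_ratio(self):
        ss = make_ss([0.1], [0.07], se_out=0.03)
        res = ivw(ss)
        w_est, w_se = wald_ratio(0.1, 0.01, 0.07, 0.03)
        assert res.estimate == pytest.approx(w_est, abs=1e-14)
        assert res.se == pytest.approx(w_se, abs=1e-14)

    def test_equal_se_closed_form(self):
        bx = np.array([0.1, 0.2, -0.1])
        by = np.array([0.05, 0.09, -0.06])
        res = ivw(make_ss(bx, by, se_out=0.05))
        assert res.estimate == pytest.approx(np.sum(bx * by) / np.sum(bx**2))

    def test_parameter_recovery_no_pleiotropy(self):
        rng = np.random.default_rng(9)
        res = ivw(simulated_ss(rng))
        assert abs(res.estimate - (-0.27)) < 3 * res.se

    def test_no_valid_variants_rejected(self):
        ss = make_ss([0.0], [0.05])
        with pytest.raises(ValueError, match="valid variants"):
            IVW(ss)


class TestEgger:
    def test_recovery_with_zero_intercept(self):
        rng = np.random.default_rng(13)
        res = egger(simulated_ss(rng))
        assert abs(res.intercept["estimate"]) < 3 * res.intercept["se"]
        assert abs(res.estimate - (-0.27)) < 3 * res.se

    def test_planted_directional_pleiotropy_recovered(self):
        rng = np.random.default_rng(14)
        delta = 0.02
        ss = simulated_ss(rng, pleio=np.full(69, delta))
        res = egger(ss)
        res_ivw = ivw(ss)
        assert abs(res.intercept["estimate"] - delta) < 3 * res.intercept["se"]
        assert abs(res.estimate - (-0.27)) < abs(res_ivw.estimate - (-0.27))

    def test_collinear_design_rejected(self):
        ss = make_ss([0.1, 0.1, 0.1], [0.05, 0.06, 0.04])
        with pytest.raises(ValueError, match="collinear"):
            egger(ss)

    def test_intercept_constrained_to_zero_equals_ivw(self):
        rng = np.random.default_rng(15)
        ss = simulated_ss(rng, n_var=20)
        constrained = Egger(ss, intercept=False).fit()
        res_ivw = ivw(ss)
        assert constrained.estimate == pytest.approx(res_ivw.estimate, abs=1e-14)

    def test_orientation_invariance(self):
        # flipping the sign of both associations of a variant leaves the
        # Egger fit unchanged (internal orientation to beta_exp >= 0)
        rng = np.random.default_rng(16)
        ss = simulated_ss(rng, n_var=12)
        df = ss.df.copy()
        df.loc[0, ["beta_exp", "beta_out"]] *= -1
        flipped = SummaryStats(df)
        a, b = egger(ss), egger(flipped)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
        assert a.intercept["estimate"] == pytest.approx(
            b.intercept["estimate"], abs=1e-12
        )

    def test_too_few_variants(self):
        with pytest.raises(ValueError, match=">= 3"):
            egger(make_ss([0.1, 0.2], [0.05, 0.1]))


class TestWeightedMedian:
    def test_hand_computed_crossing(self):
        # ratios {0.2, 0.3, 1.0} with equal weights: the mid-point
        # cumulative weights are {1/6, 1/2, 5/6}, so 0.5 falls on 0.3
        ss = make_ss([1.0, 1.0, 1.0], [0.2, 0.3, 1.0], se_out=0.05)
        res = weighted_median(ss, n_boot=50, seed=1)
        assert res.estimate == pytest.approx(0.3, abs=1e-12)

    def test_identical_ratios(self):
        ss = make_ss([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], se_out=0.01)
        res = weighted_median(ss, n_boot=200, seed=1)
        assert res.estimate == pytest.approx(0.5, abs=1e-12)
        assert res.se < 0.2

    def test_majority_valid_robustness(self):
        # 49% of the weight carries large pleiotropy: the weighted median
        # stays near the truth while IVW is dragged away
        rng = np.random.default_rng(19)
        n_var = 69
        n_bad = 34  # 34/69 = 49% of equally weighted variants
        pleio = np.zeros(n_var)
        pleio[:n_bad] = 0.08
        bx_true = np.full(n_var, 0.05)
        bx = rng.normal(bx_true, 0.002)
        by = rng.normal(-0.27 * bx_true + pleio, 0.002)
        ss = make_ss(bx, by, se_exp=0.002, se_out=0.002)
        wm = weighted_median(ss, n_boot=300, seed=2)
        res_ivw = ivw(ss)
        assert abs(wm.estimate - (-0.27)) < 3 * wm.se
        assert abs(res_ivw.estimate - (-0.27)) > 3 * res_ivw.se

    def test_duplicating_tail_variant_with_half_weight_invariant(self):
        bx = np.array([1.0, 1.0, 1.0, 1.0])
        by = np.array([0.1, 0.3, 0.35, 0.9])
        ss = make_ss(bx, by, se_out=0.05)
        base = weighted_median(ss, n_boot=10, seed=1).estimate
        # duplicate the lowest-ratio variant, halving its weight
        # (inverse-variance weight halves when se multiplies by sqrt(2))
        df = ss.df.copy()
        dup = df.iloc[[0]].assign(rsid="rs_dup", se_out=0.05 * np.sqrt(2))
        df.loc[0, "se_out"] = 0.05 * np.sqrt(2)
        ss2 = SummaryStats(pd.concat([df, dup], ignore_index=True))
        dup_est = weighted_median(ss2, n_boot=10, seed=1).estimate
        assert dup_est == pytest.approx(base, abs=1e-12)


class TestWeightedMode:
    def test_cluster_with_outlier(self):
        bx = np.ones(8)
        by = np.array([0.48, 0.5, 0.52, 0.49, 0.51, 0.5, 0.47, 5.0])
        res = weighted_mode(make_ss(bx, by, se_out=0.05), n_boot=50, seed=3)
        assert res.estimate == pytest.approx(0.5, abs=0.05)

    def test_single_tight_cluster_centre(self):
        bx = np.ones(5)
        by = np.full(5, 0.7)
        res = weighted_mode(make_ss(bx, by, se_out=0.05), n_boot=50, seed=3)
        assert res.estimate == pytest.approx(0.7, abs=1e-9)

    def test_plurality_valid_recovery(self):
        # 40% of weight at the valid ratio, two 30% pleiotropic blocs
        rng = np.random.default_rng(23)
        ratios = np.concatenate([
            rng.normal(0.5, 0.02, 8),   # valid plurality
            rng.normal(2.0, 0.02, 6),
            rng.normal(-1.0, 0.02, 6),
        ])
        ss = make_ss(np.ones(20), ratios, se_out=0.05)
        res = weighted_mode(ss, n_boot=50, seed=4)
        assert res.estimate == pytest.approx(0.5, abs=0.1)


class TestBootstrap:
    def test_seed_reproducibility(self):
        rng = np.random.default_rng(29)
        ss = simulated_ss(rng, n_var=15)
        a = weighted_median(ss, n_boot=200, seed=11)
        b = weighted_median(ss, n_boot=200, seed=11)
        assert a.se == b.se

    def test_bootstrap_convergence(self):
        rng = np.random.default_rng(31)
        ss = simulated_ss(rng, n_var=30)
        se1 = weighted_median(ss, n_boot=1000, seed=7).se
        se2 = weighted_median(ss, n_boot=2000, seed=7).se
        assert abs(se2 - se1) / se1 < 0.05


class TestConcordance:
    def _res(self, est, se=0.05, method="ivw"):
        return MRResult(method=method, exposure="edu", outcome="mse",
                        estimate=est, se=se, p=0.5, n=100)

    def test_identical_results(self):
        rep = method_concordance([self._res(-0.2), self._res(-0.2, method="egger")])
        assert rep["range"] == 0.0
        assert rep["sign_agreement"] is True
        assert rep["max_pairwise_z"] == 0.0

    def test_reported_estimate_range(self):
        rep = method_concordance(
            [self._res(-0.17), self._res(-0.27, method="egger"),
             self._res(-0.40, method="weighted_median")]
        )
        assert rep["range"] == pytest.approx(0.23)
        assert rep["sign_agreement"] is True

    def test_opposite_signs_flagged(self):
        rep = method_concordance([self._res(-0.2), self._res(0.1, method="egger")])
        assert rep["sign_agreement"] is False

    def test_mixed_directions_rejected(self):
        other = MRResult(method="ivw", exposure="mse", outcome="edu",
                         estimate=0.0, se=1.0, p=0.9, n=10)
        with pytest.raises(ValueError, match="mixed"):
            method_concordance([self._res(-0.2), other])
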