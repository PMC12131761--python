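"""The seven causal estimators, heterogeneity diagnostics and leave-one-out."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabomr.estimators import (cml, cochran_q, contamination_mixture, egger,
                                 ivw, leave_one_out, mr_lasso, wald_ratio,
                                 weighted_median)
from metabomr.instruments import InstrumentSet
from metabomr.simulate import ScenarioConfig, as_instruments, simulate_pair


def equal_weight_set(ratios, bx=1.0, se=0.1):
    """Instruments whose ratio estimates are ``ratios`` with equal weights."""
    k = len(ratios)
    return InstrumentSet.from_arrays([bx] * k, [0.01] * k,
                                     [bx * r for r in ratios], [se] * k)


class TestWaldRatio:
    def test_point_and_se(self):
        est = wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)

    def test_null_outcome_gives_p_one(self):
        est = wald_ratio(1.0, 0.05, 0.0, 0.02)
        assert est.beta == 0.0
        assert est.p == pytest.approx(1.0)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.05, 0.1, 0.02)

    def test_first_order_se_close_to_monte_carlo_when_strong(self, rng):
        """At F > 100 the delta SE is within 5% of the simulated ratio SD."""
        bx, sx, by, sy = 0.5, 0.01, 0.1, 0.02  # F = 2500
        draws = rng.normal(by, sy, 200_000) / rng.normal(bx, sx, 200_000)
        assert wald_ratio(bx, sx, by, sy).se == pytest.approx(
            draws.std(), rel=0.05)


class TestIVW:
    def test_equal_weight_mean_of_two_ratios(self):
        est = ivw(equal_weight_set([0.1, 0.3]))
        assert est.beta == pytest.approx(0.2)

    def test_matches_closed_form_weighted_mean(self, rng):
        bx = rng.uniform(0.05, 0.2, 15)
        sy = rng.uniform(0.01, 0.05, 15)
        by = rng.normal(0.1 * bx, sy)
        ins = InstrumentSet.from_arrays(bx, [0.01] * 15, by, sy)
        w = bx**2 / sy**2
        expected = np.sum(w * (by / bx)) / np.sum(w)
        assert ivw(ins).beta == pytest.approx(expected, abs=1e-12)

    def test_mre_se_never_below_fixed_effect(self, clean_instruments):
        ins, _ = clean_instruments
        assert ivw(ins, model="mre").se >= ivw(ins, model="fe").se - 1e-15

    def test_single_variant_rejected(self):
        with pytest.raises(ValueError):
            ivw(InstrumentSet.from_arrays([0.1], [0.01], [0.02], [0.01]))


class TestEgger:
    def test_exact_line_recovers_slope_and_zero_intercept(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        ins = InstrumentSet.from_arrays(bx, [0.01] * 4, 0.3 * bx, [0.02] * 4)
        est = egger(ins)
        assert est.beta == pytest.approx(0.3, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_directional_pleiotropy_lands_in_intercept(self, rng):
        """Data with mean direct effect 0.05 yield intercept ~0.05."""
        reps = []
        for s in range(60):
            r = np.random.default_rng(s)
            bx = r.uniform(0.05, 0.2, 30)
            alpha = r.normal(0.05, 0.01, 30)  # InSIDE holds: alpha indep of bx
            by = r.normal(0.1 * bx + alpha, 0.01)
            ins = InstrumentSet.from_arrays(bx, [0.005] * 30, by, [0.01] * 30)
            reps.append(egger(ins).extras["intercept"])
        assert np.mean(reps) == pytest.approx(0.05, abs=0.01)

    def test_intercept_p_uniform_without_pleiotropy(self):
        ps = []
        for s in range(200):
            r = np.random.default_rng(1000 + s)
            bx = r.uniform(0.05, 0.2, 20)
            by = r.normal(0.1 * bx, 0.01)
            ins = InstrumentSet.from_arrays(bx, [0.005] * 20, by, [0.01] * 20)
            ps.append(egger(ins).extras["p_intercept"])
        assert np.mean(np.array(ps) < 0.05) == pytest.approx(0.05, abs=0.04)


class TestWeightedMedian:
    def test_simple_median_with_equal_weights(self):
        est = weighted_median(equal_weight_set([0.1, 0.2, 0.3]))
        assert est.beta == pytest.approx(0.2)

    def test_matches_percentile_oracle(self, rng):
        """Interpolated weighted median equals the exhaustive definition."""
        bx = rng.uniform(0.05, 0.2, 9)
        sy = rng.uniform(0.01, 0.03, 9)
        by = rng.normal(0.1 * bx, sy)
        ins = InstrumentSet.from_arrays(bx, [0.005] * 9, by, sy)
        theta = by / bx
        w = bx**2 / sy**2
        order = np.argsort(theta)
        t, ww = theta[order], w[order] / w.sum()
        s = np.cumsum(ww) - ww / 2
        j = np.searchsorted(s, 0.5)
        expected = t[j - 1] + (t[j] - t[j - 1]) * (0.5 - s[j - 1]) / (s[j] - s[j - 1])
        assert weighted_median(ins).beta == pytest.approx(expected, abs=1e-12)

    def test_outlier_with_small_weight_ignored(self):
        # gross outlier ratio carried by a tiny weight leaves the median
        # at the median of the remaining ratios
        bx = [1, 1, 1, 1, 0.01]
        by = [0.1, 0.2, 0.3, 0.25, 50 * 0.01]
        ins = InstrumentSet.from_arrays(bx, [0.01] * 5, by, [0.1] * 5)
        assert weighted_median(ins).beta == pytest.approx(0.225, abs=0.03)

    def test_penalisation_reduces_outlier_weight(self, outlier_instruments):
        ins, theta = outlier_instruments
        pen = weighted_median(ins, penalised=True, seed=0)
        unpen = weighted_median(ins, penalised=False, seed=0)
        # oracle for the penalty factor of the planted outlier (ratio = 1)
        from scipy import stats
        t = ins.table
        ratios = t["beta_out"] / t["beta_exp"]
        w = t["beta_exp"] ** 2 / t["se_out"] ** 2
        q_out = (w * (ratios - unpen.beta) ** 2).iloc[-1]
        assert min(1.0, 20 * stats.chi2.sf(q_out, 1)) < 1e-6
        # the outlier pulls the plain median up; penalising removes the pull
        assert pen.beta <= unpen.beta + 1e-12

    def test_bootstrap_seeded_reproducible(self, clean_instruments):
        ins, _ = clean_instruments
        a = weighted_median(ins, seed=42)
        b = weighted_median(ins, seed=42)
        assert a.se == b.se


class TestLasso:
    def test_clean_data_keeps_all_and_equals_ivw(self, clean_instruments):
        ins, _ = clean_instruments
        est = mr_lasso(ins)
        assert est.extras["n_valid"] == len(ins)
        assert est.beta == pytest.approx(ivw(ins).beta, abs=1e-10)

    def test_planted_outlier_excluded(self, outlier_instruments):
        ins, _ = outlier_instruments
        est = mr_lasso(ins)
        assert "v_outlier" in est.extras["invalid_variants"]

    def test_estimate_equals_ivw_on_valid_subset(self, outlier_instruments):
        ins, _ = outlier_instruments
        est = mr_lasso(ins)
        valid = [v for v in ins.table["variant_id"]
                 if v not in est.extras["invalid_variants"]]
        sub = ins.table.set_index("variant_id").loc[valid].reset_index()
        sub_ins = InstrumentSet("e", "o", sub)
        assert est.beta == pytest.approx(ivw(sub_ins).beta, abs=1e-12)


class TestContaminationMixture:
    def test_all_valid_recovers_truth(self, clean_instruments):
        ins, theta = clean_instruments
        est = contamination_mixture(ins)
        assert est.beta == pytest.approx(theta, abs=0.03)
        assert len(est.extras["valid_variants"]) >= len(ins) - 2

    def test_half_invalid_identified_and_ci_covers(self):
        hits = 0
        covered = 0
        for s in range(30):
            r = np.random.default_rng(s)
            bx = r.uniform(0.04, 0.08, 20)
            valid = np.arange(20) < 10
            by = r.normal(np.where(valid, 0.2 * bx, 0.0), 0.003)
            ins = InstrumentSet.from_arrays(r.normal(bx, 0.004), [0.004] * 20,
                                            by, [0.003] * 20)
            est = contamination_mixture(ins)
            called_valid = np.isin(ins.table["variant_id"],
                                   est.extras["valid_variants"])
            hits += np.mean(called_valid == valid) > 0.8
            covered += est.ci_low <= 0.2 <= est.ci_high
        assert hits >= 24
        assert covered >= 24

    def test_too_few_variants_rejected(self):
        with pytest.raises(ValueError):
            contamination_mixture(
                InstrumentSet.from_arrays([0.1], [0.01], [0.02], [0.01]))


class TestCML:
    def test_k0_equals_fixed_effect_ivw(self, clean_instruments):
        ins, _ = clean_instruments
        est = cml(ins)
        assert est.extras["theta_by_k"][0] == pytest.approx(
            ivw(ins, model="fe").beta, abs=1e-8)

    def test_planted_invalid_pair_detected(self):
        k_hats = []
        for s in range(20):
            r = np.random.default_rng(s)
            bx = r.uniform(0.04, 0.08, 12)
            by = r.normal(0.1 * bx, 0.003)
            by[0] += 0.05
            by[1] -= 0.06
            ins = InstrumentSet.from_arrays(bx, [0.004] * 12, by, [0.003] * 12)
            est = cml(ins)
            # the two planted invalid instruments always carry direct effects;
            # BIC may add the odd borderline variant on noisy replicates
            assert {"v0", "v1"} <= set(est.extras["invalid_variants"])
            k_hats.append(est.extras["k_hat"])
        assert int(np.median(k_hats)) == 2

    def test_minimal_three_variant_case_runs(self):
        ins = equal_weight_set([0.1, 0.2, 0.3])
        est = cml(ins)
        assert set(est.extras["theta_by_k"]) == {0, 1}


class TestHeterogeneityAndLOO:
    def test_identical_ratios_give_zero_q(self):
        q, p = cochran_q(equal_weight_set([0.2, 0.2, 0.2]))
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_q_matches_textbook_formula(self, rng):
        bx = rng.uniform(0.05, 0.2, 8)
        sy = rng.uniform(0.01, 0.05, 8)
        by = rng.normal(0.1 * bx, sy)
        ins = InstrumentSet.from_arrays(bx, [0.005] * 8, by, sy)
        theta = by / bx
        se_t = sy / np.abs(bx)
        w = 1 / se_t**2
        t0 = np.sum(w * theta) / np.sum(w)
        q, _ = cochran_q(ins)
        assert q == pytest.approx(np.sum(w * (theta - t0) ** 2), rel=1e-9)

    def test_overdispersion_inflates_q(self):
        qs = []
        for s in range(100):
            r = np.random.default_rng(s)
            bx = r.uniform(0.1, 0.2, 10)
            sy = np.full(10, 0.01)
            # outcome noise variance 5x the assumed sampling variance
            by = r.normal(0.1 * bx, np.sqrt(5.0) * sy)
            ins = InstrumentSet.from_arrays(bx, [1e-4] * 10, by, sy)
            qs.append(cochran_q(ins)[0] / 9)
        # Q/(k-1) estimates the variance inflation factor
        assert np.mean(qs) == pytest.approx(5.0, rel=0.2)

    def test_loo_flags_single_driver(self):
        e, o, t = simulate_pair(ScenarioConfig(seed=2, regime="single_locus",
                                               n_snps=5))
        table, influential = leave_one_out(as_instruments(e, o))
        assert len(table) == 5
        assert influential == t["driver"]

    def test_homogeneous_signal_flags_nothing(self, clean_instruments):
        ins, _ = clean_instruments
        table, influential = leave_one_out(ins)
        assert len(table) == len(ins)
        assert influential is None


@pytest.mark.parametrize("method", ["ivw", "egger", "wmedian", "lasso",
                                    "contmix", "cml"])
def test_allele_relabel_symmetry(method, clean_instruments):
    """Flipping (beta_exp, beta_out) signs of any variant leaves estimates
    unchanged (allele relabelling must not matter)."""
    ins, _ = clean_instruments
    t = ins.table.copy()
    flip = np.resize([1.0, -1.0], len(t))
    t["beta_exp"] = t["beta_exp"] * flip
    t["beta_out"] = t["beta_out"] * flip
    flipped = InstrumentSet("e", "o", t)
    runners = {
        "ivw": lambda x: ivw(x).beta,
        "egger": lambda x: egger(x).beta,
        "wmedian": lambda x: weighted_median(x, seed=0).beta,
        "lasso": lambda x: mr_lasso(x).beta,
        "contmix": lambda x: contamination_mixture(x).beta,
        "cml": lambda x: cml(x).beta,
    }
    assert runners[method](flipped) == pytest.approx(runners[method](ins),
                                                     abs=1e-9)


@given(theta=st.floats(-0.5, 0.5), scale=st.floats(0.5, 2.0))
@settings(max_examples=20, deadline=None)
def test_ivw_equivariance_under_outcome_scaling(theta, scale):
    """Scaling all outcome betas and SEs by c scales the IVW estimate by c."""
    rng = np.random.default_rng(0)
    bx = rng.uniform(0.05, 0.2, 10)
    sy = rng.uniform(0.01, 0.03, 10)
    by = rng.normal(theta * bx, sy)
    base = ivw(InstrumentSet.from_arrays(bx, [0.01] * 10, by, sy))
    scaled = ivw(InstrumentSet.from_arrays(bx, [0.01] * 10,
                                           by * scale, sy * scale))
    assert scaled.beta == pytest.approx(base.beta * scale, rel=1e-9)
    assert scaled.p == pytest.approx(base.p, rel=1e-9)
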