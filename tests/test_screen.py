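"""FDR, sensitivity verdict, verdict classification and the full screen."""

import numpy as np
import pytest

from metabomr.estimators import MREstimate, MRDiagnostics, SENSITIVITY_METHODS
from metabomr.screen import (ScreenConfig, bh_fdr, classify, reverse_mr,
                             run_screen, sensitivity_verdict, wald_refit)
from metabomr.screen import TestRecord as ScreenTestRecord
from metabomr.simulate import ScenarioConfig, make_ld_block, simulate_pair
from tests.conftest import make_sumstats


def brute_force_bh(p):
    """Step-up oracle straight from the definition."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBHFDR:
    def test_three_ordered_p_values(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_empty_list(self):
        assert len(bh_fdr([])) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        p = np.random.default_rng(seed).uniform(1e-6, 1, 37)
        np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), rtol=1e-12)

    def test_monotone_in_rank(self, rng):
        p = np.sort(rng.uniform(0, 1, 25))
        adj = bh_fdr(p)
        assert (np.diff(adj) >= -1e-15).all()

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 10)
        assert (bh_fdr(p) >= p - 1e-15).all()


def _fake_est(beta, p, method="ivw_mre"):
    return MREstimate(method, beta, 0.1, beta - 0.2, beta + 0.2, p, 10)


def _panel(signs, ps):
    return {name: _fake_est(s * 0.1, p, method=name)
            for name, s, p in zip(SENSITIVITY_METHODS, signs, ps)}


class TestSensitivityVerdict:
    primary = _fake_est(0.1, 1e-5)

    def test_all_concordant_four_significant_passes(self):
        panel = _panel([1] * 6, [0.01] * 4 + [0.5, 0.5])
        assert sensitivity_verdict(self.primary, panel)

    def test_three_significant_fails(self):
        panel = _panel([1] * 6, [0.01] * 3 + [0.5] * 3)
        assert not sensitivity_verdict(self.primary, panel)

    def test_one_discordant_fails_despite_significance(self):
        panel = _panel([1] * 5 + [-1], [0.01] * 6)
        assert not sensitivity_verdict(self.primary, panel)

    def test_errored_method_counts_as_fail(self):
        panel = _panel([1] * 6, [0.01] * 6)
        panel["contmix"] = ValueError("boom")
        assert not sensitivity_verdict(self.primary, panel)


class TestClassify:
    def _record(self, p_fdr, sens_pass, influential):
        rec = ScreenTestRecord("m", "d")
        rec.p_fdr = p_fdr
        rec.sensitivity = {"pass": sens_pass}
        rec.diagnostics = MRDiagnostics(
            q=1.0, p_q=0.5, egger_intercept=0.0, p_egger_intercept=0.5,
            i2_gx=0.99, loo_table=None, influential_variant=influential)
        return rec

    def test_polygenic(self):
        assert classify(self._record(0.01, True, None)) == "polygenic"

    def test_single_instrument(self):
        assert classify(self._record(0.01, True, "rs1")) == "single_instrument"

    def test_fdr_gate_dominates(self):
        assert classify(self._record(0.06, True, None)) == "not_significant"

    def test_failed_sensitivity(self):
        assert classify(self._record(0.01, False, None)) == "failed_sensitivity"


class TestWaldRefit:
    def test_refit_uses_influential_variant_only(self):
        e, o, t = simulate_pair(ScenarioConfig(seed=4, regime="single_locus",
                                               n_snps=5))
        from metabomr.instruments import select_instruments
        from metabomr.estimators import diagnostics, ivw
        sel = select_instruments(e, o, t["ld"])
        rec = ScreenTestRecord("m", "d")
        rec.instruments = sel
        rec.primary = ivw(sel)
        rec.p_fdr = 0.001
        rec.sensitivity = {"pass": True}
        rec.diagnostics = diagnostics(sel)
        rec.verdict = classify(rec)
        assert rec.verdict == "single_instrument"
        refit = wald_refit(rec)
        row = sel.table.set_index("variant_id").loc[t["driver"]]
        assert refit.beta == pytest.approx(row["beta_out"] / row["beta_exp"])
        assert np.sign(refit.beta) == np.sign(rec.primary.beta)
        assert refit.extras["f"] >= 10

    def test_polygenic_record_refused(self):
        rec = ScreenTestRecord("m", "d")
        rec.verdict = "polygenic"
        with pytest.raises(ValueError):
            wald_refit(rec)


class TestReverseMR:
    def test_underpowered_disorder_is_untestable(self):
        e, o, t = simulate_pair(ScenarioConfig(seed=8, regime="polygenic",
                                               theta=0.1))
        # the disorder's per-variant effects are far from genome-wide
        # significance, so it yields no instruments of its own
        assert reverse_mr(o, e, t["ld"], ScreenConfig()) == "reverse_untestable"

    def test_symmetric_scenario_reverse_detectable(self):
        # construct a disorder with genome-wide significant hits that also
        # move the metabolite (shared latent cause): reverse MR must fire
        ld = make_ld_block(8, rho=0.0)
        b = np.full(8, 0.05)
        disorder = make_sumstats(ld.variant_ids, b, [0.004] * 8,
                                 pos=ld.positions, trait_name="disorder")
        metabolite = make_sumstats(ld.variant_ids, 0.5 * b, [0.004] * 8,
                                   pos=ld.positions, trait_name="metabolite")
        est = reverse_mr(disorder, metabolite, ld, ScreenConfig())
        assert isinstance(est, MREstimate)
        assert est.p < 0.05
        assert est.beta == pytest.approx(0.5, abs=0.05)


class TestRunScreen:
    def _toy(self):
        ld = make_ld_block(12, rho=0.0)
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.1, 12)
        exposures = [
            make_sumstats(ld.variant_ids, bx, [0.004] * 12, pos=ld.positions,
                          trait_name="met_causal"),
            make_sumstats(ld.variant_ids, rng.uniform(0.0, 0.002, 12),
                          [0.004] * 12, pos=ld.positions,
                          trait_name="met_weak"),
        ]
        outcomes = [
            make_sumstats(ld.variant_ids, 0.2 * bx + rng.normal(0, 0.003, 12),
                          [0.003] * 12, pos=ld.positions, trait_name="dis_a",
                          trait_type="binary"),
            make_sumstats(ld.variant_ids, rng.normal(0, 0.003, 12),
                          [0.003] * 12, pos=ld.positions, trait_name="dis_b",
                          trait_type="binary"),
        ]
        return exposures, outcomes, ld

    def test_two_by_two_screen_produces_four_records(self):
        exposures, outcomes, ld = self._toy()
        records, table, summary = run_screen(exposures, outcomes, ld)
        assert len(records) == 4
        assert summary["n_tests"] == 4
        # verdict counts + exclusions partition the tests
        assert (sum(summary["verdict_counts"].values())
                + summary["n_excluded"] == 4)

    def test_causal_pair_found_weak_exposure_excluded(self):
        exposures, outcomes, ld = self._toy()
        records, table, _ = run_screen(exposures, outcomes, ld)
        by_key = {(r.exposure, r.outcome): r for r in records}
        assert by_key[("met_causal", "dis_a")].verdict == "polygenic"
        assert by_key[("met_weak", "dis_a")].excluded_reason == "too_few_ivs"
        assert by_key[("met_causal", "dis_b")].verdict == "not_significant"

    def test_rerun_is_deterministic(self, tmp_path):
        exposures, outcomes, ld = self._toy()
        _, t1, s1 = run_screen(exposures, outcomes, ld)
        _, t2, s2 = run_screen(exposures, outcomes, ld)
        from metabomr.screen import write_outputs
        write_outputs(t1, s1, tmp_path / "a.tsv", tmp_path / "a.json")
        write_outputs(t2, s2, tmp_path / "b.tsv", tmp_path / "b.json")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_fdr_within_outcome_only(self):
        # identical p-values across two outcomes of different family sizes
        # adjust differently, proving families are outcome-specific
        exposures, outcomes, ld = self._toy()
        records, _, _ = run_screen(exposures, outcomes, ld)
        fdr_by_outcome = {}
        for r in records:
            if r.p_fdr is not None:
                fdr_by_outcome.setdefault(r.outcome, []).append(r.p_fdr)
        # each family has exactly one testable exposure here
        assert all(len(v) == 1 for v in fdr_by_outcome.values())
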