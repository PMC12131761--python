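"""Seeded simulation studies that characterise the pipeline's operating points.

Each function runs a self-contained Monte-Carlo experiment on the synthetic
generators — type-I error calibration of IVW, CI coverage of the seven
estimators, verdict accuracy of the screening cascade, colocalisation and
SMR/HEIDI operating characteristics, and MR-BMA ranking behaviour — and
returns the measured rates.  They are what the test suite asserts against
and what the reproduction script reports; rep counts default to sizes that
complete in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from .bma import BMAInput, mr_bma
from .coloc import coloc
from .estimators import (MREstimate, cml, contamination_mixture, egger, ivw,
                         leave_one_out, mr_lasso, sensitivity_panel,
                         weighted_median)
from .eqtl import mediation, smr_heidi
from .instruments import Excluded, select_instruments
from .screen import ScreenConfig, TestRecord, bh_fdr, classify, sensitivity_verdict
from .simulate import (ScenarioConfig, as_instruments, simulate_coloc_region,
                       simulate_multivariable, simulate_pair, simulate_triplet)

#: estimator battery used in coverage studies (wald excluded: needs k = 1)
SEVEN = ("ivw", "egger", "wmedian", "pwmedian", "lasso", "contmix", "cml")


def _run_all(ins, seed):
    return {
        "ivw": ivw(ins),
        "egger": egger(ins),
        "wmedian": weighted_median(ins, seed=seed),
        "pwmedian": weighted_median(ins, penalised=True, seed=seed),
        "lasso": mr_lasso(ins),
        "contmix": contamination_mixture(ins),
        "cml": cml(ins),
    }


def ivw_type1_error(seed: int, n_reps: int = 2000, alpha: float = 0.05) -> float:
    """Rejection rate of IVW-MRE at nominal ``alpha`` under the null scenario
    (theta = 0, no pleiotropy, 20 SNPs, n = 50k/100k)."""
    rej = 0
    for i in range(n_reps):
        e, o, _ = simulate_pair(ScenarioConfig(seed=seed + i, regime="null"))
        rej += ivw(as_instruments(e, o)).p < alpha
    return rej / n_reps


def estimator_coverage(seed: int, n_reps: int = 1000, theta: float = 0.1
                       ) -> tuple[dict, float]:
    """95% CI coverage of the seven estimators on the clean polygenic
    scenario, plus the largest |cML(K=0) - fixed-effect IVW| discrepancy."""
    cover = {k: 0 for k in SEVEN}
    max_dev = 0.0
    for i in range(n_reps):
        e, o, _ = simulate_pair(ScenarioConfig(seed=seed + i,
                                               regime="polygenic", theta=theta))
        ins = as_instruments(e, o)
        ests = _run_all(ins, seed=seed + i)
        for k, est in ests.items():
            cover[k] += est.ci_low <= theta <= est.ci_high
        dev = abs(ests["cml"].extras["theta_by_k"][0] - ivw(ins, model="fe").beta)
        max_dev = max(max_dev, dev)
    return {k: v / n_reps for k, v in cover.items()}, max_dev


def loo_flag_rate(seed: int, n_reps: int = 2000) -> float:
    """Fraction of single-locus replicates in which the leave-one-out rule
    flags the planted driver variant."""
    flagged = 0
    for i in range(n_reps):
        e, o, t = simulate_pair(ScenarioConfig(seed=seed + i,
                                               regime="single_locus", n_snps=5))
        _, influential = leave_one_out(as_instruments(e, o))
        flagged += influential == t["driver"]
    return flagged / n_reps


def verdict_benchmark(seed: int, n_per_class: int = 150,
                      theta: float = 0.1) -> dict:
    """Run the full cascade on a mixed null/polygenic/single-locus benchmark.

    Every replicate is one exposure tested against a common disorder outcome;
    FDR is applied across the whole benchmark (one outcome family).  Returns
    overall verdict accuracy, per-class recall and the within-cascade driver
    flag rate.
    """
    arms = (["null"] * n_per_class + ["polygenic"] * n_per_class
            + ["single_locus"] * n_per_class)
    truth_label = {"null": "not_significant", "polygenic": "polygenic",
                   "single_locus": "single_instrument"}
    cfg = ScreenConfig()
    records = []
    for i, regime in enumerate(arms):
        scen = ScenarioConfig(seed=seed + i, regime=regime,
                              theta=theta if regime == "polygenic" else 0.0,
                              n_snps=5 if regime == "single_locus" else 20)
        e, o, t = simulate_pair(scen)
        sel = select_instruments(e, o, t["ld"], cfg.selection)
        rec = TestRecord(exposure=f"m{i}", outcome="disorder")
        rec.excluded_reason = sel.reason if isinstance(sel, Excluded) else None
        if not isinstance(sel, Excluded):
            rec.instruments = sel
            rec.primary = ivw(sel)
        records.append((rec, regime, t))
    tested = [r for r, _, _ in records if r.primary is not None]
    for rec, q in zip(tested, bh_fdr([r.primary.p for r in tested])):
        rec.p_fdr = float(q)
    correct = {k: 0 for k in truth_label.values()}
    totals = {k: 0 for k in truth_label.values()}
    flagged_in_cascade = 0
    n_reached_loo = 0
    for rec, regime, t in records:
        totals[truth_label[regime]] += 1
        if rec.primary is not None and rec.p_fdr <= cfg.fdr_alpha:
            panel = sensitivity_panel(rec.instruments, seed=cfg.seed,
                                      n_boot=cfg.n_boot)
            ok = sensitivity_verdict(rec.primary, panel, cfg.sens_min_sig,
                                     cfg.sens_alpha)
            rec.sensitivity = {"pass": ok, "panel": panel}
            if ok:
                from .estimators import diagnostics
                rec.diagnostics = diagnostics(rec.instruments,
                                              loo_alpha=cfg.loo_alpha)
                if regime == "single_locus":
                    n_reached_loo += 1
                    if rec.diagnostics.influential_variant == t["driver"]:
                        flagged_in_cascade += 1
        rec.verdict = classify(rec, cfg.fdr_alpha)
        if rec.verdict == truth_label[regime]:
            correct[truth_label[regime]] += 1
    accuracy = sum(correct.values()) / len(records)
    recall = {k: correct[k] / totals[k] for k in totals}
    return {"accuracy": accuracy, "recall": recall,
            "driver_flag_rate_in_cascade": (flagged_in_cascade / n_reached_loo
                                            if n_reached_loo else float("nan")),
            "n_tests": len(records)}


def coloc_rates(seed: int, n_reps: int = 150) -> dict:
    """Shared-variant H4 call rate, distinct-variant H3-modal rate and the
    worst posterior-sum deviation across both arms (n = 10k per trait,
    1% variance explained)."""
    h4_rate = 0
    h3_modal = 0
    max_dev = 0.0
    for i in range(n_reps):
        cfg = ScenarioConfig(seed=seed + i, n_exp=10_000, n_out=10_000)
        r1, r2, _ = simulate_coloc_region(cfg, regime="shared")
        res = coloc(r1, r2)
        max_dev = max(max_dev, abs(sum(res.pp.values()) - 1.0))
        h4_rate += res.pp["H4"] >= 0.8
        r1, r2, _ = simulate_coloc_region(
            ScenarioConfig(seed=seed + 10**6 + i, n_exp=10_000, n_out=10_000),
            regime="distinct")
        res = coloc(r1, r2)
        max_dev = max(max_dev, abs(sum(res.pp.values()) - 1.0))
        h3_modal += max(res.pp, key=res.pp.get) == "H3"
    return {"h4_rate_shared": h4_rate / n_reps,
            "h3_modal_rate_distinct": h3_modal / n_reps,
            "max_pp_sum_deviation": max_dev}


def bma_rates(seed: int, n_reps: int = 150, d: int = 10) -> dict:
    """Top-MIP recovery of the single true exposure among d correlated
    candidates, and the mean MIP under null outcome data."""
    names = [f"x{j}" for j in range(d)]
    top = 0
    for i in range(n_reps):
        cfg = ScenarioConfig(seed=seed + i, regime="multivariable", n_snps=50,
                             theta=0.15, d_exposures=d, true_set=(0,))
        bX, bY, sY, _ = simulate_multivariable(cfg)
        res = mr_bma(BMAInput(bX, bY, sY, names))
        top += res.mip.idxmax() == "x0"
    null_mips = []
    post_sum_dev = 0.0
    for i in range(n_reps):
        cfg = ScenarioConfig(seed=seed + 10**6 + i, regime="multivariable",
                             n_snps=50, theta=0.0, d_exposures=d, true_set=())
        bX, bY, sY, _ = simulate_multivariable(cfg)
        res = mr_bma(BMAInput(bX, bY, sY, names))
        null_mips.append(res.mip.mean())
        post_sum_dev = max(post_sum_dev,
                           abs(sum(res.model_posteriors.values()) - 1.0))
    return {"top_mip_rate": top / n_reps,
            "null_mean_mip": float(np.mean(null_mips)),
            "max_posterior_sum_deviation": post_sum_dev}


def smr_heidi_rates(seed: int, n_reps: int = 150) -> dict:
    """HEIDI behaviour at n = 30k: p-value distribution under a shared causal
    variant (should be near-uniform) and rejection power under distinct
    causal variants."""
    shared_p = []
    distinct_rej = 0
    n_distinct = 0
    for i in range(n_reps):
        cfg = ScenarioConfig(seed=seed + i, n_exp=30_000, n_out=30_000,
                             var_explained_1=0.04, var_explained_2=0.002)
        r1, r2, t = simulate_coloc_region(cfg, regime="shared")
        res = smr_heidi(r1, r2, t["ld"])
        if res.p_heidi is not None:
            shared_p.append(res.p_heidi)
        cfg = ScenarioConfig(seed=seed + 10**6 + i, n_exp=30_000, n_out=30_000,
                             var_explained_1=0.04, var_explained_2=0.002)
        r1, r2, t = simulate_coloc_region(cfg, regime="distinct")
        res = smr_heidi(r1, r2, t["ld"])
        if res.p_heidi is not None:
            n_distinct += 1
            distinct_rej += res.p_heidi < 0.05
    shared_p = np.array(shared_p)
    return {"shared_mean_p": float(shared_p.mean()),
            "shared_rejection_rate": float(np.mean(shared_p < 0.05)),
            "distinct_power": distinct_rej / max(n_distinct, 1),
            "n_shared": len(shared_p), "n_distinct": n_distinct}


def mediation_recovery(seed: int, n_reps: int = 200,
                       proportion: float = 0.6) -> dict:
    """Planted-mediation recovery on the expression->metabolite->disorder
    triplet: mean estimated proportion and per-replicate CI coverage."""
    a_eff, b_eff = 0.3, 0.2
    direct = a_eff * b_eff * (1.0 - proportion) / proportion
    from .eqtl import eqtl_ivw
    props = []
    covered = 0
    for i in range(n_reps):
        cfg = ScenarioConfig(seed=seed + i, regime="triplet", a_effect=a_eff,
                             b_effect=b_eff, direct_effect=direct)
        expr, metab, outc, t = simulate_triplet(cfg)
        a = eqtl_ivw(expr, metab, t["ld"])
        c = eqtl_ivw(expr, outc, t["ld"])
        if not isinstance(a, MREstimate) or not isinstance(c, MREstimate):
            continue
        b = ivw(as_instruments(metab, outc, t["metab_ivs"]))
        med = mediation(a.beta, a.se, b.beta, b.se, c.beta, c.se)
        props.append(med.proportion)
        lo, hi = med.ci_proportion
        covered += lo <= proportion <= hi
    return {"mean_proportion": float(np.mean(props)),
            "ci_coverage": covered / len(props), "n": len(props)}
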