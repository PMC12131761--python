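"""The metabolome-wide screening cascade.

For every exposure-outcome pair: select instruments, estimate the primary
IVW (multiplicative random effects) effect, apply Benjamini-Hochberg FDR
within each outcome's family of tests, run the six-method sensitivity panel
on FDR-significant pairs, and classify each surviving pair as *polygenic*
(no single influential instrument) or *single instrument* (a leave-one-out
outlier drives the estimate).  Sensitivity passers are additionally tested
for reverse causation, and single-instrument pairs re-estimated by a Wald
ratio on the influential variant alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .estimators import (MRDiagnostics, MREstimate, SENSITIVITY_METHODS,
                         diagnostics, ivw, sensitivity_panel, wald_ratio)
from .instruments import Excluded, InstrumentSet, SelectionConfig, select_instruments
from .ld import LDMatrix
from .sumstats import SummaryStats

VERDICTS = ("not_significant", "failed_sensitivity", "polygenic",
            "single_instrument")


@dataclass
class ScreenConfig:
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    fdr_alpha: float = 0.05
    sens_min_sig: int = 4
    sens_alpha: float = 0.05
    loo_alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0


@dataclass
class TestRecord:
    exposure: str
    outcome: str
    primary: MREstimate | None = None
    p_fdr: float | None = None
    sensitivity: dict | None = None
    diagnostics: MRDiagnostics | None = None
    verdict: str | None = None
    reverse: MREstimate | str | None = None
    reverse_p_fdr: float | None = None
    wald_refit: MREstimate | None = None
    excluded_reason: str | None = None
    instruments: InstrumentSet | None = None


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonicity enforced).

    Applied within a single outcome's family of tests; callers must not pool
    across outcomes.
    """
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sensitivity_verdict(primary: MREstimate, panel: dict,
                        min_sig: int = 4, alpha: float = 0.05) -> bool:
    """Robustness rule for an FDR-significant IVW estimate.

    Passes only when every sensitivity point estimate is directionally
    concordant with the IVW estimate and at least ``min_sig`` of the six are
    significant at ``alpha``.  A method that errored counts as discordant.
    """
    sign = np.sign(primary.beta)
    n_sig = 0
    for name in SENSITIVITY_METHODS:
        est = panel.get(name)
        if not isinstance(est, MREstimate):
            return False
        if np.sign(est.beta) != sign:
            return False
        if est.p <= alpha:
            n_sig += 1
    return n_sig >= min_sig


def classify(record: TestRecord, fdr_alpha: float = 0.05) -> str:
    """Cascade verdict: FDR gate, then sensitivity, then the LOO split."""
    if record.p_fdr is None or record.p_fdr > fdr_alpha:
        return "not_significant"
    if not record.sensitivity or not record.sensitivity.get("pass"):
        return "failed_sensitivity"
    if record.diagnostics and record.diagnostics.influential_variant is not None:
        return "single_instrument"
    return "polygenic"


def wald_refit(record: TestRecord) -> MREstimate:
    """Re-estimate a single-instrument pair from its influential variant only."""
    if record.verdict != "single_instrument":
        raise ValueError("wald_refit applies to single_instrument records only")
    vid = record.diagnostics.influential_variant
    row = record.instruments.table.set_index("variant_id").loc[vid]
    est = wald_ratio(row["beta_exp"], row["se_exp"], row["beta_out"],
                     row["se_out"], variant_id=vid)
    est.extras["f"] = float(row["f"])
    return est


def reverse_mr(outcome: SummaryStats, exposure: SummaryStats, ld: LDMatrix,
               config: ScreenConfig) -> MREstimate | str:
    """IVW with the disorder as exposure; 'reverse_untestable' when the
    disorder yields too few instruments at either threshold."""
    sel = select_instruments(outcome, exposure, ld, config.selection)
    if isinstance(sel, Excluded):
        return "reverse_untestable"
    return ivw(sel, model="mre")


def run_screen(exposures: list[SummaryStats], outcomes: list[SummaryStats],
               ld: LDMatrix, config: ScreenConfig | None = None
               ) -> tuple[list[TestRecord], pd.DataFrame, dict]:
    """Run the full cascade over every exposure x outcome pair.

    Returns (records, results table, summary).  Per-test failures are
    recorded in the table, never raised.  Given identical inputs and config
    (including the seed used for the bootstrap SEs) the outputs are
    deterministic.
    """
    cfg = config or ScreenConfig()
    records: list[TestRecord] = []
    for outcome in outcomes:
        outcome_records: list[TestRecord] = []
        for exposure in exposures:
            rec = TestRecord(exposure.trait_name, outcome.trait_name)
            sel = select_instruments(exposure, outcome, ld, cfg.selection)
            if isinstance(sel, Excluded):
                rec.excluded_reason = sel.reason
            else:
                rec.instruments = sel
                rec.primary = ivw(sel, model="mre")
            outcome_records.append(rec)
        tested = [r for r in outcome_records if r.primary is not None]
        if tested:
            adj = bh_fdr([r.primary.p for r in tested])
            for r, q in zip(tested, adj):
                r.p_fdr = float(q)
        for rec in tested:
            if rec.p_fdr <= cfg.fdr_alpha:
                panel = sensitivity_panel(rec.instruments, seed=cfg.seed,
                                          n_boot=cfg.n_boot)
                ok = sensitivity_verdict(rec.primary, panel,
                                         cfg.sens_min_sig, cfg.sens_alpha)
                rec.sensitivity = {"pass": ok, "panel": panel}
                if ok:
                    rec.diagnostics = diagnostics(rec.instruments,
                                                  loo_alpha=cfg.loo_alpha)
            rec.verdict = classify(rec, cfg.fdr_alpha)
            if rec.verdict == "single_instrument":
                rec.wald_refit = wald_refit(rec)
        for rec in outcome_records:
            if rec.verdict is None:
                rec.verdict = "not_significant" if rec.primary is not None else None
        records.extend(outcome_records)

    # reverse MR for sensitivity passers, FDR over the reverse family only
    by_name_exp = {s.trait_name: s for s in exposures}
    by_name_out = {s.trait_name: s for s in outcomes}
    reverse_recs = [r for r in records
                    if r.verdict in ("polygenic", "single_instrument")]
    for rec in reverse_recs:
        rec.reverse = reverse_mr(by_name_out[rec.outcome],
                                 by_name_exp[rec.exposure], ld, cfg)
    testable = [r for r in reverse_recs if isinstance(r.reverse, MREstimate)]
    if testable:
        adj = bh_fdr([r.reverse.p for r in testable])
        for r, q in zip(testable, adj):
            r.reverse_p_fdr = float(q)

    table = results_table(records)
    summary = summarise(records)
    return records, table, summary


def results_table(records: list[TestRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"exposure": r.exposure, "outcome": r.outcome,
               "excluded_reason": r.excluded_reason, "verdict": r.verdict,
               "p_fdr": r.p_fdr, "reverse_p_fdr": r.reverse_p_fdr}
        if r.primary is not None:
            row.update(beta=r.primary.beta, se=r.primary.se, p=r.primary.p,
                       odds_ratio=r.primary.odds_ratio,
                       ci_low=r.primary.ci_low, ci_high=r.primary.ci_high,
                       n_snps=r.primary.n_snps,
                       threshold=r.instruments.selection_threshold,
                       i2_gx=r.instruments.i2_gx)
        if r.sensitivity:
            for name in SENSITIVITY_METHODS:
                est = r.sensitivity["panel"].get(name)
                if isinstance(est, MREstimate):
                    row[f"beta_{name}"] = est.beta
                    row[f"p_{name}"] = est.p
        if r.diagnostics:
            row.update(q=r.diagnostics.q, p_q=r.diagnostics.p_q,
                       egger_intercept=r.diagnostics.egger_intercept,
                       p_egger_intercept=r.diagnostics.p_egger_intercept,
                       influential_variant=r.diagnostics.influential_variant)
        if r.wald_refit is not None:
            row.update(wald_beta=r.wald_refit.beta, wald_se=r.wald_refit.se,
                       wald_p=r.wald_refit.p,
                       wald_f=r.wald_refit.extras.get("f"))
        rows.append(row)
    return pd.DataFrame(rows)


def summarise(records: list[TestRecord]) -> dict:
    n_excluded = sum(1 for r in records if r.excluded_reason is not None)
    counts = {v: sum(1 for r in records if r.verdict == v) for v in VERDICTS}
    tiers = {}
    for r in records:
        if r.instruments is not None:
            key = f"{r.instruments.selection_threshold:.0e}"
            tiers[key] = tiers.get(key, 0) + 1
    return {"n_tests": len(records), "n_excluded": n_excluded,
            "verdict_counts": counts, "threshold_tiers": tiers,
            "n_reverse_tested": sum(1 for r in records
                                    if isinstance(r.reverse, MREstimate))}


def write_outputs(table: pd.DataFrame, summary: dict, tsv_path, json_path) -> None:
    table.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
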