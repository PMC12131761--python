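"""Instrument selection: LD clumping, proxy search and strength diagnostics.

The selection cascade mirrors common metabolite-MR practice: clump at
genome-wide significance (5e-8, r^2 0.001, +/-10 Mb); if fewer than five
independent variants remain, relax to 5e-6; exposures still short of five
instruments are excluded.  Instruments missing from the outcome are replaced
by LD proxies (r^2 > 0.8, nearest position breaking ties), palindromic
variants with MAF > 0.42 are dropped, and weak instruments (F < 10) removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import LDMatrix
from .sumstats import SummaryStats, harmonise_pair, kept


@dataclass
class SelectionConfig:
    p_threshold_primary: float = 5e-8
    p_threshold_fallback: float | None = 5e-6
    min_ivs: int = 5
    clump_r2: float = 0.001
    window_kb: float = 10_000.0
    proxy_r2: float = 0.8
    f_min: float = 10.0
    maf_palindrome: float = 0.42
    i2_flag: float = 0.9


@dataclass
class InstrumentSet:
    """Harmonised exposure/outcome effect pairs for the selected instruments."""

    exposure_name: str
    outcome_name: str
    table: pd.DataFrame  # variant_id, beta_exp, se_exp, beta_out, se_out, f
    selection_threshold: float | None = None
    n_proxies_used: int = 0
    i2_gx: float | None = None
    i2_flagged: bool = False

    def __post_init__(self) -> None:
        req = {"variant_id", "beta_exp", "se_exp", "beta_out", "se_out", "f"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"instrument table missing columns {req - set(self.table.columns)}")
        if len(self.table) < 1:
            raise ValueError("instrument set must contain at least one variant")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        t = self.table
        return (t["beta_exp"].to_numpy(float), t["se_exp"].to_numpy(float),
                t["beta_out"].to_numpy(float), t["se_out"].to_numpy(float))

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out, variant_ids=None,
                    exposure_name: str = "exposure", outcome_name: str = "outcome",
                    **kwargs) -> "InstrumentSet":
        beta_exp = np.asarray(beta_exp, float)
        if variant_ids is None:
            variant_ids = [f"v{i}" for i in range(len(beta_exp))]
        table = pd.DataFrame({
            "variant_id": variant_ids,
            "beta_exp": beta_exp, "se_exp": np.asarray(se_exp, float),
            "beta_out": np.asarray(beta_out, float),
            "se_out": np.asarray(se_out, float),
        })
        table["f"] = f_statistic(table["beta_exp"], table["se_exp"])
        return cls(exposure_name, outcome_name, table, **kwargs)

    def drop(self, variant_id: str) -> "InstrumentSet":
        t = self.table.loc[self.table["variant_id"] != variant_id].reset_index(drop=True)
        return InstrumentSet(self.exposure_name, self.outcome_name, t,
                             self.selection_threshold, self.n_proxies_used)


@dataclass
class Excluded:
    """Marker for an exposure that failed the selection cascade."""

    exposure_name: str
    outcome_name: str
    reason: str  # too_few_ivs | too_few_after_qc
    detail: dict = field(default_factory=dict)


def f_statistic(beta_exp, se_exp):
    """Per-variant instrument strength, beta^2 / SE^2."""
    beta_exp = np.asarray(beta_exp, float)
    se_exp = np.asarray(se_exp, float)
    if np.any(se_exp <= 0):
        raise ValueError("se_exp must be positive")
    return beta_exp**2 / se_exp**2


def i2_gx(beta_exp, se_exp) -> float | None:
    """I^2 for exposure-effect measurement error (regression-dilution risk).

    Q_GX = sum((b_j - b_w)^2 / se_j^2) about the inverse-variance weighted
    mean; I^2 = max(0, (Q_GX - (k-1)) / Q_GX).  Values < 0.9 flag material
    measurement error in the variant-exposure effects.  Returns None for
    fewer than two variants.
    """
    beta_exp = np.asarray(beta_exp, float)
    se_exp = np.asarray(se_exp, float)
    k = len(beta_exp)
    if k < 2:
        return None
    w = 1.0 / se_exp**2
    bw = np.sum(w * beta_exp) / np.sum(w)
    q = float(np.sum((beta_exp - bw) ** 2 * w))
    if q <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / q)


def clump(stats: SummaryStats, ld: LDMatrix, p_threshold: float,
          r2: float = 0.001, window_kb: float = 10_000.0) -> list[str]:
    """Greedy p-value-ordered LD clumping.

    Repeatedly takes the smallest-p remaining variant with p <= threshold and
    removes every variant with LD r^2 > ``r2`` within ``window_kb`` kb of it.
    Variants absent from the LD panel are treated as unlinked singletons (a
    warning notes how many).  Ties in p are broken by variant order in the
    table, making the result deterministic.
    """
    df = stats.df.loc[stats.df["p"] <= p_threshold,
                      ["variant_id", "chrom", "pos", "p"]].copy()
    if df.empty:
        return []
    missing = [v for v in df["variant_id"] if v not in ld]
    if missing:
        warnings.warn(f"{len(missing)} significant variants absent from the LD "
                      "panel are treated as unlinked")
    order = df.sort_values(["p", "variant_id"], kind="mergesort")
    window_bp = window_kb * 1000.0
    kept_ids: list[str] = []
    removed: set[str] = set()
    rows = list(order.itertuples(index=False))
    for row in rows:
        if row.variant_id in removed:
            continue
        kept_ids.append(row.variant_id)
        if row.variant_id not in ld:
            continue
        for other in rows:
            if other.variant_id in removed or other.variant_id == row.variant_id:
                continue
            if other.variant_id not in ld:
                continue
            if other.chrom != row.chrom or abs(other.pos - row.pos) > window_bp:
                continue
            if ld.r2_between(row.variant_id, other.variant_id) > r2:
                removed.add(other.variant_id)
    return kept_ids


def find_proxy(target: str, available, ld: LDMatrix,
               r2_min: float = 0.8) -> str | None:
    """Best LD proxy for a missing instrument.

    Among ``available`` variants with r^2 > ``r2_min`` to the target, returns
    the highest-r^2 candidate, breaking ties by smallest base-pair distance
    (then ID, for determinism).  None if the target is absent from the panel
    or no candidate qualifies.
    """
    if target not in ld:
        warnings.warn(f"proxy target {target} absent from LD panel")
        return None
    tpos = ld.pos(target)
    best: tuple[float, float, str] | None = None
    for cand in available:
        if cand == target or cand not in ld:
            continue
        r2 = ld.r2_between(target, cand)
        if r2 <= r2_min:
            continue
        key = (-r2, abs(ld.pos(cand) - tpos), cand)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


def select_instruments(exposure: SummaryStats, outcome: SummaryStats,
                       ld: LDMatrix, config: SelectionConfig | None = None
                       ) -> InstrumentSet | Excluded:
    """Run the full instrument-selection cascade for one exposure-outcome pair.

    Clump at the primary threshold; fall back to the relaxed threshold when
    fewer than ``min_ivs`` survive; proxy-search instruments missing from the
    outcome; harmonise alleles; drop palindromic and weak (F < f_min)
    variants.  Returns an :class:`InstrumentSet` or an :class:`Excluded`
    record with reason ``too_few_ivs`` / ``too_few_after_qc``.
    """
    cfg = config or SelectionConfig()
    selected = clump(exposure, ld, cfg.p_threshold_primary, cfg.clump_r2,
                     cfg.window_kb)
    threshold = cfg.p_threshold_primary
    if len(selected) < cfg.min_ivs and cfg.p_threshold_fallback is not None:
        selected = clump(exposure, ld, cfg.p_threshold_fallback, cfg.clump_r2,
                         cfg.window_kb)
        threshold = cfg.p_threshold_fallback
    if len(selected) < cfg.min_ivs:
        return Excluded(exposure.trait_name, outcome.trait_name, "too_few_ivs",
                        {"n_selected": len(selected), "threshold": threshold})

    # proxy search for instruments absent from the outcome
    outcome_ids = set(outcome.variant_ids)
    exposure_ids = set(exposure.variant_ids)
    final_ids: list[str] = []
    n_proxies = 0
    for vid in selected:
        if vid in outcome_ids:
            final_ids.append(vid)
            continue
        proxy = find_proxy(vid, outcome_ids & exposure_ids, ld, cfg.proxy_r2)
        if proxy is not None and proxy not in final_ids:
            final_ids.append(proxy)
            n_proxies += 1
    proxied = set(final_ids) - set(selected)

    harm = harmonise_pair(exposure, outcome, final_ids, cfg.maf_palindrome)
    good = kept(harm)
    if len(good):
        f = f_statistic(good["beta_exp"], good["se_exp"])
        good = good.assign(f=f).loc[f >= cfg.f_min].reset_index(drop=True)
    if len(good) < cfg.min_ivs:
        return Excluded(exposure.trait_name, outcome.trait_name,
                        "too_few_after_qc",
                        {"n_after_qc": len(good), "threshold": threshold})
    good["proxy_used"] = good["variant_id"].isin(proxied)
    i2 = i2_gx(good["beta_exp"], good["se_exp"])
    table = good[["variant_id", "beta_exp", "se_exp", "beta_out", "se_out",
                  "f", "proxy_used"]]
    return InstrumentSet(exposure.trait_name, outcome.trait_name, table,
                         selection_threshold=threshold,
                         n_proxies_used=n_proxies, i2_gx=i2,
                         i2_flagged=(i2 is not None and i2 < cfg.i2_flag))
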