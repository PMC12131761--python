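"""GWAS / eQTL summary-statistic containers, I/O, harmonisation and meta-analysis.

Summary statistics are held as a pandas DataFrame with one row per variant and
the canonical columns ``variant_id, chrom, pos, effect_allele, other_allele,
eaf, beta, se, p, n``.  ``beta`` is the additive effect per copy of the effect
allele; for binary traits it is a log odds ratio (so ``exp(beta)`` is the OR).
Positions are GRCh37, 1-based inclusive throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: canonical internal column order
COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]

#: default on-disk header (tab-delimited), mapped onto the internal names
DEFAULT_COLUMN_MAP = {
    "SNP": "variant_id", "CHR": "chrom", "BP": "pos", "A1": "effect_allele",
    "A2": "other_allele", "EAF": "eaf", "BETA": "beta", "SE": "se",
    "P": "p", "N": "n",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SummaryStats:
    """Per-variant association records for one trait.

    ``df`` is indexed 0..m-1 with the canonical :data:`COLUMNS`; variant_id is
    unique within the set.
    """

    df: pd.DataFrame
    trait_name: str = ""
    trait_type: str = "quantitative"  # or "binary"
    n: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    genome_build: str = "GRCh37"
    load_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        if self.df["variant_id"].duplicated().any():
            raise ValueError("variant_id must be unique within a SummaryStats set")

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.df["variant_id"])

    def indexed(self) -> pd.DataFrame:
        return self.df.set_index("variant_id")

    def subset(self, variant_ids: Sequence[str]) -> "SummaryStats":
        sub = self.indexed().loc[list(variant_ids)].reset_index()
        return SummaryStats(sub[COLUMNS], self.trait_name, self.trait_type,
                            self.n, self.n_cases, self.n_controls, self.genome_build)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop rows violating the record invariants; count drops per reason."""
    report: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> pd.DataFrame:
        nonlocal df
        n_bad = int(mask.sum())
        if n_bad:
            report[reason] = report.get(reason, 0) + n_bad
            df = df.loc[~mask]
        return df

    df = drop(df["se"].isna() | (df["se"] <= 0), "nonpositive_se")
    df = drop(df["beta"].isna(), "missing_beta")
    df = drop(df["p"].isna() | (df["p"] <= 0) | (df["p"] > 1), "invalid_p")
    df = drop(df["pos"].isna() | (df["pos"] < 1), "invalid_pos")
    df = drop(df["effect_allele"].isna() | df["other_allele"].isna()
              | (df["effect_allele"] == df["other_allele"]), "bad_alleles")
    eaf_bad = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    df = drop(eaf_bad, "invalid_eaf")
    dup = df["variant_id"].duplicated(keep="first")
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicated variant_id rows; keeping first by file order")
    df = drop(dup, "duplicate_variant_id")
    return df, report


def read_sumstats(path, column_map: Mapping[str, str] | None = None,
                  trait_meta: Mapping | None = None, sep: str = "\t") -> SummaryStats:
    """Read a delimited summary-statistics table into a validated SummaryStats.

    Rows failing the record invariants (se <= 0, p outside (0,1], identical
    alleles, duplicated IDs, ...) are dropped and counted in ``load_report``.
    Gzip input is handled transparently by pandas.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    raw = pd.read_csv(path, sep=sep)
    raw = raw.rename(columns=cmap)
    required = [c for c in COLUMNS if c not in ("eaf", "n")]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"required columns missing from {path}: {missing}")
    for optional in ("eaf", "n"):
        if optional not in raw.columns:
            raw[optional] = np.nan
    raw = raw[COLUMNS].copy()
    raw["variant_id"] = raw["variant_id"].astype(str)
    raw["chrom"] = raw["chrom"].astype(str)
    for allele_col in ("effect_allele", "other_allele"):
        raw[allele_col] = raw[allele_col].astype(str).str.upper()
    n_input = len(raw)
    df, report = _validate_rows(raw)
    if df.empty:
        raise ValueError(f"no valid rows in {path}")
    report["n_input"] = n_input
    report["n_valid"] = len(df)
    meta = dict(trait_meta or {})
    return SummaryStats(df.reset_index(drop=True),
                        trait_name=meta.get("trait_name", ""),
                        trait_type=meta.get("trait_type", "quantitative"),
                        n=meta.get("n"), n_cases=meta.get("n_cases"),
                        n_controls=meta.get("n_controls"),
                        load_report=report)


def write_sumstats(stats: SummaryStats, path, sep: str = "\t") -> None:
    out = stats.df.rename(columns={v: k for k, v in DEFAULT_COLUMN_MAP.items()})
    out.to_csv(path, sep=sep, index=False)


def write_load_report(stats: SummaryStats, path) -> None:
    with open(path, "w") as fh:
        json.dump(stats.load_report, fh, indent=2, sort_keys=True)


def is_palindromic(a1: str, a2: str, eaf: float | None,
                   maf_threshold: float = 0.42) -> str:
    """Classify an allele pair for the strand-ambiguity filter.

    A/T and C/G pairs cannot be strand-resolved; they are dropped when the
    minor allele frequency exceeds ``maf_threshold`` (the frequency no longer
    identifies the allele).  Returns one of ``not_palindromic``, ``keep``,
    ``drop_palindromic`` or ``drop_missing_eaf`` (palindromic pair whose
    frequency is unknown: dropped conservatively, counted separately).
    """
    a1, a2 = a1.upper(), a2.upper()
    if len(a1) != 1 or len(a2) != 1:
        return "not_palindromic"
    if _COMPLEMENT.get(a1) != a2:
        return "not_palindromic"
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
        return "drop_missing_eaf"
    maf = min(eaf, 1.0 - eaf)
    return "drop_palindromic" if maf > maf_threshold else "keep"


def _alleles_match(e1: str, o1: str, e2: str, o2: str) -> str:
    """Relationship of allele pair 2 to pair 1: same / flipped / mismatch."""
    if (e1, o1) == (e2, o2):
        return "same"
    if (e1, o1) == (o2, e2):
        return "flipped"
    # strand complement resolution (non-palindromic pairs only)
    ce2, co2 = _COMPLEMENT.get(e2), _COMPLEMENT.get(o2)
    if ce2 is not None and co2 is not None and {e2, o2} != {ce2, co2}:
        if (e1, o1) == (ce2, co2):
            return "same"
        if (e1, o1) == (co2, ce2):
            return "flipped"
    return "mismatch"


def harmonise_pair(exposure: SummaryStats, outcome: SummaryStats,
                   variant_ids: Iterable[str],
                   maf_palindrome: float = 0.42) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele.

    Returns one row per requested variant with aligned
    ``beta_exp/se_exp/beta_out/se_out/eaf``; rows that cannot be used carry a
    ``dropped_reason`` in {palindromic, missing_in_outcome, allele_mismatch}
    and NaN effect columns.  Where the outcome's effect allele equals the
    exposure's other allele the outcome beta is sign-flipped and its frequency
    reflected (eaf -> 1 - eaf).
    """
    exp = exposure.indexed()
    out = outcome.indexed()
    rows = []
    for vid in variant_ids:
        e = exp.loc[vid]
        row = {
            "variant_id": vid, "beta_exp": e["beta"], "se_exp": e["se"],
            "beta_out": np.nan, "se_out": np.nan, "eaf": e["eaf"],
            "proxy_used": False, "dropped_reason": None,
        }
        pal = is_palindromic(e["effect_allele"], e["other_allele"], e["eaf"],
                             maf_palindrome)
        if pal in ("drop_palindromic", "drop_missing_eaf"):
            row["dropped_reason"] = "palindromic"
        elif vid not in out.index:
            row["dropped_reason"] = "missing_in_outcome"
        else:
            o = out.loc[vid]
            rel = _alleles_match(e["effect_allele"], e["other_allele"],
                                 o["effect_allele"], o["other_allele"])
            if rel == "mismatch":
                row["dropped_reason"] = "allele_mismatch"
            else:
                sign = 1.0 if rel == "same" else -1.0
                row["beta_out"] = sign * o["beta"]
                row["se_out"] = o["se"]
        rows.append(row)
    return pd.DataFrame(rows)


def kept(harmonised: pd.DataFrame) -> pd.DataFrame:
    """Rows of a harmonised table that survived all drop rules."""
    return harmonised.loc[harmonised["dropped_reason"].isna()].reset_index(drop=True)


def meta_analyse(studies: Sequence[SummaryStats],
                 trait_name: str = "") -> SummaryStats:
    """Fixed-effect inverse-variance meta-analysis of per-variant effects.

    Per shared variant: beta = sum(b_i/se_i^2) / sum(1/se_i^2),
    se = sqrt(1 / sum(1/se_i^2)), p from a two-sided normal test.  Alleles of
    later studies are harmonised to the first study before combining; variants
    present in a single study are carried through unchanged (flagged in the
    returned frame's ``n_studies`` column).
    """
    if len(studies) < 2:
        raise ValueError("meta-analysis requires at least two studies")
    ref = studies[0]
    ref_df = ref.indexed()
    # collect aligned (beta, se) per study, keyed by variant
    contrib: dict[str, list[tuple[float, float]]] = {
        vid: [(row["beta"], row["se"])] for vid, row in ref_df.iterrows()
    }
    extra_rows: dict[str, pd.Series] = {}
    for study in studies[1:]:
        for vid, row in study.indexed().iterrows():
            if vid in contrib:
                e = ref_df.loc[vid] if vid in ref_df.index else extra_rows[vid]
                rel = _alleles_match(e["effect_allele"], e["other_allele"],
                                     row["effect_allele"], row["other_allele"])
                if rel == "mismatch":
                    continue
                sign = 1.0 if rel == "same" else -1.0
                contrib[vid].append((sign * row["beta"], row["se"]))
            else:
                contrib[vid] = [(row["beta"], row["se"])]
                extra_rows[vid] = row
    n_overlap = sum(1 for v in contrib.values() if len(v) > 1)
    if n_overlap == 0:
        raise ValueError("no overlapping variants across studies")

    records = []
    for vid, pairs in contrib.items():
        base = ref_df.loc[vid] if vid in ref_df.index else extra_rows[vid]
        betas = np.array([b for b, _ in pairs])
        ses = np.array([s for _, s in pairs])
        w = 1.0 / ses**2
        beta = float(np.sum(w * betas) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
        records.append({
            "variant_id": vid, "chrom": base["chrom"], "pos": base["pos"],
            "effect_allele": base["effect_allele"],
            "other_allele": base["other_allele"], "eaf": base["eaf"],
            "beta": beta, "se": se, "p": max(p, np.nextafter(0, 1)),
            "n": np.nansum([s.n or np.nan for s in studies]) if ref.n else np.nan,
            "n_studies": len(pairs),
        })
    df = pd.DataFrame(records)
    meta = SummaryStats(df[COLUMNS].assign(n_studies=df["n_studies"]),
                        trait_name=trait_name or ref.trait_name,
                        trait_type=ref.trait_type)
    return meta
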