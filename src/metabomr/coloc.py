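"""Approximate-Bayes-factor colocalisation over a genomic region.

Given per-variant summary statistics for two traits across the same region,
five hypotheses are weighed: H0 no association with either trait; H1/H2 a
causal variant for one trait only; H3 two distinct causal variants; H4 one
shared causal variant.  Each variant's evidence is a Wakefield approximate
Bayes factor computed from (beta, se) and a prior effect variance W, and the
hypothesis posteriors sum single- and pair-variant configurations weighted by
the per-configuration priors p1, p2 and p12.

The region of interest is taken as +/- 250 kb around an index variant (the
influential instrument from leave-one-out analysis), matching standard
practice for single-signal colocalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .simulate import Region
from .sumstats import SummaryStats

#: prior SD of a true log-OR at a causal variant for a binary trait
W_BINARY = 0.2**2


@dataclass
class ColocResult:
    pp: dict            # {"H0": .., ..., "H4": ..}
    per_snp_h4: pd.Series
    credible_set: list
    label: str          # colocalised | suggestive | distinct | distinct_suggestive | inconclusive
    n_shared: int

    @property
    def pp_h4(self) -> float:
        return self.pp["H4"]


def extract_region(stats: SummaryStats, center_variant: str,
                   halfwidth_kb: float = 250.0) -> Region:
    """Cut the +/- ``halfwidth_kb`` window (1-based inclusive) around a variant."""
    df = stats.indexed()
    if center_variant not in df.index:
        raise KeyError(f"{center_variant} not present in {stats.trait_name!r}")
    center = int(df.loc[center_variant, "pos"])
    chrom = str(df.loc[center_variant, "chrom"])
    half = int(halfwidth_kb * 1000)
    start, end = center - half, center + half
    sel = stats.df.loc[(stats.df["chrom"].astype(str) == chrom)
                       & (stats.df["pos"] >= start) & (stats.df["pos"] <= end)]
    out = sel.rename(columns={"variant_id": "variant_id"})[
        ["variant_id", "pos", "beta", "se", "eaf", "n"]].reset_index(drop=True)
    return Region(chrom, start, end, out, trait_type=stats.trait_type,
                  trait_name=stats.trait_name)


def log_abf(beta, se, W: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor for H1 vs H0 at one variant.

    With V = se^2 and z = beta/se:
        lABF = 0.5 * [ log(V / (V + W)) + z^2 * W / (V + W) ]
    W is the prior variance of the true effect: (0.15 * sdY)^2 for a
    quantitative trait, 0.2^2 on the log-odds scale for a binary trait.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    V = se**2
    z2 = (beta / se) ** 2
    return 0.5 * (np.log(V / (V + W)) + z2 * W / (V + W))


def _prior_w(region: Region) -> float:
    if region.trait_type == "binary":
        return W_BINARY
    return (0.15 * region.sdY) ** 2


def coloc(region1: Region, region2: Region, p1: float = 1e-4,
          p2: float = 1e-4, p12: float = 1e-5,
          credible_mass: float = 0.95) -> ColocResult:
    """Five-hypothesis ABF colocalisation on the shared variants of two regions.

    Default configuration priors: p1 = p2 = 1e-4 (a variant is causal for one
    trait), p12 = 1e-5 (causal for both).  Labels: PP.H4 >= 0.8 colocalised,
    >= 0.6 suggestive; the analogous thresholds on PP.H3 mark distinct
    signals; otherwise inconclusive.
    """
    d1 = region1.df.set_index("variant_id")
    d2 = region2.df.set_index("variant_id")
    shared = d1.index.intersection(d2.index)
    if len(shared) < 2:
        if len(shared) == 0:
            raise ValueError("no shared variants between regions")
    d1 = d1.loc[shared]
    d2 = d2.loc[shared]
    l1 = log_abf(d1["beta"], d1["se"], _prior_w(region1))
    l2 = log_abf(d2["beta"], d2["se"], _prior_w(region2))

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    # H3 sums l1_i + l2_j over i != j: total cross product minus the diagonal
    lh3_all = lsum1 + lsum2
    if len(shared) > 1:
        lh3 = lh3_all + np.log1p(-np.exp(min(lsum12 - lh3_all, -1e-12)))
    else:
        lh3 = -np.inf
    terms = np.array([
        0.0,
        np.log(p1) + lsum1,
        np.log(p2) + lsum2,
        np.log(p1) + np.log(p2) + lh3,
        np.log(p12) + lsum12,
    ])
    denom = logsumexp(terms)
    pp = np.exp(terms - denom)
    pp_map = {f"H{i}": float(v) for i, v in enumerate(pp)}

    per_snp = np.exp((l1 + l2) - lsum12)
    per_snp = pd.Series(per_snp.to_numpy() if hasattr(per_snp, "to_numpy")
                        else per_snp, index=shared, name="pp_h4")
    positions = d1["pos"]
    credible = credible_snps(per_snp, positions, mass=credible_mass)

    if pp_map["H4"] >= 0.8:
        label = "colocalised"
    elif pp_map["H4"] >= 0.6:
        label = "suggestive"
    elif pp_map["H3"] >= 0.8:
        label = "distinct"
    elif pp_map["H3"] >= 0.6:
        label = "distinct_suggestive"
    else:
        label = "inconclusive"
    return ColocResult(pp=pp_map, per_snp_h4=per_snp, credible_set=credible,
                       label=label, n_shared=int(len(shared)))


def credible_snps(per_snp_h4: pd.Series, positions: pd.Series | None = None,
                  mass: float = 0.95) -> list:
    """Smallest variant set holding >= ``mass`` of the shared-signal posterior.

    Variants are added in decreasing posterior order; ties are broken by
    genomic position (then ID) for determinism.  Accepts either the per-SNP
    posterior series or a full :class:`ColocResult`.
    """
    if isinstance(per_snp_h4, ColocResult):
        per_snp_h4 = per_snp_h4.per_snp_h4
    df = pd.DataFrame({"pp": per_snp_h4})
    df["pos"] = positions if positions is not None else 0
    df["vid"] = df.index.astype(str)
    df = df.sort_values(["pp", "pos", "vid"],
                        ascending=[False, True, True], kind="mergesort")
    csum = df["pp"].cumsum()
    n_needed = int(np.searchsorted(csum.to_numpy(), mass - 1e-12) + 1)
    n_needed = min(n_needed, len(df))
    return list(df.index[:n_needed])
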