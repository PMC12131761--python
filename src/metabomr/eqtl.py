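"""eQTL follow-up: gene discovery, expression MR, SMR/HEIDI and mediation.

Once a metabolite-disorder pair colocalises, nearby genes (within 10 kb of
the credible SNPs) become candidate mediating transcripts.  Their causal
effects on metabolite and disorder are estimated by IVW on independent
cis-eQTL instruments, cross-checked with summary-based MR (SMR) on the top
cis-eQTL, and the single-causal-variant assumption probed with the HEIDI
heterogeneity test.  Where expression affects both metabolite and disorder,
the share of the expression->disorder effect running through the metabolite
is quantified by the product-of-coefficients method with delta-method SEs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, ivw, wald_ratio
from .instruments import Excluded, SelectionConfig, select_instruments
from .ld import LDMatrix
from .simulate import Region
from .sumstats import SummaryStats


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("gene start must be <= end")


@dataclass
class SMRResult:
    beta_smr: float
    se_smr: float
    p_smr: float
    p_heidi: float | None
    n_heidi_snps: int
    top_eqtl: str | None = None


@dataclass
class MediationResult:
    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    indirect: float
    se_indirect: float
    proportion: float
    se_proportion: float
    p: float

    @property
    def ci_proportion(self) -> tuple[float, float]:
        z = stats.norm.ppf(0.975)
        return (self.proportion - z * self.se_proportion,
                self.proportion + z * self.se_proportion)


def read_gene_table(path, sep: str = "\t", bed: bool = False) -> list[GeneRecord]:
    """Delimited gene table (GENE, CHR, START, END), 1-based inclusive.

    ``bed=True`` converts half-open 0-based starts at the boundary.
    """
    df = pd.read_csv(path, sep=sep)
    offset = 1 if bed else 0
    return [GeneRecord(str(r.GENE), str(r.CHR), int(r.START) + offset, int(r.END))
            for r in df.itertuples(index=False)]


def genes_near_credible(credible: list[str], positions: dict,
                        genes: list[GeneRecord],
                        window_kb: float = 10.0) -> list[str]:
    """Genes whose body lies within ``window_kb`` of any credible SNP.

    ``positions`` maps variant_id -> (chrom, pos).  A SNP inside the gene has
    distance zero.
    """
    window = window_kb * 1000.0
    hits = []
    for gene in genes:
        for vid in credible:
            chrom, pos = positions[vid]
            if str(chrom) != gene.chrom:
                continue
            if gene.start - window <= pos <= gene.end + window:
                hits.append(gene.gene_id)
                break
    return hits


def eqtl_ivw(eqtl_stats: SummaryStats, target_stats: SummaryStats,
             ld: LDMatrix, config: SelectionConfig | None = None
             ) -> MREstimate | Excluded:
    """IVW (or single-instrument Wald) MR of gene expression on a target trait.

    eQTL instruments are clumped at genome-wide significance only (no relaxed
    fallback), and as few as one instrument is accepted: with one the Wald
    ratio is returned, with two or more the multiplicative random-effects IVW.
    """
    cfg = config or SelectionConfig()
    eqtl_cfg = SelectionConfig(
        p_threshold_primary=cfg.p_threshold_primary,
        p_threshold_fallback=None, min_ivs=1, clump_r2=cfg.clump_r2,
        window_kb=cfg.window_kb, proxy_r2=cfg.proxy_r2, f_min=cfg.f_min,
        maf_palindrome=cfg.maf_palindrome)
    sel = select_instruments(eqtl_stats, target_stats, ld, eqtl_cfg)
    if isinstance(sel, Excluded):
        return sel
    if len(sel) == 1:
        row = sel.table.iloc[0]
        return wald_ratio(row["beta_exp"], row["se_exp"], row["beta_out"],
                          row["se_out"], variant_id=row["variant_id"])
    return ivw(sel, model="mre")


def smr(beta_e: float, se_e: float, beta_g: float, se_g: float
        ) -> tuple[float, float, float]:
    """Summary-based MR from the top cis-eQTL.

    beta_SMR = beta_gwas / beta_eqtl; the test statistic combines the two z
    scores, T = z_g^2 z_e^2 / (z_g^2 + z_e^2) ~ chi-square(1), and
    se_SMR = |beta_SMR| / sqrt(T).  Returns (beta_smr, se_smr, p_smr).
    """
    if beta_e == 0:
        raise ValueError("smr undefined for a null eQTL effect")
    z_e = beta_e / se_e
    z_g = beta_g / se_g
    beta_smr = beta_g / beta_e
    t = (z_g**2 * z_e**2) / (z_g**2 + z_e**2)
    p = float(stats.chi2.sf(t, df=1))
    se_smr = abs(beta_smr) / np.sqrt(t) if t > 0 else np.inf
    return float(beta_smr), float(se_smr), p


def heidi(region_eqtl: Region, region_gwas: Region, ld: LDMatrix,
          top_eqtl: str | None = None, p_eqtl_max: float = 1.57e-3,
          r2_window: tuple[float, float] = (0.05, 0.9),
          max_snps: int = 20) -> tuple[float | None, int]:
    """HEIDI heterogeneity test around the top cis-eQTL.

    Under a single shared causal variant, the SMR ratio b_XY(i) computed at
    any nearby SNP i equals the ratio at the top eQTL, so the differences
    d_i = b_XY(i) - b_XY(top) are centred at zero.  Their covariance follows
    from first-order error propagation with LD correlations among the SNPs
    (GWAS and eQTL samples independent).  The statistic sums the standardised
    d_i^2 and is referred to a Satterthwaite-matched scaled chi-square whose
    moments come from the correlation matrix of d.

    Eligible SNPs have eQTL p < ``p_eqtl_max`` and LD r^2 with the top eQTL
    inside ``r2_window``; at most ``max_snps`` (smallest eQTL p) are used.
    Returns (p_heidi or None, n_heidi_snps); None when fewer than three
    eligible SNPs remain.
    """
    e = region_eqtl.df.set_index("variant_id")
    g = region_gwas.df.set_index("variant_id")
    shared = [v for v in e.index if v in g.index and v in ld]
    if not shared:
        return None, 0
    e = e.loc[shared]
    g = g.loc[shared]
    z_e = e["beta"] / e["se"]
    p_e = pd.Series(2.0 * stats.norm.sf(np.abs(z_e)), index=e.index)
    if top_eqtl is None:
        top_eqtl = str(p_e.idxmin())
    if top_eqtl not in e.index:
        return None, 0

    r2_top = pd.Series([ld.r_between(top_eqtl, v) ** 2 for v in e.index],
                       index=e.index)
    eligible = [v for v in e.index
                if v != top_eqtl and p_e[v] < p_eqtl_max
                and r2_window[0] <= r2_top[v] <= r2_window[1]]
    eligible = sorted(eligible, key=lambda v: (p_e[v], v))[:max_snps]
    if len(eligible) < 3:
        return None, len(eligible)

    snps = [top_eqtl] + eligible
    be = e.loc[snps, "beta"].to_numpy()
    se_e_arr = e.loc[snps, "se"].to_numpy()
    bg = g.loc[snps, "beta"].to_numpy()
    se_g_arr = g.loc[snps, "se"].to_numpy()
    b_xy = bg / be
    R = np.array([[ld.r_between(a, b) for b in snps] for a in snps])

    # delta-method covariance of the b_XY vector
    cov_g = R * np.outer(se_g_arr, se_g_arr)
    cov_e = R * np.outer(se_e_arr, se_e_arr)
    grad_g = 1.0 / be
    grad_e = -bg / be**2
    cov_xy = (np.outer(grad_g, grad_g) * cov_g
              + np.outer(grad_e, grad_e) * cov_e)
    k = len(eligible)
    # d_i = b_xy[i] - b_xy[top];  V = cov of d
    V = (cov_xy[1:, 1:] - cov_xy[1:, [0]] - cov_xy[[0], 1:]
         + cov_xy[0, 0])
    d = b_xy[1:] - b_xy[0]
    sd = np.sqrt(np.diag(V))
    z_d = d / sd
    C = V / np.outer(sd, sd)

    # prune near-collinear rows if the correlation matrix is degenerate
    while True:
        eig = np.linalg.eigvalsh(C)
        if eig.min() > 1e-10 or len(z_d) <= 1:
            break
        off = np.abs(C - np.eye(len(C)))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        keep = np.ones(len(z_d), bool)
        keep[max(i, j)] = False
        z_d, C = z_d[keep], C[np.ix_(keep, keep)]
    if len(z_d) < 1:
        return None, 0

    T = float(np.sum(z_d**2))
    # T ~ sum lambda_i chi2_1 with lambdas the eigenvalues of C
    lam = np.linalg.eigvalsh(C)
    lam = lam[lam > 0]
    scale = float(np.sum(lam**2) / np.sum(lam))
    dof = float(np.sum(lam) ** 2 / np.sum(lam**2))
    p = float(stats.chi2.sf(T / scale, df=dof))
    return p, len(z_d)


def smr_heidi(region_eqtl: Region, region_gwas: Region, ld: LDMatrix,
              p_instrument: float = 5e-8, **heidi_kwargs) -> SMRResult:
    """SMR on the region's top eQTL plus the HEIDI follow-up.

    The top eQTL must reach genome-wide significance to instrument expression.
    """
    e = region_eqtl.df.set_index("variant_id")
    g = region_gwas.df.set_index("variant_id")
    shared = [v for v in e.index if v in g.index]
    if not shared:
        raise ValueError("no shared variants for SMR")
    z = (e.loc[shared, "beta"] / e.loc[shared, "se"]).abs()
    top = str(z.idxmax())
    p_top = float(2.0 * stats.norm.sf(z.loc[top]))
    if p_top > p_instrument:
        raise ValueError("top eQTL below genome-wide significance; "
                         "not a valid SMR instrument")
    beta_smr, se_smr, p_smr = smr(e.loc[top, "beta"], e.loc[top, "se"],
                                  g.loc[top, "beta"], g.loc[top, "se"])
    p_heidi, n_heidi = heidi(region_eqtl, region_gwas, ld, top_eqtl=top,
                             **heidi_kwargs)
    return SMRResult(beta_smr, se_smr, p_smr, p_heidi, n_heidi, top_eqtl=top)


def mediation(a: float, se_a: float, b: float, se_b: float,
              c: float, se_c: float) -> MediationResult:
    """Product-of-coefficients mediation with delta-method standard errors.

    a: exposure->mediator, b: mediator->outcome, c: exposure->outcome total
    effect, each with its SE from independent two-sample analyses.  The
    indirect effect is a*b with se = sqrt(a^2 se_b^2 + b^2 se_a^2); the
    proportion mediated is a*b/c with a first-order delta SE treating (a*b)
    and c as independent.  The p-value tests proportion = 0 against a normal
    reference.
    """
    for name, se in (("a", se_a), ("b", se_b), ("c", se_c)):
        if se <= 0:
            raise ValueError(f"se_{name} must be positive")
    if c == 0:
        raise ValueError("total effect c must be non-zero")
    indirect = a * b
    se_indirect = np.sqrt(a**2 * se_b**2 + b**2 * se_a**2)
    proportion = indirect / c
    var_prop = (se_indirect**2 / c**2
                + indirect**2 * se_c**2 / c**4)
    se_prop = float(np.sqrt(var_prop))
    if indirect == 0:
        p = 1.0
    else:
        p = float(2.0 * stats.norm.sf(abs(proportion) / se_prop))
    return MediationResult(a, se_a, b, se_b, c, se_c,
                           float(indirect), float(se_indirect),
                           float(proportion), se_prop, p)
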