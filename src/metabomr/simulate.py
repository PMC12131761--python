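"""Synthetic GWAS summary statistics under controlled causal regimes.

Summary statistics are simulated directly on the standardised scale: with R
the LD correlation matrix among m variants and b their joint (conditional)
effects on a trait with unit variance, the marginal GWAS estimates are drawn

    beta_hat ~ Normal(R b, R / n),    se = 1 / sqrt(n)

which is the asymptotic distribution of per-variant regression coefficients
on standardised genotypes.  Binary outcomes are simulated on the log-odds
scale with an effective sample size, sidestepping liability-scale conversion.
No individual-level genotypes are generated.

Regimes
-------
null          no exposure -> outcome effect (theta = 0)
polygenic     many instruments of comparable strength, shared causal theta
single_locus  one dominant instrument carrying the entire outcome
              association, plus weak satellites with no outcome effect
multivariable d correlated exposures, a designated true causal subset
coloc         regional scenario with a shared or distinct causal variant
triplet       expression -> metabolite -> disease chain with a direct path

Every generator is a pure function of its configuration, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDMatrix
from .instruments import InstrumentSet
from .sumstats import COLUMNS, SummaryStats

# default study sizes: a metabolite GWAS of ~50k and a disorder
# case-control GWAS with effective n ~100k, matching the scale of the
# consortium data this pipeline is designed for
N_EXPOSURE = 50_000
N_OUTCOME = 100_000


@dataclass
class ScenarioConfig:
    seed: int
    regime: str = "polygenic"
    n_exp: int = N_EXPOSURE
    n_out: int = N_OUTCOME
    n_snps: int = 20
    ld_rho: float = 0.0
    theta: float = 0.0
    # horizontal pleiotropy on the outcome's joint effects
    pleiotropy: str = "none"  # none | balanced | directional
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    invalid_fraction: float = 0.0
    # exposure genetics
    h2_exposure: float = 0.05
    # single-locus regime
    driver_beta: float = 0.2
    satellite_beta: float = 0.03
    driver_ratio: float = 0.2
    # multivariable regime
    d_exposures: int = 10
    true_set: tuple = (0,)
    exposure_corr: float = 0.5
    # regional / coloc regimes
    region_snps: int = 100
    region_rho: float = 0.9
    var_explained_1: float = 0.01
    var_explained_2: float = 0.01
    distinct_ld_r: float = 0.55
    # triplet regime
    a_effect: float = 0.3    # expression -> metabolite
    b_effect: float = 0.2    # metabolite -> outcome
    direct_effect: float = 0.0  # expression -> outcome, not via metabolite
    n_eqtl: int = 31_684
    eqtl_h2: float = 0.06
    n_iv: int = 5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.invalid_fraction <= 1:
            raise ValueError("invalid_fraction must be in [0, 1]")


def make_ld_block(m: int, rho: float, seed: int | None = None,
                  start_pos: int = 1_000_000, spacing: int = 1000) -> LDMatrix:
    """AR(1) LD block: r_ij = rho^|i-j|, positions ``spacing`` bp apart."""
    idx = np.arange(m)
    r = rho ** np.abs(idx[:, None] - idx[None, :]) if rho != 0 else np.eye(m)
    ids = [f"rs{seed if seed is not None else 0}_{i}" for i in range(m)]
    positions = start_pos + spacing * idx
    return LDMatrix(ids, r, positions, aligned_allele=["A"] * m)


def _marginal_draws(rng: np.random.Generator, R: np.ndarray, chol: np.ndarray,
                    b: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    mu = R @ b
    z = rng.standard_normal(len(b))
    beta_hat = mu + (chol @ z) / np.sqrt(n)
    se = np.full(len(b), 1.0 / np.sqrt(n))
    return beta_hat, se


def _as_sumstats(ids, positions, beta, se, eaf, n, trait_name, trait_type,
                 chrom="1") -> SummaryStats:
    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    df = pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": positions,
        "effect_allele": "A", "other_allele": "G",
        "eaf": eaf, "beta": beta, "se": se, "p": p, "n": n,
    })
    return SummaryStats(df[COLUMNS], trait_name=trait_name,
                        trait_type=trait_type, n=n)


def _exposure_effects(rng: np.random.Generator, cfg: ScenarioConfig) -> np.ndarray:
    """Joint exposure effects for instrument-style scenarios.

    Polygenic instruments: magnitudes jittered around sqrt(h2/m) with random
    signs, emulating a set of genome-wide-significant, comparably strong hits.
    """
    m = cfg.n_snps
    if cfg.regime == "single_locus":
        b = np.full(m, cfg.satellite_beta)
        b[0] = cfg.driver_beta
        return b * rng.choice([-1.0, 1.0], size=m)
    base = np.sqrt(cfg.h2_exposure / m)
    mags = base * rng.uniform(0.7, 1.3, size=m)
    return mags * rng.choice([-1.0, 1.0], size=m)


def simulate_pair(cfg: ScenarioConfig
                  ) -> tuple[SummaryStats, SummaryStats, dict]:
    """Two-sample exposure/outcome summary statistics plus the truth record.

    The truth record stores the causal effect, per-variant direct effects,
    the valid-instrument mask and (for single-locus runs) the driver ID.
    """
    if cfg.regime not in ("null", "polygenic", "single_locus"):
        raise ValueError(f"simulate_pair does not handle regime {cfg.regime!r}")
    m = cfg.n_snps
    n_invalid = int(round(cfg.invalid_fraction * m))
    if 0 < n_invalid and m < 3:
        raise ValueError("invalid_fraction requires >= 3 SNPs")
    rng = np.random.default_rng(cfg.seed)
    ld = make_ld_block(m, cfg.ld_rho, seed=cfg.seed)
    R = ld.r
    chol = np.linalg.cholesky(R)

    b = _exposure_effects(rng, cfg)
    theta = 0.0 if cfg.regime == "null" else cfg.theta
    d = np.zeros(m)
    if cfg.regime == "single_locus":
        # entire outcome association concentrated at the driver variant
        outcome_joint = np.zeros(m)
        outcome_joint[0] = cfg.driver_ratio * b[0]
        theta = 0.0
    else:
        if cfg.pleiotropy != "none":
            targets = (rng.choice(m, size=n_invalid, replace=False)
                       if n_invalid > 0 else np.arange(m))
            if cfg.pleiotropy == "balanced":
                d[targets] = rng.normal(0.0, cfg.pleio_sd, size=len(targets))
            elif cfg.pleiotropy == "directional":
                d[targets] = rng.normal(cfg.pleio_mean, cfg.pleio_sd,
                                        size=len(targets))
            else:
                raise ValueError(f"unknown pleiotropy {cfg.pleiotropy!r}")
        outcome_joint = theta * b + d

    beta_x, se_x = _marginal_draws(rng, R, chol, b, cfg.n_exp)
    beta_y, se_y = _marginal_draws(rng, R, chol, outcome_joint, cfg.n_out)
    eaf = rng.uniform(0.05, 0.95, size=m)

    exposure = _as_sumstats(ld.variant_ids, ld.positions, beta_x, se_x, eaf,
                            cfg.n_exp, "exposure", "quantitative")
    outcome = _as_sumstats(ld.variant_ids, ld.positions, beta_y, se_y, eaf,
                           cfg.n_out, "outcome", "binary")
    truth = {
        "theta": theta, "joint_exposure": b, "direct_effects": d,
        "valid": d == 0.0, "regime": cfg.regime, "ld": ld,
        "driver": ld.variant_ids[0] if cfg.regime == "single_locus" else None,
        "driver_ratio": cfg.driver_ratio if cfg.regime == "single_locus" else None,
    }
    return exposure, outcome, truth


def as_instruments(exposure: SummaryStats, outcome: SummaryStats,
                   variant_ids=None) -> InstrumentSet:
    """Pair all (or selected) shared variants into an InstrumentSet directly,
    bypassing the selection cascade — for estimator studies on simulated data
    where the instruments are known by construction."""
    e = exposure.indexed()
    o = outcome.indexed()
    ids = list(variant_ids) if variant_ids is not None else \
        [v for v in exposure.variant_ids if v in o.index]
    return InstrumentSet.from_arrays(
        e.loc[ids, "beta"].to_numpy(), e.loc[ids, "se"].to_numpy(),
        o.loc[ids, "beta"].to_numpy(), o.loc[ids, "se"].to_numpy(),
        variant_ids=ids, exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name)


@dataclass
class Region:
    """Regional summary statistics for one trait (1-based inclusive bounds)."""

    chrom: str
    start: int
    end: int
    df: pd.DataFrame  # variant_id, pos, beta, se, eaf, n
    trait_type: str = "quantitative"
    trait_name: str = ""
    sdY: float = 1.0

    def __post_init__(self) -> None:
        if len(self.df) and not (
                (self.df["pos"] >= self.start) & (self.df["pos"] <= self.end)).all():
            raise ValueError("region contains variants outside [start, end]")


def simulate_coloc_region(cfg: ScenarioConfig,
                          regime: str = "shared"
                          ) -> tuple[Region, Region, dict]:
    """Two traits measured over one LD region, sharing (or not) a causal variant.

    ``shared``: a single causal variant affects both traits with effect sizes
    set by the configured variance explained.  ``distinct``: each trait has
    its own causal variant, placed so their LD is ``cfg.distinct_ld_r``.
    """
    m = cfg.region_snps
    rng = np.random.default_rng(cfg.seed)
    ld = make_ld_block(m, cfg.region_rho, seed=cfg.seed)
    R = ld.r
    chol = np.linalg.cholesky(R)
    c1 = m // 2
    if regime == "shared":
        c2 = c1
    elif regime == "distinct":
        if cfg.region_rho <= 0:
            offset = 1
        else:
            offset = max(1, int(round(np.log(cfg.distinct_ld_r)
                                      / np.log(cfg.region_rho))))
        c2 = min(m - 1, c1 + offset)
    else:
        raise ValueError(f"unknown coloc regime {regime!r}")

    b1 = np.zeros(m)
    b1[c1] = np.sqrt(cfg.var_explained_1)
    b2 = np.zeros(m)
    b2[c2] = np.sqrt(cfg.var_explained_2)
    beta1, se1 = _marginal_draws(rng, R, chol, b1, cfg.n_exp)
    beta2, se2 = _marginal_draws(rng, R, chol, b2, cfg.n_out)
    eaf = rng.uniform(0.05, 0.95, size=m)

    def region(beta, se, n, name, trait_type):
        df = pd.DataFrame({"variant_id": ld.variant_ids, "pos": ld.positions,
                           "beta": beta, "se": se, "eaf": eaf, "n": n})
        return Region("1", int(ld.positions[0]), int(ld.positions[-1]), df,
                      trait_type=trait_type, trait_name=name)

    truth = {"regime": regime, "causal_1": ld.variant_ids[c1],
             "causal_2": ld.variant_ids[c2], "ld": ld,
             "hypothesis": "H4" if regime == "shared" else "H3"}
    return (region(beta1, se1, cfg.n_exp, "trait1", "quantitative"),
            region(beta2, se2, cfg.n_out, "trait2", "binary"), truth)


def simulate_multivariable(cfg: ScenarioConfig
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Instrument effects on d correlated exposures plus outcome effects.

    Returns (beta_X [n_snps x d], beta_Y, se_Y, truth).  Exposure columns are
    genetically correlated via a shared latent structure
    (equicorrelation ``exposure_corr``); the outcome responds only to the
    exposures in ``true_set``.
    """
    rng = np.random.default_rng(cfg.seed)
    m, d = cfg.n_snps, cfg.d_exposures
    rho = cfg.exposure_corr
    C = np.full((d, d), rho) + (1 - rho) * np.eye(d)
    cholC = np.linalg.cholesky(C)
    base = np.sqrt(cfg.h2_exposure / m)
    # joint per-SNP effects on the d exposures, correlated across exposures
    B = (rng.standard_normal((m, d)) @ cholC.T) * base
    beta_X = B + rng.standard_normal((m, d)) / np.sqrt(cfg.n_exp)
    theta = np.zeros(d)
    theta[list(cfg.true_set)] = cfg.theta
    se_Y = np.full(m, 1.0 / np.sqrt(cfg.n_out))
    beta_Y = B @ theta + rng.standard_normal(m) * se_Y
    truth = {"theta": theta, "true_set": tuple(cfg.true_set),
             "exposure_corr": C}
    return beta_X, beta_Y, se_Y, truth


def simulate_triplet(cfg: ScenarioConfig, n_iv_metab: int = 10
                     ) -> tuple[SummaryStats, SummaryStats, SummaryStats, dict]:
    """Expression -> metabolite -> disorder chain with an optional direct path.

    Two unlinked instrument blocks are generated.  In the cis block
    (``cfg.n_iv`` SNPs) variant j affects expression with joint effect e_j;
    the metabolite inherits a * e_j and the disorder (b*a + direct) * e_j on
    the log-odds scale.  A second, trans block of ``n_iv_metab`` SNPs
    instruments the metabolite only (joint effects g_j), so the disorder
    inherits b * g_j there — these are the instruments from which the
    mediator -> outcome path b is identifiable free of the direct path.  The
    implied proportion of the expression -> disorder effect running through
    the metabolite is a*b / (a*b + direct).
    """
    m1, m2 = cfg.n_iv, n_iv_metab
    m = m1 + m2
    rng = np.random.default_rng(cfg.seed)
    ld1 = make_ld_block(m1, cfg.ld_rho, seed=cfg.seed)
    ld2 = make_ld_block(m2, cfg.ld_rho, seed=cfg.seed,
                        start_pos=50_000_000)
    ids = [f"{v}_cis" for v in ld1.variant_ids] + \
          [f"{v}_trans" for v in ld2.variant_ids]
    positions = np.concatenate([ld1.positions, ld2.positions])
    R = np.block([[ld1.r, np.zeros((m1, m2))], [np.zeros((m2, m1)), ld2.r]])
    ld = LDMatrix(ids, R, positions, aligned_allele=["A"] * m)
    chol = np.linalg.cholesky(R)

    a, bb, direct = cfg.a_effect, cfg.b_effect, cfg.direct_effect
    e = (np.sqrt(cfg.eqtl_h2 / m1) * rng.uniform(0.8, 1.2, size=m1)
         * rng.choice([-1.0, 1.0], size=m1))
    g = (np.sqrt(cfg.h2_exposure / m2) * rng.uniform(0.8, 1.2, size=m2)
         * rng.choice([-1.0, 1.0], size=m2))
    joint_e = np.concatenate([e, np.zeros(m2)])
    joint_m = np.concatenate([a * e, g])
    joint_o = np.concatenate([(bb * a + direct) * e, bb * g])

    beta_e, se_e = _marginal_draws(rng, R, chol, joint_e, cfg.n_eqtl)
    beta_m, se_m = _marginal_draws(rng, R, chol, joint_m, cfg.n_exp)
    beta_o, se_o = _marginal_draws(rng, R, chol, joint_o, cfg.n_out)
    eaf = rng.uniform(0.05, 0.95, size=m)
    chroms = ["1"] * m1 + ["2"] * m2
    expr = _as_sumstats(ids, positions, beta_e, se_e, eaf, cfg.n_eqtl,
                        "expression", "quantitative", chrom=chroms)
    metab = _as_sumstats(ids, positions, beta_m, se_m, eaf, cfg.n_exp,
                         "metabolite", "quantitative", chrom=chroms)
    outcome = _as_sumstats(ids, positions, beta_o, se_o, eaf, cfg.n_out,
                           "disorder", "binary", chrom=chroms)
    total = bb * a + direct
    truth = {"a": a, "b": bb, "direct": direct, "total": total,
             "proportion_mediated": (a * bb / total) if total != 0 else np.nan,
             "ld": ld, "expr_ivs": ids[:m1], "metab_ivs": ids[m1:]}
    return expr, metab, outcome, truth


def with_seed(cfg: ScenarioConfig, seed: int) -> ScenarioConfig:
    """Copy of a scenario with a new seed (generators are pure in cfg)."""
    return replace(cfg, seed=seed)
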