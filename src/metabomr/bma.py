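"""Multivariable MR with Bayesian model averaging (MR-BMA).

Candidate exposures (metabolites already significant in the univariable
screen) compete within multivariable weighted-regression models of the
outcome's per-variant effects on the exposures' per-variant effects.  Every
subset S of exposures up to ``k_max`` members receives a closed-form marginal
likelihood under independent normal effect priors; subsets are weighted by an
independence prior with per-exposure inclusion probability ``prior_p``.  The
marginal inclusion probability (MIP) of an exposure is the posterior mass of
all models containing it, and the model-averaged causal effect (MACE) the
posterior-weighted mean of its conditional estimates.

Before modelling, near-duplicate exposures (pairwise correlation >= 0.95 in a
supplied genetic-correlation matrix) are pruned: an exposure that highly
correlates with more than one other candidate is removed outright, otherwise
the member of the pair with the weaker univariable evidence is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .ld import LDMatrix


@dataclass
class BMAInput:
    beta_X: np.ndarray       # n_snps x d
    beta_Y: np.ndarray       # n_snps
    se_Y: np.ndarray         # n_snps
    exposure_names: list[str]
    corr: np.ndarray | None = None  # d x d exposure correlation (supplied)

    def __post_init__(self) -> None:
        self.beta_X = np.atleast_2d(np.asarray(self.beta_X, float))
        self.beta_Y = np.asarray(self.beta_Y, float)
        self.se_Y = np.asarray(self.se_Y, float)
        n, d = self.beta_X.shape
        if len(self.beta_Y) != n or len(self.se_Y) != n:
            raise ValueError("beta_Y / se_Y length must match beta_X rows")
        if len(self.exposure_names) != d:
            raise ValueError("exposure_names length must match beta_X columns")
        if np.any(~np.isfinite(self.beta_X)) or np.any(~np.isfinite(self.beta_Y)):
            raise ValueError("missing cells are not allowed")
        if n <= d:
            import warnings
            warnings.warn("fewer instruments than exposures; estimates may be unstable")


@dataclass
class BMAResult:
    model_posteriors: dict
    mip: "pd.Series"
    mace: "pd.Series"
    excluded_by_corr: list = field(default_factory=list)


def correlation_prefilter(candidates: list[str], corr: pd.DataFrame,
                          ivw_p: dict, threshold: float = 0.95
                          ) -> tuple[list[str], list[tuple[str, str]]]:
    """Prune near-collinear candidates before model averaging.

    Iterating over pairs with |correlation| >= ``threshold``: a member that is
    highly correlated with more than one other remaining candidate is dropped
    (reason ``multi_correlated``); otherwise the pair member with the larger
    univariable IVW p-value is dropped (reason ``less_significant``).
    Returns (retained, [(dropped, reason), ...]).
    """
    retained = list(candidates)
    exclusions: list[tuple[str, str]] = []
    while True:
        sub = corr.loc[retained, retained].abs()
        np.fill_diagonal(sub.values, 0.0)
        counts = (sub >= threshold).sum(axis=1)
        if counts.max() == 0:
            break
        multi = counts[counts > 1]
        if len(multi):
            # drop the exposure entangled with the most others
            drop = multi.sort_values(ascending=False).index[0]
            exclusions.append((drop, "multi_correlated"))
        else:
            pair_idx = np.argwhere(sub.values >= threshold)[0]
            a, b = retained[pair_idx[0]], retained[pair_idx[1]]
            drop = a if ivw_p[a] > ivw_p[b] else b
            exclusions.append((drop, "less_significant"))
        retained.remove(drop)
    return retained, exclusions


def pool_instruments(iv_sets: dict, exposure_p: dict, ld: LDMatrix,
                     r2: float = 0.001, window_kb: float = 10_000.0
                     ) -> list[str]:
    """Union of per-exposure instruments, re-clumped.

    ``iv_sets`` maps exposure -> variant list and ``exposure_p`` maps
    (exposure, variant) -> exposure GWAS p.  Each pooled variant is scored by
    its best (smallest) exposure p across the contributing exposures, then
    the standard greedy clump is applied.
    """
    best_p: dict[str, float] = {}
    positions: dict[str, int] = {}
    for exp_name, ids in iv_sets.items():
        for vid in ids:
            p = exposure_p[(exp_name, vid)]
            if vid not in best_p or p < best_p[vid]:
                best_p[vid] = p
            if vid in ld:
                positions[vid] = ld.pos(vid)
    order = sorted(best_p, key=lambda v: (best_p[v], v))
    window_bp = window_kb * 1000.0
    kept: list[str] = []
    removed: set[str] = set()
    for vid in order:
        if vid in removed:
            continue
        kept.append(vid)
        if vid not in ld:
            continue
        for other in order:
            if other in removed or other == vid or other not in ld:
                continue
            if abs(positions[other] - positions[vid]) > window_bp:
                continue
            if ld.r2_between(vid, other) > r2:
                removed.add(other)
    return kept


def _log_marginal_likelihood(X: np.ndarray, y: np.ndarray,
                             prior_var: float) -> tuple[float, np.ndarray]:
    """log p(y | S) and posterior mean of theta for y ~ N(X theta, I),
    theta ~ N(0, prior_var * I), via the conjugate closed form."""
    n = len(y)
    const = -0.5 * n * np.log(2 * np.pi)
    if X.shape[1] == 0:
        return const - 0.5 * float(y @ y), np.zeros(0)
    A = X.T @ X + np.eye(X.shape[1]) / prior_var
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular design")
    Xty = X.T @ y
    theta_hat = np.linalg.solve(A, Xty)
    quad = float(y @ y - Xty @ theta_hat)
    logdet = X.shape[1] * np.log(prior_var) + logdet_A
    return const - 0.5 * logdet - 0.5 * quad, theta_hat


def mr_bma(inp: BMAInput, prior_p: float = 0.1, prior_var: float = 0.25,
           k_max: int = 4) -> BMAResult:
    """Exhaustive Bayesian model averaging over exposure subsets.

    Effects are modelled on the inverse-se_Y-weighted scale with each design
    column standardised to unit norm (the prior variance then refers to
    comparably scaled effects); MACE values are mapped back to the original
    per-exposure scale.  Subsets up to ``k_max`` members are enumerated
    exactly; posteriors are normalised over the enumerated space.  Singular
    subsets are skipped with a warning.
    """
    d = inp.beta_X.shape[1]
    if d < 1:
        raise ValueError("at least one exposure required")
    wy = 1.0 / inp.se_Y
    y = inp.beta_Y * wy
    X = inp.beta_X * wy[:, None]
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise ValueError("an exposure has all-zero weighted effects")
    Xs = X / norms

    log_post: dict[tuple, float] = {}
    theta_by_model: dict[tuple, np.ndarray] = {}
    log_prior_base = d * np.log1p(-prior_p)
    log_odds = np.log(prior_p) - np.log1p(-prior_p)
    for size in range(0, min(k_max, d) + 1):
        for S in combinations(range(d), size):
            try:
                ml, theta_hat = _log_marginal_likelihood(Xs[:, list(S)], y,
                                                         prior_var)
            except np.linalg.LinAlgError:
                import warnings
                warnings.warn(f"singular design for subset {S}; skipped")
                continue
            log_post[S] = ml + log_prior_base + size * log_odds
            theta_by_model[S] = theta_hat
    models = list(log_post)
    lp = np.array([log_post[S] for S in models])
    lp -= lp.max()
    post = np.exp(lp)
    post /= post.sum()
    posteriors = {S: float(p) for S, p in zip(models, post)}

    mip = np.zeros(d)
    mace = np.zeros(d)
    for S, p in posteriors.items():
        for pos, m in enumerate(S):
            mip[m] += p
            mace[m] += p * theta_by_model[S][pos] / norms[m]
    names = inp.exposure_names
    return BMAResult(model_posteriors=posteriors,
                     mip=pd.Series(mip, index=names, name="MIP"),
                     mace=pd.Series(mace, index=names, name="MACE"))


def rank_table(result: BMAResult, mip_threshold: float = 0.1) -> pd.DataFrame:
    """MIP/MACE ranking with the causal call at the MIP threshold."""
    df = pd.DataFrame({"MIP": result.mip, "MACE": result.mace})
    df["prioritised"] = df["MIP"] >= mip_threshold
    return df.sort_values("MIP", ascending=False)
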