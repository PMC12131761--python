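"""Two-sample MR causal estimators and their diagnostics.

All estimators consume an :class:`~metabomr.instruments.InstrumentSet` of k
harmonised variant effects (beta_exp, se_exp, beta_out, se_out) and return an
:class:`MREstimate` holding the causal log-odds (or SD-unit) effect, its
standard error, a 95% confidence interval and p-value.

Implemented methods
-------------------
wald_ratio            single-variant ratio estimate (first-order delta SE)
ivw                   inverse-variance weighted regression through the origin;
                      the default multiplicative random-effects model scales
                      the SE by the residual standard deviation, floored at 1
                      so the SE is never smaller than the fixed-effect SE
egger                 weighted regression with intercept; the slope is robust
                      to directional pleiotropy under InSIDE, the intercept
                      estimates the average direct effect
weighted_median       consistent when >= 50% of the weight is on valid
                      instruments; penalised variant down-weights
                      heterogeneity outliers
mr_lasso              per-variant direct effects penalised by L1; lambda is
                      chosen by a heterogeneity stopping rule and the causal
                      effect re-estimated by IVW on the selected valid set
contamination_mixture profile likelihood over a grid with each variant
                      assigned to a valid or invalid (null-centred) component
cml                   constrained maximum likelihood: for each allowed number
                      K of invalid instruments, jointly estimate which K carry
                      direct effects; select/average models by BIC
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .instruments import InstrumentSet

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    extras: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        """Causal odds ratio, exp(beta), for binary outcomes."""
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass
class MRDiagnostics:
    q: float | None
    p_q: float | None
    egger_intercept: float | None
    p_egger_intercept: float | None
    i2_gx: float | None
    loo_table: "object" = None  # pandas DataFrame
    influential_variant: str | None = None


def _estimate(method, beta, se, p, k, ci=None, **extras) -> MREstimate:
    if ci is None:
        ci = (beta - Z95 * se, beta + Z95 * se)
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return MREstimate(method, float(beta), float(se), float(ci[0]),
                      float(ci[1]), p, int(k), dict(extras))


def _ratios(ins: InstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant Wald ratios and their first-order standard errors."""
    bx, _, by, sy = ins.arrays
    return by / bx, sy / np.abs(bx)


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float,
               se_out: float, variant_id: str | None = None) -> MREstimate:
    """Single-variant causal estimate beta_out / beta_exp.

    The SE is the first-order delta approximation se_out / |beta_exp|, which
    ignores exposure-side sampling error and is accurate for strong
    instruments (F >> 10).
    """
    if beta_exp == 0:
        raise ValueError("wald_ratio undefined for beta_exp = 0")
    theta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    p = 2.0 * stats.norm.sf(abs(theta) / se)
    return _estimate("wald", theta, se, p, 1, variant_id=variant_id)


def ivw(ins: InstrumentSet, model: str = "mre") -> MREstimate:
    """Inverse-variance weighted estimate (weighted regression through origin).

    ``model='mre'`` is the multiplicative random-effects variant: the SE is
    scaled by the residual standard deviation sqrt(Q/(k-1)), floored at 1 so
    under-dispersion never shrinks the SE below the fixed-effect value.
    ``model='fe'`` is the fixed-effect estimate; ``model='mre_unconstrained'``
    applies the residual scale without the floor.  p-values are two-sided
    normal.
    """
    bx, _, by, sy = ins.arrays
    k = len(bx)
    if k < 2:
        raise ValueError("ivw requires >= 2 variants; use wald_ratio")
    w = 1.0 / sy**2
    sxx = np.sum(w * bx**2)
    beta = np.sum(w * bx * by) / sxx
    se_fe = np.sqrt(1.0 / sxx)
    resid = by - beta * bx
    sigma2 = np.sum(w * resid**2) / (k - 1)
    if model == "fe":
        scale = 1.0
    elif model == "mre":
        scale = max(np.sqrt(sigma2), 1.0)
    elif model == "mre_unconstrained":
        scale = np.sqrt(sigma2)
    else:
        raise ValueError(f"unknown ivw model {model!r}")
    se = se_fe * scale
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return _estimate("ivw_mre" if model.startswith("mre") else "ivw_fe",
                     beta, se, p, k, sigma=float(np.sqrt(sigma2)))


def egger(ins: InstrumentSet) -> MREstimate:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with intercept.

    Variants are first oriented so every beta_exp >= 0 (the fit is otherwise
    not invariant to allele relabelling).  The intercept estimates the average
    directional pleiotropic effect; the slope remains consistent under InSIDE.
    SEs carry the same floored multiplicative residual scaling as IVW and
    p-values use a t reference on k - 2 df.  Intercept fields are stored in
    ``extras``.
    """
    bx, _, by, sy = ins.arrays
    k = len(bx)
    if k < 3:
        raise ValueError("egger requires >= 3 variants")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    w = 1.0 / sy**2
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    sigma2 = np.sum(w * resid**2) / (k - 2)
    scale2 = max(sigma2, 1.0)
    se_slope = np.sqrt(scale2 / sxx)
    se_int = np.sqrt(scale2 * (1.0 / sw + xbar**2 / sxx))
    tq = stats.t.ppf(0.975, k - 2)
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, k - 2)
    p_int = 2.0 * stats.t.sf(abs(intercept) / se_int, k - 2)
    return _estimate("egger", slope, se_slope, p_slope, k,
                     ci=(slope - tq * se_slope, slope + tq * se_slope),
                     intercept=float(intercept), se_intercept=float(se_int),
                     p_intercept=float(p_int))


def _weighted_median_batch(theta: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median with interpolation at the 0.5 crossing.

    ``theta`` and ``weights`` are (B, k); returns (B,).  The estimate
    interpolates between the order statistics bracketing the point where the
    standardised cumulative weight s_j = (cum_j - w_j/2) / sum(w) crosses 0.5.
    """
    order = np.argsort(theta, axis=1, kind="mergesort")
    t = np.take_along_axis(theta, order, 1)
    w = np.take_along_axis(weights, order, 1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - 0.5 * w
    b_idx = np.arange(t.shape[0])
    j = np.clip((s < 0.5).sum(axis=1), 1, t.shape[1] - 1)
    s_lo, s_hi = s[b_idx, j - 1], s[b_idx, j]
    t_lo, t_hi = t[b_idx, j - 1], t[b_idx, j]
    gap = np.where(s_hi > s_lo, s_hi - s_lo, 1.0)
    est = t_lo + (t_hi - t_lo) * (0.5 - s_lo) / gap
    return np.where(s[:, 0] >= 0.5, t[:, 0], est)


def _weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    return float(_weighted_median_batch(theta[None, :], weights[None, :])[0])


def weighted_median(ins: InstrumentSet, penalised: bool = False,
                    n_boot: int = 1000, seed: int | None = 0) -> MREstimate:
    """(Penalised) weighted median of the per-variant ratio estimates.

    The estimate interpolates where the standardised cumulative
    inverse-variance weight crosses 0.5, and is consistent when at least half
    of the total weight comes from valid instruments.  The penalised variant
    multiplies each weight by min(1, 20 * P(chi2_1 > q_j)), q_j being the
    variant's one-df heterogeneity contribution about the unpenalised
    estimate, which sharply down-weights outliers.  The SE comes from a
    seeded parametric bootstrap of (beta_exp, beta_out).
    """
    bx, sx, by, sy = ins.arrays
    k = len(bx)
    if k < 3:
        raise ValueError("weighted_median requires >= 3 variants")
    theta, se_theta = _ratios(ins)
    w = 1.0 / se_theta**2

    def point(th, wt):
        if penalised:
            q = wt * (th - _weighted_median_batch(th, wt)[:, None]) ** 2
            wt = wt * np.minimum(1.0, 20.0 * stats.chi2.sf(q, df=1))
        return _weighted_median_batch(th, wt)

    beta = float(point(theta[None, :], w[None, :])[0])
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    th_b = by_b / bx_b
    w_b = bx_b**2 / sy**2
    boots = point(th_b, w_b)
    se = float(np.std(boots, ddof=1))
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 1.0
    return _estimate("pwmedian" if penalised else "wmedian", beta, se, p, k,
                     n_boot=n_boot)


def cochran_q(ins: InstrumentSet, theta: float | None = None
              ) -> tuple[float, float]:
    """Cochran's Q heterogeneity of the ratio estimates about ``theta``.

    ``theta`` defaults to the fixed-effect IVW estimate.  Returns (Q, p) with
    p from chi-square on k-1 df.
    """
    th, se_th = _ratios(ins)
    k = len(th)
    if k < 2:
        raise ValueError("cochran_q requires >= 2 variants")
    if theta is None:
        theta = ivw(ins, model="fe").beta
    w = 1.0 / se_th**2
    q = float(np.sum(w * (th - theta) ** 2))
    p = float(stats.chi2.sf(q, df=k - 1))
    return q, p


def mr_lasso(ins: InstrumentSet, lambda_grid=None, n_lambda: int = 50
             ) -> MREstimate:
    """MR-Lasso: L1-penalised per-variant direct effects.

    Minimises sum_j w_j (beta_out_j - theta*beta_exp_j - alpha_j)^2
    + 2*lambda*sum_j |alpha_j| by coordinate descent with soft-thresholding
    of the alphas (w_j = 1/se_out_j^2).  Descending the lambda grid, the
    chosen lambda is the largest whose selected valid set {j: alpha_j = 0}
    has Cochran's Q below the 0.95 chi-square quantile on |valid|-1 df; the
    reported estimate is IVW on that valid set.
    """
    bx, sx, by, sy = ins.arrays
    k = len(bx)
    if k < 3:
        raise ValueError("mr_lasso requires >= 3 variants")
    w = 1.0 / sy**2
    theta0 = ivw(ins, model="fe").beta
    if lambda_grid is None:
        lam_max = float(np.max(np.abs(w * (by - theta0 * bx))))
        lambda_grid = np.geomspace(lam_max * 1.001, lam_max * 1e-3, n_lambda)
    else:
        lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]

    chosen = None
    for lam in lambda_grid:
        alpha = np.zeros(k)
        theta = theta0
        for _ in range(500):
            r = by - theta * bx
            alpha_new = np.sign(r) * np.maximum(np.abs(r) - lam / w, 0.0)
            theta_new = np.sum(w * bx * (by - alpha_new)) / np.sum(w * bx**2)
            if (np.max(np.abs(alpha_new - alpha)) < 1e-10
                    and abs(theta_new - theta) < 1e-10):
                alpha, theta = alpha_new, theta_new
                break
            alpha, theta = alpha_new, theta_new
        valid = np.flatnonzero(alpha == 0.0)
        if len(valid) < 2:
            continue
        sub = InstrumentSet.from_arrays(bx[valid], sx[valid], by[valid],
                                        sy[valid])
        q, _ = cochran_q(sub)
        if q < stats.chi2.ppf(0.95, df=len(valid) - 1):
            chosen = (lam, valid)
            break
    if chosen is None:
        raise ValueError("no_valid_subset: no lambda yields a homogeneous "
                         "valid set of >= 2 instruments")
    lam, valid = chosen
    sub = InstrumentSet.from_arrays(bx[valid], sx[valid], by[valid], sy[valid])
    est = ivw(sub, model="mre")
    invalid_ids = [ins.table["variant_id"].iloc[j]
                   for j in range(k) if j not in set(valid.tolist())]
    return _estimate("lasso", est.beta, est.se, est.p, len(valid),
                     ci=(est.ci_low, est.ci_high), n_valid=len(valid),
                     lambda_selected=float(lam), invalid_variants=invalid_ids)


def contamination_mixture(ins: InstrumentSet, psi: float | None = None,
                          grid: np.ndarray | None = None,
                          grid_step: float = 1e-3,
                          max_grid_points: int = 20001) -> MREstimate:
    """Contamination-mixture estimate over a profile likelihood grid.

    Each variant's ratio estimate is modelled as either valid,
    N(theta, se_j^2), or invalid, N(0, se_j^2 + psi^2); the profile
    log-likelihood at each grid theta takes the better component per variant.
    The estimate is the grid argmax and the 95% CI the set within 3.841/2 of
    the maximum (chi-square 1 df).

    psi sets the scale of pleiotropic (invalid) effects and defaults to
    1.5 x max(SD of the ratio estimates, 2 x RMS ratio SE): the usual
    1.5 x SD heuristic, floored at twice the measurement-error scale so that
    pure sampling scatter in a fully valid instrument set is not absorbed by
    the contamination component (which would truncate the valid set one-sided
    and bias the estimate away from zero).
    """
    th, se_th = _ratios(ins)
    k = len(th)
    if k < 3:
        raise ValueError("contamination_mixture requires >= 3 variants")
    if psi is None:
        rms_se = float(np.sqrt(np.mean(se_th**2)))
        psi = 1.5 * max(float(np.std(th, ddof=1)), 2.0 * rms_se)
    if grid is None:
        span = float(np.max(th) - np.min(th))
        span = max(span, float(np.min(se_th)))
        lo, hi = float(np.min(th)) - 3 * span, float(np.max(th)) + 3 * span
        step = max(grid_step, (hi - lo) / (max_grid_points - 1))
        grid = np.arange(lo, hi + step / 2, step)
    grid = np.asarray(grid, float)
    if grid.size < 3:
        raise ValueError("degenerate grid for contamination mixture")

    inv_var = 1.0 / se_th**2
    ll_invalid = (-0.5 * np.log(2 * np.pi * (se_th**2 + psi**2))
                  - 0.5 * th**2 / (se_th**2 + psi**2))  # (k,)
    diff = grid[:, None] - th[None, :]
    ll_valid = (-0.5 * np.log(2 * np.pi * se_th**2)[None, :]
                - 0.5 * diff**2 * inv_var[None, :])
    ll = np.maximum(ll_valid, ll_invalid[None, :]).sum(axis=1)
    j = int(np.argmax(ll))
    beta = float(grid[j])
    inside = 2.0 * (ll[j] - ll) <= stats.chi2.ppf(0.95, 1)
    ci_low = float(grid[inside].min())
    ci_high = float(grid[inside].max())
    se = (ci_high - ci_low) / (2 * Z95)
    # likelihood-ratio p against theta = 0
    ll0 = float(np.maximum(
        -0.5 * np.log(2 * np.pi * se_th**2) - 0.5 * th**2 * inv_var,
        ll_invalid).sum())
    p = float(stats.chi2.sf(2.0 * (ll[j] - ll0), df=1))
    valid_mask = ll_valid[j] >= ll_invalid
    valid_ids = list(ins.table["variant_id"].iloc[np.flatnonzero(valid_mask)])
    return _estimate("contmix", beta, se, p, k, ci=(ci_low, ci_high),
                     psi=float(psi), valid_variants=valid_ids)


def cml(ins: InstrumentSet, ma: bool = True, k_range=None,
        max_iter: int = 200, tol: float = 1e-10) -> MREstimate:
    """Constrained maximum likelihood with BIC model selection / averaging.

    For each candidate number K of invalid instruments, alternately (i) flag
    the K variants with the largest squared standardised residuals about the
    current theta as carrying free direct effects, and (ii) re-estimate theta
    by fixed-effect IVW on the remaining valid set, until the invalid set
    stabilises.  BIC(K) = RSS_valid + K log k.  With ``ma`` the reported
    estimate is the BIC-weighted model average, its variance inflated by the
    between-model spread; otherwise the single BIC-minimising model.
    ``extras`` records the per-K estimates and the selected K.
    """
    bx, sx, by, sy = ins.arrays
    k = len(bx)
    if k < 3:
        raise ValueError("cml requires >= 3 variants")
    w = 1.0 / sy**2
    if k_range is None:
        k_range = range(0, k - 1)
    theta_fe = np.sum(w * bx * by) / np.sum(w * bx**2)

    results = []  # (K, theta, se, bic, converged, invalid_idx)
    for K in k_range:
        theta = theta_fe
        invalid: tuple[int, ...] = ()
        converged = False
        for _ in range(max_iter):
            resid2 = w * (by - theta * bx) ** 2
            new_invalid = tuple(sorted(np.argsort(-resid2, kind="mergesort")[:K].tolist()))
            valid = np.setdiff1d(np.arange(k), new_invalid)
            theta_new = (np.sum(w[valid] * bx[valid] * by[valid])
                         / np.sum(w[valid] * bx[valid] ** 2))
            if new_invalid == invalid and abs(theta_new - theta) < tol:
                theta = theta_new
                converged = True
                break
            theta, invalid = theta_new, new_invalid
        valid = np.setdiff1d(np.arange(k), invalid)
        rss = float(np.sum(w[valid] * (by[valid] - theta * bx[valid]) ** 2))
        se = float(np.sqrt(1.0 / np.sum(w[valid] * bx[valid] ** 2)))
        bic = rss + K * np.log(k)
        results.append((K, float(theta), se, bic, converged, invalid))

    converged_results = [r for r in results if r[4]] or results
    bics = np.array([r[3] for r in converged_results])
    best = converged_results[int(np.argmin(bics))]
    if ma:
        wts = np.exp(-0.5 * (bics - bics.min()))
        wts /= wts.sum()
        thetas = np.array([r[1] for r in converged_results])
        ses = np.array([r[2] for r in converged_results])
        beta = float(np.sum(wts * thetas))
        var = float(np.sum(wts * (ses**2 + (thetas - beta) ** 2)))
        se = np.sqrt(var)
    else:
        beta, se = best[1], best[2]
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 1.0
    return _estimate("cml", beta, se, p, k,
                     k_hat=int(best[0]),
                     invalid_variants=[ins.table["variant_id"].iloc[j]
                                       for j in best[5]],
                     theta_by_k={r[0]: r[1] for r in results},
                     all_converged=all(r[4] for r in results))


def leave_one_out(ins: InstrumentSet, loo_alpha: float = 0.05,
                  model: str = "mre"):
    """Leave-one-out IVW and the single-influential-variant rule.

    Recomputes the IVW estimate excluding each variant in turn.  A variant is
    flagged influential when its exclusion lifts the IVW p-value above
    ``loo_alpha`` (the estimate is no longer nominally significant without
    it); when several qualify the one with the largest leave-out p is
    reported.  Returns (loo_table, influential_variant_or_None).
    """
    import pandas as pd

    k = len(ins)
    if k < 3:
        raise ValueError("leave_one_out requires >= 3 variants")
    rows = []
    for vid in ins.table["variant_id"]:
        est = ivw(ins.drop(vid), model=model)
        rows.append({"variant_id": vid, "beta_loo": est.beta,
                     "se_loo": est.se, "p_loo": est.p})
    table = pd.DataFrame(rows)
    above = table.loc[table["p_loo"] > loo_alpha]
    influential = (above.sort_values(["p_loo", "variant_id"]).iloc[-1]["variant_id"]
                   if len(above) else None)
    return table, influential


#: the six sensitivity estimators run alongside IVW in the screen
SENSITIVITY_METHODS = ("wmedian", "pwmedian", "cml", "contmix", "lasso", "egger")


def sensitivity_panel(ins: InstrumentSet, seed: int | None = 0,
                      n_boot: int = 1000) -> dict[str, MREstimate | Exception]:
    """Run the six sensitivity estimators; failures are returned, not raised."""
    runners = {
        "wmedian": lambda: weighted_median(ins, penalised=False, seed=seed,
                                           n_boot=n_boot),
        "pwmedian": lambda: weighted_median(ins, penalised=True, seed=seed,
                                            n_boot=n_boot),
        "cml": lambda: cml(ins),
        "contmix": lambda: contamination_mixture(ins),
        "lasso": lambda: mr_lasso(ins),
        "egger": lambda: egger(ins),
    }
    panel: dict[str, MREstimate | Exception] = {}
    for name, run in runners.items():
        try:
            panel[name] = run()
        except Exception as err:  # recorded and treated as discordant downstream
            panel[name] = err
    return panel


def diagnostics(ins: InstrumentSet, loo_alpha: float = 0.05) -> MRDiagnostics:
    """Cochran's Q, Egger intercept, I2_GX and leave-one-out in one bundle."""
    from .instruments import i2_gx as _i2

    q, p_q = cochran_q(ins)
    try:
        eg = egger(ins)
        e_int, e_p = eg.extras["intercept"], eg.extras["p_intercept"]
    except ValueError:
        e_int = e_p = None
    bx, sx, _, _ = ins.arrays
    loo_table, influential = leave_one_out(ins, loo_alpha=loo_alpha)
    return MRDiagnostics(q=q, p_q=p_q, egger_intercept=e_int,
                         p_egger_intercept=e_p, i2_gx=_i2(bx, sx),
                         loo_table=loo_table, influential_variant=influential)
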