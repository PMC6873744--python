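"""Causal-effect estimators for two-sample summary-data MR.

All estimators combine per-SNP Wald ratios ``beta_outcome / beta_exposure``
(log odds of outcome per SD of exposure) under different assumptions about
instrument validity:

- ``ivw``: inverse-variance-weighted mean of the ratios; unbiased only when
  every instrument is valid (no horizontal pleiotropy).
- ``maximum_likelihood``: joint bivariate-normal likelihood over the true
  per-SNP exposure effects and the causal slope; accounts for exposure-side
  measurement error, which first-order IVW ignores.
- ``egger``: weighted regression of outcome on exposure betas with a free
  intercept; the intercept estimates average directional pleiotropy, the
  slope remains consistent under the InSIDE assumption.
- ``weighted_median``: consistent when instruments carrying at least half of
  the weight are valid.
- ``weighted_mode``: kernel-density argmax of the ratios; consistent when
  the largest weight cluster comes from valid instruments (plurality
  validity).

Internally everything works per SD *increase* of the exposure; when a
panel's ``sign_convention`` is ``per_sd_decrease`` the pooled log odds ratio
is negated (and the interval reflected) at report time, so printed odds
ratios read "odds of outcome per 1-SD decrease in exposure".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import ConvergenceError, DataError
from .summary_data import HarmonizedInstrument, InstrumentPanel

_TINY_P = 5e-324  # p-values are reported in (0, 1], never exactly 0

RATIO_SE_MODES = ("first_order", "second_order")


@dataclass(frozen=True)
class MREstimate:
    """One method's pooled causal estimate.

    ``beta`` is the log odds ratio per 1 SD of exposure *under*
    ``convention``; ``odds_ratio`` and its CI are its exponential.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_snps: int
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    convention: str

    def __post_init__(self):
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("estimate outside its own confidence interval")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must be in (0, 1]")


@dataclass(frozen=True)
class EggerFit:
    """Egger regression result: causal slope plus pleiotropy intercept."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float

    def __post_init__(self):
        if self.intercept_se <= 0:
            raise ValueError("intercept se must be > 0")


def _finalize(
    method: str,
    beta_increase: float,
    se: float,
    n_snps: int,
    convention: str,
    t_df: int | None = None,
) -> MREstimate:
    """Apply the sign convention and normal/t inference to a point estimate."""
    beta = -beta_increase if convention == "per_sd_decrease" else beta_increase
    if t_df is not None:
        crit = stats.t.ppf(0.975, t_df)
        p = 2.0 * stats.t.sf(abs(beta) / se, t_df) if se > 0 else (1.0 if beta == 0 else _TINY_P)
    else:
        crit = stats.norm.ppf(0.975)
        p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else _TINY_P)
    p = min(max(p, _TINY_P), 1.0)
    lo, hi = beta - crit * se, beta + crit * se
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n_snps=n_snps,
        odds_ratio=float(np.exp(beta)),
        or_ci_low=float(np.exp(lo)),
        or_ci_high=float(np.exp(hi)),
        convention=convention,
    )


def ratio_standard_errors(panel: InstrumentPanel, ratio_se: str = "first_order") -> np.ndarray:
    """Per-SNP Wald-ratio standard errors by the delta method.

    ``first_order`` ignores exposure-side uncertainty (se_out/|b_exp|);
    ``second_order`` adds the exposure term
    ``sqrt(se_out^2/b_exp^2 + b_out^2 se_exp^2 / b_exp^4)``.
    """
    if ratio_se not in RATIO_SE_MODES:
        raise ValueError(f"ratio_se must be one of {RATIO_SE_MODES}")
    bx, sx = panel.beta_exposure, panel.se_exposure
    by, sy = panel.beta_outcome, panel.se_outcome
    if ratio_se == "first_order":
        return sy / np.abs(bx)
    return np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)


def wald_ratio(
    instr: HarmonizedInstrument,
    convention: str = "per_sd_increase",
    second_order: bool = False,
) -> MREstimate:
    """Single-SNP causal estimate beta_outcome / beta_exposure."""
    if instr.beta_exposure == 0:
        raise DataError(f"{instr.snp_id}: Wald ratio undefined for zero exposure beta")
    beta = instr.beta_outcome / instr.beta_exposure
    se = instr.se_outcome / abs(instr.beta_exposure)
    if second_order:
        se = float(
            np.sqrt(
                instr.se_outcome**2 / instr.beta_exposure**2
                + instr.beta_outcome**2 * instr.se_exposure**2 / instr.beta_exposure**4
            )
        )
    return _finalize("wald_ratio", beta, se, 1, convention)


def ivw(panel: InstrumentPanel, variance_model: str = "multiplicative_re") -> MREstimate:
    """Inverse-variance-weighted combination of Wald ratios.

    Equivalent to weighted regression of outcome betas on exposure betas
    through the origin with weights 1/se_outcome^2. Under
    ``multiplicative_re`` (default) the fixed-effect SE is inflated by
    ``sqrt(Q/(n-1))`` when the heterogeneity statistic exceeds its degrees
    of freedom, and never deflated (underdispersion floored at 1); the point
    estimate is identical under both variance models.
    """
    if variance_model not in ("fixed", "multiplicative_re"):
        raise ValueError(f"unknown variance model {variance_model!r}")
    n = panel.n_snps
    if n == 1:
        return wald_ratio(panel.instruments[0], convention=panel.sign_convention)
    bx, by, sy = panel.beta_exposure, panel.beta_outcome, panel.se_outcome
    w = bx**2 / sy**2
    ratios = by / bx
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    if variance_model == "multiplicative_re":
        q = float(np.sum(w * (ratios - beta) ** 2))
        se *= max(1.0, np.sqrt(q / (n - 1)))
    return _finalize("ivw", beta, se, n, panel.sign_convention)


def maximum_likelihood(panel: InstrumentPanel, max_iter: int = 2000) -> MREstimate:
    """Joint bivariate-normal likelihood estimate of the causal slope.

    Model: ``b_exp_i ~ N(gamma_i, se_exp_i^2)``,
    ``b_out_i ~ N(beta * gamma_i, se_out_i^2)``. The per-SNP effects
    ``gamma_i`` profile out in closed form, leaving the exact profile
    objective ``0.5 sum (b_out_i - beta b_exp_i)^2 / (se_out_i^2 + beta^2
    se_exp_i^2)``, which a deterministic Brent search minimizes from the
    fixed-effect IVW start point. The SE comes from the observed
    information of the full parameter vector at the optimum.
    """
    n = panel.n_snps
    if n < 2:
        raise DataError("maximum likelihood needs at least 2 instruments")
    bx, sx = panel.beta_exposure, panel.se_exposure
    by, sy = panel.beta_outcome, panel.se_outcome
    vx, vy = sx**2, sy**2

    def profile_nll(b):
        return 0.5 * np.sum((by - b * bx) ** 2 / (vy + b**2 * vx))

    beta0 = float(np.sum(bx * by / vy) / np.sum(bx**2 / vy))
    half_width = 10.0 * (abs(beta0) + np.max(np.abs(by / bx)) + 1e-6)
    res = optimize.minimize_scalar(
        profile_nll,
        bounds=(beta0 - half_width, beta0 + half_width),
        method="bounded",
        options={"xatol": 1e-12, "maxiter": max_iter},
    )
    if not res.success:
        raise ConvergenceError(
            f"ML estimator did not converge after {max_iter} iterations", details=res
        )
    beta = float(res.x)
    # profile optimum of the per-SNP effects, for the information matrix
    g = (bx / vx + beta * by / vy) / (1.0 / vx + beta**2 / vy)

    # observed information; SE of beta via block inversion of the Hessian
    d_gg = 1.0 / vx + beta**2 / vy
    d_gb = -(by - 2 * beta * g) / vy
    d_bb = float(np.sum(g**2 / vy))
    info_beta = d_bb - float(np.sum(d_gb**2 / d_gg))
    if info_beta <= 0:
        raise ConvergenceError("observed information for beta not positive", details=res)
    se = info_beta**-0.5
    return _finalize("maximum_likelihood", beta, se, n, panel.sign_convention)


def egger(panel: InstrumentPanel) -> EggerFit:
    """MR-Egger: weighted regression of outcome on exposure betas with intercept.

    Weights are 1/se_outcome^2; instruments must be oriented with positive
    exposure betas (guaranteed by harmonization). Standard errors use
    multiplicative residual scaling floored at 1 (never below the
    fixed-effect SEs); inference uses the t distribution with n-2 df.
    """
    n = panel.n_snps
    if n < 3:
        raise DataError("Egger regression needs at least 3 instruments")
    bx, by, sy = panel.beta_exposure, panel.beta_outcome, panel.se_outcome
    fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    # statsmodels scales the covariance by RSS/(n-2); floor that factor at 1
    # (computed from the unscaled covariance so an exact fit stays finite)
    se_int, se_slope = np.sqrt(
        np.diag(fit.normalized_cov_params) * max(1.0, fit.scale)
    )
    intercept, slope = fit.params
    slope_est = _finalize("egger_slope", float(slope), float(se_slope), n,
                          panel.sign_convention, t_df=n - 2)
    p_int = float(2 * stats.t.sf(abs(intercept) / se_int, n - 2)) if se_int > 0 else 1.0
    return EggerFit(
        slope=slope_est,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_p=min(max(p_int, _TINY_P), 1.0),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: percentile positions (cum w - w/2)/sum w."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, r))


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float,
                grid_points: int = 512) -> float:
    """Argmax of the weighted Gaussian KDE of the ratios on a fine grid."""
    n = len(ratios)
    sd = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    h = phi * 0.9 * min(sd, mad) * n ** (-0.2)
    h = max(h, 1e-8)  # all-identical ratios: degenerate but well-defined
    wn = weights / np.sum(weights)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_points)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ wn
    return float(grid[np.argmax(dens)])


def _bootstrap_se(panel: InstrumentPanel, point_fn, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: resample betas from their sampling distributions."""
    rng = np.random.default_rng(seed)
    bx, sx = panel.beta_exposure, panel.se_exposure
    by, sy = panel.beta_outcome, panel.se_outcome
    n = panel.n_snps
    est = np.empty(n_boot)
    for b in range(n_boot):
        bx_s = bx + sx * rng.standard_normal(n)
        by_s = by + sy * rng.standard_normal(n)
        est[b] = point_fn(bx_s, by_s)
    return float(np.std(est, ddof=1))


def weighted_median(
    panel: InstrumentPanel,
    n_boot: int = 1000,
    seed: int = 0,
    ratio_se: str = "first_order",
) -> MREstimate:
    """Weighted median of Wald ratios; robust to <50% invalid weight.

    Weights are inverse squared ratio SEs (``ratio_se`` selects the
    first-order or exposure-aware second-order delta SE); the estimate
    interpolates the weighted empirical quantile function at 0.5. The SE is
    a parametric bootstrap with the recorded seed.
    """
    if panel.n_snps < 3:
        raise DataError("weighted median needs at least 3 instruments")
    sx, sy = panel.se_exposure, panel.se_outcome

    def point(bx_s, by_s):
        r = by_s / bx_s
        if ratio_se == "first_order":
            w = (bx_s / sy) ** 2
        else:
            w = 1.0 / (sy**2 / bx_s**2 + by_s**2 * sx**2 / bx_s**4)
        return _weighted_median_point(r, w)

    beta = point(panel.beta_exposure, panel.beta_outcome)
    se = _bootstrap_se(panel, point, n_boot, seed)
    return _finalize("weighted_median", beta, se, panel.n_snps, panel.sign_convention)


def weighted_mode(
    panel: InstrumentPanel,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    ratio_se: str = "first_order",
    grid_points: int = 512,
) -> MREstimate:
    """Mode-based estimate: weighted KDE argmax of the Wald ratios.

    Bandwidth ``h = phi * 0.9 * min(sd, 1.4826 MAD) * n^(-1/5)`` over a
    ``grid_points``-point grid spanning the ratios +/- 3h. Consistent under
    plurality validity; SE by parametric bootstrap with the recorded seed.
    """
    if panel.n_snps < 3:
        raise DataError("weighted mode needs at least 3 instruments")
    if ratio_se not in RATIO_SE_MODES:
        raise ValueError(f"ratio_se must be one of {RATIO_SE_MODES}")
    sx, sy = panel.se_exposure, panel.se_outcome

    def point(bx_s, by_s):
        r = by_s / bx_s
        if ratio_se == "first_order":
            w = (bx_s / sy) ** 2
        else:
            w = 1.0 / (sy**2 / bx_s**2 + by_s**2 * sx**2 / bx_s**4)
        return _mode_point(r, w, phi, grid_points)

    beta = point(panel.beta_exposure, panel.beta_outcome)
    se = _bootstrap_se(panel, point, n_boot, seed)
    return _finalize("weighted_mode", beta, se, panel.n_snps, panel.sign_convention)


def all_estimates(
    panel: InstrumentPanel,
    variance_model: str = "multiplicative_re",
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    ratio_se: str = "first_order",
) -> list[MREstimate]:
    """IVW, maximum likelihood, Egger slope, weighted median and mode."""
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    return [
        ivw(panel, variance_model=variance_model),
        maximum_likelihood(panel),
        egger(panel).slope,
        weighted_median(panel, n_boot=n_boot, seed=int(seeds[0]), ratio_se=ratio_se),
        weighted_mode(panel, phi=phi, n_boot=n_boot, seed=int(seeds[1]), ratio_se=ratio_se),
    ]
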