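"""Heterogeneity, pleiotropy, outlier and sensitivity diagnostics.

These checks probe the MR identifying assumptions from different angles:
Cochran's Q (about the IVW fit) and Ruecker's Q' (about the Egger fit)
measure excess dispersion of the per-SNP Wald ratios; leave-one-out
re-estimation shows whether any single SNP drives the pooled estimate;
MR-PRESSO resamples the no-pleiotropy model to test the observed residual
sum of squares globally and per SNP; and a two-estimate Cochran Q compares
the MR result against an external (e.g. observational) estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError
from .estimators import MREstimate, ivw
from .summary_data import InstrumentPanel


@dataclass(frozen=True)
class HeterogeneityResult:
    """A chi-square heterogeneity statistic and its context."""

    statistic: float
    df: int
    p_value: float
    context: str

    def __post_init__(self):
        if self.statistic < 0 or self.df < 1:
            raise ValueError("Q must be >= 0 with df >= 1")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must be in (0, 1]")


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, per-SNP outlier and distortion test results."""

    rss_observed: float
    global_p: float
    per_snp_outlier_p: Mapping[str, float]
    outliers: tuple[str, ...]
    distortion_p: float | None
    n_sim: int
    seed: int


@dataclass(frozen=True)
class LooResult:
    """Leave-one-out estimates plus the full-panel reference estimate."""

    entries: tuple[tuple[str, MREstimate], ...]
    full_panel_estimate: MREstimate


def cochran_q(panel: InstrumentPanel, context: str = "ivw") -> HeterogeneityResult:
    """Modified Cochran Q about the IVW fit, or Ruecker's Q' about Egger's.

    IVW context: ``Q = sum w_i (ratio_i - beta_ivw)^2`` with
    ``w_i = (b_exp_i / se_out_i)^2`` and ``n-1`` df. Egger context: weighted
    residual sum of squares about the intercept-free-slope fit with ``n-2``
    df. p-values from the chi-square upper tail.
    """
    n = panel.n_snps
    bx, by, sy = panel.beta_exposure, panel.beta_outcome, panel.se_outcome
    if context == "ivw":
        if n < 2:
            raise DataError("IVW heterogeneity needs at least 2 instruments")
        w = (bx / sy) ** 2
        ratios = by / bx
        beta = np.sum(w * ratios) / np.sum(w)
        q = float(np.sum(w * (ratios - beta) ** 2))
        df = n - 1
    elif context == "egger":
        if n < 3:
            raise DataError("Egger heterogeneity needs at least 3 instruments")
        wls_w = 1.0 / sy**2
        x = np.column_stack([np.ones(n), bx])
        coef = np.linalg.solve(x.T @ (wls_w[:, None] * x), x.T @ (wls_w * by))
        q = float(np.sum(wls_w * (by - x @ coef) ** 2))
        df = n - 2
    else:
        raise ValueError(f"unknown heterogeneity context {context!r}")
    p = min(max(float(stats.chi2.sf(q, df)), 5e-324), 1.0)
    return HeterogeneityResult(statistic=q, df=df, p_value=p, context=context)


def leave_one_out(
    panel: InstrumentPanel,
    estimator: Callable[[InstrumentPanel], MREstimate] = ivw,
) -> LooResult:
    """Re-estimate the causal effect excluding each SNP in turn."""
    if panel.n_snps < 3:
        raise DataError("leave-one-out needs at least 3 instruments")
    entries = tuple(
        (snp, estimator(panel.subset(exclude=[snp]))) for snp in panel.snp_ids
    )
    return LooResult(entries=entries, full_panel_estimate=estimator(panel))


def _loo_ivw_slopes(bx: np.ndarray, by: np.ndarray, sy2: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW slope excluding each SNP, vectorized.

    Supports a trailing batch: ``bx``/``by`` may be (n,) or (n_sim, n).
    """
    s1 = np.sum(bx * by / sy2, axis=-1, keepdims=True)
    s2 = np.sum(bx**2 / sy2, axis=-1, keepdims=True)
    return (s1 - bx * by / sy2) / (s2 - bx**2 / sy2)


def mr_presso(
    panel: InstrumentPanel,
    n_sim: int = 5000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global pleiotropy and per-SNP outlier test.

    The observed statistic is the inverse-variance-weighted residual sum of
    squares ``RSS = sum_i (b_out_i - beta_{-i} b_exp_i)^2 / se_out_i^2``
    with ``beta_{-i}`` the leave-one-out fixed-effect IVW slope. Its null
    distribution comes from ``n_sim`` parametric simulations of the
    no-pleiotropy model (``b_exp_i* ~ N(b_exp_i, se_exp_i)``,
    ``b_out_i* ~ N(beta_{-i} b_exp_i, se_out_i)``), re-deriving the
    leave-one-out slopes within each simulation. Monte-Carlo p-values are
    floored at ``1/(n_sim+1)`` and never 0; per-SNP outlier p-values
    (invariant to the residual weighting, which is a per-SNP constant) are
    Bonferroni-adjusted across the panel. When outliers are flagged, the
    distortion test compares the IVW estimate with and without them by a
    two-estimate Cochran Q.
    """
    n = panel.n_snps
    if n < 4:
        raise DataError("MR-PRESSO needs at least 4 instruments")
    if n_sim < 100:
        raise ConfigError("n_sim below 100 gives too coarse a p-value resolution")
    bx, sx = panel.beta_exposure, panel.se_exposure
    by, sy = panel.beta_outcome, panel.se_outcome
    sy2 = sy**2

    beta_loo = _loo_ivw_slopes(bx, by, sy2)
    resid2_obs = (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(resid2_obs / sy2))

    rng = np.random.default_rng(seed)
    bx_sim = bx + sx * rng.standard_normal((n_sim, n))
    by_sim = beta_loo * bx + sy * rng.standard_normal((n_sim, n))
    beta_loo_sim = _loo_ivw_slopes(bx_sim, by_sim, sy2)
    resid2_sim = (by_sim - beta_loo_sim * bx_sim) ** 2
    rss_sim = np.sum(resid2_sim / sy2, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    per_snp_raw = (1 + np.sum(resid2_sim >= resid2_obs, axis=0)) / (n_sim + 1)
    per_snp_adj = np.minimum(1.0, per_snp_raw * n)
    per_snp = dict(zip(panel.snp_ids, per_snp_adj.astype(float)))
    outliers = tuple(s for s, p in per_snp.items() if p < outlier_alpha)

    distortion_p = None
    if outliers and len(outliers) < n - 1:
        full = ivw(panel, variance_model="fixed")
        pruned = ivw(panel.subset(exclude=outliers), variance_model="fixed")
        distortion_p = compare_estimates_q(full, pruned).p_value
    return PressoResult(
        rss_observed=rss_obs,
        global_p=global_p,
        per_snp_outlier_p=per_snp,
        outliers=outliers,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


def compare_estimates_q(a: MREstimate, b: MREstimate) -> HeterogeneityResult:
    """Cochran Q comparing two estimates: ``(ba-bb)^2/(se_a^2+se_b^2)``, 1 df.

    Used to compare the MR estimate against an external estimate on the same
    scale (e.g. an observational meta-analysis log odds ratio).
    """
    if a.convention != b.convention:
        raise DataError(
            f"cannot compare estimates under different sign conventions "
            f"({a.convention} vs {b.convention})"
        )
    q = (a.beta - b.beta) ** 2 / (a.se**2 + b.se**2)
    p = min(max(float(stats.chi2.sf(q, 1)), 5e-324), 1.0)
    return HeterogeneityResult(statistic=float(q), df=1, p_value=p,
                               context="estimate_comparison")
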