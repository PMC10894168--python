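"""Two-sample MR estimators and diagnostics.

All estimators consume harmonized exposure/outcome pairs.  Notation:
``g`` = exposure beta, ``G`` = outcome beta, ``sy`` = outcome SE for one
variant.  Wald-ratio SEs use the first-order delta method (exposure
uncertainty ignored — adequate for strong instruments).  The IVW and Egger
estimators use multiplicative random effects with the dispersion floored
at 1, so their SEs never undercut the fixed-effect SE.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import EstimationError
from .gwas_io import HarmonizedPair

Z95 = float(stats.norm.ppf(0.975))

IVW_MRE = "IVW-MRE"
EGGER = "Egger"
WEIGHTED_MEDIAN = "WeightedMedian"
WEIGHTED_MODE = "WeightedMode"
METHODS = (IVW_MRE, EGGER, WEIGHTED_MEDIAN, WEIGHTED_MODE)


@dataclass(frozen=True)
class WaldRatio:
    """Per-variant causal estimate: outcome beta over exposure beta."""

    snp_id: str
    ratio: float
    ratio_se: float

    @property
    def weight(self) -> float:
        return 1.0 / self.ratio_se**2


@dataclass(frozen=True)
class MREstimate:
    """One estimator's result on the log-odds scale, with diagnostics."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    q_stat: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    or_: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None


def _arrays(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    g = np.array([p.exposure_beta for p in pairs], dtype=float)
    sx = np.array([p.exposure_se for p in pairs], dtype=float)
    G = np.array([p.outcome_beta for p in pairs], dtype=float)
    sy = np.array([p.outcome_se for p in pairs], dtype=float)
    if np.any(sy <= 0) or np.any(sx <= 0):
        raise EstimationError("all standard errors must be positive")
    return g, sx, G, sy


def wald_ratios(pairs: Sequence[HarmonizedPair]) -> list[WaldRatio]:
    """Per-variant ratio estimates with delta-method SEs."""
    out = []
    for p in pairs:
        if p.exposure_beta == 0:
            raise EstimationError(
                f"{p.snp_id}: exposure beta is 0; Wald ratio undefined")
        out.append(WaldRatio(
            snp_id=p.snp_id,
            ratio=p.outcome_beta / p.exposure_beta,
            ratio_se=p.outcome_se / abs(p.exposure_beta),
        ))
    return out


def _ivw_fixed(g: np.ndarray, G: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    """Fixed-effect IVW beta and SE (through-origin WLS of G on g, w = 1/sy^2)."""
    w = 1.0 / sy**2
    denom = float(np.sum(w * g**2))
    beta = float(np.sum(w * g * G)) / denom
    return beta, float(np.sqrt(1.0 / denom))


def cochran_q(pairs: Sequence[HarmonizedPair]) -> tuple[float, float]:
    """Heterogeneity of per-variant ratio estimates around the fixed IVW mean."""
    if len(pairs) < 2:
        raise EstimationError("Cochran's Q needs at least 2 instruments")
    g, _, G, sy = _arrays(pairs)
    beta_fixed, _ = _ivw_fixed(g, G, sy)
    ratios = G / g
    weights = (g / sy) ** 2          # = 1 / ratio_se^2
    q = float(np.sum(weights * (ratios - beta_fixed) ** 2))
    q_pval = float(stats.chi2.sf(q, len(pairs) - 1))
    return q, q_pval


def ivw_mre(pairs: Sequence[HarmonizedPair]) -> MREstimate:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    The point estimate is the 1/sy^2-weighted through-origin regression of
    outcome on exposure betas (equivalently, the weighted mean of Wald
    ratios).  The fixed-effect SE is inflated by sqrt(max(1, Q/(J-1)));
    p-values are normal-based.
    """
    if len(pairs) < 2:
        raise EstimationError(
            "IVW needs at least 2 instruments; use wald_ratios for a "
            "single-instrument analysis")
    g, _, G, sy = _arrays(pairs)
    beta, se_fixed = _ivw_fixed(g, G, sy)
    q, q_pval = cochran_q(pairs)
    dispersion = q / (len(pairs) - 1)
    se = se_fixed * float(np.sqrt(max(1.0, dispersion)))
    pval = float(2 * stats.norm.sf(abs(beta) / se))
    return MREstimate(
        method=IVW_MRE,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=max(pval, np.finfo(float).tiny),
        n_snps=len(pairs),
        q_stat=q,
        q_pval=q_pval,
    )


def mr_egger(pairs: Sequence[HarmonizedPair]) -> MREstimate:
    """Egger regression: weighted LS of G on g with an intercept.

    Pairs are oriented so every exposure beta is non-negative before
    fitting.  The intercept estimates directional pleiotropy; SEs carry a
    multiplicative dispersion floored at 1 and p-values use t with J-2 df.
    """
    if len(pairs) < 3:
        raise EstimationError("MR-Egger needs at least 3 instruments")
    g, _, G, sy = _arrays(pairs)
    sign = np.where(g >= 0, 1.0, -1.0)
    x, y, w = sign * g, sign * G, 1.0 / sy**2
    if np.ptp(x) == 0:
        raise EstimationError(
            "MR-Egger needs variation in exposure betas; all oriented "
            "betas are identical")

    sw = np.sqrt(w)
    design = np.column_stack([sw, sw * x])
    coef, _, _, _ = np.linalg.lstsq(design, sw * y, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])

    df = len(pairs) - 2
    resid = y - intercept - slope * x
    rss = float(np.sum(w * resid**2))
    dispersion = rss / df
    cov_unscaled = np.linalg.inv(design.T @ design)
    scale = max(1.0, dispersion)
    se_intercept = float(np.sqrt(cov_unscaled[0, 0] * scale))
    se_slope = float(np.sqrt(cov_unscaled[1, 1] * scale))

    t95 = float(stats.t.ppf(0.975, df))
    p_slope = float(2 * stats.t.sf(abs(slope) / se_slope, df))
    p_intercept = float(2 * stats.t.sf(abs(intercept) / se_intercept, df))
    return MREstimate(
        method=EGGER,
        beta=slope,
        se=se_slope,
        ci_low=slope - t95 * se_slope,
        ci_high=slope + t95 * se_slope,
        pval=max(p_slope, np.finfo(float).tiny),
        n_snps=len(pairs),
        q_stat=rss,
        q_pval=float(stats.chi2.sf(rss, df)),
        egger_intercept=intercept,
        egger_intercept_se=se_intercept,
        egger_intercept_pval=max(p_intercept, np.finfo(float).tiny),
    )


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates.

    Ratios are sorted; the cumulative weight midpoint of the j-th ratio is
    ``(S_{j-1} + w_j/2) / S_total`` and the estimate interpolates ratio
    against midpoint at 0.5.
    """
    order = np.argsort(ratios)
    r, w = np.asarray(ratios, float)[order], np.asarray(weights, float)[order]
    cum = np.cumsum(w)
    midpoints = (cum - w / 2.0) / cum[-1]
    return float(np.interp(0.5, midpoints, r))


def weighted_mode_point(
    ratios: np.ndarray,
    weights: np.ndarray,
    bandwidth_factor: float = 1.0,
    grid_size: int = 4096,
) -> float:
    """Argmax of the weighted Gaussian kernel density of ratio estimates.

    Bandwidth follows a scaled median-absolute-deviation rule,
    ``bandwidth_factor * 0.9 * min(sd, mad) * J^(-1/5)``, with the MAD on
    the normal-consistent scale.
    """
    r = np.asarray(ratios, float)
    w = np.asarray(weights, float)
    w = w / w.sum()
    sd = float(np.std(r, ddof=1)) if len(r) > 1 else 0.0
    mad = float(stats.median_abs_deviation(r, scale="normal"))
    spread = min(x for x in (sd, mad) if x > 0) if max(sd, mad) > 0 else 0.0
    if spread == 0.0:
        return float(r[0])  # all ratios identical
    h = bandwidth_factor * 0.9 * spread * len(r) ** (-0.2)
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, grid_size)
    density = np.sum(
        w[:, None] * stats.norm.pdf((grid[None, :] - r[:, None]) / h), axis=0
    )
    return float(grid[int(np.argmax(density))])


def _bootstrap_se(
    pairs: Sequence[HarmonizedPair],
    point_fn,
    n_boot: int,
    seed: int,
) -> float:
    """Parametric bootstrap: resample betas from their SEs, recompute the point."""
    g, sx, G, sy = _arrays(pairs)
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        g_star = rng.normal(g, sx)
        G_star = rng.normal(G, sy)
        g_star[g_star == 0] = np.finfo(float).tiny
        ratios = G_star / g_star
        weights = (g_star / sy) ** 2
        estimates[b] = point_fn(ratios, weights)
    return float(np.std(estimates, ddof=1))


def _robust_estimate(method: str, point: float, se: float, n_snps: int) -> MREstimate:
    se = max(se, np.finfo(float).tiny)
    pval = float(2 * stats.norm.sf(abs(point) / se))
    return MREstimate(
        method=method,
        beta=point,
        se=se,
        ci_low=point - Z95 * se,
        ci_high=point + Z95 * se,
        pval=max(pval, np.finfo(float).tiny),
        n_snps=n_snps,
    )


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = 2000,
    *,
    seed: int,
) -> MREstimate:
    """Weighted-median estimate; SE by parametric bootstrap (fixed seed)."""
    if len(pairs) < 3:
        raise EstimationError("weighted median needs at least 3 instruments")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ratios = wald_ratios(pairs)
    point = weighted_median_point(
        np.array([r.ratio for r in ratios]),
        np.array([r.weight for r in ratios]),
    )
    se = _bootstrap_se(pairs, weighted_median_point, n_boot, seed)
    return _robust_estimate(WEIGHTED_MEDIAN, point, se, len(pairs))


def weighted_mode(
    pairs: Sequence[HarmonizedPair],
    bandwidth_factor: float = 1.0,
    n_boot: int = 2000,
    *,
    seed: int,
) -> MREstimate:
    """Weighted-mode estimate; SE by parametric bootstrap (fixed seed)."""
    if len(pairs) < 3:
        raise EstimationError("weighted mode needs at least 3 instruments")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ratios = wald_ratios(pairs)
    point = weighted_mode_point(
        np.array([r.ratio for r in ratios]),
        np.array([r.weight for r in ratios]),
        bandwidth_factor,
    )

    def point_fn(r, w):
        return weighted_mode_point(r, w, bandwidth_factor)

    se = _bootstrap_se(pairs, point_fn, n_boot, seed)
    return _robust_estimate(WEIGHTED_MODE, point, se, len(pairs))


def leave_one_out(pairs: Sequence[HarmonizedPair]) -> list[tuple[str, MREstimate]]:
    """IVW-MRE estimate with each instrument omitted in turn, in input order."""
    if len(pairs) < 3:
        raise EstimationError("leave-one-out needs at least 3 instruments")
    out = []
    for i, p in enumerate(pairs):
        subset = list(pairs[:i]) + list(pairs[i + 1:])
        out.append((p.snp_id, ivw_mre(subset)))
    return out


def to_odds_ratio(est: MREstimate) -> MREstimate:
    """Attach exponentiated (odds-ratio scale) effect and CI."""
    return replace(
        est,
        or_=float(np.exp(est.beta)),
        or_ci_low=float(np.exp(est.ci_low)),
        or_ci_high=float(np.exp(est.ci_high)),
    )


def all_estimates(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = 2000,
    bandwidth_factor: float = 1.0,
    *,
    seed: int,
) -> dict[str, MREstimate]:
    """All four estimators on OR scale, keyed by method name."""
    estimates = {
        IVW_MRE: ivw_mre(pairs),
        EGGER: mr_egger(pairs),
        WEIGHTED_MEDIAN: weighted_median(pairs, n_boot, seed=seed),
        WEIGHTED_MODE: weighted_mode(pairs, bandwidth_factor, n_boot, seed=seed + 1),
    }
    return {name: to_odds_ratio(est) for name, est in estimates.items()}
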