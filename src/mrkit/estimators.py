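"""Causal-effect estimators for harmonized two-sample summary data.

All estimators consume per-variant pairs (βxj, σxj, βyj, σyj) and return a
causal effect θ on the scale of the outcome effect per unit exposure effect
(log odds per unit exposure liability for binary traits).

The estimator ladder, ordered by the strength of its identifying
assumptions:

* **Wald/ratio** — per-variant βyj/βxj with first-order delta SE σyj/|βxj|
  (the no-measurement-error approximation: σxj is ignored, which keeps the
  weights and Cochran's Q on the conventional k−1 degrees of freedom).
* **IVW** — the inverse-variance-weighted average of ratio estimates,
  algebraically a weighted regression of βy on βx through the origin.
  Fixed effects assumes every instrument estimates the same θ;
  multiplicative random effects inflates the SE by √(Q/(k−1)) when the
  instruments are over-dispersed (never deflates — the factor is floored
  at 1).
* **MR-Egger** — the same regression with a free intercept; the intercept
  estimates the average directional pleiotropy and its test is the
  standard pleiotropy diagnostic.  Valid under InSIDE (instrument strength
  independent of direct effects).  Inference uses the t distribution with
  k−2 df and multiplicative SE scaling floored at 1.
* **Weighted median** — the 50th weighted percentile of ratio estimates;
  consistent when ≥50% of the weight comes from valid instruments.  Its SE
  comes from a seeded parametric bootstrap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AnalysisError
from .harmonization import HarmonizedDataset

logger = logging.getLogger(__name__)

#: two-sided 95% normal multiplier used for every CI in the package
CI_Z = 1.96


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio with delta-method SE and IVW weight."""

    variant_id: str
    estimate: float
    se: float
    weight: float


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q (and, for Egger fits, the intercept diagnostics)."""

    Q: float
    df: int
    pvalue: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with normal-theory CI and OR-scale view."""

    method: str  # ivw_fe | ivw_mre | egger | weighted_median | presso_*
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int

    @property
    def or_scale(self) -> tuple[float, float, float]:
        return (math.exp(self.theta), math.exp(self.ci_low),
                math.exp(self.ci_high))


def _arrays(data: HarmonizedDataset):
    bx = np.array([p.beta_exposure for p in data.pairs], dtype=float)
    sx = np.array([p.se_exposure for p in data.pairs], dtype=float)
    by = np.array([p.beta_outcome for p in data.pairs], dtype=float)
    sy = np.array([p.se_outcome for p in data.pairs], dtype=float)
    return bx, sx, by, sy


def _estimate(method: str, theta: float, se: float, pvalue: float,
              k: int) -> MREstimate:
    return MREstimate(method=method, theta=theta, se=se,
                      ci_low=theta - CI_Z * se, ci_high=theta + CI_Z * se,
                      pvalue=pvalue, n_snps=k)


def ratio_estimates(data: HarmonizedDataset) -> list[RatioEstimate]:
    """Per-variant Wald ratios βyj/βxj with SE σyj/|βxj|.

    Raises :class:`AnalysisError` naming the variant if any βxj is 0.
    """
    out = []
    for p in data.pairs:
        if p.beta_exposure == 0:
            raise AnalysisError(
                f"zero exposure effect for {p.variant_id}: ratio undefined")
        se = p.se_outcome / abs(p.beta_exposure)
        out.append(RatioEstimate(variant_id=p.variant_id,
                                 estimate=p.beta_outcome / p.beta_exposure,
                                 se=se, weight=se ** -2))
    return out


def ivw_from_arrays(bx: np.ndarray, by: np.ndarray, sy: np.ndarray,
                    model: str = "multiplicative_random"
                    ) -> tuple[float, float, float, float]:
    """Core IVW on raw arrays: returns (theta, se, Q, pvalue).

    Equivalent to the ratio-estimate form: with wj = (βxj/σyj)² and
    β̂j = βyj/βxj, θ̂ = Σwjβ̂j/Σwj = Σ(βxβy/σy²)/Σ(βx²/σy²), i.e. weighted
    least squares of βy on βx through the origin with weights σy⁻².
    """
    w = (bx / sy) ** 2
    ratios = by / bx
    sw = w.sum()
    theta = float((w * ratios).sum() / sw)
    se_fe = float(sw ** -0.5)
    k = bx.size
    Q = float((w * (ratios - theta) ** 2).sum())
    if model == "fixed" or k < 2:
        se = se_fe
    elif model == "multiplicative_random":
        se = se_fe * max(1.0, math.sqrt(Q / (k - 1)))
    else:
        raise ValueError(f"unknown IVW model {model!r}")
    pvalue = 2 * stats.norm.sf(abs(theta) / se) if se > 0 else float("nan")
    return theta, se, Q, float(pvalue)


def ivw(data: HarmonizedDataset,
        model: str = "multiplicative_random"
        ) -> tuple[MREstimate, HeterogeneityResult | None]:
    """Inverse-variance-weighted estimate with Cochran's Q.

    ``model`` is ``"fixed"`` or ``"multiplicative_random"``.  With a single
    instrument the estimate degenerates to its Wald ratio and no
    heterogeneity result is returned.
    """
    k = len(data.pairs)
    if k < 1:
        raise AnalysisError("IVW requires at least one instrument")
    ratio_estimates(data)  # validates beta_exposure != 0
    bx, _, by, sy = _arrays(data)
    theta, se, Q, pvalue = ivw_from_arrays(bx, by, sy, model=model)
    label = "ivw_fe" if model == "fixed" else "ivw_mre"
    est = _estimate(label, theta, se, pvalue, k)
    if k < 2:
        return est, None
    het = HeterogeneityResult(Q=Q, df=k - 1,
                              pvalue=float(stats.chi2.sf(Q, k - 1)))
    return est, het


def egger_from_arrays(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Weighted Egger regression on raw arrays.

    Orients to βx ≥ 0 first (the intercept is only meaningful on that
    orientation), then solves the weighted normal equations for
    βy = a + θβx.  Returns (slope, slope_se, intercept, intercept_se,
    rss_w, scale) where ``scale`` = max(1, √(rss_w/(k−2))) has already been
    applied to both SEs.
    """
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = sy ** -2.0
    k = x.size
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (x - mx) ** 2).sum()
    sxy = (w * (x - mx) * (y - my)).sum()
    slope = sxy / sxx
    intercept = my - slope * mx
    resid = y - intercept - slope * x
    rss_w = float((w * resid ** 2).sum())
    scale = max(1.0, math.sqrt(rss_w / (k - 2)))
    slope_se = scale / math.sqrt(sxx)
    intercept_se = scale * math.sqrt(1.0 / sw + mx ** 2 / sxx)
    return (float(slope), float(slope_se), float(intercept),
            float(intercept_se), rss_w, scale)


def egger(data: HarmonizedDataset
          ) -> tuple[MREstimate, HeterogeneityResult]:
    """MR-Egger regression: slope estimate plus intercept pleiotropy test.

    Requires at least 3 instruments.  P-values use the t distribution with
    k−2 df; the heterogeneity result carries the weighted residual sum of
    squares as Q with k−2 df and the intercept diagnostics.
    """
    k = len(data.pairs)
    if k < 3:
        raise AnalysisError(f"MR-Egger requires >= 3 instruments, got {k}")
    bx, _, by, sy = _arrays(data)
    slope, slope_se, intercept, intercept_se, rss_w, _ = \
        egger_from_arrays(bx, by, sy)
    df = k - 2
    slope_p = float(2 * stats.t.sf(abs(slope) / slope_se, df))
    intercept_p = float(2 * stats.t.sf(abs(intercept) / intercept_se, df))
    est = _estimate("egger", slope, slope_se, slope_p, k)
    het = HeterogeneityResult(
        Q=rss_w, df=df, pvalue=float(stats.chi2.sf(rss_w, df)),
        egger_intercept=intercept, egger_intercept_se=intercept_se,
        egger_intercept_p=intercept_p)
    return est, het


def weighted_median_from_arrays(ratios: np.ndarray,
                                weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of cumulative weight midpoints.

    Order the ratio estimates ascending; with normalized weights w'j the
    j-th order statistic sits at cumulative midpoint sj = Σ_{i<=j} w'i −
    w'j/2; the estimate interpolates the ordered ratios at s = 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def weighted_median(data: HarmonizedDataset,
                    n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Each bootstrap replicate redraws βxj* ~ N(βxj, σxj) and
    βyj* ~ N(βyj, σyj), recomputes the ratio estimates, weights, and the
    weighted median; the SE is the standard deviation of the replicates.
    The bootstrap stream is fully determined by ``seed``.
    """
    k = len(data.pairs)
    if k < 3:
        raise AnalysisError(
            f"weighted median requires >= 3 instruments, got {k}")
    if n_boot < 100:
        raise AnalysisError("n_boot must be >= 100")
    ests = ratio_estimates(data)
    ratios = np.array([e.estimate for e in ests])
    weights = np.array([e.weight for e in ests])
    theta = weighted_median_from_arrays(ratios, weights)

    bx, sx, by, sy = _arrays(data)
    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, k))
    by_star = rng.normal(by, sy, size=(n_boot, k))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        xb = bx_star[b]
        xb = np.where(xb == 0, np.finfo(float).tiny, xb)
        rb = by_star[b] / xb
        wb = (xb / sy) ** 2
        boot[b] = weighted_median_from_arrays(rb, wb)
    se = float(boot.std(ddof=1))
    if se == 0:
        logger.warning("degenerate bootstrap: all weighted-median "
                       "replicates equal; SE is 0")
        pvalue = float("nan")
    else:
        pvalue = float(2 * stats.norm.sf(abs(theta) / se))
    return _estimate("weighted_median", theta, se, pvalue, k)


def or_with_ci(theta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect and its 95% CI to the OR scale."""
    if se <= 0:
        raise AnalysisError("se must be > 0")
    return (math.exp(theta), math.exp(theta - CI_Z * se),
            math.exp(theta + CI_Z * se))


__all__ = [
    "CI_Z",
    "RatioEstimate",
    "HeterogeneityResult",
    "MREstimate",
    "ratio_estimates",
    "ivw",
    "ivw_from_arrays",
    "egger",
    "egger_from_arrays",
    "weighted_median",
    "weighted_median_from_arrays",
    "or_with_ci",
]
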