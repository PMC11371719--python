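"""Causal-effect estimators on a harmonized instrument set.

Implements the Wald ratio, inverse-variance-weighted (IVW) regression with
the intercept restricted to zero, MR-Egger regression with a free intercept,
and the interpolated weighted-median estimator, all with odds-ratio
reporting.  IVW and Egger are closed-form weighted least squares with
weights 1/se_out²; Egger applies a multiplicative over-dispersion scale
max(1, sqrt(Q'/(n−2))) and t-based inference with n−2 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateDesignError, NotEstimableError, ValidationError
from .harmonize import HarmonizedInstrument

__all__ = [
    "MREstimate",
    "EggerFit",
    "Z_975",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "to_odds_ratio",
]

#: Normal 97.5th percentile used for all Wald-type confidence intervals.
Z_975 = 1.959964

MODEL_FIXED = "fixed"
MODEL_RANDOM = "multiplicative_random"

METHOD_MIN_NSNP = {"Wald": 1, "IVW": 1, "MR-Egger": 3, "WME": 3}


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds scale plus OR reporting."""

    method: str
    theta: float
    se: float
    pval: float
    nsnp: int
    or_: float = field(default=math.nan)
    ci_low: float = field(default=math.nan)
    ci_high: float = field(default=math.nan)
    model: Optional[str] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError(f"{self.method}: se must be > 0, got {self.se}")
        if math.isnan(self.or_):
            or_, lo, hi = to_odds_ratio(self.theta, self.se)
            object.__setattr__(self, "or_", or_)
            object.__setattr__(self, "ci_low", lo)
            object.__setattr__(self, "ci_high", hi)


@dataclass(frozen=True)
class EggerFit:
    """MR-Egger slope (causal effect) and intercept (directional pleiotropy)."""

    slope: float
    slope_se: float
    slope_pval: float
    intercept: float
    intercept_se: float
    intercept_pval: float
    nsnp: int
    df: int
    scale: float  # over-dispersion multiplier applied to both SEs


def _arrays(insts: Sequence[HarmonizedInstrument]) -> tuple[np.ndarray, ...]:
    bx = np.array([h.beta_exp for h in insts], dtype=float)
    by = np.array([h.beta_out for h in insts], dtype=float)
    sx = np.array([h.se_exp for h in insts], dtype=float)
    sy = np.array([h.se_out for h in insts], dtype=float)
    return bx, by, sx, sy


def to_odds_ratio(theta: float, se: float) -> tuple[float, float, float]:
    """(exp(theta), exp(theta − z·se), exp(theta + z·se)) with z = 1.959964."""
    if se <= 0:
        raise ValidationError(f"se must be > 0, got {se}")
    return math.exp(theta), math.exp(theta - Z_975 * se), math.exp(theta + Z_975 * se)


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-SNP ratio estimate with first-order delta-method SE."""
    if inst.beta_exp == 0:
        raise DegenerateDesignError(f"{inst.snp_id}: beta_exp = 0, Wald ratio undefined")
    theta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    pval = 2.0 * stats.norm.sf(abs(theta / se))
    return MREstimate(method="Wald", theta=theta, se=se, pval=max(pval, 5e-324), nsnp=1)


def ivw(
    insts: Sequence[HarmonizedInstrument],
    model: str = MODEL_RANDOM,
) -> MREstimate:
    """Inverse-variance-weighted estimate: zero-intercept WLS of beta_out on
    beta_exp with weights 1/se_out².

    ``model="fixed"`` uses se = 1/sqrt(Σ w·βX²); ``"multiplicative_random"``
    scales it by max(1, sqrt(Q/(n−1))).  A single instrument degenerates to
    the Wald ratio (returned with a note).
    """
    if model not in (MODEL_FIXED, MODEL_RANDOM):
        raise ValidationError(f"unknown IVW model {model!r}")
    n = len(insts)
    if n == 0:
        raise NotEstimableError("IVW requires at least 1 instrument")
    if n == 1:
        w = wald_ratio(insts[0])
        return MREstimate(
            method="IVW", theta=w.theta, se=w.se, pval=w.pval, nsnp=1,
            model=model, note="single instrument: Wald ratio",
        )
    bx, by, _, sy = _arrays(insts)
    if np.all(bx == 0):
        raise DegenerateDesignError("all exposure effects are zero")
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    theta = float(np.sum(w * bx * by)) / sxx
    se = 1.0 / math.sqrt(sxx)
    if model == MODEL_RANDOM:
        q = float(np.sum(w * (by - theta * bx) ** 2))
        se *= max(1.0, math.sqrt(q / (n - 1)))
    pval = 2.0 * stats.norm.sf(abs(theta / se))
    return MREstimate(
        method="IVW", theta=theta, se=se, pval=max(pval, 5e-324), nsnp=n, model=model
    )


def mr_egger(insts: Sequence[HarmonizedInstrument]) -> tuple[MREstimate, EggerFit]:
    """MR-Egger: WLS of beta_out on beta_exp with a free intercept.

    Instruments are first oriented so beta_exp >= 0 (outcome signs flipped
    with them).  The slope is the causal estimate; the intercept estimates
    average directional pleiotropy.  Inference uses a t distribution with
    n−2 df and multiplicative over-dispersion max(1, sqrt(Q'/(n−2))).
    """
    n = len(insts)
    if n < 3:
        raise NotEstimableError(f"MR-Egger requires >= 3 instruments, got {n}")
    bx, by, _, sy = _arrays(insts)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign

    if np.ptp(bx) == 0:
        raise DegenerateDesignError("zero spread in exposure effects; Egger slope undefined")

    w = 1.0 / sy**2
    sw = float(np.sum(w))
    swx = float(np.sum(w * bx))
    swxx = float(np.sum(w * bx * bx))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swxx - swx**2
    if det <= 0:
        raise DegenerateDesignError("singular Egger design")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det

    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    df = n - 2
    scale = max(1.0, math.sqrt(q / df))
    slope_se = math.sqrt(sw / det) * scale
    intercept_se = math.sqrt(swxx / det) * scale
    slope_pval = 2.0 * stats.t.sf(abs(slope / slope_se), df)
    intercept_pval = 2.0 * stats.t.sf(abs(intercept / intercept_se), df)

    fit = EggerFit(
        slope=slope,
        slope_se=slope_se,
        slope_pval=max(slope_pval, 5e-324),
        intercept=intercept,
        intercept_se=intercept_se,
        intercept_pval=max(intercept_pval, 5e-324),
        nsnp=n,
        df=df,
        scale=scale,
    )
    est = MREstimate(
        method="MR-Egger", theta=slope, se=slope_se, pval=fit.slope_pval, nsnp=n
    )
    return est, fit


def interpolated_weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Linear interpolation of sorted ``values`` at cumulative weight 0.5,
    using cumulative weight minus half the item's own weight as abscissa."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, v))


def weighted_median(
    insts: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MREstimate:
    """Weighted-median estimate of per-SNP ratios.

    Weights are βX²/se_out² (the inverse variance of each Wald ratio),
    normalized to sum to one.  The SE comes from a parametric bootstrap:
    βX and βY are resampled from normal(β, se) ``n_boot`` times with a
    fixed ``seed`` and the estimator recomputed.
    """
    n = len(insts)
    if n < 3:
        raise NotEstimableError(f"weighted median requires >= 3 instruments, got {n}")
    bx, by, sx, sy = _arrays(insts)
    if np.any(bx == 0):
        raise DegenerateDesignError("beta_exp = 0 instrument: ratio undefined")
    ratios = by / bx
    weights = bx**2 / sy**2
    theta = interpolated_weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, n))
    by_star = rng.normal(by, sy, size=(n_boot, n))
    bx_star = np.where(bx_star == 0, np.finfo(float).tiny, bx_star)
    r_star = by_star / bx_star
    w_star = bx_star**2 / sy**2

    order = np.argsort(r_star, axis=1, kind="stable")
    r_sorted = np.take_along_axis(r_star, order, axis=1)
    w_sorted = np.take_along_axis(w_star, order, axis=1)
    w_sorted = w_sorted / w_sorted.sum(axis=1, keepdims=True)
    cum = np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted
    boots = np.empty(n_boot)
    for i in range(n_boot):  # np.interp is 1-D; loop is cheap at desk scale
        boots[i] = np.interp(0.5, cum[i], r_sorted[i])
    se = float(np.std(boots, ddof=1))
    if se <= 0:
        se = np.finfo(float).tiny
    pval = 2.0 * stats.norm.sf(abs(theta / se))
    return MREstimate(
        method="WME", theta=theta, se=se, pval=max(pval, 5e-324), nsnp=n
    )
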