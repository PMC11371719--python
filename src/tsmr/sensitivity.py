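"""Heterogeneity, pleiotropy, influence, and outlier diagnostics.

Cochran's Q against the fitted IVW or Egger line, the Egger-intercept
pleiotropy test, leave-one-out IVW re-estimation, and a simulation-based
residual-sum outlier procedure (global test, per-SNP outlier test with
Bonferroni correction, distortion test, and an outlier-corrected IVW).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .estimators import (
    MODEL_FIXED,
    MODEL_RANDOM,
    EggerFit,
    MREstimate,
    ivw,
)
from .exceptions import NotEstimableError
from .harmonize import HarmonizedInstrument

__all__ = [
    "HeterogeneityResult",
    "PleiotropyTest",
    "LeaveOneOutSeries",
    "PressoResult",
    "cochran_q",
    "egger_intercept_test",
    "leave_one_out",
    "mr_presso",
]

HETEROGENEITY_P_RULE = 0.05  # p > 0.05 => "no heterogeneity" verdict


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str  # "IVW" or "MR-Egger"
    q: float
    df: int
    pval: float

    @property
    def no_heterogeneity(self) -> bool:
        return self.pval > HETEROGENEITY_P_RULE


@dataclass(frozen=True)
class PleiotropyTest:
    intercept: float
    se: float
    pval: float

    @property
    def no_pleiotropy(self) -> bool:
        return self.pval > HETEROGENEITY_P_RULE


@dataclass
class LeaveOneOutSeries:
    """IVW re-estimated with each SNP dropped in turn, plus the full-set fit."""

    full: MREstimate
    estimates: dict[str, MREstimate] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.estimates)

    def most_influential(self) -> str:
        """snp_id whose exclusion moves theta farthest from the full estimate."""
        return max(
            self.estimates, key=lambda s: abs(self.estimates[s].theta - self.full.theta)
        )


@dataclass
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_pvals: dict[str, float]  # Bonferroni-adjusted per-SNP p-values
    outliers: set[str]
    distortion_pval: Optional[float]
    corrected: Optional[MREstimate]
    n_sim: int
    seed: Optional[int]


def cochran_q(
    insts: Sequence[HarmonizedInstrument],
    fit: Union[MREstimate, EggerFit],
) -> HeterogeneityResult:
    """Q = Σ wⱼ(βYⱼ − ŷⱼ)² with w = 1/se_out²; chi-square p.

    ``fit`` may be an IVW/Wald :class:`MREstimate` (ŷ = θ·βX, df = n−1) or an
    :class:`EggerFit` (ŷ = intercept + slope·|βX| on the oriented data,
    df = n−2).
    """
    n = len(insts)
    bx = np.array([h.beta_exp for h in insts], dtype=float)
    by = np.array([h.beta_out for h in insts], dtype=float)
    w = 1.0 / np.array([h.se_out for h in insts], dtype=float) ** 2
    if isinstance(fit, EggerFit):
        if n < 3:
            raise NotEstimableError("Egger Q requires >= 3 instruments")
        sign = np.where(bx < 0, -1.0, 1.0)
        pred = fit.intercept + fit.slope * (bx * sign)
        resid = by * sign - pred
        df = n - 2
        method = "MR-Egger"
    else:
        if n < 2:
            raise NotEstimableError("IVW Q requires >= 2 instruments")
        resid = by - fit.theta * bx
        df = n - 1
        method = "IVW"
    q = float(np.sum(w * resid**2))
    pval = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(method=method, q=q, df=df, pval=pval)


def egger_intercept_test(fit: EggerFit) -> PleiotropyTest:
    """Two-sided t test of intercept = 0 with nsnp − 2 df (from the fit)."""
    return PleiotropyTest(intercept=fit.intercept, se=fit.intercept_se, pval=fit.intercept_pval)


def leave_one_out(
    insts: Sequence[HarmonizedInstrument], model: str = MODEL_RANDOM
) -> LeaveOneOutSeries:
    """IVW re-estimated nsnp times, each run excluding one SNP."""
    n = len(insts)
    if n < 3:
        raise NotEstimableError(f"leave-one-out requires >= 3 instruments, got {n}")
    series = LeaveOneOutSeries(full=ivw(insts, model=model))
    for i, h in enumerate(insts):
        rest = [g for j, g in enumerate(insts) if j != i]
        series.estimates[h.snp_id] = ivw(rest, model=model)
    return series


def _loo_thetas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW thetas, vectorized via sums."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    insts: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: Optional[int] = None,
    model: str = MODEL_RANDOM,
) -> PressoResult:
    """Residual-sum outlier procedure on the IVW regression.

    Global test: observed weighted RSS uses each SNP's leave-one-out IVW
    prediction; the null distribution is built by drawing
    βY*ⱼ ~ normal(θ̂₋ⱼ·βXⱼ, se_outⱼ) and recomputing the leave-one-out RSS
    per replicate; p = (1 + #{RSS* ≥ RSS}) / (n_sim + 1).  Outlier test:
    per-SNP observed weighted squared residual against its simulated
    distribution, Bonferroni-adjusted by nsnp.  Distortion test: the relative
    change in θ̂ after removing outliers, compared with removals of random
    subsets of the same size.  ``corrected`` is IVW on the non-outlier set
    (present iff outliers were found).
    """
    n = len(insts)
    if n < 4:
        raise NotEstimableError(f"MR-PRESSO requires >= 4 instruments, got {n}")
    if n_sim < 100:
        warnings.warn(f"n_sim = {n_sim} < 100: p-value resolution is poor", stacklevel=2)

    bx = np.array([h.beta_exp for h in insts], dtype=float)
    by = np.array([h.beta_out for h in insts], dtype=float)
    sy = np.array([h.se_out for h in insts], dtype=float)
    w = 1.0 / sy**2
    ids = [h.snp_id for h in insts]

    theta_loo = _loo_thetas(bx, by, w)
    obs_sq = w * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(obs_sq))

    rng = np.random.default_rng(seed)
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, n))
    sxy_star = by_star * (w * bx)  # per-element contributions
    sxy_tot = sxy_star.sum(axis=1, keepdims=True)
    sxx = float(np.sum(w * bx * bx))
    theta_loo_star = (sxy_tot - sxy_star) / (sxx - w * bx * bx)
    sim_sq = w * (by_star - theta_loo_star * bx) ** 2
    rss_star = sim_sq.sum(axis=1)

    global_pval = (1.0 + float(np.sum(rss_star >= rss_obs))) / (n_sim + 1.0)

    raw_p = (1.0 + np.sum(sim_sq >= obs_sq[None, :], axis=0)) / (n_sim + 1.0)
    adj_p = np.minimum(1.0, raw_p * n)
    outlier_mask = adj_p < outlier_alpha
    outliers = {ids[i] for i in np.flatnonzero(outlier_mask)}
    outlier_pvals = {ids[i]: float(adj_p[i]) for i in range(n)}

    distortion_pval: Optional[float] = None
    corrected: Optional[MREstimate] = None
    if outliers:
        keep = [h for h in insts if h.snp_id not in outliers]
        if len(keep) >= 1:
            corrected = ivw(keep, model=model)
            theta_all = ivw(insts, model=MODEL_FIXED).theta
            if corrected.theta != 0:
                d_obs = (theta_all - corrected.theta) / abs(corrected.theta)
                k = len(outliers)
                if n - k >= 2:
                    d_null = np.empty(n_sim)
                    sxy = np.sum(w * bx * by)
                    for b in range(n_sim):
                        drop = rng.choice(n, size=k, replace=False)
                        t_sub = (sxy - np.sum(w[drop] * bx[drop] * by[drop])) / (
                            sxx - np.sum(w[drop] * bx[drop] ** 2)
                        )
                        d_null[b] = (theta_all - t_sub) / abs(t_sub) if t_sub != 0 else np.inf
                    distortion_pval = (1.0 + float(np.sum(np.abs(d_null) >= abs(d_obs)))) / (
                        n_sim + 1.0
                    )

    return PressoResult(
        global_rss=rss_obs,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        distortion_pval=distortion_pval,
        corrected=corrected,
        n_sim=n_sim,
        seed=seed,
    )
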