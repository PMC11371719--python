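"""Independent oracles used to cross-check the estimators.

These are deliberately written against the generic mathematical definitions
(lstsq on a scaled design, explicit summation, explicit interpolation) and
never call the package's own closed forms.
"""

from __future__ import annotations

import numpy as np


def wls_oracle(x: np.ndarray, y: np.ndarray, w: np.ndarray, intercept: bool):
    """Generic weighted least squares via lstsq on the sqrt(w)-scaled design.

    Returns (coefs, cov) where cov = (X'WX)^-1 (no dispersion scaling);
    coefs is [slope] without intercept, [intercept, slope] with.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if intercept:
        design = np.column_stack([np.ones_like(x), x])
    else:
        design = x[:, None]
    sw = np.sqrt(w)
    coefs, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    cov = np.linalg.inv(design.T @ (design * w[:, None]))
    return coefs, cov


def weighted_median_oracle(values, weights) -> float:
    """Interpolated weighted median, written as an explicit scan."""
    pairs = sorted(zip(values, weights), key=lambda p: p[0])
    total = sum(w for _, w in pairs)
    cum = 0.0
    xs, ps = [], []
    for v, w in pairs:
        ps.append((cum + w / 2.0) / total)
        xs.append(v)
        cum += w
    if 0.5 <= ps[0]:
        return xs[0]
    for i in range(1, len(xs)):
        if ps[i] >= 0.5:
            frac = (0.5 - ps[i - 1]) / (ps[i] - ps[i - 1])
            return xs[i - 1] + frac * (xs[i] - xs[i - 1])
    return xs[-1]


def cochran_q_oracle(bx, by, sy, predict) -> float:
    """Q = sum over SNPs of (by_j - predict(bx_j))^2 / sy_j^2, term by term."""
    q = 0.0
    for bxj, byj, syj in zip(bx, by, sy):
        q += (byj - predict(bxj)) ** 2 / syj**2
    return q
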