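"""Synthetic GWAS summary-statistic generator with known ground truth.

Produces matched exposure/outcome association tables for a two-sample
design: true instrument effects, an optional pleiotropy regime (balanced or
directional, with an optional violation of the independence between
pleiotropy and instrument strength), injected outliers, and observation
noise drawn independently for the two samples.  Standard errors follow the
usual GWAS approximations — 1/sqrt(n·v) for a quantitative trait and
1/sqrt(n·v·cp·(1−cp)) for a binary trait on the log-odds scale, with
v = 2·maf·(1−maf) and cp the case fraction — so a handful of cases against
two hundred thousand controls yields the very large outcome SEs the
estimators must tolerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError
from .instruments import LDMatrix
from .summary_stats import AssociationTable, StudyMeta, VariantAssociation

__all__ = ["SimulationTruth", "simulate_pair", "simulate_ld"]

PLEIOTROPY_REGIMES = ("none", "balanced", "directional")

#: Coupling between pleiotropy and instrument strength when the independence
#: assumption is deliberately violated: alpha_j += INSIDE_COUPLING * beta_x_j.
INSIDE_COUPLING = 0.3

_NON_PALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters of one synthetic exposure/outcome pair."""

    theta_true: float
    n_instruments: int
    seed: int
    n_exp: int = 18_340
    n_out: int = 213_353
    n_cases: int = 208
    beta_exp_mean: float = 0.15
    beta_exp_sd: float = 0.05
    pleiotropy: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violated: bool = False
    n_outliers: int = 0
    outlier_multiplier: float = 1.0
    maf_low: float = 0.1
    maf_high: float = 0.5
    palindromic_fraction: float = 0.0
    exposure_name: str = "synthetic_exposure"
    outcome_name: str = "synthetic_outcome"

    def __post_init__(self) -> None:
        if self.n_instruments < 1:
            raise ConfigurationError("n_instruments must be >= 1")
        if self.pleiotropy not in PLEIOTROPY_REGIMES:
            raise ConfigurationError(f"pleiotropy must be one of {PLEIOTROPY_REGIMES}")
        if self.pleiotropy_sd < 0 or self.beta_exp_sd < 0:
            raise ConfigurationError("sd parameters must be >= 0")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigurationError("maf range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.n_outliers <= self.n_instruments):
            raise ConfigurationError("n_outliers must be in [0, n_instruments]")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise ConfigurationError("palindromic_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, 5e-324, 1.0)


def simulate_pair(
    truth: SimulationTruth,
) -> tuple[AssociationTable, AssociationTable, SimulationTruth]:
    """Generate one matched exposure/outcome summary-statistic pair.

    Per instrument j: draw maf ~ U(maf_low, maf_high) and a true exposure
    effect from normal(beta_exp_mean, beta_exp_sd); draw a pleiotropy term
    per the configured regime; set the true outcome effect to
    theta·betaX + alpha (scaled by ``outlier_multiplier`` for the randomly
    chosen outlier SNPs); then draw observed effects from
    normal(true, se) independently for the two samples, with p-values from
    the normal approximation.  Alleles are assigned randomly, a configurable
    fraction palindromic, identically oriented in both tables.
    """
    rng = np.random.default_rng(truth.seed)
    m = truth.n_instruments

    maf = rng.uniform(truth.maf_low, truth.maf_high, size=m)
    bx_true = rng.normal(truth.beta_exp_mean, truth.beta_exp_sd, size=m)

    if truth.pleiotropy == "none":
        alpha = np.zeros(m)
    elif truth.pleiotropy == "balanced":
        alpha = rng.normal(0.0, truth.pleiotropy_sd, size=m)
    else:  # directional
        alpha = rng.normal(truth.pleiotropy_mean, truth.pleiotropy_sd, size=m)
    if truth.inside_violated:
        alpha = alpha + INSIDE_COUPLING * bx_true

    # Standard-normal noise and allele draws happen before outlier injection so
    # matched replicates with/without outliers share every other draw.
    zx = rng.standard_normal(m)
    zy = rng.standard_normal(m)
    is_palindromic = rng.random(m) < truth.palindromic_fraction
    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    nonpal_choice = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=m)

    by_true = truth.theta_true * bx_true + alpha
    if truth.n_outliers > 0:
        outlier_idx = rng.choice(m, size=truth.n_outliers, replace=False)
        by_true[outlier_idx] = by_true[outlier_idx] * truth.outlier_multiplier

    v = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(truth.n_exp * v)
    cp = truth.n_cases / truth.n_out
    se_y = 1.0 / np.sqrt(truth.n_out * v * cp * (1.0 - cp))

    bx_obs = bx_true + zx * se_x
    by_obs = by_true + zy * se_y
    px = _pvals(bx_obs, se_x)
    py = _pvals(by_obs, se_y)

    exp_records, out_records = [], []
    for j in range(m):
        if is_palindromic[j]:
            ea, oa = _PALINDROMIC_PAIRS[pal_choice[j]]
        else:
            ea, oa = _NON_PALINDROMIC_PAIRS[nonpal_choice[j]]
        snp = f"rs{j + 1}"
        exp_records.append(
            VariantAssociation(
                snp_id=snp, effect_allele=ea, other_allele=oa, eaf=float(maf[j]),
                beta=float(bx_obs[j]), se=float(se_x[j]), pval=float(px[j]), n=truth.n_exp,
            )
        )
        out_records.append(
            VariantAssociation(
                snp_id=snp, effect_allele=ea, other_allele=oa, eaf=float(maf[j]),
                beta=float(by_obs[j]), se=float(se_y[j]), pval=float(py[j]), n=truth.n_out,
            )
        )

    exp_meta = StudyMeta(
        trait_name=truth.exposure_name, trait_type="continuous", n_total=truth.n_exp
    )
    out_meta = StudyMeta(
        trait_name=truth.outcome_name,
        trait_type="binary",
        n_total=truth.n_out,
        n_cases=truth.n_cases,
        n_controls=truth.n_out - truth.n_cases,
    )
    exposure = AssociationTable(meta=exp_meta, records=exp_records)
    outcome = AssociationTable(meta=out_meta, records=out_records)
    return exposure, outcome, truth


def simulate_ld(
    n_snps: int,
    block_size: int,
    within_r2: float,
    seed: int = 0,
    snp_ids: Optional[list[str]] = None,
) -> LDMatrix:
    """Block-diagonal r² matrix: ``within_r2`` inside blocks, 0 between.

    The last block is truncated when ``block_size`` does not divide
    ``n_snps``.  ``seed`` is accepted for interface symmetry; the structure
    is deterministic.
    """
    if not (0.0 <= within_r2 <= 1.0):
        raise ConfigurationError(f"within_r2 must be in [0, 1], got {within_r2}")
    if block_size < 1:
        raise ConfigurationError("block_size must be >= 1")
    ids = snp_ids if snp_ids is not None else [f"rs{i + 1}" for i in range(n_snps)]
    if len(ids) != n_snps:
        raise ConfigurationError("snp_ids length must equal n_snps")
    r2 = np.zeros((n_snps, n_snps))
    for start in range(0, n_snps, block_size):
        stop = min(start + block_size, n_snps)
        r2[start:stop, start:stop] = within_r2
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(snp_ids=list(ids), r2=r2)
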