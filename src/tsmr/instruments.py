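"""Instrument selection: significance filter, LD clumping, confounder
exclusion, and weak-instrument screening via the F-statistic.

The confounder screen is an explicit exclusion list (one snp_id per line,
optional second column with a reason) rather than a live web query, so runs
are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .summary_stats import AssociationTable, VariantAssociation

__all__ = [
    "LDMatrix",
    "InstrumentDiagnostics",
    "filter_by_pvalue",
    "ld_clump",
    "exclude_snps",
    "variance_explained",
    "f_statistic",
    "screen_weak_instruments",
    "read_ld_matrix",
    "read_exclusion_list",
]

logger = logging.getLogger(__name__)

DEFAULT_IV_PVAL = 1e-5
DEFAULT_LD_R2 = 0.001
DEFAULT_CLUMP_WINDOW_KB = 10_000
DEFAULT_F_THRESHOLD = 10.0


@dataclass
class LDMatrix:
    """Squared-correlation (r²) matrix over an ordered SNP list."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValidationError(f"LD matrix shape {self.r2.shape} does not match {n} SNP ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValidationError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValidationError("LD r² values must lie in [0, 1]")
        self._pos = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._pos

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._pos[a], self._pos[b]])


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """Per-SNP instrument-strength report."""

    snp_id: str
    r2_exposure: float
    f_stat: float
    n: int
    k: int


def filter_by_pvalue(table: AssociationTable, threshold: float = DEFAULT_IV_PVAL) -> AssociationTable:
    """Keep rows with ``pval < threshold``; order preserved."""
    if not (0 < threshold <= 1):
        raise ConfigurationError(f"p-value threshold must be in (0, 1], got {threshold}")
    kept = [r for r in table.records if r.pval < threshold]
    logger.info("p-value filter (< %g): kept %d of %d SNPs", threshold, len(kept), len(table))
    return table.replace_records(kept)


def ld_clump(
    candidates: AssociationTable,
    ld: LDMatrix,
    r2_threshold: float = DEFAULT_LD_R2,
    positions: Optional[Mapping[str, tuple[str, int]]] = None,
    window_kb: float = DEFAULT_CLUMP_WINDOW_KB,
) -> AssociationTable:
    """Greedy LD clumping by ascending p-value.

    A candidate is accepted iff its r² with every previously accepted SNP is
    below ``r2_threshold``.  When ``positions`` maps snp_id -> (chrom, bp),
    pairs farther apart than ``window_kb`` (or on different chromosomes) are
    treated as unlinked (r² = 0).  The smallest-p candidate is always kept.
    """
    for rec in candidates.records:
        if rec.snp_id not in ld:
            raise ConfigurationError(f"candidate {rec.snp_id} absent from LD matrix")

    def unlinked_by_distance(a: str, b: str) -> bool:
        if positions is None:
            return False
        ca, pa = positions[a]
        cb, pb = positions[b]
        return ca != cb or abs(pa - pb) > window_kb * 1000

    ranked = sorted(candidates.records, key=lambda r: r.pval)  # stable: ties keep input order
    accepted: list[VariantAssociation] = []
    for rec in ranked:
        independent = all(
            unlinked_by_distance(rec.snp_id, prev.snp_id)
            or ld.r2_between(rec.snp_id, prev.snp_id) < r2_threshold
            for prev in accepted
        )
        if independent:
            accepted.append(rec)
    logger.info(
        "LD clump (r² < %g): kept %d of %d SNPs", r2_threshold, len(accepted), len(candidates)
    )
    return candidates.subset([r.snp_id for r in accepted])


def exclude_snps(
    table: AssociationTable, exclusion_list: Iterable[str], reason: str = "confounder-associated"
) -> AssociationTable:
    """Remove listed SNPs, logging each removal; unknown IDs warn only."""
    listed = set(exclusion_list)
    present = listed & set(table.snp_ids)
    for snp_id in sorted(listed - present):
        logger.warning("exclusion list entry %s not found in table (ignored)", snp_id)
    for snp_id in sorted(present):
        logger.info("excluding %s: %s", snp_id, reason)
    return table.replace_records([r for r in table.records if r.snp_id not in present])


def variance_explained(assoc: VariantAssociation, method: str = "t") -> float:
    """Per-SNP fraction of exposure variance explained.

    ``method="t"`` (default): r² = t²/(t² + n − 2) with t = beta/se — scale
    free and usable when eaf is missing.  ``method="maf"``: the
    2·eaf·(1−eaf)·beta² form for standardized traits (requires eaf).
    """
    if method == "t":
        if assoc.n <= 2:
            raise ValidationError(f"{assoc.snp_id}: need n > 2 for r², got n={assoc.n}")
        t2 = (assoc.beta / assoc.se) ** 2
        return t2 / (t2 + assoc.n - 2)
    if method == "maf":
        if assoc.eaf is None:
            raise ValidationError(f"{assoc.snp_id}: maf-based r² requires eaf")
        return min(2.0 * assoc.eaf * (1.0 - assoc.eaf) * assoc.beta**2, 1.0 - 1e-15)
    raise ConfigurationError(f"unknown r² method {method!r}")


def f_statistic(r2: float, n: int, k: int) -> float:
    """Instrument-strength F = r²·(n − k − 1) / [k·(1 − r²)]."""
    if not (0 <= r2 < 1):
        raise ValidationError(f"r² must be in [0, 1), got {r2}")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise ValidationError(f"need n > k + 1, got n={n}, k={k}")
    return r2 * (n - k - 1) / (k * (1 - r2))


def screen_weak_instruments(
    table: AssociationTable,
    f_threshold: float = DEFAULT_F_THRESHOLD,
    r2_method: str = "t",
) -> tuple[AssociationTable, list[InstrumentDiagnostics]]:
    """Drop SNPs with per-SNP F <= ``f_threshold`` (k = 1 per SNP).

    Returns the surviving table plus diagnostics for every candidate.
    """
    diagnostics: list[InstrumentDiagnostics] = []
    keep: list[str] = []
    for rec in table.records:
        r2 = variance_explained(rec, method=r2_method)
        f = f_statistic(r2, rec.n, 1)
        diagnostics.append(InstrumentDiagnostics(rec.snp_id, r2, f, rec.n, 1))
        if f > f_threshold:
            keep.append(rec.snp_id)
        else:
            logger.info("weak instrument %s removed (F = %.3f <= %g)", rec.snp_id, f, f_threshold)
    return table.subset(keep), diagnostics


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square delimited r² matrix with an ID header row and column."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: LD matrix row/column IDs differ")
    return LDMatrix(snp_ids=[str(s) for s in df.index], r2=df.to_numpy(dtype=float))


def read_exclusion_list(path: str | Path) -> dict[str, str]:
    """Read an exclusion list: one snp_id per line, optional tab-separated reason."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        out[parts[0]] = parts[1] if len(parts) > 1 else "listed"
    return out
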