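"""GWAS summary-statistic data model, readers, writers, and validation.

The canonical on-disk format is a tab-delimited table with columns
``SNP, effect_allele, other_allele, eaf, beta, se, pval, n`` and the
sentinel ``NA`` for a missing effect-allele frequency.  A ``column_map``
lets arbitrary source headers be read into the canonical model.

Only biallelic SNPs (single-base A/C/G/T alleles) are accepted; indels and
multi-allelic records are rejected with a row diagnostic because downstream
allele harmonization is defined only for biallelic variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DuplicateSNPError, ValidationError

__all__ = [
    "VariantAssociation",
    "StudyMeta",
    "AssociationTable",
    "RowDiagnostic",
    "CANONICAL_COLUMNS",
    "read_association_table",
    "write_association_table",
]

VALID_ALLELES = frozenset("ACGT")

#: Canonical column order for on-disk tables.
CANONICAL_COLUMNS = ("SNP", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")

#: A reported p-value more than this many orders of magnitude away from the
#: normal-approximation p implied by |beta/se| triggers a consistency warning.
PVAL_CONSISTENCY_LOG10_TOL = 2.0


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association record in one GWAS.

    ``beta`` is the per-effect-allele estimate: log-odds for binary traits,
    SD units for quantitative traits.  ``eaf`` may be ``None`` (missing).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pval: float
    n: int

    def validate(self) -> list["RowDiagnostic"]:
        """Return hard-invariant violations (empty when the record is valid)."""
        problems: list[RowDiagnostic] = []

        def bad(fieldname: str, message: str) -> None:
            problems.append(RowDiagnostic(self.snp_id, fieldname, message, fatal=True))

        if self.effect_allele not in VALID_ALLELES:
            bad("effect_allele", f"not a biallelic SNP allele: {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            bad("other_allele", f"not a biallelic SNP allele: {self.other_allele!r}")
        if (
            self.effect_allele in VALID_ALLELES
            and self.other_allele in VALID_ALLELES
            and self.effect_allele == self.other_allele
        ):
            bad("other_allele", "effect_allele equals other_allele")
        if not math.isfinite(self.beta):
            bad("beta", "non-finite beta")
        if not (math.isfinite(self.se) and self.se > 0):
            bad("se", f"se must be > 0, got {self.se}")
        if not (math.isfinite(self.pval) and 0 < self.pval <= 1):
            bad("pval", f"pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            bad("eaf", f"eaf must be in [0, 1], got {self.eaf}")
        if self.n < 1:
            bad("n", f"sample size must be >= 1, got {self.n}")
        return problems

    def pval_consistency_warning(self) -> Optional["RowDiagnostic"]:
        """Check the reported p against the normal approximation 2*Phi(-|beta/se|).

        Returns a non-fatal diagnostic when they disagree by more than two
        orders of magnitude; ``None`` otherwise.
        """
        if self.se <= 0 or not math.isfinite(self.beta):
            return None
        z = abs(self.beta / self.se)
        # logsf avoids underflow for large |z|
        log10_expected = (stats.norm.logsf(z) + math.log(2.0)) / math.log(10.0)
        log10_reported = math.log10(self.pval)
        if abs(log10_reported - log10_expected) > PVAL_CONSISTENCY_LOG10_TOL:
            return RowDiagnostic(
                self.snp_id,
                "pval",
                f"reported p={self.pval:.3g} vs normal-approx p=1e{log10_expected:.2f}"
                " (beyond 2 orders of magnitude)",
                fatal=False,
            )
        return None


@dataclass(frozen=True)
class StudyMeta:
    """Study-level metadata for one GWAS."""

    trait_name: str
    trait_type: str  # "binary" or "continuous"
    n_total: int
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValidationError(f"trait_type must be binary|continuous, got {self.trait_type!r}")
        if (
            self.n_cases is not None
            and self.n_controls is not None
            and self.n_cases + self.n_controls != self.n_total
        ):
            raise ValidationError(
                f"n_cases + n_controls = {self.n_cases + self.n_controls} != n_total = {self.n_total}"
            )


@dataclass(frozen=True)
class RowDiagnostic:
    """One validation finding for one input row."""

    snp_id: str
    field: str
    message: str
    fatal: bool = True

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        kind = "ERROR" if self.fatal else "WARNING"
        return f"[{kind}] {self.snp_id}/{self.field}: {self.message}"


@dataclass
class AssociationTable:
    """Ordered collection of :class:`VariantAssociation`, unique by snp_id."""

    meta: StudyMeta
    records: list[VariantAssociation] = field(default_factory=list)
    diagnostics: list[RowDiagnostic] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, VariantAssociation] = {}
        for rec in self.records:
            if rec.snp_id in self._index:
                raise DuplicateSNPError(f"duplicate snp_id: {rec.snp_id}")
            self._index[rec.snp_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> Optional[VariantAssociation]:
        return self._index.get(snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def subset(self, keep: Iterable[str]) -> "AssociationTable":
        """New table with only ``keep`` SNPs, original order preserved."""
        keep_set = set(keep)
        return AssociationTable(
            meta=self.meta,
            records=[r for r in self.records if r.snp_id in keep_set],
        )

    def replace_records(self, records: Sequence[VariantAssociation]) -> "AssociationTable":
        return AssociationTable(meta=self.meta, records=list(records))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "SNP": r.snp_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _parse_float(value, snp_id: str, fieldname: str, diagnostics: list[RowDiagnostic]):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip().upper() in ("", "NA", "NAN", "."):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        diagnostics.append(
            RowDiagnostic(snp_id, fieldname, f"unparseable numeric: {value!r}", fatal=True)
        )
        return math.nan  # sentinel: parse failure, distinct from missing


def read_association_table(
    path: str | Path,
    meta: StudyMeta,
    column_map: Optional[Mapping[str, str]] = None,
) -> AssociationTable:
    """Read a delimited (tab or comma) summary-statistic table.

    ``column_map`` maps canonical field names (``SNP``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``) to the
    source file's column headers; omit it for canonical headers.  Rows that
    violate hard invariants are dropped, each with exactly one or more
    :class:`RowDiagnostic` entries on the returned table; a duplicate
    ``snp_id`` raises :class:`DuplicateSNPError` naming the ID.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    colmap = dict(column_map) if column_map else {c: c for c in CANONICAL_COLUMNS}
    for canonical in CANONICAL_COLUMNS:
        source = colmap.get(canonical, canonical)
        if canonical == "eaf" and source not in raw.columns:
            colmap[canonical] = None  # eaf column optional
            continue
        if source not in raw.columns:
            raise ConfigurationError(
                f"{path}: mapped column {source!r} (for {canonical!r}) not found; "
                f"available: {list(raw.columns)}"
            )
        colmap[canonical] = source

    records: list[VariantAssociation] = []
    diagnostics: list[RowDiagnostic] = []
    seen: set[str] = set()
    for _, row in raw.iterrows():
        snp_id = str(row[colmap["SNP"]]).strip()
        if snp_id in seen:
            raise DuplicateSNPError(f"{path}: duplicate snp_id: {snp_id}")
        seen.add(snp_id)

        row_diags: list[RowDiagnostic] = []
        eaf = None
        if colmap["eaf"] is not None:
            eaf = _parse_float(row[colmap["eaf"]], snp_id, "eaf", row_diags)
        beta = _parse_float(row[colmap["beta"]], snp_id, "beta", row_diags)
        se = _parse_float(row[colmap["se"]], snp_id, "se", row_diags)
        pval = _parse_float(row[colmap["pval"]], snp_id, "pval", row_diags)
        n_raw = _parse_float(row[colmap["n"]], snp_id, "n", row_diags)
        if beta is None or se is None or pval is None or n_raw is None:
            row_diags.append(
                RowDiagnostic(snp_id, "row", "required numeric field missing", fatal=True)
            )
        if any(d.fatal for d in row_diags):
            diagnostics.extend(row_diags)
            continue

        rec = VariantAssociation(
            snp_id=snp_id,
            effect_allele=str(row[colmap["effect_allele"]]).strip().upper(),
            other_allele=str(row[colmap["other_allele"]]).strip().upper(),
            eaf=None if eaf is None or math.isnan(eaf) else eaf,
            beta=beta,
            se=se,
            pval=pval,
            n=int(n_raw),
        )
        problems = rec.validate()
        if problems:
            diagnostics.extend(problems)
            continue
        warning = rec.pval_consistency_warning()
        if warning is not None:
            diagnostics.append(warning)  # non-fatal: record is kept
        records.append(rec)

    table = AssociationTable(meta=meta, records=records)
    table.diagnostics = diagnostics
    return table


def _fmt_float(x: Optional[float]) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return format(x, ".17g")


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    """Write the canonical tab-delimited format; ``NA`` for missing eaf.

    ``read_association_table(write(x))`` reproduces ``x`` field-for-field.
    """
    path = Path(path)
    lines = ["\t".join(CANONICAL_COLUMNS)]
    for r in table.records:
        lines.append(
            "\t".join(
                [
                    r.snp_id,
                    r.effect_allele,
                    r.other_allele,
                    _fmt_float(r.eaf),
                    _fmt_float(r.beta),
                    _fmt_float(r.se),
                    _fmt_float(r.pval),
                    str(r.n),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
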