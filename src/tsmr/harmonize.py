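"""Align exposure and outcome associations onto a common effect allele.

Non-palindromic SNPs are reconciled by allele identity, allowing for a
swapped orientation (outcome beta negated, eaf complemented) and for a
strand complement.  Palindromic SNPs (A/T, C/G) carry no strand information
in their alleles, so orientation is inferred from effect-allele frequency:
both frequencies must fall outside the ambiguity band
``[limit, 1 - limit]`` (default limit 0.42), and the record is flipped when
they sit on opposite sides of 0.5.  Anything unresolvable is dropped with a
reason; every input SNP appears exactly once in the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .exceptions import ValidationError
from .summary_stats import AssociationTable, VariantAssociation

__all__ = [
    "HarmonizedInstrument",
    "is_palindromic",
    "harmonize_pair",
    "surviving",
    "write_harmonization_audit",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_PALINDROME_EAF_LIMIT = 0.42

ACTION_KEPT = "kept_as_is"
ACTION_FLIPPED = "outcome_flipped"
ACTION_PALINDROME = "palindrome_resolved"
ACTION_DROPPED = "dropped"


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP carried through exposure and outcome on a common effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float] = None
    eaf_out: Optional[float] = None
    action: str = ACTION_KEPT
    drop_reason: str = ""

    @property
    def dropped(self) -> bool:
        return self.action == ACTION_DROPPED

    def __post_init__(self) -> None:
        if self.dropped and not self.drop_reason:
            raise ValidationError(f"{self.snp_id}: dropped record must carry a drop_reason")
        if not self.dropped and (self.se_exp <= 0 or self.se_out <= 0):
            raise ValidationError(f"{self.snp_id}: standard errors must be > 0")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is A/T or C/G (strand-ambiguous)."""
    return COMPLEMENT.get(effect_allele) == other_allele


def _dropped(exp: VariantAssociation, out: Optional[VariantAssociation], reason: str) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=exp.snp_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=out.beta if out is not None else float("nan"),
        se_out=out.se if out is not None else float("nan"),
        eaf_exp=exp.eaf,
        eaf_out=out.eaf if out is not None else None,
        action=ACTION_DROPPED,
        drop_reason=reason,
    )


def _resolve_palindrome(
    exp: VariantAssociation, out: VariantAssociation, limit: float
) -> HarmonizedInstrument:
    # Alleles of a palindrome cannot distinguish a swapped orientation from a
    # strand flip; only frequencies can.
    if {out.effect_allele, out.other_allele} != {exp.effect_allele, exp.other_allele}:
        return _dropped(exp, out, "allele_mismatch")
    if exp.eaf is None or out.eaf is None:
        return _dropped(exp, out, "ambiguous_palindrome")
    band_low, band_high = limit, 1.0 - limit
    if band_low <= exp.eaf <= band_high or band_low <= out.eaf <= band_high:
        return _dropped(exp, out, "ambiguous_palindrome")
    same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
    beta_out = out.beta if same_side else -out.beta
    eaf_out = out.eaf if same_side else 1.0 - out.eaf
    return HarmonizedInstrument(
        snp_id=exp.snp_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=beta_out,
        se_out=out.se,
        eaf_exp=exp.eaf,
        eaf_out=eaf_out,
        action=ACTION_PALINDROME,
    )


def harmonize_pair(
    exposure: AssociationTable,
    outcome: AssociationTable,
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT,
    drop_palindromic: bool = False,
) -> list[HarmonizedInstrument]:
    """Harmonize each exposure SNP against the outcome table.

    Returns one record per exposure SNP, in input order, either harmonized
    (action ``kept_as_is`` / ``outcome_flipped`` / ``palindrome_resolved``)
    or ``dropped`` with a reason among ``missing_in_outcome``,
    ``ambiguous_palindrome``, ``allele_mismatch``.  Set
    ``drop_palindromic=True`` to drop all palindromic SNPs outright instead
    of frequency-resolving them.
    """
    results: list[HarmonizedInstrument] = []
    for exp in exposure.records:
        out = outcome.get(exp.snp_id)
        if out is None:
            results.append(_dropped(exp, None, "missing_in_outcome"))
            continue

        if is_palindromic(exp.effect_allele, exp.other_allele):
            if drop_palindromic:
                results.append(_dropped(exp, out, "ambiguous_palindrome"))
            else:
                results.append(_resolve_palindrome(exp, out, palindrome_eaf_limit))
            continue

        pair_exp = (exp.effect_allele, exp.other_allele)
        pair_out = (out.effect_allele, out.other_allele)
        pair_out_comp = (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele])

        if pair_out == pair_exp or pair_out_comp == pair_exp:
            results.append(
                HarmonizedInstrument(
                    snp_id=exp.snp_id,
                    beta_exp=exp.beta,
                    se_exp=exp.se,
                    beta_out=out.beta,
                    se_out=out.se,
                    eaf_exp=exp.eaf,
                    eaf_out=out.eaf,
                    action=ACTION_KEPT,
                )
            )
        elif pair_out == pair_exp[::-1] or pair_out_comp == pair_exp[::-1]:
            results.append(
                HarmonizedInstrument(
                    snp_id=exp.snp_id,
                    beta_exp=exp.beta,
                    se_exp=exp.se,
                    beta_out=-out.beta,
                    se_out=out.se,
                    eaf_exp=exp.eaf,
                    eaf_out=None if out.eaf is None else 1.0 - out.eaf,
                    action=ACTION_FLIPPED,
                )
            )
        else:
            results.append(_dropped(exp, out, "allele_mismatch"))
    return results


def surviving(harmonized: list[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """Non-dropped records, order preserved."""
    return [h for h in harmonized if not h.dropped]


def write_harmonization_audit(harmonized: list[HarmonizedInstrument], path: str | Path) -> None:
    """Write the per-SNP harmonization audit (snp_id, action, drop_reason)."""
    lines = ["snp_id\taction\tdrop_reason"]
    for h in harmonized:
        lines.append(f"{h.snp_id}\t{h.action}\t{h.drop_reason}")
    Path(path).write_text("\n".join(lines) + "\n")
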