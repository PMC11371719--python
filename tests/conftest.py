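from __future__ import annotations

import numpy as np
import pytest

from tsmr.harmonize import HarmonizedInstrument
from tsmr.summary_stats import AssociationTable, StudyMeta, VariantAssociation


def make_assoc(
    snp_id="rs1",
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pval=1e-8,
    n=18_340,
) -> VariantAssociation:
    return VariantAssociation(
        snp_id=snp_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


def make_inst(
    snp_id="rs1", beta_exp=0.1, se_exp=0.02, beta_out=0.05, se_out=0.1, **kw
) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=snp_id, beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out, **kw
    )


def random_insts(rng: np.random.Generator, n: int, theta: float = 0.4) -> list[HarmonizedInstrument]:
    """Random but valid instrument set: by = theta*bx + noise, varied weights."""
    bx = rng.uniform(0.05, 0.4, n) * rng.choice([-1.0, 1.0], n)
    sy = rng.uniform(0.05, 0.3, n)
    by = theta * bx + rng.normal(0.0, sy)
    sx = rng.uniform(0.005, 0.03, n)
    return [
        make_inst(snp_id=f"rs{i + 1}", beta_exp=bx[i], se_exp=sx[i], beta_out=by[i], se_out=sy[i])
        for i in range(n)
    ]


def consensus_insts(n: int = 5, ratio: float = 0.3) -> list[HarmonizedInstrument]:
    """All per-SNP ratios exactly equal (zero heterogeneity)."""
    return [
        make_inst(
            snp_id=f"rs{i + 1}",
            beta_exp=0.1 + 0.05 * i,
            beta_out=ratio * (0.1 + 0.05 * i),
            se_out=0.05 + 0.01 * i,
        )
        for i in range(n)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240821)


@pytest.fixture
def meta_continuous() -> StudyMeta:
    return StudyMeta(trait_name="abundance", trait_type="continuous", n_total=18_340)


@pytest.fixture
def meta_binary() -> StudyMeta:
    return StudyMeta(
        trait_name="disease",
        trait_type="binary",
        n_total=213_353,
        n_cases=208,
        n_controls=213_145,
    )


def table_of(records, meta=None) -> AssociationTable:
    meta = meta or StudyMeta(trait_name="t", trait_type="continuous", n_total=18_340)
    return AssociationTable(meta=meta, records=list(records))
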