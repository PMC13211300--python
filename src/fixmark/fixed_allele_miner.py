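"""Mining of fixed species-diagnostic alleles.

A locus is diagnostic when (a) every reference-set individual is non-missing
and homozygous for one common allele, and (b) that allele is completely
absent (frequency exactly zero) from the contrast set, with no missing
contrast genotype at the locus.  Missingness anywhere disqualifies the locus:
"100%" and "frequency = 0%" are undefined under missing data, and the strict
reading protects assay specificity.

The two-stage refinement mirrors the study design of training on all
morphologically target-labelled individuals first (Stage 1), then removing
individuals reclassified by assay validation (a cryptic hybrid) or excluded
as atypical phenotypic variants, and re-mining (Stage 2).  The contrast set
holds the non-target *species* individuals: known hybrids are excluded from
it, because a true hybrid is heterozygous at every genuinely diagnostic
locus and its presence in the contrast would veto the entire genome — the
point of the markers is to detect such hybrids, not to mine against them.
Reclassified samples are therefore routed by their molecular identity:
non-target purebreds (the variants) join the contrast, hybrids join neither
set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .variant_io import GenotypeMatrix, HOM_ALT, HOM_REF, LocusMeta, MISSING

#: Minimum allele-length difference for an InDel to support gel resolution.
SCAR_MIN_LEN_DIFF: int = 20


@dataclass(frozen=True)
class CandidateLocus:
    """A mined diagnostic locus with its fixed target allele."""

    locus_index: int
    locus: LocusMeta
    diagnostic_allele: str  # "ref" or "alt"
    stage: str  # "stage1" or "stage2"
    n_reference_support: int
    kasp_eligible: bool
    scar_eligible: bool

    @property
    def diagnostic_sequence(self) -> str:
        return self.locus.allele(self.diagnostic_allele)


def _scar_eligible(locus: LocusMeta) -> bool:
    return (
        locus.variant_type == "InDel"
        and abs(len(locus.ref) - len(locus.alt)) >= SCAR_MIN_LEN_DIFF
    )


def mine_fixed_alleles(
    gm: GenotypeMatrix,
    reference_set: Iterable[str],
    contrast_set: Iterable[str],
    *,
    stage: str = "stage1",
) -> list[CandidateLocus]:
    """Return all loci carrying a fixed allele unique to the reference set."""
    reference = list(reference_set)
    contrast = list(contrast_set)
    if not reference or not contrast:
        raise ValueError("reference and contrast sets must both be non-empty")
    overlap = set(reference) & set(contrast)
    if overlap:
        raise ValueError(f"reference and contrast sets overlap: {sorted(overlap)}")

    ref_g = gm.genotypes[gm.sample_indices(reference)]
    con_g = gm.genotypes[gm.sample_indices(contrast)]

    ref_clean = (ref_g != MISSING).all(axis=0)
    con_clean = (con_g != MISSING).all(axis=0)
    # diagnostic allele = alt: reference all hom-alt, contrast carries no alt
    # allele at all, i.e. contrast is uniformly hom-ref (het would carry it).
    alt_diag = (
        ref_clean & con_clean
        & (ref_g == HOM_ALT).all(axis=0)
        & (con_g == HOM_REF).all(axis=0)
    )
    ref_diag = (
        ref_clean & con_clean
        & (ref_g == HOM_REF).all(axis=0)
        & (con_g == HOM_ALT).all(axis=0)
    )

    candidates: list[CandidateLocus] = []
    for j in np.flatnonzero(alt_diag | ref_diag):
        locus = gm.loci[j]
        candidates.append(
            CandidateLocus(
                locus_index=int(j),
                locus=locus,
                diagnostic_allele="alt" if alt_diag[j] else "ref",
                stage=stage,
                n_reference_support=len(reference),
                kasp_eligible=True,  # SNPs and InDels both suit KASP
                scar_eligible=_scar_eligible(locus),
            )
        )
    return candidates


def two_stage_mining(
    gm: GenotypeMatrix,
    sheet,
    reclassified_ids: Iterable[str],
) -> tuple[list[CandidateLocus], list[CandidateLocus]]:
    """Run Stage-1 and Stage-2 mining from a sample sheet.

    Stage 1 uses all training-flagged (morphologically target-labelled)
    samples as reference and the non-target species individuals as contrast
    (known hybrids belong to neither set).  Stage 2 removes
    ``reclassified_ids`` (cryptic hybrid plus excluded variants) from the
    reference, adds the genetically non-target ones to the contrast, and
    re-mines.
    """
    reclassified = set(reclassified_ids)
    stage1_ref = list(sheet.training_ids())
    stage1_con = [
        s
        for s in sheet.ids()
        if s not in set(stage1_ref)
        and sheet.morphological_label(s) == "nontarget_species"
    ]
    bad = reclassified - set(stage1_ref)
    if bad:
        raise ValueError(
            f"reclassified ids not in the stage-1 reference set: {sorted(bad)}"
        )
    stage2_ref = [s for s in stage1_ref if s not in reclassified]
    if not stage2_ref:
        raise ValueError("reclassification would empty the reference set")
    stage2_con = stage1_con + [
        s
        for s in stage1_ref
        if s in reclassified and sheet.genetic_truth(s) == "nontarget"
    ]

    stage1 = mine_fixed_alleles(gm, stage1_ref, stage1_con, stage="stage1")
    if not reclassified:
        stage2 = [
            CandidateLocus(**{**c.__dict__, "stage": "stage2"}) for c in stage1
        ]
    else:
        stage2 = mine_fixed_alleles(gm, stage2_ref, stage2_con, stage="stage2")
    return stage1, stage2


__all__ = [
    "SCAR_MIN_LEN_DIFF",
    "CandidateLocus",
    "mine_fixed_alleles",
    "two_stage_mining",
]
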