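"""Quality-control cascade for the raw variant pool.

The cascade reduces a genotype matrix to high-quality loci in a fixed,
documented order:

1. per-genotype depth masking (calls with depth below ``min_depth`` become
   missing; the call itself is unreliable, the locus may still be fine),
2. site mapping quality (``MAPQ >= min_mapq``, inclusive),
3. per-locus missingness (< ``max_missing``, strict, computed after depth
   masking over all samples),
4. panel-wide minor allele frequency (> ``min_maf``, strict),
5. Hardy-Weinberg exact test within the target-species population, keeping
   loci with p >= ``hwe_alpha``.

Boundary semantics follow the printed thresholds verbatim: depth and MAPQ
are inclusive (>=), MAF and missingness strict (>, <).  HWE uses the exact
conditional test (not chi-square) because the within-species sample is small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .variant_io import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING


@dataclass(frozen=True)
class FilterThresholds:
    """QC thresholds; defaults are the marker-development pipeline values."""

    min_depth: int = 3
    min_maf: float = 0.05
    max_missing: float = 0.30
    min_mapq: float = 20.0
    hwe_alpha: float = 0.001

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        for name in ("min_maf", "max_missing"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 < self.hwe_alpha < 1.0:
            raise ValueError("hwe_alpha must be in (0, 1)")


@dataclass
class FilterStage:
    name: str
    entering_snp: int
    entering_indel: int
    surviving_snp: int
    surviving_indel: int

    @property
    def entering(self) -> int:
        return self.entering_snp + self.entering_indel

    @property
    def surviving(self) -> int:
        return self.surviving_snp + self.surviving_indel


@dataclass
class FilterReport:
    """Per-stage locus counts, split by SNP vs InDel; stages telescope."""

    stages: list[FilterStage] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "entering_snp": s.entering_snp,
                    "entering_indel": s.entering_indel,
                    "entering": s.entering,
                    "surviving_snp": s.surviving_snp,
                    "surviving_indel": s.surviving_indel,
                    "surviving": s.surviving,
                }
                for s in self.stages
            ]
        )

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def apply_depth_mask(gm: GenotypeMatrix, min_depth: int) -> GenotypeMatrix:
    """Set genotypes with depth below ``min_depth`` to missing.

    Idempotent; all other entries (and the depth array) are unchanged.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    out = gm.copy()
    out.genotypes[out.depth < min_depth] = MISSING
    return out


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed configuration (the standard exact HWE construction).  Returns a
    p-value in (0, 1].
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotype is required")
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_ref, n_alt)
    log_denom = gammaln(2 * n + 1) - gammaln(n_ref + 1) - gammaln(n_alt + 1)

    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    log_probs = (
        gammaln(n + 1)
        - gammaln(hom_common + 1)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        + hets * math.log(2)
        - log_denom
    )
    probs = np.exp(log_probs)
    p_obs = probs[hets == n_het][0]
    p = float(probs[probs <= p_obs * (1 + 1e-9)].sum())
    return min(1.0, p)


def _hwe_pvalues(gm: GenotypeMatrix, population_rows: np.ndarray) -> np.ndarray:
    """Per-locus HWE exact p within the given sample rows.

    Loci with no called genotype in the population carry no evidence and get
    p = 1.
    """
    sub = gm.genotypes[population_rows]
    pvals = np.ones(gm.n_loci)
    n_rr = (sub == HOM_REF).sum(axis=0)
    n_ra = (sub == HET).sum(axis=0)
    n_aa = (sub == HOM_ALT).sum(axis=0)
    for j in range(gm.n_loci):
        total = int(n_rr[j] + n_ra[j] + n_aa[j])
        if total > 0:
            pvals[j] = hwe_exact_test(int(n_rr[j]), int(n_ra[j]), int(n_aa[j]))
    return pvals


def filter_loci(
    gm: GenotypeMatrix,
    thresholds: FilterThresholds,
    hwe_population: Iterable[str],
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the full QC cascade; return surviving loci and a stage report."""
    hwe_population = list(hwe_population)
    if not hwe_population:
        raise ValueError("hwe_population must not be empty")
    unknown = set(hwe_population) - set(gm.sample_ids)
    if unknown:
        raise ValueError(f"hwe_population ids not in panel: {sorted(unknown)}")
    pop_rows = gm.sample_indices(hwe_population)

    report = FilterReport()
    masked = apply_depth_mask(gm, thresholds.min_depth)
    is_indel = masked.variant_types() == "InDel"

    def _record(name: str, keep: np.ndarray, current: np.ndarray) -> np.ndarray:
        entering = current
        surviving = current & keep
        report.stages.append(
            FilterStage(
                name=name,
                entering_snp=int((entering & ~is_indel).sum()),
                entering_indel=int((entering & is_indel).sum()),
                surviving_snp=int((surviving & ~is_indel).sum()),
                surviving_indel=int((surviving & is_indel).sum()),
            )
        )
        return surviving

    alive = np.ones(gm.n_loci, dtype=bool)
    # Depth masking operates on genotypes, not loci; recorded as a stage with
    # no locus-level attrition so the report still shows the full cascade.
    alive = _record("depth_mask", np.ones(gm.n_loci, dtype=bool), alive)
    alive = _record("site_mapq", masked.site_mapq() >= thresholds.min_mapq, alive)
    alive = _record(
        "missingness", masked.missing_fraction() < thresholds.max_missing, alive
    )
    maf = masked.minor_allele_freq()
    alive = _record("maf", np.nan_to_num(maf, nan=0.0) > thresholds.min_maf, alive)
    pvals = _hwe_pvalues(masked, pop_rows)
    alive = _record("hwe", pvals >= thresholds.hwe_alpha, alive)

    return masked.subset_loci(alive), report


__all__ = [
    "FilterThresholds",
    "FilterStage",
    "FilterReport",
    "apply_depth_mask",
    "hwe_exact_test",
    "filter_loci",
]
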