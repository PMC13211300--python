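"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from fixmark.variant_io import (
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    LocusMeta,
    MISSING,
)


def make_gm(
    genotypes,
    depth=None,
    mapq=None,
    loci=None,
    sample_ids=None,
) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from nested lists of codes."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if depth is None:
        depth = np.full((n, m), 50, dtype=np.int64)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    if loci is None:
        loci = [
            LocusMeta(
                chrom="chr1",
                pos=100 * (j + 1),
                ref="A",
                alt="T",
                site_mapq=50.0 if mapq is None else float(mapq[j]),
            )
            for j in range(m)
        ]
    return GenotypeMatrix(sample_ids, loci, genotypes, np.asarray(depth))


def random_gm(rng: np.random.Generator, n_samples=8, n_loci=30) -> GenotypeMatrix:
    codes = rng.choice(
        [HOM_REF, HET, HOM_ALT, MISSING], size=(n_samples, n_loci),
        p=[0.4, 0.2, 0.3, 0.1],
    )
    depth = rng.integers(0, 40, size=(n_samples, n_loci))
    mapq = rng.uniform(5, 60, size=n_loci)
    return make_gm(codes, depth=depth, mapq=mapq)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def mine_oracle(gm: GenotypeMatrix, reference_ids, contrast_ids):
    """Direct per-locus scan of the fixed-allele definition.

    Returns {locus_index: diagnostic_allele} for qualifying loci.
    """
    ref_rows = [gm.sample_ids.index(s) for s in reference_ids]
    con_rows = [gm.sample_ids.index(s) for s in contrast_ids]
    found = {}
    for j in range(gm.n_loci):
        ref = [int(gm.genotypes[i, j]) for i in ref_rows]
        con = [int(gm.genotypes[i, j]) for i in con_rows]
        for diag, hom_diag, hom_other in (
            ("alt", HOM_ALT, HOM_REF),
            ("ref", HOM_REF, HOM_ALT),
        ):
            if all(g == hom_diag for g in ref) and all(g == hom_other for g in con):
                found[j] = diag
    return found


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Exact-rational enumeration of the conditional HWE test."""
    n = n_hom_ref + n_het + n_hom_alt
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_ref, n_alt)
    denom = math.comb(2 * n, n_ref)

    def weight(h: int) -> Fraction:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_common) * math.factorial(h) * math.factorial(hom_rare),
        ) / denom

    probs = {h: weight(h) for h in range(rare % 2, rare + 1, 2)}
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs)


def filter_oracle(gm: GenotypeMatrix, thresholds, hwe_rows):
    """Plain-python re-evaluation of all five QC rules; returns kept indices."""
    from fixmark.variant_filters import hwe_exact_test

    kept = []
    for j in range(gm.n_loci):
        codes = [
            MISSING
            if gm.depth[i, j] < thresholds.min_depth
            else int(gm.genotypes[i, j])
            for i in range(gm.n_samples)
        ]
        if gm.loci[j].site_mapq < thresholds.min_mapq:
            continue
        miss = sum(c == MISSING for c in codes) / gm.n_samples
        if not miss < thresholds.max_missing:
            continue
        called = [c for c in codes if c != MISSING]
        if not called:
            continue
        p_alt = sum(called) / (2.0 * len(called))
        maf = min(p_alt, 1 - p_alt)
        if not maf > thresholds.min_maf:
            continue
        pop = [codes[i] for i in hwe_rows if codes[i] != MISSING]
        if pop:
            p = hwe_exact_test(
                sum(c == HOM_REF for c in pop),
                sum(c == HET for c in pop),
                sum(c == HOM_ALT for c in pop),
            )
            if p < thresholds.hwe_alpha:
                continue
        kept.append(j)
    return kept


def wilson_oracle(successes: int, n: int, confidence: float = 0.95):
    """Numerical inversion of the score test (independent of statsmodels)."""
    from scipy.optimize import brentq
    from scipy.stats import norm

    z = norm.ppf(0.5 * (1 + confidence))
    phat = successes / n

    def score(p):
        return (phat - p) ** 2 - z**2 * p * (1 - p) / n

    eps = 1e-12
    if successes == 0:
        return 0.0, brentq(score, eps, 1 - eps)
    if successes == n:
        return brentq(score, eps, 1 - eps), 1.0
    return brentq(score, eps, phat), brentq(score, phat, 1 - eps)


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)
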