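"""Genotype-matrix data model and VCF / TSV input-output.

The central container is :class:`GenotypeMatrix`: a samples x loci array of
diploid genotype codes (homozygous reference, heterozygous, homozygous
alternative, missing) together with per-genotype read depth and per-site
metadata (coordinates, alleles, mapping quality).  Only biallelic sites are
representable; multi-allelic VCF records are rejected explicitly rather than
split, because the downstream fixed-allele definition is biallelic.

All coordinates are 1-based, as in VCF.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

# Genotype codes.  MISSING is negative so that ``genotypes >= 0`` masks calls.
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

VALID_CODES = frozenset((HOM_REF, HET, HOM_ALT, MISSING))

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

# Depth sentinel used when a VCF lacks per-genotype DP: treated as "deep
# enough" so the depth filter is a no-op rather than a mass deletion.
NO_DEPTH_SENTINEL: int = 2**31 - 1


class VcfParseError(ValueError):
    """A VCF record could not be parsed into the biallelic data model."""


class MultiAllelicSiteError(VcfParseError):
    """Raised for records with more than one ALT allele (not split)."""


@dataclass(frozen=True)
class LocusMeta:
    """Per-site metadata for one biallelic variant.

    ``site_mapq`` defaults to +infinity, meaning "no mapping-quality
    annotation, treat as passing" (the MAPQ rule is a filter, not a format
    requirement).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    site_mapq: float = math.inf

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")

    @property
    def variant_type(self) -> str:
        """``"InDel"`` iff the allele lengths differ, else ``"SNP"``."""
        return "InDel" if len(self.ref) != len(self.alt) else "SNP"

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}"

    def allele(self, which: str) -> str:
        if which == "ref":
            return self.ref
        if which == "alt":
            return self.alt
        raise ValueError(f"allele must be 'ref' or 'alt', got {which!r}")


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid genotype codes with depth and site metadata."""

    sample_ids: list[str]
    loci: list[LocusMeta]
    genotypes: np.ndarray  # (n_samples, n_loci) int8
    depth: np.ndarray  # (n_samples, n_loci) int64, >= 0

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        n, m = len(self.sample_ids), len(self.loci)
        if self.genotypes.shape != (n, m):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != ({n}, {m})"
            )
        if self.depth.shape != (n, m):
            raise ValueError(f"depth shape {self.depth.shape} != ({n}, {m})")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        bad = set(np.unique(self.genotypes)) - VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        if (self.depth < 0).any():
            raise ValueError("depth must be non-negative")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            list(self.loci),
            self.genotypes.copy(),
            self.depth.copy(),
        )

    def sample_indices(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def subset_loci(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.loci[i] for i in index],
            self.genotypes[:, index].copy(),
            self.depth[:, index].copy(),
        )

    # -- per-locus summaries --------------------------------------------
    def missing_fraction(self) -> np.ndarray:
        """Fraction of samples with a missing call, per locus."""
        return (self.genotypes == MISSING).mean(axis=0)

    def alt_allele_freq(self) -> np.ndarray:
        """Alternative-allele frequency over non-missing calls, per locus.

        Monomorphic-missing loci (no calls at all) get frequency NaN.
        """
        called = self.genotypes != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, self.genotypes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.alt_allele_freq()
        return np.minimum(p, 1.0 - p)

    def site_mapq(self) -> np.ndarray:
        return np.array([loc.site_mapq for loc in self.loci], dtype=float)

    def variant_types(self) -> np.ndarray:
        return np.array([loc.variant_type for loc in self.loci])


# ---------------------------------------------------------------------------
# VCF reading (cyvcf2) and writing (minimal text subset)
# ---------------------------------------------------------------------------


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a biallelic VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records raise :class:`MultiAllelicSiteError` naming the
    site; malformed records raise :class:`VcfParseError` naming the record
    number.  Nothing is silently dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    loci: list[LocusMeta] = []
    geno_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    warned_no_dp = False

    record_no = 0
    iterator = iter(vcf)
    while True:
        try:
            variant = next(iterator)
        except StopIteration:
            break
        except Exception as exc:
            raise VcfParseError(
                f"malformed VCF record #{record_no + 1} in {path}: {exc}"
            ) from exc
        record_no += 1
        if len(variant.ALT) != 1:
            raise MultiAllelicSiteError(
                f"multi-allelic site {variant.CHROM}:{variant.POS} "
                f"(ALT={variant.ALT}); split or drop it upstream"
            )
        mq = variant.INFO.get("MQ")
        if mq is None:
            warnings.warn(
                f"site {variant.CHROM}:{variant.POS} has no MQ annotation; "
                "treating as passing",
                stacklevel=2,
            )
            mq = math.inf
        loci.append(
            LocusMeta(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=variant.ALT[0],
                site_mapq=float(mq),
            )
        )
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gts = np.asarray(variant.gt_types, dtype=np.int8)
        gts[gts == 3] = MISSING
        geno_rows.append(gts)
        dp = variant.format("DP")
        if dp is None:
            if not warned_no_dp:
                warnings.warn(
                    f"{path}: no per-genotype DP field; depth filter will be "
                    "a no-op",
                    stacklevel=2,
                )
                warned_no_dp = True
            depth_rows.append(
                np.full(len(sample_ids), NO_DEPTH_SENTINEL, dtype=np.int64)
            )
        else:
            dp = np.asarray(dp, dtype=np.int64).reshape(-1)
            dp[dp < 0] = 0  # htslib missing-value sentinel
            depth_rows.append(dp)

    genotypes = (
        np.stack(geno_rows, axis=1)
        if geno_rows
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    depth = (
        np.stack(depth_rows, axis=1)
        if depth_rows
        else np.zeros((len(sample_ids), 0), dtype=np.int64)
    )
    return GenotypeMatrix(sample_ids, loci, genotypes, depth)


def _format_mq(mq: float) -> str | None:
    if math.isinf(mq):
        return None  # absent MQ round-trips to "treated as passing"
    if float(mq).is_integer():
        return f"MQ={int(mq)}"
    return f"MQ={mq:.6g}"


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF (GT:DP per genotype, MQ per site).

    ``read_vcf(write_vcf(gm))`` reproduces genotype codes, depths and site
    MAPQ exactly.  Depth is written even for missing genotypes (a masked
    low-depth call still has an observed depth).
    """
    if gm.n_loci == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    contigs = sorted({loc.chrom for loc in gm.loci})
    order = sorted(range(gm.n_loci), key=lambda i: (gm.loci[i].chrom, gm.loci[i].pos))
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Site mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    lines.extend(f"##contig=<ID={c}>" for c in contigs)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.sample_ids)
    )
    for j in order:
        loc = gm.loci[j]
        mq = _format_mq(loc.site_mapq)
        info = mq if mq is not None else "."
        fields = [
            loc.chrom,
            str(loc.pos),
            ".",
            loc.ref,
            loc.alt,
            ".",
            "PASS",
            info,
            "GT:DP",
        ]
        for i in range(gm.n_samples):
            fields.append(
                f"{_GT_STRINGS[int(gm.genotypes[i, j])]}:{int(gm.depth[i, j])}"
            )
        lines.append("\t".join(fields))
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


def write_candidates(candidates, path: str) -> None:
    """Write mined candidate loci as TSV, sorted by (chrom, pos).

    Works for an empty list (header-only file).  Each row carries both-assay
    eligibility flags so that a large InDel can feed KASP and SCAR design at
    once.
    """
    header = (
        "chrom\tpos\tref\talt\tvariant_type\tdiagnostic_allele\tstage\t"
        "n_reference_support\tkasp_eligible\tscar_eligible"
    )
    rows = []
    for cand in sorted(candidates, key=lambda c: (c.locus.chrom, c.locus.pos)):
        loc = cand.locus
        rows.append(
            "\t".join(
                [
                    loc.chrom,
                    str(loc.pos),
                    loc.ref,
                    loc.alt,
                    loc.variant_type,
                    cand.diagnostic_allele,
                    cand.stage,
                    str(cand.n_reference_support),
                    str(cand.kasp_eligible),
                    str(cand.scar_eligible),
                ]
            )
        )
    with open(path, "w") as handle:
        handle.write("\n".join([header, *rows]) + "\n")


__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "VALID_CODES",
    "LocusMeta",
    "GenotypeMatrix",
    "VcfParseError",
    "MultiAllelicSiteError",
    "read_vcf",
    "write_vcf",
    "write_candidates",
]
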