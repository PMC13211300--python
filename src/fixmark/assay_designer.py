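"""KASP and SCAR primer screening for candidate diagnostic loci.

Melting temperatures come from nearest-neighbor thermodynamics (the unified
Allawi & SantaLucia 1997 parameter set as implemented in Biopython's
``Tm_NN``, at its default 50 mM Na+ and 25 nM strand concentrations).  The
Tm model is isolated behind :func:`primer_properties` so an alternative
parameterization is a one-line change.

KASP design enumerates allele-specific forward primers that terminate 3' on
the discriminating base (SNPs) or span the InDel junction, paired with a
common reverse primer within a bounded amplicon, on both strand
orientations.  Candidates are ranked by deviation of Tm from the middle of
the target range, then primer length, then lexicographic sequence — a
deterministic ordering that is invariant under reverse-complementing the
input flank.

SCAR design places a primer pair around an InDel: codominant when both
alleles amplify with a size difference at or above the gel-resolution
threshold, dominant when the reverse primer site lies wholly inside the
segment deleted from one allele (that allele then yields no band).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, NamedTuple

from Bio.SeqUtils import MeltingTemp, gc_fraction

from .variant_io import LocusMeta

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DesignConstraints:
    """Primer design constraints (closed ranges, as printed specs usually are)."""

    tm_range: tuple[float, float] = (58.0, 62.0)
    gc_range: tuple[float, float] = (0.40, 0.60)
    length_range: tuple[int, int] = (20, 30)
    min_scar_size_diff: int = 20

    def __post_init__(self) -> None:
        for name in ("tm_range", "gc_range", "length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if self.min_scar_size_diff < 1:
            raise ValueError("min_scar_size_diff must be >= 1")

    @property
    def tm_target(self) -> float:
        return 0.5 * (self.tm_range[0] + self.tm_range[1])


class PrimerProperties(NamedTuple):
    length: int
    gc: float
    tm: float


@lru_cache(maxsize=65536)
def _tm_nn(seq: str) -> float:
    return float(MeltingTemp.Tm_NN(seq))


def primer_properties(seq: str) -> PrimerProperties:
    """Length, GC fraction and nearest-neighbor Tm (deg C) of a primer."""
    if not seq:
        raise ValueError("primer sequence must be non-empty")
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"primer must be plain ACGT, got {seq!r}")
    return PrimerProperties(
        length=len(seq), gc=float(gc_fraction(seq)), tm=_tm_nn(seq)
    )


def _passes(seq: str, constraints: DesignConstraints) -> PrimerProperties | None:
    props = primer_properties(seq)
    lo, hi = constraints.length_range
    if not lo <= props.length <= hi:
        return None
    lo, hi = constraints.gc_range
    if not lo <= props.gc <= hi:
        return None
    lo, hi = constraints.tm_range
    if not lo <= props.tm <= hi:
        return None
    return props


@dataclass(frozen=True)
class KaspAssay:
    """Two allele-specific primers plus a common reverse primer.

    Universal fluorescent tail sequences are proprietary and not appended;
    the assay carries a dye map (diagnostic allele -> dye) instead.
    """

    name: str
    allele_ref_primer: str
    allele_alt_primer: str
    common_primer: str
    dye_map: dict[str, str]  # {"ref": "FAM"/"HEX", "alt": ...}
    diagnostic_allele: str
    locus: LocusMeta | None = None

    def __post_init__(self) -> None:
        if set(self.dye_map) != {"ref", "alt"} or set(self.dye_map.values()) != {
            "FAM",
            "HEX",
        }:
            raise ValueError("dye_map must assign FAM and HEX to ref and alt")
        if self.diagnostic_allele not in ("ref", "alt"):
            raise ValueError("diagnostic_allele must be 'ref' or 'alt'")
        if (
            self.locus is not None
            and self.locus.variant_type == "SNP"
            and len(self.allele_ref_primer) == len(self.allele_alt_primer)
        ):
            a, b = self.allele_ref_primer, self.allele_alt_primer
            if a[:-1] != b[:-1] or a[-1] == b[-1]:
                raise ValueError(
                    "SNP allele primers must differ exactly at the 3' base"
                )


@dataclass(frozen=True)
class ScarAssay:
    """A SCAR primer pair with its allele -> amplicon-size map."""

    name: str
    forward_primer: str
    reverse_primer: str
    size_map: dict[str, int | None]  # {"ref"/"alt": bp or None (no band)}
    mode: str  # "dominant" or "codominant"
    diagnostic_allele: str
    locus: LocusMeta | None = None

    def __post_init__(self) -> None:
        if set(self.size_map) != {"ref", "alt"}:
            raise ValueError("size_map must have 'ref' and 'alt' entries")
        sizes = list(self.size_map.values())
        if self.mode == "codominant":
            if any(s is None for s in sizes):
                raise ValueError("codominant assay must map both alleles to sizes")
            if sizes[0] == sizes[1]:
                raise ValueError("codominant sizes must differ")
        elif self.mode == "dominant":
            if sum(s is None for s in sizes) != 1:
                raise ValueError("dominant assay needs exactly one no-band allele")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.diagnostic_allele not in ("ref", "alt"):
            raise ValueError("diagnostic_allele must be 'ref' or 'alt'")


def _orientations(
    flank: str, pos: int, ref: str, alt: str
) -> Iterator[tuple[str, int, str, str]]:
    yield flank, pos, ref, alt
    n = len(flank)
    yield reverse_complement(flank), n - pos - len(ref), reverse_complement(
        ref
    ), reverse_complement(alt)


def _check_flank(flank: str, pos: int, ref: str, min_flank: int = 100) -> None:
    flank_len = len(flank)
    if pos < 0 or pos + len(ref) > flank_len:
        raise ValueError("variant does not lie inside the flank")
    if flank.upper() != flank or set(flank) - set("ACGT"):
        raise ValueError("flank must be uppercase ACGT")
    if flank[pos : pos + len(ref)] != ref:
        raise ValueError("flank does not carry the reference allele at pos")
    if min(pos, flank_len - pos - len(ref)) < min_flank:
        raise ValueError(
            f"flank must extend >= {min_flank} bp on both sides of the variant"
        )


def design_kasp(
    flank: str,
    pos: int,
    ref: str,
    alt: str,
    *,
    diagnostic_allele: str = "alt",
    constraints: DesignConstraints = DesignConstraints(),
    max_amplicon: int = 120,
    locus: LocusMeta | None = None,
    name: str = "KASP",
) -> KaspAssay | None:
    """Design a KASP assay; returns None when no primer set satisfies the
    constraints.

    ``pos`` is the 0-based offset of the reference allele inside ``flank``.
    """
    flank = flank.upper()
    _check_flank(flank, pos, ref)
    lmin, lmax = constraints.length_range
    target = constraints.tm_target

    candidates: list[tuple] = []
    for hap_ref, p, r, a in _orientations(flank, pos, ref, alt):
        hap_alt = hap_ref[:p] + a + hap_ref[p + len(r) :]
        e_ref, e_alt = p + len(r), p + len(a)
        for length in range(lmin, lmax + 1):
            if e_ref - length < 0 or e_alt - length < 0:
                continue
            primer_ref = hap_ref[e_ref - length : e_ref]
            primer_alt = hap_alt[e_alt - length : e_alt]
            props_ref = _passes(primer_ref, constraints)
            props_alt = _passes(primer_alt, constraints)
            if props_ref is None or props_alt is None:
                continue
            pair_dev = abs(props_ref.tm - target) + abs(props_alt.tm - target)
            allele_start = e_ref - length
            # common reverse primer downstream, identical in both haplotypes
            for lc in range(lmin, lmax + 1):
                s_max = min(len(hap_ref) - lc, allele_start + max_amplicon - lc)
                for s in range(e_ref, s_max + 1):
                    common = reverse_complement(hap_ref[s : s + lc])
                    props_c = _passes(common, constraints)
                    if props_c is None:
                        continue
                    candidates.append(
                        (
                            round(pair_dev, 6),
                            round(abs(props_c.tm - target), 6),
                            length,
                            lc,
                            primer_ref,
                            primer_alt,
                            common,
                        )
                    )
    if not candidates:
        return None
    best = min(candidates)
    _, _, _, _, primer_ref, primer_alt, common = best
    other = "alt" if diagnostic_allele == "ref" else "ref"
    return KaspAssay(
        name=name,
        allele_ref_primer=primer_ref,
        allele_alt_primer=primer_alt,
        common_primer=common,
        dye_map={diagnostic_allele: "HEX", other: "FAM"},
        diagnostic_allele=diagnostic_allele,
        locus=locus,
    )


def design_scar(
    flank: str,
    pos: int,
    ref: str,
    alt: str,
    *,
    diagnostic_allele: str = "alt",
    constraints: DesignConstraints = DesignConstraints(),
    mode: str = "auto",
    max_amplicon: int = 600,
    locus: LocusMeta | None = None,
    name: str = "SCAR",
) -> ScarAssay | None:
    """Design a SCAR assay around a simple (left-anchored) InDel.

    ``mode`` is ``"codominant"``, ``"dominant"`` or ``"auto"`` (codominant
    preferred, dominant as fallback).  Returns None when infeasible.
    """
    flank = flank.upper()
    ref, alt = ref.upper(), alt.upper()
    if len(ref) == len(alt):
        raise ValueError("SCAR design requires an InDel locus")
    _check_flank(flank, pos, ref, min_flank=50)
    long_allele, short_allele = (ref, alt) if len(ref) > len(alt) else (alt, ref)
    if len(short_allele) != 1 or not long_allele.startswith(short_allele):
        raise ValueError("only simple left-anchored InDels are supported")
    d = len(long_allele) - 1
    long_is_ref = len(ref) > len(alt)
    hap_long = (
        flank if long_is_ref else flank[:pos] + alt + flank[pos + len(ref) :]
    )
    seg_start, seg_end = pos + 1, pos + 1 + d  # deleted segment in hap_long

    if mode not in ("auto", "codominant", "dominant"):
        raise ValueError(f"unknown mode {mode!r}")
    modes = ("codominant", "dominant") if mode == "auto" else (mode,)

    lmin, lmax = constraints.length_range
    target = constraints.tm_target

    for try_mode in modes:
        if try_mode == "codominant" and d < constraints.min_scar_size_diff:
            continue
        candidates: list[tuple] = []
        for lf in range(lmin, lmax + 1):
            for f in range(max(0, seg_start - lf - 150), seg_start - lf + 1):
                fwd = hap_long[f : f + lf]
                props_f = _passes(fwd, constraints)
                if props_f is None:
                    continue
                if try_mode == "codominant":
                    s_range_start = seg_end
                    s_limit = len(hap_long)
                else:
                    s_range_start = seg_start
                    s_limit = seg_end
                for lr in range(lmin, lmax + 1):
                    hi = min(s_limit - lr, f + max_amplicon - lr)
                    for s in range(s_range_start, hi + 1):
                        rev = reverse_complement(hap_long[s : s + lr])
                        props_r = _passes(rev, constraints)
                        if props_r is None:
                            continue
                        size_long = s + lr - f
                        candidates.append(
                            (
                                round(
                                    abs(props_f.tm - target)
                                    + abs(props_r.tm - target),
                                    6,
                                ),
                                size_long,
                                fwd,
                                rev,
                            )
                        )
        if not candidates:
            continue
        _, size_long, fwd, rev = min(candidates)
        if try_mode == "codominant":
            sizes = {"long": size_long, "short": size_long - d}
        else:
            sizes = {"long": size_long, "short": None}
        size_map = {
            "ref": sizes["long"] if long_is_ref else sizes["short"],
            "alt": sizes["short"] if long_is_ref else sizes["long"],
        }
        return ScarAssay(
            name=name,
            forward_primer=fwd,
            reverse_primer=rev,
            size_map=size_map,
            mode=try_mode,
            diagnostic_allele=diagnostic_allele,
            locus=locus,
        )
    return None


__all__ = [
    "reverse_complement",
    "DesignConstraints",
    "PrimerProperties",
    "primer_properties",
    "KaspAssay",
    "ScarAssay",
    "design_kasp",
    "design_scar",
]
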