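"""Genotype and species calling from raw assay observations.

KASP endpoint fluorescence is called with a deterministic allele-ratio rule
rather than clustering: wells below a total-intensity floor are no-calls
(NTC-like); otherwise the HEX fraction r = hex / (fam + hex) is banded into
target homozygote (r >= 0.80), alternative homozygote (r <= 0.20),
heterozygote (0.35 <= r <= 0.65) and no-call in between.  The rule is
auditable and, under the simulator's class geometry, every decision boundary
sits several noise standard deviations from the nearest class mean.

SCAR gels are interpreted per locus (band sizes matched within a tolerance)
and then merged across the dominant and codominant locus with the combined
two-locus decision table.  Patterns outside the validated table return
``ambiguous``, never ``target`` — the fail-safe direction for a conservation
screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

CALL_VALUES = ("target", "nontarget", "heterozygous_hybrid", "ambiguous", "no_call")

GENOTYPE_CLASSES = ("target_hom", "alt_hom", "het", "no_call")


@dataclass(frozen=True)
class FluorescencePoint:
    """One two-channel endpoint fluorescence reading."""

    sample_id: str
    assay: str
    fam: float
    hex: float

    def __post_init__(self) -> None:
        for name in ("fam", "hex"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} intensity must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class BandPattern:
    """Set of amplicon sizes observed on a gel for one sample (may be empty)."""

    sample_id: str
    assay: str
    sizes: frozenset[int]

    def __post_init__(self) -> None:
        if any((not isinstance(s, (int,)) and not float(s).is_integer()) or s <= 0
               for s in self.sizes):
            raise ValueError(f"band sizes must be positive integers: {self.sizes}")


@dataclass(frozen=True)
class SpeciesCall:
    """Per-sample species-level decision."""

    value: str
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.value not in CALL_VALUES:
            raise ValueError(f"unknown call value {self.value!r}")


@dataclass(frozen=True)
class KaspCallingThresholds:
    """Ratio bands and intensity floor of the deterministic KASP caller."""

    min_total_intensity: float = 0.30
    hom_target_min_ratio: float = 0.80
    hom_alt_max_ratio: float = 0.20
    het_low: float = 0.35
    het_high: float = 0.65

    def __post_init__(self) -> None:
        ordered = (
            0.0
            <= self.hom_alt_max_ratio
            < self.het_low
            <= self.het_high
            < self.hom_target_min_ratio
            <= 1.0
        )
        if not ordered or self.min_total_intensity < 0:
            raise ValueError("inconsistent KASP calling thresholds")


DEFAULT_KASP_THRESHOLDS = KaspCallingThresholds()


def call_kasp(
    point: FluorescencePoint,
    thresholds: KaspCallingThresholds = DEFAULT_KASP_THRESHOLDS,
) -> str:
    """Classify one fluorescence point into a genotype class.

    Total function on the non-negative quadrant: exactly one of
    ``target_hom``, ``alt_hom``, ``het``, ``no_call``.
    """
    total = point.fam + point.hex
    if total < thresholds.min_total_intensity:
        return "no_call"
    ratio = point.hex / total
    if ratio >= thresholds.hom_target_min_ratio:
        return "target_hom"
    if ratio <= thresholds.hom_alt_max_ratio:
        return "alt_hom"
    if thresholds.het_low <= ratio <= thresholds.het_high:
        return "het"
    return "no_call"


class AmbiguousBandError(ValueError):
    """A band matches more than one expected amplicon size."""


@dataclass(frozen=True)
class Scar2Call:
    """Codominant-locus interpretation of one band pattern."""

    pattern: str  # target_only / other_only / both / none
    unmatched: tuple[int, ...] = ()  # bands matching no expected size


def call_scar2(
    band_pattern: BandPattern,
    assay,
    size_tolerance: int = 5,
) -> Scar2Call:
    """Match observed bands to a codominant assay's two expected sizes.

    ``assay`` needs a ``size_map`` ({"ref"/"alt": size}) and a
    ``diagnostic_allele``.  Bands matching neither size are reported as
    unmatched; a band within tolerance of both sizes raises
    :class:`AmbiguousBandError`.
    """
    if getattr(assay, "mode", "codominant") != "codominant":
        raise ValueError("call_scar2 requires a codominant assay")
    target_size = assay.size_map[assay.diagnostic_allele]
    other_allele = "alt" if assay.diagnostic_allele == "ref" else "ref"
    other_size = assay.size_map[other_allele]
    if target_size is None or other_size is None:
        raise ValueError("codominant assay must map both alleles to sizes")

    saw_target = saw_other = False
    unmatched: list[int] = []
    for band in sorted(band_pattern.sizes):
        near_target = abs(band - target_size) <= size_tolerance
        near_other = abs(band - other_size) <= size_tolerance
        if near_target and near_other:
            raise AmbiguousBandError(
                f"band {band} bp within {size_tolerance} bp of both expected "
                f"sizes {target_size}/{other_size}"
            )
        if near_target:
            saw_target = True
        elif near_other:
            saw_other = True
        else:
            unmatched.append(band)
    pattern = {
        (True, True): "both",
        (True, False): "target_only",
        (False, True): "other_only",
        (False, False): "none",
    }[(saw_target, saw_other)]
    return Scar2Call(pattern=pattern, unmatched=tuple(unmatched))


#: Merged two-locus decision table.  Keys: (dominant-locus band present,
#: codominant-locus pattern).  The dominant locus amplifies only the
#: non-target allele, so "absent" is the target-typical state.  The
#: heterozygous combined pattern counts as non-target for concordance.
COMBINED_SCAR_TABLE: dict[tuple[bool, str], str] = {
    (False, "target_only"): "target",  # X:516
    (False, "both"): "target",  # X:516/537
    (True, "target_only"): "target",  # O:516 (as validated)
    (True, "other_only"): "nontarget",  # O:537
    (True, "both"): "heterozygous_hybrid",  # O:516/537
}


def combined_scar_classify(scar1_present: bool, scar2_pattern: str) -> SpeciesCall:
    """Species call from the merged two-locus band framework.

    Total over the input domain; combinations outside the validated table
    (e.g. no band anywhere, or dominant-locus absence with only the
    non-target codominant size) are ``ambiguous``.
    """
    if scar2_pattern not in ("target_only", "other_only", "both", "none"):
        raise ValueError(f"unknown codominant pattern {scar2_pattern!r}")
    value = COMBINED_SCAR_TABLE.get((bool(scar1_present), scar2_pattern), "ambiguous")
    return SpeciesCall(value=value)


def kasp_species_call(genotype_classes: Sequence[str]) -> SpeciesCall:
    """Aggregate per-assay genotype classes into one species call.

    All assays target-homozygous -> target; all alternative-homozygous ->
    nontarget; any heterozygous -> heterozygous hybrid; conflicting
    homozygote calls -> ambiguous.  No-calls are dropped first; if the rest
    is consistent the call is flagged low-confidence.
    """
    classes = list(genotype_classes)
    if not classes:
        raise ValueError("at least one assay call is required")
    bad = set(classes) - set(GENOTYPE_CLASSES)
    if bad:
        raise ValueError(f"unknown genotype classes: {sorted(bad)}")
    called = [c for c in classes if c != "no_call"]
    low_confidence = len(called) < len(classes)
    if not called:
        return SpeciesCall(value="no_call", low_confidence=True)
    if any(c == "het" for c in called):
        return SpeciesCall(value="heterozygous_hybrid", low_confidence=low_confidence)
    if all(c == "target_hom" for c in called):
        return SpeciesCall(value="target", low_confidence=low_confidence)
    if all(c == "alt_hom" for c in called):
        return SpeciesCall(value="nontarget", low_confidence=low_confidence)
    return SpeciesCall(value="ambiguous", low_confidence=low_confidence)


def plot_allelic_discrimination(points: Iterable[FluorescencePoint], ax=None):
    """Scatter the FAM/HEX plane (the allelic-discrimination plot)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs = [p.fam for p in points]
    ys = [p.hex for p in points]
    ax.scatter(xs, ys, s=12)
    ax.set_xlabel("FAM intensity")
    ax.set_ylabel("HEX intensity")
    return ax


__all__ = [
    "CALL_VALUES",
    "GENOTYPE_CLASSES",
    "FluorescencePoint",
    "BandPattern",
    "SpeciesCall",
    "KaspCallingThresholds",
    "DEFAULT_KASP_THRESHOLDS",
    "call_kasp",
    "AmbiguousBandError",
    "Scar2Call",
    "call_scar2",
    "COMBINED_SCAR_TABLE",
    "combined_scar_classify",
    "kasp_species_call",
    "plot_allelic_discrimination",
]
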