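"""Diagnostic performance statistics and the hybrid index.

Species calls are scored against one of two explicit conventions:

* ``morphological`` — a call is concordant when it matches the sample's
  morphological pre-classification (variant-labelled samples count toward
  their validated non-target expectation; a heterozygous-hybrid call counts
  as non-target for matching), and
* ``genetic`` — concordance against the molecular ground truth (hybrids are
  non-target; a plain non-target call for a hybrid is still a correct
  exclusion).

The convention must be named explicitly: headline concordance figures are
only meaningful relative to the chosen reference labelling.  Sensitivity is
always the concordant fraction among genetically confirmed purebreds and
specificity the concordant fraction among genetic non-targets (hybrids
included), under the chosen convention.

Binomial fractions carry two-sided Wilson score intervals (no continuity
correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .assay_caller import SpeciesCall
from .variant_io import MISSING

CONVENTIONS = ("morphological", "genetic")

#: Call values accepted as "non-target" when matching non-target expectations.
_NONTARGET_OK = frozenset({"nontarget", "heterozygous_hybrid"})


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts; the positive class is the genetic purebred."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.positives + self.negatives


@dataclass(frozen=True)
class DiagnosticReport:
    convention: str
    counts: ConfusionCounts
    concordance: float
    concordance_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    discordant_ids: tuple[str, ...]

    def concordance_percent(self) -> float:
        return round_percent(self.concordance)

    def sensitivity_percent(self) -> float:
        return round_percent(self.sensitivity)

    def specificity_percent(self) -> float:
        return round_percent(self.specificity)

    def summary(self) -> str:
        lo, hi = self.concordance_ci
        lines = [
            f"convention: {self.convention}",
            f"concordance: {self.concordance_percent()}% "
            f"({self.counts.total - len(self.discordant_ids)}/{self.counts.total}; "
            f"95% CI {round_percent(lo)}-{round_percent(hi)}%)",
            f"sensitivity: {self.sensitivity_percent()}% "
            f"({self.counts.tp}/{self.counts.positives})",
            f"specificity: {self.specificity_percent()}% "
            f"({self.counts.tn}/{self.counts.negatives})",
            "discordant: " + (", ".join(self.discordant_ids) or "none"),
        ]
        return "\n".join(lines)


def round_percent(fraction: float, digits: int = 1) -> float:
    """Percentage rounded half away from zero (display convention)."""
    q = Decimal(1).scaleb(-digits)
    return float(
        (Decimal(repr(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP)
    )


def wilson_interval(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Two-sided Wilson score interval, no continuity correction."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"need 0 <= successes <= n, got {successes}/{n}")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    lower, upper = proportion_confint(
        successes, n, alpha=1.0 - confidence, method="wilson"
    )
    return float(lower), float(upper)


def _expected_match(call: SpeciesCall, label: str, convention: str) -> bool:
    value = call.value
    if convention == "morphological":
        if label == "target":
            return value == "target"
        # target_variant, nontarget_species, nontarget_hybrid all carry a
        # validated non-target expectation.
        return value in _NONTARGET_OK
    # genetic convention
    if label == "target":
        return value == "target"
    return value in _NONTARGET_OK  # nontarget and hybrid truths


def score_panel(
    calls: Mapping[str, SpeciesCall],
    sheet,
    convention: str,
) -> tuple[ConfusionCounts, DiagnosticReport]:
    """Score per-sample species calls against a sample sheet."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; use {CONVENTIONS}")
    ids = sheet.ids()
    missing = [s for s in ids if s not in calls]
    if missing:
        raise ValueError(f"no call for samples: {missing}")

    tp = fn = tn = fp = 0
    discordant: list[str] = []
    for sample_id in ids:
        call = calls[sample_id]
        truth = sheet.genetic_truth(sample_id)
        label = (
            sheet.morphological_label(sample_id)
            if convention == "morphological"
            else truth
        )
        ok = _expected_match(call, label, convention)
        if not ok:
            discordant.append(sample_id)
        if truth == "target":
            tp += ok
            fn += not ok
        else:
            tn += ok
            fp += not ok

    counts = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
    n = counts.total
    concordant = n - len(discordant)
    report = DiagnosticReport(
        convention=convention,
        counts=counts,
        concordance=concordant / n,
        concordance_ci=wilson_interval(concordant, n),
        sensitivity=counts.tp / counts.positives if counts.positives else float("nan"),
        specificity=counts.tn / counts.negatives if counts.negatives else float("nan"),
        discordant_ids=tuple(discordant),
    )
    return counts, report


def hybrid_index(
    genotypes: Sequence[int] | np.ndarray,
    diagnostic_alleles: Sequence[str],
) -> float:
    """Fraction of target-species alleles among non-missing diagnostic loci.

    1.0 for a pure target individual, 0.5 for an F1, 0.0 for a pure
    non-target; a BC1 toward the target expects 0.75.
    """
    codes = np.asarray(genotypes, dtype=int)
    alleles = np.asarray(diagnostic_alleles)
    if codes.shape != alleles.shape:
        raise ValueError("genotypes and diagnostic_alleles must align")
    called = codes != MISSING
    if not called.any():
        raise ValueError("all diagnostic genotypes are missing")
    codes = codes[called]
    alleles = alleles[called]
    target_alleles = np.where(alleles == "alt", codes, 2 - codes)
    return float(target_alleles.sum() / (2.0 * codes.size))


__all__ = [
    "CONVENTIONS",
    "ConfusionCounts",
    "DiagnosticReport",
    "round_percent",
    "wilson_interval",
    "score_panel",
    "hybrid_index",
]
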