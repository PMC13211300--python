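"""Synthetic genotype panels, fluorescence readings and gel band patterns.

The simulator emulates a 64-accession hybrid-swarm panel: two diverged
diploid populations (the target species and a sympatric non-target pool)
fixed for alternative alleles at a set of diagnostic loci, plus F1 hybrids,
optional first-generation backcrosses, one cryptic F1 whose morphology
matches the target purebreds, and atypical "variant" individuals that look
target-like but carry non-target alleles at the diagnostic loci.

Background (non-diagnostic) loci draw per-population allele frequencies from
independent Beta distributions.  Contamination is applied after genotype
assignment: negative-binomial read depth, locus-structured missingness
(GBS dropout concentrates in loci with polymorphic restriction sites, so a
fraction of "dirty" loci carries most of the missing and low-depth calls),
and a fraction of sites with low mapping quality.

Fluorescence points for KASP wells are drawn from class-conditional
bivariate Gaussians whose means are pairwise separated by many multiples of
the default noise so that a deterministic ratio caller recovers essentially
every class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import (
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    LocusMeta,
    MISSING,
    write_vcf,
)

# Re-export: panels are written with the shared VCF writer.
write_panel_vcf = write_vcf

SAMPLE_CLASSES = (
    "target_purebred",
    "target_variant",
    "cryptic_f1",
    "nontarget_species",
    "f1_hybrid",
    "bc1_target",
    "bc1_nontarget",
)

MORPH_LABELS = ("target", "target_variant", "nontarget_species", "nontarget_hybrid")
GENETIC_LABELS = ("target", "hybrid", "nontarget")

_CLASS_MORPH = {
    "target_purebred": "target",
    "cryptic_f1": "target",
    "target_variant": "target_variant",
    "nontarget_species": "nontarget_species",
    "f1_hybrid": "nontarget_hybrid",
    "bc1_target": "nontarget_hybrid",
    "bc1_nontarget": "nontarget_hybrid",
}
_CLASS_TRUTH = {
    "target_purebred": "target",
    "cryptic_f1": "hybrid",
    "target_variant": "nontarget",
    "nontarget_species": "nontarget",
    "f1_hybrid": "hybrid",
    "bc1_target": "hybrid",
    "bc1_nontarget": "hybrid",
}

#: Class-conditional endpoint-fluorescence means (FAM, HEX), normalized units.
#: The target homozygote sits on the HEX axis, the alternative homozygote on
#: the FAM axis, heterozygotes in the dual-signal region, no-template
#: controls near the origin.
FLUOR_CLASS_MEANS: dict[str, tuple[float, float]] = {
    "target_hom": (0.10, 1.00),
    "alt_hom": (1.00, 0.10),
    "het": (0.55, 0.55),
    "ntc": (0.05, 0.05),
}

#: Default isotropic Gaussian noise (intensity units) on each channel.  The
#: smallest pairwise distance between class means is ~0.64, i.e. 16 sigma,
#: and every ratio-caller decision boundary sits >= 3 sigma from the nearest
#: class mean, which guarantees >= 99% label recovery.
DEFAULT_FLUOR_NOISE_SD: float = 0.04


@dataclass(frozen=True)
class SimulationConfig:
    """Panel-generation parameters.

    ``class_counts`` maps sample classes (see :data:`SAMPLE_CLASSES`) to
    counts.  ``background_allele_freq_model`` gives the Beta(a, b) from which
    each population's background allele frequencies are drawn independently.
    Missingness is locus-structured: a ``locus_dropout_rate`` fraction of
    loci are "dirty" and receive a per-locus missing probability drawn
    uniformly from ``dirty_missing_range`` plus low-depth resampling at
    ``low_depth_rate``; clean loci only see the baseline ``missing_rate``.
    """

    n_loci: int = 2000
    n_fixed_diff: int = 200
    class_counts: Mapping[str, int] = field(
        default_factory=lambda: {"target_purebred": 2, "nontarget_species": 2}
    )
    background_allele_freq_model: tuple[float, float] = (2.0, 2.0)
    missing_rate: float = 0.002
    locus_dropout_rate: float = 0.30
    dirty_missing_range: tuple[float, float] = (0.05, 0.50)
    depth_mean: float = 90.0
    depth_dispersion: float = 5.0
    low_depth_rate: float = 0.01
    low_mapq_rate: float = 0.02
    fluorescence_noise_sd: float = DEFAULT_FLUOR_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 1 <= self.n_fixed_diff <= self.n_loci:
            raise ValueError("need 1 <= n_fixed_diff <= n_loci")
        unknown = set(self.class_counts) - set(SAMPLE_CLASSES)
        if unknown:
            raise ValueError(f"unknown sample classes: {sorted(unknown)}")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if sum(self.class_counts.values()) == 0:
            raise ValueError("at least one sample class must be non-empty")
        for name in ("missing_rate", "locus_dropout_rate", "low_depth_rate",
                     "low_mapq_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.fluorescence_noise_sd < 0:
            raise ValueError("fluorescence_noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return sum(self.class_counts.values())

    def without_contamination(self) -> "SimulationConfig":
        return replace(
            self,
            missing_rate=0.0,
            locus_dropout_rate=0.0,
            low_depth_rate=0.0,
            low_mapq_rate=0.0,
        )


@dataclass
class SampleSheet:
    """Per-sample morphological label, genetic truth and training flag."""

    frame: pd.DataFrame  # columns: id, morphological_label, genetic_truth, in_training

    REQUIRED = ("id", "morphological_label", "genetic_truth", "in_training")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame["id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        bad_morph = set(self.frame["morphological_label"]) - set(MORPH_LABELS)
        if bad_morph:
            raise ValueError(f"unknown morphological labels: {sorted(bad_morph)}")
        bad_truth = set(self.frame["genetic_truth"]) - set(GENETIC_LABELS)
        if bad_truth:
            raise ValueError(f"unknown genetic truth labels: {sorted(bad_truth)}")

    def ids(self) -> list[str]:
        return list(self.frame["id"])

    def training_ids(self) -> list[str]:
        return list(self.frame.loc[self.frame["in_training"], "id"])

    def morphological_label(self, sample_id: str) -> str:
        return self._lookup(sample_id, "morphological_label")

    def genetic_truth(self, sample_id: str) -> str:
        return self._lookup(sample_id, "genetic_truth")

    def _lookup(self, sample_id: str, column: str) -> str:
        rows = self.frame.loc[self.frame["id"] == sample_id, column]
        if rows.empty:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return str(rows.iloc[0])

    def to_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "SampleSheet":
        frame = pd.read_csv(path, sep="\t", dtype={"id": str})
        frame["in_training"] = frame["in_training"].astype(bool)
        return cls(frame)


@dataclass
class Panel:
    """A simulated panel with its generating truth."""

    gm: GenotypeMatrix  # contaminated (observed) matrix
    sheet: SampleSheet
    truth_genotypes: np.ndarray  # uncontaminated codes, samples x loci
    fixed_idx: np.ndarray  # locus indices of planted fixed differences
    diagnostic_allele: dict[int, str]  # locus index -> "ref"/"alt"
    sample_classes: list[str]
    config: SimulationConfig

    def truth_class_at(
        self, locus_index: int, sample_row: int, diagnostic_allele: str | None = None
    ) -> str:
        """Genotype class of one sample at a diagnostic locus.

        Classes follow the fluorescence nomenclature: ``target_hom`` (both
        alleles diagnostic), ``het``, ``alt_hom`` (no diagnostic allele).
        ``diagnostic_allele`` defaults to the planted one for the locus.
        """
        code = int(self.truth_genotypes[sample_row, locus_index])
        if diagnostic_allele is None:
            diagnostic_allele = self.diagnostic_allele[locus_index]
        diag_alt = diagnostic_allele == "alt"
        n_target = code if diag_alt else 2 - code
        return {2: "target_hom", 1: "het", 0: "alt_hom"}[n_target]

    def allele_pair_at(self, locus_index: int, sample_row: int) -> tuple[str, str]:
        code = int(self.truth_genotypes[sample_row, locus_index])
        return {
            HOM_REF: ("ref", "ref"),
            HET: ("ref", "alt"),
            HOM_ALT: ("alt", "alt"),
        }[code]


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _plan_loci(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[LocusMeta], np.ndarray, dict[int, str], dict[int, int]]:
    """Lay out locus metadata and the planted fixed-difference structure.

    Among the planted diagnostic loci, up to six get a large (~120 bp) InDel
    (dominant-SCAR material: the diagnostic allele is the deletion) and up to
    six a 21 bp InDel (codominant-SCAR material); the rest are SNPs.  The
    diagnostic allele of every planted InDel is the short allele.
    """
    n = config.n_loci
    fixed_idx = np.sort(rng.choice(n, size=config.n_fixed_diff, replace=False))
    fixed_set = set(int(i) for i in fixed_idx)

    big_indels: set[int] = set()
    small_indels: set[int] = set()
    if config.n_fixed_diff >= 12:
        picks = rng.choice(fixed_idx, size=12, replace=False)
        big_indels = set(int(i) for i in picks[:6])
        small_indels = set(int(i) for i in picks[6:])

    loci: list[LocusMeta] = []
    diagnostic: dict[int, str] = {}
    indel_diff: dict[int, int] = {}
    pos = 0
    for j in range(n):
        chrom = f"ptg{j // 250:05d}l"
        if j % 250 == 0:
            pos = 0
        pos += int(rng.integers(200, 2000))
        anchor = str(rng.choice(_BASES))
        if j in big_indels or j in small_indels:
            seg_len = 120 if j in big_indels else 21
            ref = anchor + _random_seq(rng, seg_len)
            alt = anchor
            diagnostic[j] = "alt"  # target carries the deletion (short) allele
            indel_diff[j] = seg_len
        elif j in fixed_set:
            ref = anchor
            alt = str(rng.choice([b for b in "ACGT" if b != anchor]))
            diagnostic[j] = str(rng.choice(["ref", "alt"]))
        elif rng.random() < 0.05:  # background short InDel
            seg_len = int(rng.integers(1, 9))
            ref = anchor + _random_seq(rng, seg_len)
            alt = anchor
        else:
            ref = anchor
            alt = str(rng.choice([b for b in "ACGT" if b != anchor]))
        loci.append(LocusMeta(chrom=chrom, pos=pos, ref=ref, alt=alt))
    return loci, fixed_idx, diagnostic, indel_diff


def _population_freqs(
    config: SimulationConfig,
    rng: np.random.Generator,
    fixed_idx: np.ndarray,
    diagnostic: dict[int, str],
) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele frequencies per locus for the two parental populations."""
    a, b = config.background_allele_freq_model
    p1 = rng.beta(a, b, size=config.n_loci)  # target population
    p2 = rng.beta(a, b, size=config.n_loci)  # non-target pool
    for j in fixed_idx:
        if diagnostic[int(j)] == "alt":
            p1[j], p2[j] = 1.0, 0.0
        else:
            p1[j], p2[j] = 0.0, 1.0
    return p1, p2


def _class_genotypes(
    cls: str,
    count: int,
    p1: np.ndarray,
    p2: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw truth genotype codes (count x loci) for one sample class.

    At planted loci the population frequencies are 0/1, so the same allele
    draws produce the exact diagnostic structure: purebreds homozygous for
    the target allele, F1s obligate heterozygotes, BC1s heterozygous at each
    locus independently with probability 1/2.
    """
    m = p1.shape[0]
    p_f1_gamete = 0.5 * (p1 + p2)  # allele from an F1 parent
    parents = {
        "target_purebred": (p1, p1),
        "target_variant": (p2, p2),
        "nontarget_species": (p2, p2),
        "cryptic_f1": (p1, p2),
        "f1_hybrid": (p1, p2),
        "bc1_target": (p1, p_f1_gamete),
        "bc1_nontarget": (p2, p_f1_gamete),
    }
    pa, pb = parents[cls]
    allele_a = rng.random((count, m)) < pa
    allele_b = rng.random((count, m)) < pb
    return (allele_a.astype(np.int8) + allele_b.astype(np.int8))


def simulate_panel_full(config: SimulationConfig) -> Panel:
    """Generate a full panel (truth + contaminated observation + sheet)."""
    rng = np.random.default_rng(config.seed)
    loci, fixed_idx, diagnostic, _ = _plan_loci(config, rng)
    p1, p2 = _population_freqs(config, rng, fixed_idx, diagnostic)

    classes: list[str] = []
    blocks: list[np.ndarray] = []
    for cls in SAMPLE_CLASSES:
        count = int(config.class_counts.get(cls, 0))
        if count == 0:
            continue
        classes.extend([cls] * count)
        blocks.append(_class_genotypes(cls, count, p1, p2, rng))
    truth = np.concatenate(blocks, axis=0)
    n_samples = truth.shape[0]
    width = max(2, len(str(n_samples)))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n_samples)]

    # --- contamination, applied after genotype assignment ---------------
    n_loci = config.n_loci
    p_nb = config.depth_dispersion / (config.depth_dispersion + config.depth_mean)
    depth = rng.negative_binomial(config.depth_dispersion, p_nb, size=truth.shape)

    dirty = rng.random(n_loci) < config.locus_dropout_rate
    lo, hi = config.dirty_missing_range
    miss_p = np.where(
        dirty, rng.uniform(lo, hi, size=n_loci), config.missing_rate
    )
    missing_mask = rng.random(truth.shape) < miss_p[None, :]

    low_depth_mask = (rng.random(truth.shape) < config.low_depth_rate) & dirty[None, :]
    depth[low_depth_mask] = rng.integers(0, 3, size=int(low_depth_mask.sum()))

    low_mq = rng.random(n_loci) < config.low_mapq_rate
    mapq = np.where(low_mq, rng.uniform(5.0, 19.9, n_loci), rng.uniform(40.0, 60.0, n_loci))
    loci = [replace(loc, site_mapq=float(q)) for loc, q in zip(loci, mapq)]

    observed = truth.astype(np.int8).copy()
    observed[missing_mask] = MISSING

    gm = GenotypeMatrix(sample_ids, loci, observed, depth.astype(np.int64))
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "id": sample_ids,
                "morphological_label": [_CLASS_MORPH[c] for c in classes],
                "genetic_truth": [_CLASS_TRUTH[c] for c in classes],
                "in_training": [
                    _CLASS_MORPH[c] in ("target", "target_variant") for c in classes
                ],
            }
        )
    )
    return Panel(
        gm=gm,
        sheet=sheet,
        truth_genotypes=truth,
        fixed_idx=fixed_idx,
        diagnostic_allele=diagnostic,
        sample_classes=classes,
        config=config,
    )


def simulate_panel(config: SimulationConfig) -> tuple[GenotypeMatrix, SampleSheet]:
    """Generate a panel; returns the observed matrix and the sample sheet."""
    panel = simulate_panel_full(config)
    return panel.gm, panel.sheet


# ---------------------------------------------------------------------------
# Assay-level observation models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluorescenceTruth:
    sample_id: str
    assay: str
    genotype_class: str  # key of FLUOR_CLASS_MEANS


def simulate_fluorescence(
    assay_calls_truth: Sequence[FluorescenceTruth] | Sequence[tuple[str, str, str]],
    noise_sd: float = DEFAULT_FLUOR_NOISE_SD,
    seed: int = 0,
):
    """Draw one two-channel endpoint-fluorescence point per truth record.

    Each point is the class-conditional mean plus isotropic Gaussian noise,
    clipped to non-negative intensities.  With ``noise_sd = 0`` points sit
    exactly on the class means.
    """
    from .assay_caller import FluorescencePoint

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    points = []
    for record in assay_calls_truth:
        if isinstance(record, FluorescenceTruth):
            sample_id, assay, cls = record.sample_id, record.assay, record.genotype_class
        else:
            sample_id, assay, cls = record
        if cls not in FLUOR_CLASS_MEANS:
            raise ValueError(f"unknown genotype class {cls!r}")
        fam_mu, hex_mu = FLUOR_CLASS_MEANS[cls]
        fam, hx = rng.normal([fam_mu, hex_mu], noise_sd)
        points.append(
            FluorescencePoint(
                sample_id=sample_id,
                assay=assay,
                fam=float(max(0.0, fam)),
                hex=float(max(0.0, hx)),
            )
        )
    return points


def simulate_scar_bands(
    genotypes: Mapping[str, tuple[str, str]],
    assay,
) -> list:
    """Band pattern per sample: union of the sizes mapped from its alleles.

    ``genotypes`` maps sample id to a pair of allele names ("ref"/"alt").
    A homozygote for a no-band (null) allele yields an empty pattern.
    """
    from .assay_caller import BandPattern

    patterns = []
    for sample_id, pair in genotypes.items():
        sizes = set()
        for allele in pair:
            if allele not in assay.size_map:
                raise KeyError(
                    f"allele {allele!r} of sample {sample_id} not in assay size map"
                )
            size = assay.size_map[allele]
            if size is not None:
                sizes.add(int(size))
        patterns.append(
            BandPattern(sample_id=sample_id, assay=assay.name, sizes=frozenset(sizes))
        )
    return patterns


def simulate_flanks(
    panel: Panel,
    locus_indices: Iterable[int],
    flank: int = 250,
    seed: int | None = None,
) -> dict[int, tuple[str, int]]:
    """Synthetic reference flanks for chosen loci.

    Returns ``{locus_index: (sequence, variant_offset)}`` where the sequence
    contains the reference allele starting at ``variant_offset`` (0-based).
    Base composition is uniform (~50% GC) so primer design has material to
    work with.
    """
    rng = np.random.default_rng(panel.config.seed + 7 if seed is None else seed)
    flanks: dict[int, tuple[str, int]] = {}
    for j in locus_indices:
        locus = panel.gm.loci[j]
        left = _random_seq(rng, flank)
        right = _random_seq(rng, flank)
        flanks[int(j)] = (left + locus.ref + right, flank)
    return flanks


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------

#: 64-accession hybrid-swarm composition: 32 purebred targets, one cryptic F1
#: among the morphologically typical individuals, 3 atypical variants, 16
#: non-target species accessions and 12 F1 hybrids (33/3/16/12 by
#: morphological label).
SCENARIO_CLASS_COUNTS: dict[str, dict[str, int]] = {
    "S1": {
        "target_purebred": 32,
        "cryptic_f1": 1,
        "target_variant": 3,
        "nontarget_species": 16,
        "f1_hybrid": 12,
    },
    "S2": {
        "target_purebred": 32,
        "cryptic_f1": 1,
        "target_variant": 3,
        "nontarget_species": 16,
        "f1_hybrid": 12,
    },
}


def scenario_config(name: str, seed: int = 0) -> SimulationConfig:
    """Configuration for a named scenario ("S1": KASP panel, "S2": SCAR panel)."""
    if name not in SCENARIO_CLASS_COUNTS:
        raise ValueError(
            f"unknown scenario {name!r}; known: {sorted(SCENARIO_CLASS_COUNTS)}"
        )
    return SimulationConfig(class_counts=SCENARIO_CLASS_COUNTS[name], seed=seed)


__all__ = [
    "SAMPLE_CLASSES",
    "MORPH_LABELS",
    "GENETIC_LABELS",
    "FLUOR_CLASS_MEANS",
    "DEFAULT_FLUOR_NOISE_SD",
    "SimulationConfig",
    "SampleSheet",
    "Panel",
    "simulate_panel",
    "simulate_panel_full",
    "simulate_fluorescence",
    "simulate_scar_bands",
    "simulate_flanks",
    "scenario_config",
    "SCENARIO_CLASS_COUNTS",
    "write_panel_vcf",
    "FluorescenceTruth",
]
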