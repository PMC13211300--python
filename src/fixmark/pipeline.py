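"""End-to-end orchestration: simulate -> filter -> mine -> call -> score.

Two named scenarios reproduce the validation conditions of the marker set:

* ``S1`` ("KASP panel"): the 64-accession composition with one cryptic F1
  hidden among the morphologically typical target individuals.  Three KASP
  assays are read from simulated endpoint fluorescence and scored against
  both the morphological and the genetic labelling.
* ``S2`` ("SCAR panel"): as S1, but at the two SCAR loci one additional
  purebred yields the heterozygous combined band pattern (incomplete
  lineage sorting at the assay loci), so the merged two-locus framework
  shows two discordant samples against morphology.

Assay definitions carry the validated marker set's primer sequences and
expected amplicon sizes (Ca-KASP1-3, Ca-SCAR1-2); mining is run first and
the assay loci are taken from the mined stage-2 candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay_caller import (
    BandPattern,
    FluorescencePoint,
    SpeciesCall,
    call_kasp,
    call_scar2,
    combined_scar_classify,
    kasp_species_call,
)
from .assay_designer import KaspAssay, ScarAssay
from .diagnostics import DiagnosticReport, hybrid_index, score_panel
from .fixed_allele_miner import CandidateLocus, two_stage_mining
from .panel_simulator import (
    Panel,
    SimulationConfig,
    scenario_config,
    simulate_fluorescence,
    simulate_panel_full,
    simulate_scar_bands,
)
from .variant_filters import FilterReport, FilterThresholds, filter_loci
from .variant_io import GenotypeMatrix

#: Validated KASP marker set: allele-specific primer pairs differing at the
#: 3' discriminating base (or spanning the InDel junction for Ca-KASP3); the
#: HEX dye reports the target-species allele.
VALIDATED_KASP_PRIMERS: dict[str, dict[str, str]] = {
    "Ca-KASP1": {
        "FAM": "TCCACTTCAAGAACCACCTCCGCTCC",
        "HEX": "TCCACTTCAAGAACCACCTCCGCTCT",
        "common": "AGGGACTCACTAAGCTGATTACGGATGC",
    },
    "Ca-KASP2": {
        "FAM": "AGTTTGGCATCCAAGAGAGTCCTTAGACGC",
        "HEX": "AGTTTGGCATCCAAGAGAGTCCTTAGACGT",
        "common": "GCACTATTTGTGGTCCTACATGCTTTCTGA",
    },
    "Ca-KASP3": {
        "FAM": "CATGAGTGCAAATTGACCTCAAGGAAA",
        "HEX": "GCATGAGTGCAAATTGACCTCAACATA",
        "common": "GCCATATTTAGTCATGTGAGGGGTTGTT",
    },
}

#: Validated SCAR marker set.  Ca-SCAR1 is dominant: the target allele is a
#: null (no amplification), the non-target allele yields a 116 bp band.
#: Ca-SCAR2 is codominant: 516 bp (target) vs 537 bp.
VALIDATED_SCAR_PRIMERS: dict[str, dict[str, str]] = {
    "Ca-SCAR1": {
        "forward": "CATGAGTGCAAATTGACCTCAAGGAAA",
        "reverse": "GCCATATTTAGTCATGTGAGGGGTTGTT",
    },
    "Ca-SCAR2": {
        "forward": "AGCATGAGAGGGCGCAAAGG",
        "reverse": "AACGCATCCCCAATCCCTGC",
    },
}

SCAR1_BAND_SIZE = 116
SCAR2_TARGET_SIZE = 516
SCAR2_OTHER_SIZE = 537

N_KASP_ASSAYS = 3


@dataclass
class ScenarioResult:
    name: str
    seed: int
    panel: Panel
    filtered_gm: GenotypeMatrix
    filter_report: FilterReport
    stage1: list[CandidateLocus]
    stage2: list[CandidateLocus]
    kasp_assays: list[KaspAssay]
    kasp_loci: list[int]
    fluorescence: list[FluorescencePoint]
    kasp_genotype_calls: dict[str, dict[str, str]]  # sample -> assay -> class
    kasp_calls: dict[str, SpeciesCall]
    kasp_report_morphological: DiagnosticReport
    kasp_report_genetic: DiagnosticReport
    scar_assays: list[ScarAssay]
    scar_loci: list[int]
    bands: list[BandPattern]
    scar_calls: dict[str, SpeciesCall]
    scar_report_morphological: DiagnosticReport
    scar_report_genetic: DiagnosticReport
    warnings: list[str] = field(default_factory=list)


def _select_kasp_loci(
    stage2: list[CandidateLocus], panel: Panel
) -> tuple[list[int], list[str], list[str]]:
    """Pick assay loci (2 SNP + 1 InDel when available) from stage-2 output."""
    notes: list[str] = []
    snps = [c for c in stage2 if c.locus.variant_type == "SNP" and c.kasp_eligible]
    indels = [c for c in stage2 if c.locus.variant_type == "InDel" and c.kasp_eligible]
    chosen = snps[:2] + indels[:1]
    if len(chosen) < N_KASP_ASSAYS:
        pool = [c for c in stage2 if c not in chosen]
        chosen += pool[: N_KASP_ASSAYS - len(chosen)]
    if len(chosen) < N_KASP_ASSAYS:
        notes.append(
            "stage-2 mining yielded fewer than three KASP-eligible loci; "
            "falling back to planted diagnostic loci"
        )
        have = {c.locus_index for c in chosen}
        loci_idx = [c.locus_index for c in chosen]
        for j in panel.fixed_idx:
            if int(j) not in have:
                loci_idx.append(int(j))
            if len(loci_idx) == N_KASP_ASSAYS:
                break
        diags = [panel.diagnostic_allele[j] for j in loci_idx]
        return loci_idx, diags, notes
    return (
        [c.locus_index for c in chosen],
        [c.diagnostic_allele for c in chosen],
        notes,
    )


def _indel_len_diff(panel: Panel, j: int) -> int:
    loc = panel.gm.loci[j]
    return abs(len(loc.ref) - len(loc.alt))


def _select_scar_loci(
    stage2: list[CandidateLocus], panel: Panel
) -> tuple[int, int, list[str]]:
    """Pick the dominant (large deletion) and codominant SCAR loci."""
    notes: list[str] = []
    eligible = [c.locus_index for c in stage2 if c.scar_eligible]
    big = [j for j in eligible if _indel_len_diff(panel, j) >= 100]
    small = [j for j in eligible if 20 <= _indel_len_diff(panel, j) < 100]
    if not big or not small:
        notes.append(
            "stage-2 mining yielded no SCAR-eligible locus of the required "
            "size class; falling back to planted InDel loci"
        )
        planted = [int(j) for j in panel.fixed_idx]
        big = big or [j for j in planted if _indel_len_diff(panel, j) >= 100]
        small = small or [
            j for j in planted if 20 <= _indel_len_diff(panel, j) < 100
        ]
    if not big or not small:
        raise RuntimeError("panel contains no suitable SCAR InDel loci")
    return big[0], small[0], notes


def _scar_assays(panel: Panel, scar1_locus: int, scar2_locus: int) -> list[ScarAssay]:
    diag1 = panel.diagnostic_allele[scar1_locus]
    diag2 = panel.diagnostic_allele[scar2_locus]
    other1 = "alt" if diag1 == "ref" else "ref"
    other2 = "alt" if diag2 == "ref" else "ref"
    scar1 = ScarAssay(
        name="Ca-SCAR1",
        forward_primer=VALIDATED_SCAR_PRIMERS["Ca-SCAR1"]["forward"],
        reverse_primer=VALIDATED_SCAR_PRIMERS["Ca-SCAR1"]["reverse"],
        size_map={diag1: None, other1: SCAR1_BAND_SIZE},
        mode="dominant",
        diagnostic_allele=diag1,
        locus=panel.gm.loci[scar1_locus],
    )
    scar2 = ScarAssay(
        name="Ca-SCAR2",
        forward_primer=VALIDATED_SCAR_PRIMERS["Ca-SCAR2"]["forward"],
        reverse_primer=VALIDATED_SCAR_PRIMERS["Ca-SCAR2"]["reverse"],
        size_map={diag2: SCAR2_TARGET_SIZE, other2: SCAR2_OTHER_SIZE},
        mode="codominant",
        diagnostic_allele=diag2,
        locus=panel.gm.loci[scar2_locus],
    )
    return [scar1, scar2]


def _scar_het_override_ids(name: str, panel: Panel) -> set[str]:
    """S2 designates one purebred whose SCAR loci read heterozygous."""
    if name != "S2":
        return set()
    purebred_rows = [
        i for i, c in enumerate(panel.sample_classes) if c == "target_purebred"
    ]
    return {panel.gm.sample_ids[purebred_rows[-1]]}


def run_scenario(
    name: str,
    seed: int = 0,
    *,
    contamination: bool = True,
    thresholds: FilterThresholds = FilterThresholds(),
    config: SimulationConfig | None = None,
) -> ScenarioResult:
    """Run the whole pipeline on a named scenario."""
    if config is None:
        config = scenario_config(name, seed=seed)
    if not contamination:
        config = config.without_contamination()
    panel = simulate_panel_full(config)
    sheet = panel.sheet
    notes: list[str] = []

    # -- QC cascade within the morphologically typical target population --
    hwe_population = [
        s
        for s in sheet.ids()
        if sheet.morphological_label(s) == "target"
    ]
    filtered_gm, filter_report = filter_loci(panel.gm, thresholds, hwe_population)

    # -- two-stage mining (on the filtered loci) --------------------------
    # The reclassified ids are the training samples whose molecular identity
    # is not purebred target: the cryptic hybrid flagged by assay validation
    # plus the excluded atypical variants.
    reclassified = [
        s
        for s in sheet.training_ids()
        if sheet.genetic_truth(s) != "target"
    ]
    stage1, stage2 = two_stage_mining(filtered_gm, sheet, reclassified)
    # Map candidate indices back to panel locus indices.
    filtered_labels = {i: loc.label for i, loc in enumerate(filtered_gm.loci)}
    panel_index = {loc.label: j for j, loc in enumerate(panel.gm.loci)}
    stage1 = [_reindex(c, panel_index, filtered_labels) for c in stage1]
    stage2 = [_reindex(c, panel_index, filtered_labels) for c in stage2]

    # -- KASP assays -------------------------------------------------------
    kasp_loci, kasp_diag, kasp_notes = _select_kasp_loci(stage2, panel)
    notes.extend(kasp_notes)
    kasp_names = list(VALIDATED_KASP_PRIMERS)[: len(kasp_loci)]
    kasp_assays = []
    for assay_name, j, diag in zip(kasp_names, kasp_loci, kasp_diag):
        primers = VALIDATED_KASP_PRIMERS[assay_name]
        other = "alt" if diag == "ref" else "ref"
        allele_primers = {diag: primers["HEX"], other: primers["FAM"]}
        kasp_assays.append(
            KaspAssay(
                name=assay_name,
                allele_ref_primer=allele_primers["ref"],
                allele_alt_primer=allele_primers["alt"],
                common_primer=primers["common"],
                dye_map={diag: "HEX", other: "FAM"},
                diagnostic_allele=diag,
            )
        )

    rng = np.random.default_rng(seed)
    fluorescence: list[FluorescencePoint] = []
    for assay_name, j, diag in zip(kasp_names, kasp_loci, kasp_diag):
        truth = [
            (sample_id, assay_name, panel.truth_class_at(j, row, diag))
            for row, sample_id in enumerate(panel.gm.sample_ids)
        ]
        truth += [(f"NTC{k}", assay_name, "ntc") for k in (1, 2)]
        fluorescence.extend(
            simulate_fluorescence(
                truth,
                noise_sd=config.fluorescence_noise_sd,
                seed=int(rng.integers(2**31)),
            )
        )

    kasp_genotype_calls: dict[str, dict[str, str]] = {}
    for point in fluorescence:
        kasp_genotype_calls.setdefault(point.sample_id, {})[point.assay] = call_kasp(
            point
        )
    kasp_calls = {
        sample_id: kasp_species_call(
            [kasp_genotype_calls[sample_id][a] for a in kasp_names]
        )
        for sample_id in panel.gm.sample_ids
    }
    _, kasp_morph = score_panel(kasp_calls, sheet, "morphological")
    _, kasp_gen = score_panel(kasp_calls, sheet, "genetic")

    # -- SCAR assays -------------------------------------------------------
    scar1_locus, scar2_locus, scar_notes = _select_scar_loci(stage2, panel)
    notes.extend(scar_notes)
    scar_assays = _scar_assays(panel, scar1_locus, scar2_locus)
    override = _scar_het_override_ids(name, panel)

    bands: list[BandPattern] = []
    for assay, locus_idx in zip(scar_assays, (scar1_locus, scar2_locus)):
        genotypes = {}
        for row, sample_id in enumerate(panel.gm.sample_ids):
            if sample_id in override:
                genotypes[sample_id] = ("ref", "alt")
            else:
                genotypes[sample_id] = panel.allele_pair_at(locus_idx, row)
        bands.extend(simulate_scar_bands(genotypes, assay))

    by_assay: dict[str, dict[str, BandPattern]] = {}
    for pattern in bands:
        by_assay.setdefault(pattern.assay, {})[pattern.sample_id] = pattern
    scar_calls: dict[str, SpeciesCall] = {}
    for sample_id in panel.gm.sample_ids:
        scar1_present = len(by_assay["Ca-SCAR1"][sample_id].sizes) > 0
        scar2 = call_scar2(by_assay["Ca-SCAR2"][sample_id], scar_assays[1])
        scar_calls[sample_id] = combined_scar_classify(scar1_present, scar2.pattern)
    _, scar_morph = score_panel(scar_calls, sheet, "morphological")
    _, scar_gen = score_panel(scar_calls, sheet, "genetic")

    for note in notes:
        warnings.warn(note, stacklevel=2)

    return ScenarioResult(
        name=name,
        seed=seed,
        panel=panel,
        filtered_gm=filtered_gm,
        filter_report=filter_report,
        stage1=stage1,
        stage2=stage2,
        kasp_assays=kasp_assays,
        kasp_loci=kasp_loci,
        fluorescence=fluorescence,
        kasp_genotype_calls=kasp_genotype_calls,
        kasp_calls=kasp_calls,
        kasp_report_morphological=kasp_morph,
        kasp_report_genetic=kasp_gen,
        scar_assays=scar_assays,
        scar_loci=[scar1_locus, scar2_locus],
        bands=bands,
        scar_calls=scar_calls,
        scar_report_morphological=scar_morph,
        scar_report_genetic=scar_gen,
        warnings=notes,
    )


def _reindex(cand: CandidateLocus, panel_index, filtered_labels) -> CandidateLocus:
    label = filtered_labels[cand.locus_index]
    return CandidateLocus(
        locus_index=panel_index[label],
        locus=cand.locus,
        diagnostic_allele=cand.diagnostic_allele,
        stage=cand.stage,
        n_reference_support=cand.n_reference_support,
        kasp_eligible=cand.kasp_eligible,
        scar_eligible=cand.scar_eligible,
    )


# ---------------------------------------------------------------------------
# Hybrid-index helpers
# ---------------------------------------------------------------------------


def simulate_hybrid_indices(
    class_counts: dict[str, int],
    n_diagnostic: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Hybrid index per sample from an uncontaminated diagnostic panel."""
    config = SimulationConfig(
        n_loci=n_diagnostic,
        n_fixed_diff=n_diagnostic,
        class_counts=class_counts,
        seed=seed,
    ).without_contamination()
    panel = simulate_panel_full(config)
    alleles = np.array(
        [panel.diagnostic_allele[int(j)] for j in panel.fixed_idx]
    )
    rows = []
    for row, sample_id in enumerate(panel.gm.sample_ids):
        codes = panel.gm.genotypes[row, panel.fixed_idx]
        rows.append(
            {
                "id": sample_id,
                "class": panel.sample_classes[row],
                "hybrid_index": hybrid_index(codes, alleles),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabular output helpers (used by the CLI)
# ---------------------------------------------------------------------------


def fluorescence_frame(points: list[FluorescencePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample": p.sample_id, "assay": p.assay, "fam": p.fam, "hex": p.hex}
            for p in points
        ]
    )


def bands_frame(patterns: list[BandPattern]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": b.sample_id,
                "assay": b.assay,
                "sizes": ",".join(str(s) for s in sorted(b.sizes)),
            }
            for b in patterns
        ]
    )


def calls_frame(calls: dict[str, SpeciesCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": s,
                "call": c.value,
                "low_confidence": c.low_confidence,
            }
            for s, c in calls.items()
        ]
    )


__all__ = [
    "VALIDATED_KASP_PRIMERS",
    "VALIDATED_SCAR_PRIMERS",
    "ScenarioResult",
    "run_scenario",
    "simulate_hybrid_indices",
    "fluorescence_frame",
    "bands_frame",
    "calls_frame",
]
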