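"""Generative structure of the synthetic hybrid-swarm panels."""

import numpy as np
import pytest
from scipy.stats import binom

from fixmark.assay_designer import ScarAssay
from fixmark.panel_simulator import (
    DEFAULT_FLUOR_NOISE_SD,
    FLUOR_CLASS_MEANS,
    SimulationConfig,
    SampleSheet,
    scenario_config,
    simulate_fluorescence,
    simulate_panel_full,
    simulate_scar_bands,
)
from fixmark.variant_io import HET, MISSING, write_vcf


def _clean(counts, n_loci=100, n_fixed=20, seed=0, **kw):
    return SimulationConfig(
        n_loci=n_loci, n_fixed_diff=n_fixed, class_counts=counts, seed=seed, **kw
    ).without_contamination()


def _target_hom_code(panel, j):
    from fixmark.variant_io import HOM_ALT, HOM_REF

    return HOM_ALT if panel.diagnostic_allele[int(j)] == "alt" else HOM_REF


class TestConfigValidation:
    def test_rejects_zero_samples(self):
        with pytest.raises(ValueError):
            SimulationConfig(class_counts={})

    def test_rejects_more_fixed_than_loci(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                n_loci=10, n_fixed_diff=11, class_counts={"f1_hybrid": 1}
            )

    def test_rejects_unknown_class(self):
        with pytest.raises(ValueError):
            SimulationConfig(class_counts={"martian": 3})

    def test_scenario_lookup(self):
        cfg = scenario_config("S1", seed=4)
        assert sum(cfg.class_counts.values()) == 64
        assert cfg.class_counts["target_purebred"] == 32
        with pytest.raises(ValueError):
            scenario_config("S9")


class TestPlantedStructure:
    def test_f1_is_obligate_heterozygote_at_fixed_loci(self):
        panel = simulate_panel_full(
            _clean({"target_purebred": 2, "nontarget_species": 2, "f1_hybrid": 1},
                   n_fixed=50)
        )
        row = panel.sample_classes.index("f1_hybrid")
        genotypes = panel.gm.genotypes[row, panel.fixed_idx]
        assert (genotypes == HET).all() and len(genotypes) == 50

    def test_purebred_homozygous_for_target_allele_everywhere(self):
        panel = simulate_panel_full(
            _clean({"target_purebred": 3, "nontarget_species": 2}, n_fixed=40)
        )
        for row, cls in enumerate(panel.sample_classes):
            if cls != "target_purebred":
                continue
            for j in panel.fixed_idx:
                assert panel.gm.genotypes[row, j] == _target_hom_code(panel, j)

    def test_variant_carries_nontarget_allele_at_fixed_loci(self):
        panel = simulate_panel_full(
            _clean({"target_purebred": 2, "target_variant": 2,
                    "nontarget_species": 2}, n_fixed=30)
        )
        for row, cls in enumerate(panel.sample_classes):
            if cls != "target_variant":
                continue
            for j in panel.fixed_idx:
                assert panel.gm.genotypes[row, j] != _target_hom_code(panel, j)
                assert panel.gm.genotypes[row, j] != HET

    def test_bc1_heterozygosity_within_binomial_99_interval(self):
        n_loci = 200
        panel = simulate_panel_full(
            _clean({"target_purebred": 1, "nontarget_species": 1, "bc1_target": 1},
                   n_loci=300, n_fixed=n_loci, seed=2)
        )
        row = panel.sample_classes.index("bc1_target")
        n_het = int((panel.gm.genotypes[row, panel.fixed_idx] == HET).sum())
        lo, hi = binom.ppf([0.005, 0.995], n_loci, 0.5)
        assert lo <= n_het <= hi


class TestReproducibility:
    def test_same_seed_gives_byte_identical_vcf(self, tmp_path):
        cfg = scenario_config("S1", seed=123)
        a = simulate_panel_full(cfg)
        b = simulate_panel_full(cfg)
        pa, pb = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(a.gm, str(pa))
        write_vcf(b.gm, str(pb))
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seed_differs(self):
        cfg = _clean({"target_purebred": 4, "nontarget_species": 4})
        a = simulate_panel_full(cfg)
        b = simulate_panel_full(
            SimulationConfig(**{**cfg.__dict__, "seed": cfg.seed + 1})
        )
        assert (a.gm.genotypes != b.gm.genotypes).any()


class TestContamination:
    def test_contamination_only_adds_missingness(self):
        cfg = SimulationConfig(
            n_loci=400, n_fixed_diff=20, seed=5,
            class_counts={"target_purebred": 8, "nontarget_species": 8},
        )
        panel = simulate_panel_full(cfg)
        observed, truth = panel.gm.genotypes, panel.truth_genotypes
        changed = observed != truth
        assert observed[changed].max(initial=MISSING) == MISSING
        assert changed.mean() > 0.01  # contamination actually happened

    def test_low_mapq_fraction_is_plausible(self):
        cfg = SimulationConfig(
            n_loci=2000, n_fixed_diff=20, seed=8,
            class_counts={"target_purebred": 2, "nontarget_species": 2},
        )
        panel = simulate_panel_full(cfg)
        frac = (panel.gm.site_mapq() < 20).mean()
        assert 0.005 < frac < 0.05  # nominal rate 0.02


class TestSampleSheet:
    def test_scenario_composition_and_labels(self):
        panel = simulate_panel_full(scenario_config("S1", seed=0))
        sheet = panel.sheet
        labels = sheet.frame["morphological_label"].value_counts().to_dict()
        assert labels == {
            "target": 33,
            "target_variant": 3,
            "nontarget_species": 16,
            "nontarget_hybrid": 12,
        }
        assert len(sheet.training_ids()) == 36
        cryptic = [
            s
            for s in sheet.ids()
            if sheet.morphological_label(s) == "target"
            and sheet.genetic_truth(s) == "hybrid"
        ]
        assert len(cryptic) == 1

    def test_tsv_roundtrip(self, tmp_path):
        panel = simulate_panel_full(
            _clean({"target_purebred": 2, "f1_hybrid": 1, "nontarget_species": 1})
        )
        path = tmp_path / "sheet.tsv"
        panel.sheet.to_tsv(str(path))
        back = SampleSheet.from_tsv(str(path))
        assert back.frame.equals(panel.sheet.frame)

    def test_duplicate_ids_rejected(self):
        frame = simulate_panel_full(
            _clean({"target_purebred": 2, "nontarget_species": 1})
        ).sheet.frame.copy()
        frame.loc[1, "id"] = frame.loc[0, "id"]
        with pytest.raises(ValueError):
            SampleSheet(frame)


class TestFluorescence:
    def test_zero_noise_sits_on_class_means(self):
        points = simulate_fluorescence(
            [("a", "K1", "het"), ("ntc", "K1", "ntc")], noise_sd=0.0, seed=1
        )
        assert (points[0].fam, points[0].hex) == FLUOR_CLASS_MEANS["het"]
        assert (points[1].fam, points[1].hex) == FLUOR_CLASS_MEANS["ntc"]

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_fluorescence([("a", "K1", "het")], noise_sd=-0.1)

    def test_class_means_separated_by_six_sigma(self):
        means = list(FLUOR_CLASS_MEANS.values())
        for i in range(len(means)):
            for k in range(i + 1, len(means)):
                dist = np.hypot(
                    means[i][0] - means[k][0], means[i][1] - means[k][1]
                )
                assert dist >= 6 * DEFAULT_FLUOR_NOISE_SD

    def test_reproducible_from_seed(self):
        truth = [("a", "K1", "target_hom"), ("b", "K1", "alt_hom")]
        p1 = simulate_fluorescence(truth, seed=9)
        p2 = simulate_fluorescence(truth, seed=9)
        assert p1 == p2


@pytest.fixture
def codominant_assay():
    return ScarAssay(
        name="Ca-SCAR2",
        forward_primer="AGCATGAGAGGGCGCAAAGG",
        reverse_primer="AACGCATCCCCAATCCCTGC",
        size_map={"alt": 516, "ref": 537},
        mode="codominant",
        diagnostic_allele="alt",
    )


@pytest.fixture
def dominant_assay():
    return ScarAssay(
        name="Ca-SCAR1",
        forward_primer="CATGAGTGCAAATTGACCTCAAGGAAA",
        reverse_primer="GCCATATTTAGTCATGTGAGGGGTTGTT",
        size_map={"alt": None, "ref": 116},
        mode="dominant",
        diagnostic_allele="alt",
    )


class TestScarBands:
    def test_homozygous_null_gives_empty_pattern(self, dominant_assay):
        (pattern,) = simulate_scar_bands({"s": ("alt", "alt")}, dominant_assay)
        assert pattern.sizes == frozenset()

    def test_dominant_heterozygote_shows_single_band(self, dominant_assay):
        (pattern,) = simulate_scar_bands({"s": ("ref", "alt")}, dominant_assay)
        assert pattern.sizes == frozenset({116})

    def test_codominant_heterozygote_shows_both_sizes(self, codominant_assay):
        (pattern,) = simulate_scar_bands({"s": ("ref", "alt")}, codominant_assay)
        assert pattern.sizes == frozenset({516, 537})

    def test_codominant_target_homozygote_single_band(self, codominant_assay):
        (pattern,) = simulate_scar_bands({"s": ("alt", "alt")}, codominant_assay)
        assert pattern.sizes == frozenset({516})

    def test_unknown_allele_rejected(self, codominant_assay):
        with pytest.raises(KeyError):
            simulate_scar_bands({"s": ("alt", "weird")}, codominant_assay)
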