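"""Wilson intervals, panel scoring conventions and the hybrid index."""

import numpy as np
import pandas as pd
import pytest

from fixmark.assay_caller import SpeciesCall
from fixmark.diagnostics import (
    hybrid_index,
    round_percent,
    score_panel,
    wilson_interval,
)
from fixmark.panel_simulator import SampleSheet
from fixmark.variant_io import MISSING

from conftest import wilson_oracle


class TestWilsonInterval:
    @pytest.mark.parametrize(
        "s,n", [(0, 5), (1, 16), (8, 16), (30, 32), (32, 64), (62, 64), (199, 200)]
    )
    def test_matches_score_test_inversion(self, s, n):
        got = wilson_interval(s, n)
        expected = wilson_oracle(s, n)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_degenerate_upper_bound_at_full_success(self):
        lower, upper = wilson_interval(64, 64)
        assert upper == pytest.approx(1.0, abs=1e-12)
        assert 0 < lower < 1

    def test_symmetry_about_one_half(self):
        lower, upper = wilson_interval(32, 64)
        assert lower == pytest.approx(1 - upper, abs=1e-12)

    def test_width_shrinks_with_sample_size(self):
        w16 = np.diff(wilson_interval(8, 16))[0]
        w64 = np.diff(wilson_interval(32, 64))[0]
        w256 = np.diff(wilson_interval(128, 256))[0]
        assert w256 < w64 < w16

    def test_bounds_bracket_point_estimate(self):
        for s, n in [(3, 10), (50, 60), (1, 100)]:
            lower, upper = wilson_interval(s, n)
            assert lower <= s / n <= upper

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(5, 4)
        with pytest.raises(ValueError):
            wilson_interval(1, 0)


class TestRounding:
    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.96875, 96.9), (0.984375, 98.4), (1.0, 100.0), (0.9375, 93.8)],
    )
    def test_half_away_from_zero_display(self, fraction, expected):
        assert round_percent(fraction) == expected


def _sheet(rows):
    return SampleSheet(
        pd.DataFrame(
            rows, columns=["id", "morphological_label", "genetic_truth", "in_training"]
        )
    )


@pytest.fixture
def mini_panel():
    """Four purebreds, a cryptic F1 labelled target, a variant, two
    non-target species accessions and an overt hybrid."""
    sheet = _sheet(
        [
            ("P1", "target", "target", True),
            ("P2", "target", "target", True),
            ("P3", "target", "target", True),
            ("P4", "target", "target", True),
            ("C1", "target", "hybrid", True),  # cryptic F1
            ("V1", "target_variant", "nontarget", True),
            ("N1", "nontarget_species", "nontarget", False),
            ("N2", "nontarget_species", "nontarget", False),
            ("H1", "nontarget_hybrid", "hybrid", False),
        ]
    )
    calls = {
        "P1": SpeciesCall("target"),
        "P2": SpeciesCall("target"),
        "P3": SpeciesCall("target"),
        "P4": SpeciesCall("target"),
        "C1": SpeciesCall("heterozygous_hybrid"),
        "V1": SpeciesCall("nontarget"),
        "N1": SpeciesCall("nontarget"),
        "N2": SpeciesCall("nontarget"),
        "H1": SpeciesCall("heterozygous_hybrid"),
    }
    return sheet, calls


class TestScorePanel:
    def test_perfect_calls_are_fully_concordant(self, mini_panel):
        sheet, calls = mini_panel
        calls = dict(calls, C1=SpeciesCall("target"))  # morphology never sees it
        _, report = score_panel(calls, sheet, "morphological")
        assert report.concordance == 1.0 and report.discordant_ids == ()

    def test_cryptic_hybrid_is_the_single_morphological_discordant(self, mini_panel):
        sheet, calls = mini_panel
        counts, report = score_panel(calls, sheet, "morphological")
        assert report.discordant_ids == ("C1",)
        assert report.concordance == pytest.approx(8 / 9)
        # sensitivity over genetic purebreds is untouched
        assert report.sensitivity == 1.0
        # specificity over genetic non-targets: C1 miscounted vs morphology
        assert counts.fp == 1 and counts.tn == 4
        assert report.specificity == pytest.approx(4 / 5)

    def test_genetic_convention_accepts_the_hybrid_call(self, mini_panel):
        sheet, calls = mini_panel
        counts, report = score_panel(calls, sheet, "genetic")
        assert report.discordant_ids == ()
        assert report.specificity == 1.0
        assert counts.tp + counts.fn == 4 and counts.tn + counts.fp == 5

    def test_counts_telescope(self, mini_panel):
        sheet, calls = mini_panel
        counts, report = score_panel(calls, sheet, "morphological")
        assert counts.total == len(sheet.ids())
        assert counts.total - len(report.discordant_ids) == round(
            report.concordance * counts.total
        )
        assert report.sensitivity == counts.tp / (counts.tp + counts.fn)
        assert report.specificity == counts.tn / (counts.tn + counts.fp)

    def test_ambiguous_and_no_call_never_concordant(self, mini_panel):
        sheet, calls = mini_panel
        calls = dict(calls, N1=SpeciesCall("ambiguous"), P1=SpeciesCall("no_call"))
        _, report = score_panel(calls, sheet, "genetic")
        assert set(report.discordant_ids) == {"N1", "P1"}

    def test_unknown_convention_rejected(self, mini_panel):
        sheet, calls = mini_panel
        with pytest.raises(ValueError):
            score_panel(calls, sheet, "vibes")

    def test_missing_call_rejected(self, mini_panel):
        sheet, calls = mini_panel
        calls.pop("H1")
        with pytest.raises(ValueError):
            score_panel(calls, sheet, "genetic")


class TestHybridIndex:
    def test_f1_heterozygote_is_exactly_half(self):
        codes = [1] * 40
        assert hybrid_index(codes, ["alt"] * 40) == 0.5

    def test_pure_target_is_one(self):
        codes = [2] * 10 + [0] * 10
        alleles = ["alt"] * 10 + ["ref"] * 10
        assert hybrid_index(codes, alleles) == 1.0

    def test_mixed_diagnostic_allele_orientation(self):
        # hom target at an alt-diagnostic locus + hom non-target at a
        # ref-diagnostic locus -> (2 + 0) / 4
        assert hybrid_index([2, 2], ["alt", "ref"]) == 0.5

    def test_missing_loci_are_excluded(self):
        codes = [1, MISSING, MISSING, 1]
        assert hybrid_index(codes, ["alt"] * 4) == 0.5

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            hybrid_index([MISSING, MISSING], ["alt", "alt"])
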