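"""Primer properties and KASP/SCAR design behaviour."""

import numpy as np
import pytest

from fixmark.assay_designer import (
    DesignConstraints,
    design_kasp,
    design_scar,
    primer_properties,
    reverse_complement,
)

CONSTRAINTS = DesignConstraints()


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _within(props, constraints=CONSTRAINTS):
    return (
        constraints.length_range[0] <= props.length <= constraints.length_range[1]
        and constraints.gc_range[0] <= props.gc <= constraints.gc_range[1]
        and constraints.tm_range[0] <= props.tm <= constraints.tm_range[1]
    )


class TestPrimerProperties:
    def test_validated_allele_specific_primer_length(self):
        # an allele-specific primer of the validated marker set: 26 nt,
        # inside the 20-30 nt design window
        assert primer_properties("TCCACTTCAAGAACCACCTCCGCTCC").length == 26

    def test_gc_fraction_by_direct_count(self):
        props = primer_properties("AGCATGAGAGGGCGCAAAGG")
        assert props.length == 20
        assert props.gc == pytest.approx(0.60)

    def test_all_gc_sequence(self):
        assert primer_properties("GGGG").gc == 1.0

    def test_tm_is_deterministic_and_strand_symmetric(self):
        seq = "AGCATGAGAGGGCGCAAAGG"
        a = primer_properties(seq).tm
        assert a == primer_properties(seq).tm
        assert a == pytest.approx(primer_properties(reverse_complement(seq)).tm)

    @pytest.mark.parametrize("bad", ["", "ACGX", "acg t"])
    def test_rejects_invalid_sequences(self, bad):
        with pytest.raises(ValueError):
            primer_properties(bad)


@pytest.fixture(scope="module")
def snp_flank():
    rng = np.random.default_rng(42)
    for _ in range(20):
        flank = _rand_seq(rng, 501)
        ref = flank[250]
        alt = [b for b in "ACGT" if b != ref][0]
        if design_kasp(flank, 250, ref, alt) is not None:
            return flank, 250, ref, alt
    raise RuntimeError("no designable flank found")


class TestDesignKasp:
    def test_allele_primers_differ_only_at_three_prime_base(self, snp_flank):
        flank, pos, ref, alt = snp_flank
        assay = design_kasp(flank, pos, ref, alt)
        a, b = assay.allele_ref_primer, assay.allele_alt_primer
        assert len(a) == len(b)
        assert a[:-1] == b[:-1] and a[-1] != b[-1]

    def test_all_primers_satisfy_constraints(self, snp_flank):
        flank, pos, ref, alt = snp_flank
        assay = design_kasp(flank, pos, ref, alt)
        for primer in (
            assay.allele_ref_primer,
            assay.allele_alt_primer,
            assay.common_primer,
        ):
            assert _within(primer_properties(primer))

    def test_deterministic(self, snp_flank):
        flank, pos, ref, alt = snp_flank
        assert design_kasp(flank, pos, ref, alt) == design_kasp(flank, pos, ref, alt)

    def test_strand_symmetry(self, snp_flank):
        flank, pos, ref, alt = snp_flank
        fwd = design_kasp(flank, pos, ref, alt)
        rc = design_kasp(
            reverse_complement(flank),
            len(flank) - pos - len(ref),
            reverse_complement(ref),
            reverse_complement(alt),
        )
        assert (rc.allele_ref_primer, rc.allele_alt_primer, rc.common_primer) == (
            fwd.allele_ref_primer,
            fwd.allele_alt_primer,
            fwd.common_primer,
        )

    def test_homopolymer_flank_is_infeasible(self):
        assert design_kasp("A" * 501, 250, "A", "T") is None

    def test_selected_pair_is_tm_optimal_among_valid_windows(self, snp_flank):
        # exhaustive window scan, independent of the designer's enumeration
        flank, pos, ref, alt = snp_flank
        assay = design_kasp(flank, pos, ref, alt)
        target = CONSTRAINTS.tm_target
        best_dev = np.inf
        for hap, p, r, a in (
            (flank, pos, ref, alt),
            (
                reverse_complement(flank),
                len(flank) - pos - 1,
                reverse_complement(ref),
                reverse_complement(alt),
            ),
        ):
            hap_alt = hap[:p] + a + hap[p + 1 :]
            for length in range(*CONSTRAINTS.length_range, 1):
                pr = hap[p + 1 - length : p + 1]
                pa = hap_alt[p + 1 - length : p + 1]
                try:
                    props_r, props_a = primer_properties(pr), primer_properties(pa)
                except ValueError:
                    continue
                if _within(props_r) and _within(props_a):
                    best_dev = min(
                        best_dev,
                        abs(props_r.tm - target) + abs(props_a.tm - target),
                    )
        got = abs(primer_properties(assay.allele_ref_primer).tm - target) + abs(
            primer_properties(assay.allele_alt_primer).tm - target
        )
        assert got == pytest.approx(best_dev, abs=1e-6)

    def test_variant_outside_flank_rejected(self):
        with pytest.raises(ValueError):
            design_kasp("ACGT" * 50, 400, "A", "T")


@pytest.fixture(scope="module")
def scar_rng():
    return np.random.default_rng(2024)


class TestDesignScar:
    def _indel_flank(self, rng, seg_len):
        seg = _rand_seq(rng, seg_len)
        flank = _rand_seq(rng, 250) + "G" + seg + _rand_seq(rng, 250)
        return flank, 250, "G" + seg, "G"

    def test_21bp_indel_yields_codominant_with_21bp_difference(self, scar_rng):
        flank, pos, ref, alt = self._indel_flank(scar_rng, 21)
        assay = design_scar(flank, pos, ref, alt)
        assert assay is not None and assay.mode == "codominant"
        assert assay.size_map["ref"] - assay.size_map["alt"] == 21

    def test_10bp_indel_below_resolution_threshold(self, scar_rng):
        flank, pos, ref, alt = self._indel_flank(scar_rng, 10)
        assert design_scar(flank, pos, ref, alt, mode="codominant") is None

    def test_dominant_reverse_primer_sits_inside_deletion(self, scar_rng):
        flank, pos, ref, alt = self._indel_flank(scar_rng, 120)
        assay = design_scar(flank, pos, ref, alt, mode="dominant")
        assert assay is not None and assay.mode == "dominant"
        assert assay.size_map["alt"] is None  # deletion allele: no band
        deleted_segment = ref[1:]
        assert reverse_complement(assay.reverse_primer) in deleted_segment

    def test_primers_satisfy_constraints(self, scar_rng):
        flank, pos, ref, alt = self._indel_flank(scar_rng, 30)
        assay = design_scar(flank, pos, ref, alt)
        assert assay is not None
        assert _within(primer_properties(assay.forward_primer))
        assert _within(primer_properties(assay.reverse_primer))

    def test_snp_locus_rejected(self):
        with pytest.raises(ValueError):
            design_scar("ACGT" * 130, 250, "A", "T")
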