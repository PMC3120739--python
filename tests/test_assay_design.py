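"""Oligo parsing, placement, amplicon/TSS arithmetic and specificity verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylight.assay_design import (
    AmpliconInterval,
    Assay,
    amplicon_of,
    best_hit,
    interval_length,
    interval_overlap,
    locate_oligo,
    offset_to_tss,
    oligo_cpg_count,
    parse_oligo,
    specificity_report,
    tss_to_offset,
)
from methylight.bisulfite_core import (
    GenomicRegion,
    four_templates,
    reverse_complement,
)
from methylight.errors import DesignError, DesignWarning, OligoParseError


class TestParseOligo:
    @pytest.mark.parametrize(
        "text,role,length,n_cpg",
        [
            ("tggag ttttC ggttg attgg tt", "forward", 22, 1),  # ML-Primer-F1
            ("CgCgg tCgtg gttag ttagt", "forward", 20, 3),  # ML-Primer-F2
            ("gggaa gatgg gatag aaggg aatat", "reverse", 25, 0),  # COL2A1-R
        ],
    )
    def test_printed_primer_annotations(self, text, role, length, n_cpg):
        oligo = parse_oligo(text, role=role, name="t")
        assert len(oligo) == length
        assert oligo_cpg_count(oligo) == n_cpg

    def test_printed_probe_annotations(self, assays):
        counts = {
            "p16-ML-70bp": 4,  # accCg acccC gaacC gCg
            "p16-ML-115bp": 3,  # gttgt ttttC gtCgt Cggtt
            "COL2A1-reference": 0,
        }
        for name, expected in counts.items():
            assert oligo_cpg_count(assays[name].probe) == expected

    def test_decorations_stripped(self):
        oligo = parse_oligo("5'-acc Cga ccc-3'", role="probe", name="p")
        assert oligo.sequence == "ACCCGACCC"

    def test_non_base_character_rejected(self):
        with pytest.raises(OligoParseError, match="non-base"):
            parse_oligo("accXgt", role="forward", name="bad")

    def test_explicit_index_dialect(self):
        oligo = parse_oligo(
            "acgcgt", role="forward", name="plain", discriminating=[1, 3]
        )
        assert oligo.discriminating == (1, 3)

    def test_uppercase_at_warns_and_is_ignored(self):
        with pytest.warns(DesignWarning, match="not a CpG-derived"):
            oligo = parse_oligo("aTgCgt", role="forward", name="odd")
        assert oligo.discriminating == (3,)

    def test_reverse_primer_marked_on_g_resolves_to_scan_c(self):
        # published reverse primers uppercase the G facing the CpG C
        oligo = parse_oligo("aacaa cGccc Gcacc tcct", role="reverse", name="R1")
        assert oligo_cpg_count(oligo) == 2


class TestLocateOligo:
    def test_forward_primer_exact_on_methylated_template(
        self, assays, p16_templates
    ):
        f1 = assays["p16-ML-70bp"].forward
        hits = locate_oligo(f1, p16_templates[("antisense", "methylated")])
        assert len(hits) == 1
        assert hits[0].mismatches == 0

    def test_discriminating_bases_fail_on_unmethylated_template(
        self, assays, p16_templates
    ):
        f1 = assays["p16-ML-70bp"].forward
        hit = best_hit(f1, p16_templates[("antisense", "unmethylated")])
        assert hit is not None
        assert hit.mismatch_at_cpg >= 1

    def test_oligo_longer_than_template_yields_empty(self, assays):
        tiny = four_templates(GenomicRegion("tiny", "ACGT"))
        with pytest.warns(DesignWarning, match="longer than template"):
            assert locate_oligo(
                assays["p16-ML-70bp"].forward, tiny[("sense", "methylated")]
            ) == []

    def test_hit_counts_bounded(self, assays, p16_templates):
        for assay in assays.values():
            for oligo in assay.oligos:
                for template in p16_templates.values():
                    hit = best_hit(oligo, template)
                    assert hit is not None
                    assert 0 <= hit.mismatch_at_cpg <= hit.mismatches <= len(oligo)


class TestTssArithmetic:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            tss = int(rng.integers(0, 400))
            offset = int(rng.integers(0, 400))
            assert tss_to_offset(offset_to_tss(offset, tss), tss) == offset

    def test_no_position_zero(self):
        with pytest.raises(ValueError, match="no position 0"):
            tss_to_offset(0, 10)
        assert offset_to_tss(10, 10) == 1
        assert offset_to_tss(9, 10) == -1


class TestIntervalArithmetic:
    @pytest.mark.parametrize(
        "start,end,length",
        [(238, 307, 70), (133, 283, 151), (157, 272, 116), (-5, 5, 10)],
    )
    def test_lengths(self, start, end, length):
        assert interval_length(AmpliconInterval(start, end, "sense")) == length

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((157, 272), (133, 283), 116),  # full containment
            ((238, 307), (133, 283), 46),  # partial
            ((1, 10), (20, 30), 0),  # disjoint
        ],
    )
    def test_overlaps(self, a, b, expected):
        ia = AmpliconInterval(*a, "sense")
        ib = AmpliconInterval(*b, "antisense")
        assert interval_overlap(ia, ib) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(-300, 300).filter(lambda v: v != 0), min_size=4, max_size=4))
    def test_overlap_symmetric_and_bounded(self, coords):
        a = AmpliconInterval(min(coords[:2]), max(coords[:2]), "sense")
        b = AmpliconInterval(min(coords[2:]), max(coords[2:]), "antisense")
        assert interval_overlap(a, b) == interval_overlap(b, a)
        assert interval_overlap(a, b) <= min(interval_length(a), interval_length(b))
        assert interval_overlap(a, a) == interval_length(a)


def _synthetic_assay_from_template(template_seq, f_start, amp_len, name="fix"):
    """Build a methylation-neutral assay whose oligos are template substrings."""
    f_seq = template_seq[f_start : f_start + 20]
    r5 = f_start + amp_len - 1
    r_seq = reverse_complement(template_seq[r5 - 17 : r5 + 1])
    p_start = f_start + 25
    p_seq = template_seq[p_start : p_start + 16]
    with pytest.warns(DesignWarning, match="no methylation discrimination"):
        return Assay(
            name=name,
            forward=parse_oligo(f_seq.lower(), "forward", f"{name}-F"),
            reverse=parse_oligo(r_seq.lower(), "reverse", f"{name}-R"),
            probe=parse_oligo(p_seq.lower(), "probe", f"{name}-P"),
            target_strand="sense",
        )


class TestAmpliconOf:
    def test_published_coordinates_on_synthetic_region(self, assays, p16_templates):
        iv = amplicon_of(
            assays["p16-ML-115bp"], p16_templates[("sense", "methylated")]
        )
        assert (iv.start_tss, iv.end_tss, iv.strand) == (157, 272, "sense")
        assert interval_length(iv) == 116  # vs the assay's nominal 115
        iv70 = amplicon_of(
            assays["p16-ML-70bp"], p16_templates[("antisense", "methylated")]
        )
        assert interval_length(iv70) == 70

    def test_reference_assay_interval_identical_on_m_and_u(
        self, assays, col2a1_templates
    ):
        col = assays["COL2A1-reference"]
        iv_m = amplicon_of(col, col2a1_templates[("sense", "methylated")])
        iv_u = amplicon_of(col, col2a1_templates[("sense", "unmethylated")])
        assert iv_m == iv_u

    def test_missing_hits_raise_design_error(self, assays, p16_templates):
        with pytest.raises(DesignError, match="exactly one"):
            amplicon_of(
                assays["p16-ML-115bp"], p16_templates[("sense", "unmethylated")]
            )

    def test_random_fixtures_match_index_arithmetic(self):
        rng = np.random.default_rng(19)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            region = GenomicRegion("rand", seq, tss_offset=int(rng.integers(0, 100)))
            template = four_templates(region)[("sense", "methylated")]
            f_start = int(rng.integers(0, 150))
            amp_len = int(rng.integers(60, 120))
            assay = _synthetic_assay_from_template(template.converted, f_start, amp_len)
            try:
                iv = amplicon_of(assay, template)
            except DesignError:
                continue  # rare duplicate substring hit
            assert interval_length(iv) == amp_len
            assert tss_to_offset(iv.start_tss, region.tss_offset) == f_start

    def test_probe_outside_primer_span_warns(self):
        rng = np.random.default_rng(23)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        region = GenomicRegion("r", seq)
        template = four_templates(region)[("sense", "methylated")]
        t = template.converted
        with pytest.warns(DesignWarning, match="no methylation discrimination"):
            assay = Assay(
                name="probe-out",
                forward=parse_oligo(t[10:30].lower(), "forward", "F"),
                reverse=parse_oligo(
                    reverse_complement(t[80:100]).lower(), "reverse", "R"
                ),
                probe=parse_oligo(t[150:170].lower(), "probe", "P"),
                target_strand="sense",
            )
        with pytest.warns(DesignWarning, match="strictly between"):
            amplicon_of(assay, template)


class TestSpecificityReport:
    def test_methylated_p16_assays_are_specific(self, assays, p16_templates):
        for name in ("p16-ML-70bp", "p16-ML-115bp"):
            report = specificity_report(assays[name], p16_templates)
            assert report.verdict == "methylation-specific"

    def test_reference_assay_is_neutral(self, assays, col2a1_templates):
        report = specificity_report(assays["COL2A1-reference"], col2a1_templates)
        assert report.verdict == "methylation-neutral"
        assert report.warnings == []

    def test_every_discriminating_base_fails_on_unmethylated(
        self, assays, p16_templates
    ):
        assay = assays["p16-ML-115bp"]
        m = p16_templates[("sense", "methylated")]
        u = p16_templates[("sense", "unmethylated")]
        for oligo in assay.oligos:
            pos = locate_oligo(oligo, m)[0].position
            from methylight.assay_design import _hit_at

            assert _hit_at(oligo, u, pos).mismatch_at_cpg == oligo_cpg_count(oligo)

    def test_undiscriminating_nonreference_assay_warns(self, p16_templates):
        t = p16_templates[("sense", "methylated")].converted
        with pytest.warns(DesignWarning, match="no methylation discrimination"):
            assay = Assay(
                name="zero-disc",
                forward=parse_oligo(t[10:30].lower(), "forward", "F"),
                reverse=parse_oligo(
                    reverse_complement(t[80:100]).lower(), "reverse", "R"
                ),
                probe=parse_oligo(t[40:60].lower(), "probe", "P"),
                target_strand="sense",
            )
        report = specificity_report(assay, p16_templates)
        assert "no methylation discrimination" in report.warnings


class TestAssayValidation:
    def test_reference_with_discriminating_bases_rejected(self, assays):
        f = parse_oligo("ttttCgtt", "forward", "F")
        r = parse_oligo("aaaacaaa", "reverse", "R")
        p = parse_oligo("ttttgttt", "probe", "P")
        with pytest.raises(DesignError, match="reference assay"):
            Assay("bad-ref", f, r, p, "sense", reference=True)

    def test_role_mismatch_rejected(self):
        f = parse_oligo("ttttCgtt", "forward", "F")
        with pytest.raises(DesignError, match="role"):
            Assay("bad-roles", f, f, f, "sense")
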