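"""Degenerate-pattern parsing and the two scanning modes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tprfam.patterns import (
    ISRE_CONSENSUS,
    TPR_CONSENSUS,
    MotifPatternError,
    brute_force_scan,
    call_tpr_motifs,
    hits_to_bed,
    match_at,
    parse_pattern,
    reverse_complement,
    scan_isre,
)

# a perfect-consensus TPR window and a 3-of-8 degraded one, built by hand
# against the element list (Q belongs to no residue class)
PERFECT_TPR = "W" + "QQ" + "L" + "G" + "QQ" + "Y" + "Q" * 8 + "A" + "QQQ" + "F" + "QQ" + "A" + "QQQQ" + "P"
THREE_OF_EIGHT = "W" + "QQ" + "L" + "G" + "QQ" + "Q" + "Q" * 8 + "Q" + "QQQ" + "Q" + "QQ" + "Q" + "QQQQ" + "Q"


class TestParsing:
    def test_tpr_consensus_structure(self, tpr_pattern):
        """The printed TPR consensus has 8 bracketed key sites and a fixed
        29-aa span (8 constrained + 21 wildcard positions)."""
        assert tpr_pattern.key_site_count == 8
        assert tpr_pattern.nonkey_site_count == 0
        assert tpr_pattern.min_span == tpr_pattern.max_span == 29
        assert not tpr_pattern.variable_gaps

    def test_isre_consensus_structure(self, isre_pattern):
        """The ISRE consensus: 3 degenerate classes, 8 literal GAAA-core
        positions, one 1-2 nt gap; spans are the element-length sums."""
        assert isre_pattern.key_site_count == 3
        assert isre_pattern.nonkey_site_count == 8
        gaps = isre_pattern.variable_gaps
        assert len(gaps) == 1
        assert (gaps[0].min_len, gaps[0].max_len) == (1, 2)
        # hand sum: 1 + 4 + gap + 4 + 1 + 1
        assert isre_pattern.min_span == 12
        assert isre_pattern.max_span == 13

    @pytest.mark.parametrize(
        "text,alphabet",
        [
            ("", "protein"),
            ("   - ", "dna"),
            ("[WLF", "protein"),
            ("[WLF]-X(2)-[B]", "protein"),  # B not an amino acid
            ("(G/A/U)GAAA", "dna"),  # U not DNA
            ("X(2)", "dna"),  # X is not the DNA wildcard
        ],
    )
    def test_malformed_patterns_rejected(self, text, alphabet):
        with pytest.raises(MotifPatternError):
            parse_pattern(text, alphabet)

    def test_case_and_separators_ignored(self, tpr_pattern):
        relaxed = parse_pattern(TPR_CONSENSUS.lower().replace("-", ""), "protein")
        assert relaxed.elements == tpr_pattern.elements

    def test_bare_letters_are_nonkey_literals(self):
        pat = parse_pattern("GAAA", "dna")
        assert pat.key_site_count == 0
        assert pat.nonkey_site_count == 4


class TestMatchAt:
    def test_perfect_window_matches_all_key_sites(self, tpr_pattern):
        ev = match_at(PERFECT_TPR, tpr_pattern, 0)
        assert ev.key_matched == 8
        assert ev.full_match

    def test_constructed_three_of_eight(self, tpr_pattern):
        """Hand-built window keeping only [WLF], [LIM], [GAS] satisfied."""
        assert match_at(THREE_OF_EIGHT, tpr_pattern, 0).key_matched == 3

    def test_out_of_range_position(self, tpr_pattern):
        with pytest.raises(IndexError):
            match_at(PERFECT_TPR, tpr_pattern, 5)

    def test_gap_choice_controls_span(self, isre_pattern):
        ev1 = match_at("TGAAATGAAAGCA", isre_pattern, 0, gap_choice=(1,))
        ev2 = match_at("TGAAATGAAAGCA", isre_pattern, 0, gap_choice=(2,))
        assert (ev1.span, ev2.span) == (12, 13)


class TestTprCalling:
    def test_rejection_boundary_is_strict(self, tpr_pattern, rng):
        """'More than 4 of 8' is a strict inequality: a window with exactly
        4 matched key sites is never called, 5 always is."""
        from tprfam.simulate import gen_protein_with_tpr

        seq4, _ = gen_protein_with_tpr(200, [(50, 4)], rng)
        assert call_tpr_motifs(seq4, tpr_pattern) == []
        seq5, _ = gen_protein_with_tpr(200, [(50, 5)], rng)
        hits = call_tpr_motifs(seq5, tpr_pattern)
        assert [(h.start, h.key_sites_matched) for h in hits] == [(50, 5)]

    def test_three_planted_units_recovered(self, tpr_pattern, rng):
        from tprfam.simulate import gen_protein_with_tpr

        plants = [(10, 6), (60, 6), (120, 6)]
        seq, truth = gen_protein_with_tpr(200, plants, rng)
        hits = call_tpr_motifs(seq, tpr_pattern)
        assert [(h.start, h.key_sites_matched) for h in hits] == [
            (t.start, t.key_sites_matched) for t in truth
        ]

    def test_empty_sequence(self, tpr_pattern):
        assert call_tpr_motifs("", tpr_pattern) == []

    def test_dna_pattern_rejected(self, isre_pattern):
        with pytest.raises(MotifPatternError):
            call_tpr_motifs("ACDEF", isre_pattern)

    def test_poly_alanine_never_called(self, tpr_pattern):
        """Alanine satisfies only [GAS], [ASE] and [ASL]: 3 <= 4 key sites,
        below the calling rule."""
        assert call_tpr_motifs("A" * 120, tpr_pattern) == []
        assert match_at("A" * 29, tpr_pattern, 0).key_matched == 3

    def test_overlap_resolution_prefers_higher_count(self, tpr_pattern):
        # two overlapping candidates: the perfect window must win over a
        # shifted 5/8 overlap, whatever their order
        raw = call_tpr_motifs(
            "Q" * 3 + PERFECT_TPR + "Q" * 40, tpr_pattern, resolve_overlaps=False
        )
        resolved = call_tpr_motifs("Q" * 3 + PERFECT_TPR + "Q" * 40, tpr_pattern)
        assert len(resolved) == 1
        assert resolved[0].start == 3
        assert resolved[0].key_sites_matched == 8
        assert all(r.key_sites_matched <= 8 for r in raw)


class TestIsreScanning:
    def test_minimal_consensus_instantiation(self, isre_pattern):
        """TGAAATGAAAGC spells the consensus with a 1-nt gap: one forward
        hit covering the whole string."""
        hits = scan_isre("TGAAATGAAAGC", isre_pattern, strands="both")
        assert [(h.start, h.end, h.strand) for h in hits] == [(0, 12, "+")]

    def test_reverse_complement_is_minus_hit(self, isre_pattern):
        rc = reverse_complement("TGAAATGAAAGC")
        hits = scan_isre(rc, isre_pattern, strands="both")
        assert [(h.start, h.end, h.strand) for h in hits] == [(0, 12, "-")]

    def test_poly_a_has_no_hits(self, isre_pattern):
        assert scan_isre("A" * 12, isre_pattern) == []

    def test_n_never_matches(self, isre_pattern):
        assert scan_isre("TGAAANGAAAGC".replace("T", "N", 1), isre_pattern) == []
        # N in the gap position is fine: the gap is unconstrained
        assert len(scan_isre("TGAAANGAAAGC", isre_pattern, "forward")) == 1

    def test_non_nucleotide_rejected(self, isre_pattern):
        with pytest.raises(ValueError):
            scan_isre("TGAAAZGAAAGC", isre_pattern)

    def test_gap_choices_collapse_to_shortest(self, isre_pattern):
        # TGAAA T GAAAG C A... where both gap=1 and gap=2 could match if the
        # downstream context allows; shortest span is reported
        seq = "TGAAATGAAAGCGAAAGC"
        hits = scan_isre(seq, isre_pattern, strands="forward")
        starts = [(h.start, h.span) for h in hits]
        assert all(span in (12, 13) for _, span in starts)
        assert len({s for s, _ in starts}) == len(starts)  # one hit per start

    def test_strand_symmetry(self, isre_pattern, rng):
        """Scanning the reverse complement mirrors the hit set."""
        from tprfam.simulate import gen_promoter_with_isre

        seq, _, _ = gen_promoter_with_isre(400, [(100, "+"), (250, "-")], rng)
        fwd = scan_isre(seq, isre_pattern, strands="both")
        rev = scan_isre(reverse_complement(seq), isre_pattern, strands="both")
        mirrored = {
            (len(seq) - h.end, len(seq) - h.start, "-" if h.strand == "+" else "+")
            for h in rev
        }
        assert {(h.start, h.end, h.strand) for h in fwd} == mirrored


class TestOracleEquivalence:
    """Production scanners vs the exhaustive brute-force scanner."""

    def test_protein_scanner_matches_oracle(self, tpr_pattern):
        rng = np.random.default_rng(1234)  # logged seed
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            length = int(rng.integers(29, 300))
            seq = "".join(aa[i] for i in rng.integers(20, size=length))
            assert call_tpr_motifs(seq, tpr_pattern) == brute_force_scan(
                seq, tpr_pattern
            )

    def test_dna_scanner_matches_oracle(self, isre_pattern):
        rng = np.random.default_rng(5678)  # logged seed
        from tprfam.simulate import gen_promoter_with_isre

        for i in range(30):
            if i % 2:
                seq = "".join("ACGT"[j] for j in rng.integers(4, size=500))
            else:  # guarantee some hit-bearing sequences
                seq, _, _ = gen_promoter_with_isre(
                    300, [(100, "+" if i % 4 else "-")], rng
                )
            assert scan_isre(seq, isre_pattern, "both") == brute_force_scan(
                seq, isre_pattern, strands="both"
            )

    @given(st.text(alphabet="ACGT", min_size=0, max_size=80))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_dna_oracle_property(self, seq):
        from tprfam.patterns import parse_pattern

        pat = parse_pattern(ISRE_CONSENSUS, "dna", name="ISRE")
        assert scan_isre(seq, pat, "both") == brute_force_scan(
            seq, pat, strands="both"
        )


def test_bed_output_is_deterministic(isre_pattern):
    seq = "TGAAATGAAAGC" + "ACGT" * 10 + "TGAAATGAAAGC"
    bed1 = hits_to_bed(scan_isre(seq, isre_pattern), "ISRE")
    bed2 = hits_to_bed(scan_isre(seq, isre_pattern), "ISRE")
    assert bed1 == bed2
    assert bed1.startswith("seq\t0\t12\tISRE\t3\t+")
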