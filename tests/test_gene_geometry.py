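"""Coding-map arithmetic, NMD escape, pext ratios: examples and properties.

The brute-force oracle enumerates coding bases one by one in transcript
orientation and never touches the interval arithmetic under test.
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lofcurate.gene_geometry import (
    NonCodingPositionError,
    NonCodingTranscriptError,
    build_coding_map,
    cds_fraction_removed,
    in_frame_exon,
    minority_of_transcripts,
    nmd_escape,
    pext_category,
)
from lofcurate.models import (
    CONSERVATIVE,
    LENIENT,
    PextTrack,
    TranscriptModel,
    VariantBundle,
)


def brute_force_offsets(exons, strand):
    """Oracle: enumerate coding bases 5'->3' one position at a time."""
    positions = []
    for s, e in sorted(exons):
        positions.extend(range(s, e))
    if strand == "-":
        positions.reverse()
    return {pos: i for i, pos in enumerate(positions)}


class TestCodingMap:
    def test_single_exon_identity_layout(self):
        tx = TranscriptModel("t", "g", "+", [(100, 400)], [(100, 400)])
        cm = build_coding_map(tx)
        assert cm.cds_length == 300
        assert cm.coding_offset(100) == 0
        assert cm.coding_offset(399) == 299
        assert cm.coding_offset(400) is None

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_two_exon_map_matches_enumeration(self, strand, two_exon_plus,
                                              two_exon_minus):
        tx = two_exon_plus if strand == "+" else two_exon_minus
        cm = build_coding_map(tx)
        oracle = brute_force_offsets([(100, 200), (300, 400)], strand)
        for pos, off in oracle.items():
            assert cm.coding_offset(pos) == off
            assert cm.genomic_at_offset(off) == pos
        if strand == "+":
            assert cm.coding_offset(300) == 100
        else:
            assert cm.coding_offset(399) == 0

    def test_non_coding_transcript_rejected(self):
        tx = TranscriptModel("t", "g", "+", [(0, 90)], [], is_coding=False)
        with pytest.raises(NonCodingTranscriptError):
            build_coding_map(tx)


class TestFractionRemoved:
    def test_first_base_removes_everything(self, two_exon_plus):
        cm = build_coding_map(two_exon_plus)
        assert cds_fraction_removed(cm, 100) == 1.0

    def test_fraction_by_enumeration(self, three_exon_plus):
        cm = build_coding_map(three_exon_plus)  # CDS 300
        pos = cm.genomic_at_offset(270)
        # remaining coding bases counted one by one
        remaining = sum(
            1 for off in range(cm.cds_length) if off >= 270
        )
        assert cds_fraction_removed(cm, pos) == pytest.approx(remaining / 300)
        assert cds_fraction_removed(cm, pos) == pytest.approx(0.10)

    def test_thirty_percent_fails_conservative_truncation_rule(self):
        tx = TranscriptModel("t", "g", "+", [(0, 400)], [(0, 400)])
        cm = build_coding_map(tx)
        frac = cds_fraction_removed(cm, cm.genomic_at_offset(280))
        assert frac == pytest.approx(0.30)
        assert not frac < CONSERVATIVE.truncation_max_fraction

    def test_intronic_position_rejected(self, two_exon_plus):
        cm = build_coding_map(two_exon_plus)
        with pytest.raises(NonCodingPositionError):
            cds_fraction_removed(cm, 250)

    def test_monotone_non_increasing_along_transcript(self, three_exon_plus):
        cm = build_coding_map(three_exon_plus)
        fracs = [
            cds_fraction_removed(cm, cm.genomic_at_offset(off))
            for off in range(cm.cds_length)
        ]
        assert fracs[0] == 1.0
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == pytest.approx(1 / cm.cds_length)


class TestNmdEscape:
    def test_single_coding_exon_always_escapes(self):
        tx = TranscriptModel("t", "g", "+", [(0, 300)], [(0, 300)])
        cm = build_coding_map(tx)
        for off in (0, 150, 299):
            assert nmd_escape(cm, tx, cm.genomic_at_offset(off), CONSERVATIVE)

    def test_last_exon_escapes(self, three_exon_plus):
        cm = build_coding_map(three_exon_plus)
        assert nmd_escape(cm, three_exon_plus, 431, CONSERVATIVE)

    def test_penultimate_window_boundary(self, three_exon_plus):
        cm = build_coding_map(three_exon_plus)
        # penultimate exon covers offsets 120..200; its 3' end is offset 200
        at_50 = cm.genomic_at_offset(201 - 50)   # 50 bases from the 3' end
        at_51 = cm.genomic_at_offset(201 - 51)
        assert nmd_escape(cm, three_exon_plus, at_50, CONSERVATIVE)
        assert not nmd_escape(cm, three_exon_plus, at_51, CONSERVATIVE)

    def test_invariant_under_strand_mirror(self, three_exon_plus):
        L = 600
        exons = [(L - e, L - s) for s, e in three_exon_plus.exons]
        tx_m = TranscriptModel("tm", "g", "-", exons, list(exons))
        cm_p = build_coding_map(three_exon_plus)
        cm_m = build_coding_map(tx_m)
        for off in range(cm_p.cds_length):
            assert nmd_escape(
                cm_p, three_exon_plus, cm_p.genomic_at_offset(off), CONSERVATIVE
            ) == nmd_escape(cm_m, tx_m, cm_m.genomic_at_offset(off), CONSERVATIVE)


class TestInFrameExon:
    def test_frame_from_exon_length(self, three_exon_plus):
        cm = build_coding_map(three_exon_plus)
        assert in_frame_exon(cm, 1)  # 81 % 3 == 0
        tx = TranscriptModel("t", "g", "+", [(0, 90), (200, 280), (400, 500)],
                             [(0, 90), (200, 280), (400, 500)])
        assert not in_frame_exon(build_coding_map(tx), 1)  # 80 % 3 != 0

    def test_terminal_exons_rejected(self, three_exon_plus):
        cm = build_coding_map(three_exon_plus)
        for idx in (0, 2):
            with pytest.raises(ValueError, match="terminal"):
                in_frame_exon(cm, idx)

    def test_in_frame_skip_fraction_under_conservative_limit(self):
        # 90 bp in-frame exon of a 600 bp CDS: skipping removes 15% < 25%
        exons = [(0, 255), (400, 490), (600, 855)]
        cm = build_coding_map(TranscriptModel("t", "g", "+", exons, list(exons)))
        assert in_frame_exon(cm, 1)
        frac = cm.exon_cds_lengths[1] / cm.cds_length
        assert frac == pytest.approx(0.15)
        assert frac < CONSERVATIVE.truncation_max_fraction


class TestPextCategory:
    @pytest.mark.parametrize(
        ("mean", "gene_max", "expected"),
        [
            (0.4, 0.6, "close_to_max"),
            (0.6, 0.6, "at_max"),
            (0.05, 0.5, "low"),
            (0.2, 0.8, "mid"),
        ],
    )
    def test_ratio_bands(self, mean, gene_max, expected):
        track = PextTrack(gene_max=gene_max, exon_means={("t", 0): mean})
        assert pext_category(track, "t", 0, CONSERVATIVE) == expected

    def test_zero_gene_max_is_uninformative(self):
        track = PextTrack(gene_max=0.0, exon_means={})
        with pytest.raises(ValueError, match="uninformative"):
            pext_category(track, "t", 0, CONSERVATIVE)

    def test_missing_exon_value_yields_no_category(self):
        track = PextTrack(gene_max=0.5, exon_means={("t", 0): 0.5})
        assert pext_category(track, "t", 3, CONSERVATIVE) is None

    @settings(max_examples=60, derandomize=True)
    @given(
        mean=st.floats(0.011, 1.0),
        scale=st.floats(0.01, 1.0),
    )
    def test_scale_invariance(self, mean, scale):
        """Multiplying all pext values by a constant preserves the category."""
        gene_max = 1.0
        base = pext_category(
            PextTrack(gene_max=gene_max, exon_means={("t", 0): mean}),
            "t", 0, CONSERVATIVE,
        )
        scaled = pext_category(
            PextTrack(gene_max=gene_max * scale,
                      exon_means={("t", 0): mean * scale}),
            "t", 0, CONSERVATIVE,
        )
        assert base == scaled


class TestMinorityOfTranscripts:
    def _bundle(self, hits):
        return VariantBundle("c", 5, "A", "T", "nonsense", transcripts_hit=hits)

    def test_one_of_three_is_minority(self):
        b = self._bundle([("t1", True), ("t2", False), ("t3", False)])
        assert minority_of_transcripts(b, 3, CONSERVATIVE)

    def test_sole_transcript_is_not_minority(self):
        assert not minority_of_transcripts(
            self._bundle([("t1", True)]), 1, CONSERVATIVE)

    def test_exactly_half_is_not_minority(self):
        b = self._bundle([("t1", True), ("t2", True), ("t3", False), ("t4", False)])
        assert not minority_of_transcripts(b, 4, LENIENT)

    def test_zero_transcripts_rejected(self):
        with pytest.raises(ValueError):
            minority_of_transcripts(self._bundle([]), 0, CONSERVATIVE)
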