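"""Homopolymer, MNV, frame-restoring-indel and technical-context rules.

The MNV oracle is Biopython's translator applied to the fully mutated
haplotype sequence — an independent route from the per-codon logic under test.
"""

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from lofcurate.gene_geometry import build_coding_map, revcomp
from lofcurate.models import CONSERVATIVE, LENIENT, QCMetrics, TranscriptModel, VariantBundle
from lofcurate.sequence_rules import (
    CODON_TABLE,
    PhaseGroup,
    RefContext,
    combine_mnv,
    homopolymer_run,
    net_indel_frame,
    reinitiation_class,
    technical_context,
)

BASES = "ACGT"


def test_codon_table_matches_biopython():
    for codon, aa in CODON_TABLE.items():
        assert str(Seq(codon).translate()) == aa


class TestHomopolymer:
    def _ctx(self, seq):
        return RefContext(seq=seq, start=0)

    def test_deletion_in_run_of_five_flags_conservative_only(self):
        seq = "CTGCTGCTGCGAAAAACTGCTGCTGCTG"  # A run at 11..16 (length 5)
        anchor = 10  # the G before the run
        v = VariantBundle("c", anchor + 1, seq[anchor : anchor + 2], seq[anchor],
                          "frameshift")
        run, flagged = homopolymer_run(self._ctx(seq), v, CONSERVATIVE)
        assert (run, flagged) == (5, True)
        run, flagged = homopolymer_run(self._ctx(seq), v, LENIENT)
        assert (run, flagged) == (5, False)

    def test_snv_in_long_run_never_flagged(self):
        seq = "CTGCTGCTGAAAAAAACTGCTGCTG"
        v = VariantBundle("c", 13, "A", "T", "nonsense")
        for profile in (CONSERVATIVE, LENIENT):
            _, flagged = homopolymer_run(self._ctx(seq), v, profile)
            assert not flagged

    def test_insertion_into_run_of_seven_flags_both(self):
        seq = "CTGCTGCTGAAAAAAACTGCTGCTG"  # A run at 9..16 (length 7)
        v = VariantBundle("c", 9, seq[8], seq[8] + "A", "frameshift")
        for profile in (CONSERVATIVE, LENIENT):
            run, flagged = homopolymer_run(self._ctx(seq), v, profile)
            assert (run, flagged) == (7, True)

    def test_window_too_small_rejected(self):
        v = VariantBundle("c", 3, "GA", "G", "frameshift")
        with pytest.raises(ValueError, match="window"):
            homopolymer_run(RefContext("GAAAG", 0), v, CONSERVATIVE)


def _mnv_case(ref_codon, subs, strand):
    """One phased-SNV case on a 9 bp CDS: ATG + ref_codon + TAA."""
    cds = "ATG" + ref_codon + "TAA"
    pad = "C" * 10
    if strand == "+":
        seq = pad + cds + pad
    else:
        seq = pad + revcomp(cds) + pad
    exons = [(10, 19)]
    tx = TranscriptModel("t", "g", strand, exons, list(exons))
    cm = build_coding_map(tx)
    members = []
    for phase, alt in subs:
        gpos = cm.genomic_at_offset(3 + phase)
        galt = alt if strand == "+" else revcomp(alt)
        members.append(
            VariantBundle("c", gpos + 1, seq[gpos], galt, "other"))
    return seq, cm, PhaseGroup("pg", members)


def _mnv_oracle(ref_codon, subs):
    combined = list(ref_codon)
    for phase, alt in subs:
        combined[phase] = alt
    joint = "".join(combined)
    if str(Seq(joint).translate()) == "*":
        return "nonsense_retained"
    if str(Seq(joint).translate()) == str(Seq(ref_codon).translate()):
        return "synonymous"
    return "missense"


class TestCombineMnv:
    def test_stop_rescued_to_missense(self):
        # TCA with phased C>G (TGA alone) + A>G: joint TGG = Trp
        seq, cm, group = _mnv_case("TCA", [(1, "G"), (2, "G")], "+")
        assert combine_mnv(group, cm, seq) == "missense"

    def test_stop_retained(self):
        # GAA with G>T (TAA alone) + A>G at phase 2: joint TAG is still a stop
        seq, cm, group = _mnv_case("GAA", [(0, "T"), (2, "G")], "+")
        assert combine_mnv(group, cm, seq) == "nonsense_retained"

    def test_single_snv_is_not_an_mnv(self):
        seq, cm, group = _mnv_case("TCA", [(1, "G")], "+")
        assert combine_mnv(group, cm, seq) == "not_mnv"

    def test_snvs_in_different_codons_are_not_an_mnv(self):
        cds = "ATG" + "TCA" + "GGG" + "TAA"
        seq = "C" * 10 + cds + "C" * 10
        exons = [(10, 22)]
        tx = TranscriptModel("t", "g", "+", exons, list(exons))
        cm = build_coding_map(tx)
        group = PhaseGroup("pg", [
            VariantBundle("c", 15, "C", "G", "other"),
            VariantBundle("c", 17, "G", "T", "other"),
        ])
        assert combine_mnv(group, cm, seq) == "not_mnv"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_agrees_with_full_haplotype_translation(self, strand):
        """Exhaustive oracle check: all 64 ref codons x phased SNV pairs."""
        for c1 in BASES:
            for c2 in BASES:
                for c3 in BASES:
                    ref = c1 + c2 + c3
                    for p1, p2 in ((0, 1), (1, 2), (0, 2)):
                        a1 = BASES[(BASES.index(ref[p1]) + 1) % 4]
                        a2 = BASES[(BASES.index(ref[p2]) + 2) % 4]
                        subs = [(p1, a1), (p2, a2)]
                        seq, cm, group = _mnv_case(ref, subs, strand)
                        assert combine_mnv(group, cm, seq) == _mnv_oracle(ref, subs)


def _indel(pos, delta):
    if delta > 0:
        return VariantBundle("c", pos, "A", "A" + "T" * delta, "other")
    return VariantBundle("c", pos, "A" + "T" * (-delta), "A", "other")


class TestNetIndelFrame:
    def test_plus_one_minus_one_pair_restores_frame(self):
        g = PhaseGroup("p", [_indel(100, 1), _indel(112, -1)])
        assert net_indel_frame(g, CONSERVATIVE) == (0, True)

    def test_aggregate_minus_three_restores_frame(self):
        g = PhaseGroup("p", [_indel(100, -1), _indel(110, -2)])
        assert net_indel_frame(g, CONSERVATIVE) == (0, True)

    def test_lone_indel_is_not_restoring(self):
        g = PhaseGroup("p", [_indel(100, -1)])
        assert net_indel_frame(g, CONSERVATIVE) == (2, False)

    def test_distant_pair_beyond_window_not_restoring(self):
        g = PhaseGroup("p", [_indel(100, 1), _indel(300, -1)])
        assert net_indel_frame(g, CONSERVATIVE) == (0, False)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from([-3, -2, -1, 1, 2, 3]), min_size=2, max_size=6))
    def test_permutation_invariant_and_additive(self, deltas):
        members = [_indel(100 + 3 * i, d) for i, d in enumerate(deltas)]
        net, _ = net_indel_frame(PhaseGroup("p", members), CONSERVATIVE)
        net_rev, _ = net_indel_frame(
            PhaseGroup("p", list(reversed(members))), CONSERVATIVE)
        assert net == net_rev == sum(deltas) % 3
        # additivity mod 3 across two halves
        h1, h2 = deltas[:1], deltas[1:]
        n1 = sum(h1) % 3
        n2 = sum(h2) % 3
        assert net == (n1 + n2) % 3


def _reinit_tx(n_codons, atg_codon=None):
    codons = ["ATG"] + ["CTG"] * (n_codons - 2) + ["TAA"]
    if atg_codon is not None:
        codons[atg_codon] = "ATG"
    cds = "".join(codons)
    seq = "C" * 10 + cds + "C" * 10
    exons = [(10, 10 + len(cds))]
    tx = TranscriptModel("t", "g", "+", exons, list(exons))
    return build_coding_map(tx), seq, tx


class TestReinitiation:
    def test_early_methionine_is_strong(self):
        cm, seq, tx = _reinit_tx(400, atg_codon=12)
        assert reinitiation_class(cm, seq, tx, CONSERVATIVE) == "strong"
        # 36/1200 = 3% of the CDS removed
        assert 36 / cm.cds_length < CONSERVATIVE.reinit_strong_max_fraction

    def test_late_methionine_removes_too_much(self):
        cm, seq, tx = _reinit_tx(400, atg_codon=150)
        assert reinitiation_class(cm, seq, tx, CONSERVATIVE) == "removes_gt_threshold"

    def test_no_inframe_atg_means_none(self):
        cm, seq, tx = _reinit_tx(400)
        assert reinitiation_class(cm, seq, tx, CONSERVATIVE) == "none"

    def test_weak_conservation_demotes_strong_to_weak(self):
        cm, seq, tx = _reinit_tx(400, atg_codon=12)
        assert reinitiation_class(
            cm, seq, tx, CONSERVATIVE, first_exon_conservation=0.3) == "weak"


class TestTechnicalContext:
    def _v(self, depth=40, gq=60, ab=0.475, sb=None):
        return VariantBundle(
            "c", 51, "G", "T", "nonsense",
            qc=QCMetrics(depth=depth, genotype_quality=gq, allele_balance=ab,
                         strand_bias=sb),
        )

    def _low_gc_ctx(self):
        return RefContext("AT" * 60, 0)

    def test_low_depth_under_conservative(self):
        flags = technical_context(self._v(depth=12), self._low_gc_ctx(), 0,
                                  CONSERVATIVE)
        assert flags == {"low_depth"}
        assert technical_context(self._v(depth=12), self._low_gc_ctx(), 0,
                                 LENIENT) == set()

    def test_gc_rich_window(self):
        ctx = RefContext("G" * 78 + "A" * 23, 0)
        assert "gc_rich" in technical_context(self._v(), ctx, 0, CONSERVATIVE)

    def test_clean_variant_has_no_flags(self):
        assert technical_context(self._v(), self._low_gc_ctx(), 0,
                                 CONSERVATIVE) == set()

    def test_strand_bias_needs_extreme_fraction_and_alt_reads(self):
        assert "strand_bias" in technical_context(
            self._v(sb=0.98), self._low_gc_ctx(), 0, CONSERVATIVE)
        assert "strand_bias" not in technical_context(
            self._v(sb=0.5), self._low_gc_ctx(), 0, CONSERVATIVE)
        few_reads = self._v(depth=10, ab=0.5, sb=0.98)  # 5 ALT reads
        assert "strand_bias" not in technical_context(
            few_reads, self._low_gc_ctx(), 0, CONSERVATIVE)

    @pytest.mark.parametrize(
        ("count", "profile", "expected"),
        [
            (0, CONSERVATIVE, set()),
            (4, CONSERVATIVE, {"minor_mapping"}),
            (6, CONSERVATIVE, {"complex_mapping"}),
            (4, LENIENT, {"complex_mapping"}),
        ],
    )
    def test_repeat_track_threshold_bands(
            self, count, profile, expected):
        assert technical_context(self._v(), self._low_gc_ctx(), count,
                                 profile) == expected

    @settings(max_examples=80, derandomize=True)
    @given(
        depth=st.integers(0, 60),
        gq=st.integers(0, 90),
        ab=st.floats(0.0, 1.0),
    )
    def test_lenient_flags_nest_within_conservative(self, depth, gq, ab):
        """With fixed repeat overlap, lenient thresholds flag a subset of what
        the conservative thresholds flag (the repeat rule is the documented
        exception and is held at zero overlap here)."""
        v = self._v(depth=depth, gq=gq, ab=ab)
        lenient = technical_context(v, self._low_gc_ctx(), 0, LENIENT)
        conservative = technical_context(v, self._low_gc_ctx(), 0, CONSERVATIVE)
        assert lenient <= conservative
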