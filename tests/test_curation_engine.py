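"""Flag assembly, verdict precedence and PVS1 non-additivity."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lofcurate.curation_engine import (
    FLAG_CATALOG,
    CurationContext,
    assign_flags,
    curate_cohort,
    make_flag,
    primary_reason,
    pvs1_decision,
    resolve_verdict,
)
from lofcurate.fixtures import generate_scenario, scenario_resources
from lofcurate.gene_geometry import build_coding_map
from lofcurate.models import (
    CONSERVATIVE,
    LENIENT,
    PROFILES,
    FlagCategory,
    PextTrack,
    PVS1Strength,
    QCMetrics,
    TranscriptModel,
    VariantBundle,
    Verdict,
)

# one representative Flag instance per catalog entry (fraction-carrying flags
# get both a small and a large truncation fraction)
ALL_FLAGS = [
    make_flag(name, data=(("fraction_removed", 0.05),))
    for name in sorted(FLAG_CATALOG)
] + [
    make_flag(name, data=(("fraction_removed", 0.2),))
    for name in ("splice_rescue_weak", "reinitiation_strong", "last_exon_nmd",
                 "in_frame_exon_skip")
]
NON_TECHNICAL = [f for f in ALL_FLAGS if f.category is not FlagCategory.TECHNICAL]


class TestAssignFlags:
    def test_low_pext_nonsense(self, curated_catalog):
        _, result, _ = curated_catalog[("low_pext", "conservative")]
        assert result.flag_names() == {"low_pext"}
        assert all(f.tier is Verdict.NOT_LOF for f in result.flags)

    def test_clean_nonsense_has_empty_flag_set(self, curated_catalog):
        for prof in PROFILES:
            _, result, _ = curated_catalog[("clean_nonsense", prof)]
            assert result.flags == frozenset()

    def test_joint_homopolymer_and_low_depth(self):
        """A frameshift deletion in an A x5 run from a depth-12 genotype
        triggers both technical rules under the conservative profile."""
        scn = generate_scenario("homopolymer_frameshift", seed=1)
        # shorten the run to 5 by editing the two bases after the fifth A
        pos0 = scn.primary.pos0
        seq = scn.seq[: pos0 + 6] + "CT" + scn.seq[pos0 + 8 :]
        tx = scn.transcripts[0]
        ctx = CurationContext(transcript=tx, cmap=build_coding_map(tx),
                              all_coding_transcripts=[tx], pext=scn.pext,
                              ref_seq=seq)
        bundle = scn.primary
        bundle.qc = QCMetrics(depth=12, genotype_quality=60, allele_balance=0.5)
        flags, _ = assign_flags(bundle, ctx, CONSERVATIVE)
        assert {f.name for f in flags} == {"homopolymer", "low_depth"}
        lenient_flags, _ = assign_flags(bundle, ctx, LENIENT)
        assert {f.name for f in lenient_flags} == set()

    def test_missing_context_recorded_in_audit_never_silently(self):
        tx = TranscriptModel("t", "g", "+", [(50, 350)], [(50, 350)])
        bundle = VariantBundle("c", 101, "G", "T", "nonsense",
                               transcripts_hit=[("t", True)])
        ctx = CurationContext(transcript=tx, cmap=build_coding_map(tx),
                              all_coding_transcripts=[tx])
        _, audit = assign_flags(bundle, ctx, CONSERVATIVE)
        joined = " ".join(audit)
        assert "reference sequence" in joined
        assert "pext" in joined
        assert "conservation" in joined


class TestResolveVerdict:
    def test_frameshift_without_reads_defaults_to_uncertain(self):
        assert resolve_verdict(set(), "frameshift", False) is Verdict.UNCERTAIN_LOF

    def test_max_tier_precedence(self):
        flags = {make_flag("minority_at_max"), make_flag("homopolymer")}
        assert resolve_verdict(flags, "nonsense", True) is Verdict.LIKELY_NOT_LOF

    def test_clean_nonsense_is_lof(self):
        assert resolve_verdict(set(), "nonsense", True) is Verdict.LOF

    @settings(max_examples=80, derandomize=True)
    @given(
        subset=st.sets(st.sampled_from(range(len(ALL_FLAGS))), max_size=6),
        extra=st.sampled_from(range(len(ALL_FLAGS))),
    )
    def test_monotone_in_flag_set_inclusion(self, subset, extra):
        """Adding a flag never moves the verdict toward LoF."""
        flags = {ALL_FLAGS[i] for i in subset}
        before = resolve_verdict(flags, "nonsense", True)
        after = resolve_verdict(flags | {ALL_FLAGS[extra]}, "nonsense", True)
        assert after.rank >= before.rank

    def test_uncertain_baseline_outranked_only_by_higher_tier(self):
        """Frameshift without reads is uncertain unless a higher-impact flag
        fires; lower-tier flags do not pull it back toward LoF."""
        low_tier = {make_flag("minor_mapping")}         # likely_LoF
        high_tier = {make_flag("homopolymer")}          # likely_not_LoF
        assert resolve_verdict(low_tier, "frameshift", False) is Verdict.UNCERTAIN_LOF
        assert resolve_verdict(high_tier, "frameshift", False) is Verdict.LIKELY_NOT_LOF


class TestPrimaryReason:
    def test_none_for_empty(self):
        assert primary_reason(set()) == "none"

    def test_highest_tier_wins_then_category_order(self):
        flags = {make_flag("minority_at_max"), make_flag("homopolymer")}
        assert primary_reason(flags) == "homopolymer"
        tie = {make_flag("low_pext"), make_flag("mnv_rescue")}  # both not_LoF
        assert primary_reason(tie) == "mnv_rescue"  # rescue outranks relevance


class TestPVS1:
    def test_worst_consequence_wins_not_the_sum(self):
        flags = {
            make_flag("splice_rescue_weak", data=(("fraction_removed", 0.05),)),
            make_flag("low_pext"),
        }
        d = pvs1_decision(Verdict.NOT_LOF, flags)
        assert d.max_strength is PVS1Strength.NOT_APPLICABLE

    def test_technical_flag_requires_confirmation(self):
        d = pvs1_decision(Verdict.LIKELY_NOT_LOF, {make_flag("homopolymer")})
        assert d.requires_analytical_confirmation
        assert d.reported_strength == "pending_confirmation"

    def test_confirmed_technical_flag_does_not_modify_pvs1(self):
        d = pvs1_decision(Verdict.LIKELY_NOT_LOF, {make_flag("homopolymer")},
                          analytically_confirmed=True)
        assert d.max_strength is PVS1Strength.VERY_STRONG
        assert d.reported_strength == "very_strong"

    def test_no_flags_leaves_full_strength(self):
        d = pvs1_decision(Verdict.LOF, set())
        assert d.max_strength is PVS1Strength.VERY_STRONG

    def test_fraction_splits_cap_strong_vs_moderate(self):
        small = pvs1_decision(Verdict.LIKELY_NOT_LOF, {
            make_flag("last_exon_nmd", data=(("fraction_removed", 0.05),))})
        large = pvs1_decision(Verdict.LIKELY_NOT_LOF, {
            make_flag("last_exon_nmd", data=(("fraction_removed", 0.15),))})
        assert small.max_strength is PVS1Strength.STRONG
        assert large.max_strength is PVS1Strength.MODERATE

    @settings(max_examples=100, derandomize=True)
    @given(subset=st.sets(st.sampled_from(range(len(NON_TECHNICAL))),
                          min_size=1, max_size=5))
    def test_non_additive_equals_single_worst_flag(self, subset):
        flags = {NON_TECHNICAL[i] for i in subset}
        combined = pvs1_decision(Verdict.NOT_LOF, flags)
        singles = [pvs1_decision(Verdict.NOT_LOF, {f}) for f in flags]
        strengths = [PVS1Strength.VERY_STRONG, PVS1Strength.STRONG,
                     PVS1Strength.MODERATE, PVS1Strength.SUPPORTING,
                     PVS1Strength.NOT_APPLICABLE]
        worst_single = max(
            (s.max_strength for s in singles), key=strengths.index)
        assert combined.max_strength is worst_single


class TestProfileOrdering:
    def test_conservative_at_least_as_far_from_lof(self, curated_catalog):
        """Where the profiles disagree, conservative sits at or beyond the
        lenient verdict — except the documented repeat-track anomaly."""
        names = {name for name, _ in curated_catalog}
        for name in names:
            _, cons, _ = curated_catalog[(name, "conservative")]
            _, len_, _ = curated_catalog[(name, "lenient")]
            if name == "minor_mapping":
                assert cons.verdict.rank < len_.verdict.rank  # the anomaly
            else:
                assert cons.verdict.rank >= len_.verdict.rank


class TestWorstTranscriptAggregation:
    def test_most_lofward_transcript_defines_the_call(self):
        """A variant pLoF in two transcripts takes the verdict of the
        transcript where it matters most (closest to LoF)."""
        scn = generate_scenario("low_pext", seed=1)
        tx1 = scn.transcripts[0]
        # second isoform identical but with maximal pext for its exons
        tx2 = TranscriptModel("t_alt", tx1.gene_id, tx1.strand,
                              list(tx1.exons), list(tx1.cds_intervals))
        scn.transcripts.append(tx2)
        scn.pext.exon_means.update({("t_alt", i): 0.8 for i in range(3)})
        b = scn.primary
        b.transcripts_hit = [(tx1.transcript_id, True), ("t_alt", True)]
        result, _ = curate_cohort(
            scn.bundles, scenario_resources(scn), CONSERVATIVE)[0]
        assert result.verdict is Verdict.LOF  # clean in t_alt
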