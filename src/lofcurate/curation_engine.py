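"""Flag assembly, verdict resolution and PVS1 strength adjustment.

The engine evaluates every applicable rule for one variant against one
transcript, emits :class:`~lofcurate.models.Flag` objects carrying the verdict
tier each rule maps to, resolves the five-level verdict by precedence (the most
impactful consequence wins), and computes the maximum allowed ACMG/AMP PVS1
strength from the single worst flag consequence (downgrading is by worst
consequence, never additive).

Technical-artifact flags do not modify PVS1: they demand analytical
confirmation of the call first, because only a real variant can confer risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import gene_geometry as gg
from . import sequence_rules as sr
from . import splice_rules as spl
from .models import (
    CATEGORY_ORDER,
    CONSEQUENCE_TO_STRENGTH,
    CurationResult,
    Flag,
    FlagCategory,
    PextTrack,
    PVS1Consequence,
    PVS1Decision,
    RuleProfile,
    TranscriptModel,
    VariantBundle,
    Verdict,
    worst_verdict,
)

# --------------------------------------------------------------------------
# Flag catalog: name -> (category, verdict tier). The tier placement follows
# the published rule table; placements the extracted table leaves ambiguous
# are resolved as documented in docs/methods.md.
# --------------------------------------------------------------------------
_R = FlagCategory.RESCUE
_B = FlagCategory.BIOLOGICAL_RELEVANCE
_T = FlagCategory.TECHNICAL

FLAG_CATALOG: dict[str, tuple[FlagCategory, Verdict]] = {
    # rescue by secondary sequence properties
    "splice_retained_stop": (_R, Verdict.LOF),
    "intron_retention": (_R, Verdict.LOF),
    "splice_out_of_frame": (_R, Verdict.LOF),
    "out_of_frame_exon_skip": (_R, Verdict.LOF),
    "reinitiation_removes_gt_threshold": (_R, Verdict.LIKELY_LOF),
    "reinitiation_weak": (_R, Verdict.UNCERTAIN_LOF),
    "mixed_splice_events": (_R, Verdict.UNCERTAIN_LOF),
    "splice_rescue_weak": (_R, Verdict.LIKELY_NOT_LOF),
    "reinitiation_strong": (_R, Verdict.LIKELY_NOT_LOF),
    "splice_rescue_strong": (_R, Verdict.NOT_LOF),
    "in_frame_exon_skip": (_R, Verdict.NOT_LOF),
    "overhang_exon": (_R, Verdict.NOT_LOF),
    "mnv_rescue": (_R, Verdict.NOT_LOF),
    "frame_restoring_indel": (_R, Verdict.NOT_LOF),
    # uncertain biological relevance
    "minority_at_max": (_B, Verdict.LOF),
    "weak_conservation_at_max": (_B, Verdict.LOF),
    "minority_close_to_max": (_B, Verdict.LIKELY_LOF),
    "weak_conservation_close_to_max": (_B, Verdict.LIKELY_LOF),
    "minority_mid": (_B, Verdict.UNCERTAIN_LOF),
    "weak_conservation_mid": (_B, Verdict.LIKELY_NOT_LOF),
    "overprinting": (_B, Verdict.LIKELY_NOT_LOF),
    "last_exon_nmd": (_B, Verdict.LIKELY_NOT_LOF),
    "low_pext": (_B, Verdict.NOT_LOF),
    "splice_not_supported_by_pext": (_B, Verdict.NOT_LOF),
    # potential technical artifacts
    "no_read_data": (_T, Verdict.UNCERTAIN_LOF),  # frameshift without reads
    "minor_mapping": (_T, Verdict.LIKELY_LOF),
    "low_depth": (_T, Verdict.LIKELY_NOT_LOF),
    "low_gq": (_T, Verdict.LIKELY_NOT_LOF),
    "skewed_ab": (_T, Verdict.LIKELY_NOT_LOF),
    "strand_bias": (_T, Verdict.LIKELY_NOT_LOF),
    "gc_rich": (_T, Verdict.LIKELY_NOT_LOF),
    "low_complexity": (_T, Verdict.LIKELY_NOT_LOF),
    "homopolymer": (_T, Verdict.LIKELY_NOT_LOF),
    "complex_mapping": (_T, Verdict.LIKELY_NOT_LOF),
}

#: PVS1 consequence of each non-technical flag. Flags in _PVS1_BY_FRACTION are
#: capped at Strong when they remove <10% of the CDS and at Moderate when they
#: remove >=10% (mirroring the SVI decision-tree split for truncations).
_PVS1_DO_NOT_USE = {
    "low_pext",
    "splice_not_supported_by_pext",
    "overhang_exon",
    "overprinting",
    "mnv_rescue",
    "frame_restoring_indel",
    "splice_rescue_strong",
}
_PVS1_CAP_STRONG = {"reinitiation_weak", "mixed_splice_events", "minority_mid",
                    "weak_conservation_mid"}
_PVS1_BY_FRACTION = {"splice_rescue_weak", "reinitiation_strong", "last_exon_nmd",
                     "in_frame_exon_skip"}
PVS1_CAP_MODERATE_FRACTION = 0.10


def make_flag(name: str, detail: str = "", data: tuple = ()) -> Flag:
    cat, tier = FLAG_CATALOG[name]
    return Flag(name=name, category=cat, tier=tier, detail=detail, data=data)


@dataclass
class CurationContext:
    """Everything one variant's rules may consult, for one assessed transcript.

    Missing optional members cause the dependent rules to be skipped with an
    audit note, never silently.
    """

    transcript: TranscriptModel
    cmap: gg.CodingMap
    all_coding_transcripts: list[TranscriptModel] = field(default_factory=list)
    pext: Optional[PextTrack] = None
    ref_seq: Optional[str] = None
    repeat_overlap_count: int = 0
    in_low_complexity: bool = False
    phase_group: Optional[sr.PhaseGroup] = None
    conservation: Optional[dict[tuple[str, int], float]] = None


def _termination_offset(
    bundle: VariantBundle, ctx: CurationContext
) -> Optional[int]:
    """Coding offset of the termination event used by fraction/NMD rules.

    Nonsense/frameshift: the variant base itself (the downstream premature stop
    of a frameshift is approximated by the variant site). Splice acceptor: the
    first coding base of the affected exon; splice donor: the base after the
    last coding base of the affected exon (= the first lost coding base).
    """
    cmap = ctx.cmap
    if bundle.variant_class in ("nonsense", "frameshift"):
        return cmap.coding_offset(bundle.pos0)
    exon_i = spl.find_affected_exon(ctx.transcript, bundle)
    if exon_i is None:
        return None
    try:
        coding_i = cmap.exon_indices.index(exon_i)
    except ValueError:
        return None
    if bundle.variant_class == "splice_acceptor":
        off = sum(cmap.exon_cds_lengths[:coding_i])
    else:
        off = sum(cmap.exon_cds_lengths[: coding_i + 1])
    return off if off < cmap.cds_length else None


def assign_flags(
    bundle: VariantBundle, ctx: CurationContext, profile: RuleProfile
) -> tuple[set[Flag], list[str]]:
    """Evaluate every applicable rule; return triggered flags and audit notes."""
    flags: set[Flag] = set()
    audit: list[str] = []

    def add(name: str, detail: str = "", **data) -> None:
        flags.add(make_flag(name, detail, tuple(sorted(data.items()))))

    cmap = ctx.cmap
    tx = ctx.transcript
    ref = ctx.ref_seq
    ref_ctx = sr.RefContext(ref, 0) if ref is not None else None

    # ---- technical artifacts -------------------------------------------
    for sub in sr.technical_context(
        bundle, ref_ctx, ctx.repeat_overlap_count, profile, ctx.in_low_complexity
    ):
        add(sub)
    if ref_ctx is None:
        audit.append("no reference sequence: GC/homopolymer rules skipped")
    elif bundle.is_indel:
        try:
            run, hp = sr.homopolymer_run(ref_ctx, bundle, profile)
            if hp:
                add("homopolymer", f"run length {run}", run_length=run)
        except ValueError as exc:
            audit.append(f"homopolymer rule skipped: {exc}")
    if bundle.variant_class == "frameshift" and not bundle.has_read_data:
        add("no_read_data", "frameshift without read data for visual confirmation")

    # ---- haplotype rescues ---------------------------------------------
    if ctx.phase_group is not None and len(ctx.phase_group.members) > 1:
        if bundle.variant_class == "nonsense":
            if ref is None:
                audit.append("no reference sequence: MNV rule skipped")
            else:
                joint = sr.combine_mnv(ctx.phase_group, cmap, ref)
                if joint in ("missense", "synonymous"):
                    add("mnv_rescue", f"combined codon is {joint}")
        if bundle.variant_class == "frameshift":
            net, restoring = sr.net_indel_frame(ctx.phase_group, profile)
            if restoring:
                add("frame_restoring_indel", f"net shift {net} over phased indels")
    elif bundle.phase_group_id is not None and ctx.phase_group is None:
        audit.append("phase group annotated but not supplied: MNV/indel rules skipped")

    # ---- geometry: termination position --------------------------------
    term_off = _termination_offset(bundle, ctx)
    if term_off is None:
        audit.append("termination position outside CDS: geometry rules skipped")

    # ---- splice interpretation -----------------------------------------
    affected_exon_i: Optional[int] = None
    pext_cat: Optional[str] = None
    if bundle.variant_class in ("splice_donor", "splice_acceptor"):
        affected_exon_i = spl.find_affected_exon(tx, bundle)
        if affected_exon_i is not None and ctx.pext is not None and ctx.pext.gene_max > 0:
            pext_cat = gg.pext_category(
                ctx.pext, tx.transcript_id, affected_exon_i, profile
            )
        event = spl.classify_splice_event(
            bundle, cmap, tx, bundle.spliceai, profile,
            ref_seq=ref, adjacent_exon_pext_low=(pext_cat == "low"),
        )
        _add_splice_flags(event, add, audit, profile)
        if ctx.pext is not None and affected_exon_i is not None and ctx.pext.gene_max > 0:
            if not spl.splice_pext_support(ctx.pext, tx, affected_exon_i, profile):
                add("splice_not_supported_by_pext",
                    "adjacent exon pext low or no drop across junction")
        elif ctx.pext is None:
            audit.append("no pext track: splice pext-support rule skipped")
    else:
        exon_i = tx.exon_index_at(bundle.pos0)
        affected_exon_i = exon_i
        if exon_i is not None and ctx.pext is not None and ctx.pext.gene_max > 0:
            pext_cat = gg.pext_category(ctx.pext, tx.transcript_id, exon_i, profile)

    # ---- translational reinitiation ------------------------------------
    if (
        bundle.variant_class in ("nonsense", "frameshift")
        and term_off is not None
        and cmap.coding_exon_of_offset(term_off) == 0
    ):
        if ref is None:
            audit.append("no reference sequence: reinitiation rule skipped")
        else:
            cons0 = None
            if ctx.conservation is not None:
                cons0 = ctx.conservation.get((tx.transcript_id, cmap.exon_indices[0]))
            cls = sr.reinitiation_class(
                cmap, ref, tx, profile,
                lesion_coding_offset=term_off, first_exon_conservation=cons0,
            )
            if cls != "none":
                atg = sr.first_inframe_atg_offset(cmap, ref, term_off)
                frac = atg / cmap.cds_length if atg is not None else 0.0
                name = {
                    "strong": "reinitiation_strong",
                    "weak": "reinitiation_weak",
                    "removes_gt_threshold": "reinitiation_removes_gt_threshold",
                }[cls]
                add(name, f"in-frame ATG at coding offset {atg}", fraction_removed=frac)

    # ---- NMD escape / last exon ----------------------------------------
    if term_off is not None:
        frac = (cmap.cds_length - term_off) / cmap.cds_length
        gpos = cmap.genomic_at_offset(term_off)
        if gg.nmd_escape(cmap, tx, gpos, profile):
            if frac < profile.truncation_max_fraction:
                add("last_exon_nmd",
                    f"termination escapes NMD, removes {frac:.3f} of CDS",
                    fraction_removed=frac)
            else:
                audit.append(
                    f"NMD escape but {frac:.3f} of CDS removed >= "
                    f"{profile.truncation_max_fraction}: no rescue flag"
                )

    # ---- pext / transcript-relevance rules -----------------------------
    if ctx.pext is None:
        audit.append("no pext track: pext rules skipped")
    elif ctx.pext.gene_max <= 0:
        audit.append("pext uninformative (gene_max 0): pext rules skipped")
    elif pext_cat is None:
        audit.append("no pext value for the affected exon: pext rules skipped")
    elif pext_cat == "low" and bundle.variant_class in ("nonsense", "frameshift"):
        add("low_pext", "exon mean pext <= low ratio of gene maximum")

    n_coding = len(ctx.all_coding_transcripts) or 1
    if gg.minority_of_transcripts(bundle, n_coding, profile):
        if pext_cat == "at_max":
            add("minority_at_max")
        elif pext_cat == "close_to_max":
            add("minority_close_to_max")
        elif pext_cat == "mid":
            add("minority_mid")
        elif pext_cat is None:
            audit.append("minority of transcripts but no pext value: rule not tiered")

    if ctx.conservation is None:
        audit.append("no conservation track: weak-conservation rule skipped")
    elif affected_exon_i is not None:
        weak = gg.weak_exon_conservation(
            ctx.conservation, tx.transcript_id, affected_exon_i
        )
        if weak:
            if pext_cat == "at_max":
                add("weak_conservation_at_max")
            elif pext_cat == "close_to_max":
                add("weak_conservation_close_to_max")
            elif pext_cat == "mid":
                add("weak_conservation_mid")

    if bundle.variant_class in ("nonsense", "frameshift"):
        others = [
            t for t in ctx.all_coding_transcripts
            if t.transcript_id != tx.transcript_id
        ]
        if others and gg.is_overhang_position(tx, others, bundle.pos0, profile):
            add("overhang_exon", "position spliced out in majority of transcripts")

    if bundle.variant_class == "nonsense" and "overprinted" in tx.tags:
        add("overprinting", "stop codon lies in novel overlapping reading frame")

    return flags, audit


def _add_splice_flags(event: spl.SpliceEvent, add, audit: list[str],
                      profile: RuleProfile) -> None:
    frac = event.fraction_removed if event.fraction_removed is not None else 0.0
    if event.kind == "in_frame_cryptic_rescue":
        if event.stop_in_retained:
            add("splice_retained_stop", "retained intronic sequence contains a stop")
        elif event.strength == "strong":
            add("splice_rescue_strong", event.detail, fraction_removed=frac)
        else:
            add("splice_rescue_weak", event.detail, fraction_removed=frac)
    elif event.kind == "out_of_frame_cryptic":
        add("splice_out_of_frame", event.detail)
    elif event.kind == "in_frame_exon_skip":
        if frac < profile.truncation_max_fraction:
            add("in_frame_exon_skip", event.detail, fraction_removed=frac)
        else:
            audit.append(
                f"in-frame exon skip removes {frac:.3f} >= "
                f"{profile.truncation_max_fraction} of CDS: not a rescue"
            )
    elif event.kind == "out_of_frame_exon_skip":
        add("out_of_frame_exon_skip", event.detail)
    elif event.kind == "intron_retention":
        add("intron_retention", event.detail)
    elif event.kind == "multiple_events":
        add("mixed_splice_events", event.detail)
    elif event.kind == "uncertain":
        audit.append(f"splice outcome uncertain: {event.detail}")
    # non_essential_site carries no rescue flag; the pext-support rule flags it


def resolve_verdict(
    flags: set[Flag], variant_class: str, has_read_data: bool
) -> Verdict:
    """Most impactful tier among the flags, with the frameshift-without-reads
    baseline of uncertain_LoF (outranked only by higher-tier flags)."""
    baseline = (
        Verdict.UNCERTAIN_LOF
        if variant_class == "frameshift" and not has_read_data
        else Verdict.LOF
    )
    return worst_verdict([f.tier for f in flags] + [baseline])


def primary_reason(flags: set[Flag]) -> str:
    """The triggered flag with the highest verdict tier; ties broken by the
    fixed category order rescue > biological_relevance > technical, then
    lexicographically."""
    if not flags:
        return "none"
    return min(
        flags, key=lambda f: (-f.tier.rank, CATEGORY_ORDER[f.category], f.name)
    ).name


def pvs1_consequence(flag: Flag) -> PVS1Consequence:
    """PVS1 consequence of a single non-technical flag."""
    if flag.name in _PVS1_DO_NOT_USE:
        return PVS1Consequence.DO_NOT_USE
    if flag.name in _PVS1_CAP_STRONG:
        return PVS1Consequence.CAP_STRONG
    if flag.name in _PVS1_BY_FRACTION:
        frac = flag.datum("fraction_removed", 0.0)
        if frac >= PVS1_CAP_MODERATE_FRACTION:
            return PVS1Consequence.CAP_MODERATE
        return PVS1Consequence.CAP_STRONG
    return PVS1Consequence.NO_CHANGE


def pvs1_decision(
    verdict: Verdict, flags: set[Flag], analytically_confirmed: bool = False
) -> PVS1Decision:
    """Maximum allowed PVS1 strength given the flags.

    Any technical flag on an unconfirmed variant leaves the strength pending
    analytical confirmation. Otherwise the single worst per-flag consequence
    applies (non-additive).
    """
    technical = [f for f in flags if f.category == FlagCategory.TECHNICAL]
    if technical and not analytically_confirmed:
        return PVS1Decision(
            max_strength=None,
            requires_analytical_confirmation=True,
            analytically_confirmed=False,
            trail=[(f.name, "requires_analytical_confirmation") for f in sorted(
                technical, key=lambda f: f.name)],
        )
    trail: list[tuple[str, str]] = []
    worst = PVS1Consequence.NO_CHANGE
    for f in sorted(flags, key=lambda f: f.name):
        if f.category == FlagCategory.TECHNICAL:
            trail.append((f.name, "analytically_confirmed; no PVS1 effect"))
            continue
        cons = pvs1_consequence(f)
        trail.append((f.name, cons.value))
        if cons.rank > worst.rank:
            worst = cons
    return PVS1Decision(
        max_strength=CONSEQUENCE_TO_STRENGTH[worst],
        requires_analytical_confirmation=bool(technical),
        analytically_confirmed=analytically_confirmed,
        trail=trail,
    )


@dataclass
class CohortResources:
    """All gene-level inputs needed to curate a set of variant bundles."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    ref_by_chrom: dict[str, str] = field(default_factory=dict)
    pext_by_gene: dict[str, PextTrack] = field(default_factory=dict)
    repeat_tracks: list = field(default_factory=list)
    conservation_by_gene: dict[str, dict] = field(default_factory=dict)

    def coding_transcripts_of_gene(self, gene_id: str) -> list[TranscriptModel]:
        return [
            t for t in self.transcripts.values()
            if t.gene_id == gene_id and t.is_coding
        ]


def build_phase_groups(bundles: list[VariantBundle]) -> dict[str, sr.PhaseGroup]:
    groups: dict[str, list[VariantBundle]] = {}
    for b in bundles:
        if b.phase_group_id is not None:
            groups.setdefault(b.phase_group_id, []).append(b)
    return {gid: sr.PhaseGroup(gid, members) for gid, members in groups.items()}


def curate_cohort(
    bundles: list[VariantBundle],
    resources: CohortResources,
    profile: RuleProfile,
    analytically_confirmed: bool = False,
) -> list[tuple[CurationResult, PVS1Decision]]:
    """Curate every pLoF bundle against its most biologically relevant transcript.

    Each variant is assessed against every coding transcript in which it is
    annotated pLoF; the per-transcript result closest to the LoF end of the
    verdict order wins (the transcript where the variant matters most defines
    the call). Phased partner variants (class ``other``) contribute to phase
    groups but are not themselves curated.
    """
    from .io_formats import in_low_complexity, repeat_overlap_count

    phase_groups = build_phase_groups(bundles)
    out: list[tuple[CurationResult, PVS1Decision]] = []
    for b in bundles:
        if b.variant_class == "other":
            continue
        candidates = [
            tid for tid in b.plof_transcript_ids()
            if tid in resources.transcripts and resources.transcripts[tid].is_coding
        ]
        if not candidates:
            import warnings

            warnings.warn(f"{b.key}: no coding transcript annotation; skipped",
                          stacklevel=2)
            continue
        best: Optional[tuple[CurationResult, PVS1Decision]] = None
        for tid in candidates:
            tx = resources.transcripts[tid]
            ctx = CurationContext(
                transcript=tx,
                cmap=gg.build_coding_map(tx),
                all_coding_transcripts=resources.coding_transcripts_of_gene(tx.gene_id),
                pext=resources.pext_by_gene.get(tx.gene_id),
                ref_seq=resources.ref_by_chrom.get(b.chrom),
                repeat_overlap_count=repeat_overlap_count(
                    resources.repeat_tracks, b.chrom, b.pos0
                ),
                in_low_complexity=in_low_complexity(
                    resources.repeat_tracks, b.chrom, b.pos0
                ),
                phase_group=phase_groups.get(b.phase_group_id)
                if b.phase_group_id else None,
                conservation=resources.conservation_by_gene.get(tx.gene_id),
            )
            pair = curate_variant(b, ctx, profile, analytically_confirmed)
            if best is None or pair[0].verdict.rank < best[0].verdict.rank:
                best = pair
        assert best is not None
        out.append(best)
    return out


def curate_variant(
    bundle: VariantBundle,
    ctx: CurationContext,
    profile: RuleProfile,
    analytically_confirmed: bool = False,
) -> tuple[CurationResult, PVS1Decision]:
    """Full per-variant curation against one assessed transcript."""
    flags, audit = assign_flags(bundle, ctx, profile)
    verdict = resolve_verdict(flags, bundle.variant_class, bundle.has_read_data)
    result = CurationResult(
        variant=bundle,
        flags=frozenset(flags),
        verdict=verdict,
        primary_reason=primary_reason(flags),
        audit=audit,
    )
    decision = pvs1_decision(verdict, flags, analytically_confirmed)
    return result, decision
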