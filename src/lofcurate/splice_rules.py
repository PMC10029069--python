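"""Interpretation of SpliceAI deltas at essential splice sites.

An essential (+/-1-2) splice variant destroys an annotated donor or acceptor.
SpliceAI's gain/loss deltas predict what the spliceosome does instead: use a
cryptic site (in-frame rescue or frameshifting), skip the exon, or retain the
intron. This module turns the four delta scores plus transcript geometry into a
:class:`SpliceEvent`, including scanning partially retained intronic sequence
for termination codons (an in-frame rescue that splices in a stop is still a
loss-of-function outcome).

Offset convention: SpliceAI DP fields are signed genomic offsets from the
variant. The distance between the cryptic and the annotated site is taken as
``dp_gain - dp_loss``: the loss position marks the annotated site being
destroyed, which sits within 2 bp of the variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .gene_geometry import CodingMap, pext_category, revcomp
from .models import (
    PextTrack,
    RuleProfile,
    SpliceAIScores,
    TranscriptModel,
    VariantBundle,
)
from .sequence_rules import STOP_CODONS

SPLICEAI_FIELDS = 10


@dataclass
class SpliceEvent:
    kind: str  # in_frame_cryptic_rescue | out_of_frame_cryptic | in_frame_exon_skip
    #      | out_of_frame_exon_skip | intron_retention | multiple_events
    #      | uncertain | non_essential_site
    strength: str = "n/a"  # strong | weak | n/a (cryptic rescues only)
    retained_interval: Optional[tuple[int, int]] = None
    stop_in_retained: Optional[bool] = None
    fraction_removed: Optional[float] = None
    detail: str = ""


def parse_spliceai_info(info_value: Optional[str], gene_id: str) -> Optional[SpliceAIScores]:
    """Parse the standard 10-field SpliceAI VCF annotation.

    ``ALLELE|SYMBOL|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL``,
    comma-separated per gene; returns the entry whose symbol matches
    ``gene_id``, or None when absent.
    """
    if not info_value:
        return None
    for entry in str(info_value).split(","):
        fields = entry.split("|")
        if len(fields) != SPLICEAI_FIELDS:
            raise ValueError(f"malformed SpliceAI entry ({len(fields)} fields): {entry!r}")
        if fields[1] != gene_id:
            continue
        return SpliceAIScores(
            ds_ag=float(fields[2]),
            ds_al=float(fields[3]),
            ds_dg=float(fields[4]),
            ds_dl=float(fields[5]),
            dp_ag=int(fields[6]),
            dp_al=int(fields[7]),
            dp_dg=int(fields[8]),
            dp_dl=int(fields[9]),
        )
    return None


def find_affected_exon(transcript: TranscriptModel, variant: VariantBundle) -> Optional[int]:
    """Transcript exon index whose essential site the variant disrupts.

    For a donor variant this is the exon immediately 5' of the intron; for an
    acceptor variant the exon immediately 3'. Returns None when the variant is
    not within 2 bp of a matching junction.
    """
    pos = variant.pos0
    plus = transcript.strand == "+"
    for i, (s, e) in enumerate(transcript.exons):
        if variant.variant_class == "splice_donor":
            sites = {e, e + 1} if plus else {s - 1, s - 2}
        elif variant.variant_class == "splice_acceptor":
            sites = {s - 1, s - 2} if plus else {e, e + 1}
        else:
            return None
        if pos in sites:
            return i
    return None


def retained_stop_scan(
    ref_seq: str,
    retained_interval: Optional[tuple[int, int]],
    reading_frame_offset: int,
    strand: str = "+",
    junction_prefix: str = "",
) -> bool:
    """Whether the retained sequence introduces a termination codon.

    ``reading_frame_offset`` is the number of bases of the current codon
    already consumed at the junction (0 = the retained sequence starts a fresh
    codon). ``junction_prefix`` may supply those consumed exonic bases so the
    junction-spanning codon is scanned too; without it that codon is skipped.
    """
    if retained_interval is None:
        return False
    s, e = retained_interval
    if e <= s:
        return False
    if reading_frame_offset not in (0, 1, 2):
        raise ValueError("reading_frame_offset must be 0, 1 or 2")
    seq = ref_seq[s:e].upper()
    if strand == "-":
        seq = revcomp(seq)
    if junction_prefix:
        if len(junction_prefix) != reading_frame_offset:
            raise ValueError("junction_prefix length must equal reading_frame_offset")
        seq = junction_prefix.upper() + seq
        start = 0
    else:
        start = (3 - reading_frame_offset) % 3
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return True
    return False


def _coding_exon_index(cmap: CodingMap, transcript_exon_index: int) -> Optional[int]:
    try:
        return cmap.exon_indices.index(transcript_exon_index)
    except ValueError:
        return None


def classify_splice_event(
    variant: VariantBundle,
    cmap: CodingMap,
    transcript: TranscriptModel,
    scores: Optional[SpliceAIScores],
    profile: RuleProfile,
    ref_seq: Optional[str] = None,
    adjacent_exon_pext_low: bool = False,
) -> SpliceEvent:
    """Classify the predicted splicing outcome of an essential splice variant.

    Rules, in order: a qualifying same-site-type gain (>= spliceai_rescue_min)
    is a cryptic event, in-frame iff the cryptic/annotated offset is a multiple
    of 3, strong iff loss - gain <= spliceai_strong_margin; loss at the
    opposite end of the same exon with no qualifying gain predicts exon
    skipping (frame from the exon's CDS length); mixed in-/out-of-frame
    candidate events are ``multiple_events``; loss with neither rescue nor
    skip signal is intron retention; no loss signal at all is
    ``non_essential_site`` when the adjacent exon's pext is low, else
    ``uncertain``. Intronic-side in-frame cryptic sites get their retained
    interval scanned for stop codons.
    """
    if variant.variant_class not in ("splice_donor", "splice_acceptor"):
        raise ValueError(f"not an essential splice variant: {variant.variant_class}")
    if scores is None:
        return SpliceEvent(kind="uncertain", detail="no SpliceAI scores")

    donor = variant.variant_class == "splice_donor"
    loss = scores.ds_dl if donor else scores.ds_al
    dp_loss = scores.dp_dl if donor else scores.dp_al
    gain = scores.ds_dg if donor else scores.ds_ag
    dp_gain = scores.dp_dg if donor else scores.dp_ag
    opp_loss = scores.ds_al if donor else scores.ds_dl

    exon_i = find_affected_exon(transcript, variant)
    tdir = 1 if transcript.strand == "+" else -1

    candidates: list[SpliceEvent] = []

    if gain >= profile.spliceai_rescue_min:
        offset = dp_gain - dp_loss  # genomic bases between cryptic and annotated site
        in_frame = offset % 3 == 0
        strength = "strong" if (loss - gain) <= profile.spliceai_strong_margin else "weak"
        retained = None
        stop_in_retained = None
        fraction = None
        t_off = offset * tdir  # positive = transcript-downstream of the annotated site
        intronic_side = (t_off > 0) if donor else (t_off < 0)
        if exon_i is not None and intronic_side:
            retained = _retained_interval(transcript, exon_i, donor, abs(t_off))
            if ref_seq is not None and in_frame:
                stop_in_retained = _scan_retained(
                    cmap, transcript, exon_i, donor, retained, ref_seq
                )
        elif not intronic_side:
            fraction = abs(t_off) / cmap.cds_length
        kind = "in_frame_cryptic_rescue" if in_frame else "out_of_frame_cryptic"
        candidates.append(
            SpliceEvent(
                kind=kind,
                strength=strength if in_frame else "n/a",
                retained_interval=retained,
                stop_in_retained=stop_in_retained,
                fraction_removed=fraction,
                detail=f"cryptic offset {offset:+d} from annotated site",
            )
        )

    if opp_loss >= profile.spliceai_rescue_min:
        skip = _exon_skip_event(cmap, transcript, exon_i)
        if skip is not None:
            candidates.append(skip)

    if not candidates:
        if loss >= profile.spliceai_rescue_min:
            return SpliceEvent(kind="intron_retention", detail="site loss with no rescue signal")
        if adjacent_exon_pext_low:
            return SpliceEvent(kind="non_essential_site", detail="no loss; adjacent exon pext low")
        return SpliceEvent(kind="uncertain", detail="no SpliceAI signal above threshold")

    if len(candidates) > 1:
        frames = {c.kind.startswith("in_frame") for c in candidates}
        if len(frames) > 1:
            return SpliceEvent(kind="multiple_events", detail="mixed in/out-of-frame events")
    return candidates[0]


def _retained_interval(
    transcript: TranscriptModel, exon_i: int, donor: bool, length: int
) -> tuple[int, int]:
    """Genomic interval of intronic sequence retained by an intronic-side
    cryptic site ``length`` bases beyond the annotated junction."""
    s, e = transcript.exons[exon_i]
    plus = transcript.strand == "+"
    if donor:
        return (e, e + length) if plus else (s - length, s)
    return (s - length, s) if plus else (e, e + length)


def _scan_retained(
    cmap: CodingMap,
    transcript: TranscriptModel,
    exon_i: int,
    donor: bool,
    retained: tuple[int, int],
    ref_seq: str,
) -> bool:
    """Stop-scan the retained intron in the inherited reading frame, including
    the codon spanning the exon/intron junction."""
    coding_i = _coding_exon_index(cmap, exon_i)
    if coding_i is None:
        return False
    if donor:
        last_off = sum(cmap.exon_cds_lengths[: coding_i + 1]) - 1
    else:
        if coding_i == 0:
            return False
        last_off = sum(cmap.exon_cds_lengths[:coding_i]) - 1
    frame_used = (last_off + 1) % 3  # bases of the junction codon already used
    cds = cmap.coding_sequence(ref_seq).upper()
    prefix = cds[last_off + 1 - frame_used : last_off + 1] if frame_used else ""
    return retained_stop_scan(
        ref_seq, retained, frame_used, strand=transcript.strand, junction_prefix=prefix
    )


def _exon_skip_event(
    cmap: CodingMap, transcript: TranscriptModel, exon_i: Optional[int]
) -> Optional[SpliceEvent]:
    if exon_i is None:
        return None
    coding_i = _coding_exon_index(cmap, exon_i)
    if coding_i is None:
        return None
    if coding_i == 0 or coding_i == cmap.n_coding_exons - 1:
        # a terminal coding exon cannot be cleanly skipped; treat as LoF-side
        return SpliceEvent(kind="out_of_frame_exon_skip", detail="terminal exon skip")
    exon_len = cmap.exon_cds_lengths[coding_i]
    fraction = exon_len / cmap.cds_length
    if exon_len % 3 == 0:
        return SpliceEvent(
            kind="in_frame_exon_skip",
            fraction_removed=fraction,
            detail=f"in-frame skip of exon removing {fraction:.3f} of CDS",
        )
    return SpliceEvent(
        kind="out_of_frame_exon_skip",
        fraction_removed=fraction,
        detail="out-of-frame exon skip",
    )


def splice_pext_support(
    track: PextTrack,
    transcript: TranscriptModel,
    affected_exon_index: int,
    profile: RuleProfile,
    flank: int = 10,
) -> bool:
    """Whether pext supports biological relevance of the disrupted splice site.

    Not supported (returns False) when the adjacent exon's pext category is
    ``low``, or when per-base pext shows no drop across the exon's annotated
    junctions (junction-side mean within 5% of the flanking-intron-side mean).
    """
    cat = pext_category(track, transcript.transcript_id, affected_exon_index, profile)
    if cat == "low":
        return False
    if track.per_base:
        s, e = transcript.exons[affected_exon_index]
        chrom = _per_base_chrom(track)
        for exon_win, intron_win in (
            ((s, min(s + flank, e)), (max(0, s - flank), s)),
            ((max(s, e - flank), e), (e, e + flank)),
        ):
            exon_mean = track.mean_over(chrom, *exon_win)
            intron_mean = track.mean_over(chrom, *intron_win)
            if exon_mean is None or intron_mean is None or exon_mean <= 0:
                continue
            if intron_mean >= 0.95 * exon_mean:
                return False  # no drop into the intron: junction likely unused
    return True


def _per_base_chrom(track: PextTrack) -> str:
    return track.per_base[0][0]
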