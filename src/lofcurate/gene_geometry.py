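"""Transcript and CDS coordinate arithmetic.

Everything downstream of NMD-escape, truncation-fraction and pext rules sits on
the :class:`CodingMap`, a bidirectional mapping between genomic positions and
0-based coding offsets along the transcript. Offset 0 is always the first base
of the translation start, regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .models import PextTrack, RuleProfile, TranscriptModel, VariantBundle

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class NonCodingTranscriptError(ValueError):
    pass


class NonCodingPositionError(ValueError):
    pass


@dataclass
class CodingMap:
    """Genomic position <-> coding offset map for one coding transcript.

    ``cds_intervals`` are in transcript orientation (index 0 holds the
    translation start); ``exon_cds_lengths`` gives the coding bases per coding
    exon in the same order; ``exon_indices`` maps each coding exon back to the
    transcript's exon index.
    """

    transcript_id: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    exon_cds_lengths: list[int]
    exon_indices: list[int]

    @property
    def cds_length(self) -> int:
        return sum(self.exon_cds_lengths)

    @property
    def n_coding_exons(self) -> int:
        return len(self.cds_intervals)

    def coding_offset(self, pos: int) -> Optional[int]:
        """0-based coding offset of genomic (0-based) ``pos``, or None."""
        acc = 0
        for s, e in self.cds_intervals:
            if s <= pos < e:
                return acc + (pos - s if self.strand == "+" else (e - 1) - pos)
            acc += e - s
        return None

    def genomic_at_offset(self, offset: int) -> int:
        """Genomic (0-based) position of coding ``offset``. Inverse of above."""
        if not (0 <= offset < self.cds_length):
            raise NonCodingPositionError(f"offset {offset} outside CDS of length {self.cds_length}")
        acc = 0
        for s, e in self.cds_intervals:
            width = e - s
            if offset < acc + width:
                within = offset - acc
                return s + within if self.strand == "+" else (e - 1) - within
            acc += width
        raise AssertionError("unreachable")

    def coding_exon_of_offset(self, offset: int) -> int:
        """Index (into the coding-exon lists) of the exon holding ``offset``."""
        acc = 0
        for i, width in enumerate(self.exon_cds_lengths):
            if offset < acc + width:
                return i
            acc += width
        raise NonCodingPositionError(f"offset {offset} outside CDS")

    def coding_sequence(self, ref_seq: str) -> str:
        """Spliced coding sequence (transcript orientation) from contig ``ref_seq``."""
        parts = []
        for s, e in self.cds_intervals:
            chunk = ref_seq[s:e]
            parts.append(chunk if self.strand == "+" else revcomp(chunk))
        return "".join(parts)


def build_coding_map(transcript: TranscriptModel) -> CodingMap:
    """Construct the coding map of a coding transcript.

    Raises :class:`NonCodingTranscriptError` for transcripts without a CDS.
    """
    if not transcript.is_coding or not transcript.cds_intervals:
        raise NonCodingTranscriptError(f"non-coding transcript {transcript.transcript_id}")
    exon_indices = []
    for cs, ce in transcript.cds_intervals:
        idx = None
        for i, (es, ee) in enumerate(transcript.exons):
            if es <= cs and ce <= ee:
                idx = i
                break
        if idx is None:
            raise ValueError("CDS interval outside all exons")
        exon_indices.append(idx)
    return CodingMap(
        transcript_id=transcript.transcript_id,
        strand=transcript.strand,
        cds_intervals=list(transcript.cds_intervals),
        exon_cds_lengths=[e - s for s, e in transcript.cds_intervals],
        exon_indices=exon_indices,
    )


def cds_fraction_removed(cmap: CodingMap, termination_genomic_pos: int) -> float:
    """Fraction of the CDS at and 3' of the termination base.

    1.0 when the first coding base terminates; splice cases should pass the
    first lost coding base. Raises for positions outside the CDS.
    """
    off = cmap.coding_offset(termination_genomic_pos)
    if off is None:
        raise NonCodingPositionError(
            f"position {termination_genomic_pos} not in CDS of {cmap.transcript_id}"
        )
    return (cmap.cds_length - off) / cmap.cds_length


def nmd_escape(
    cmap: CodingMap, transcript: TranscriptModel, pos: int, profile: RuleProfile
) -> bool:
    """True when a termination at ``pos`` is predicted to escape NMD.

    Escape applies in the 3'-most coding exon, within the final
    ``nmd_penultimate_window`` coding bases of the penultimate coding exon, or
    anywhere in a single-coding-exon transcript (no downstream junction to
    deposit an exon-junction complex).
    """
    off = cmap.coding_offset(pos)
    if off is None:
        raise NonCodingPositionError(f"position {pos} not in CDS of {cmap.transcript_id}")
    n = cmap.n_coding_exons
    if n == 1:
        return True
    exon_i = cmap.coding_exon_of_offset(off)
    if exon_i == n - 1:
        return True
    if exon_i == n - 2:
        end_of_penult = sum(cmap.exon_cds_lengths[: n - 1])
        # distance counts the termination base itself: the last base of the
        # exon is 1 base from the 3' end.
        return (end_of_penult - off) <= profile.nmd_penultimate_window
    return False


def in_frame_exon(cmap: CodingMap, exon_index: int) -> bool:
    """Whether skipping internal coding exon ``exon_index`` preserves frame.

    ``exon_index`` indexes the coding exons in transcript order; terminal exons
    cannot be rescued by skipping and raise.
    """
    if exon_index <= 0 or exon_index >= cmap.n_coding_exons - 1:
        raise ValueError("skipping not a rescue at terminal exons")
    return cmap.exon_cds_lengths[exon_index] % 3 == 0


def pext_category(
    track: PextTrack, transcript_id: str, exon_index: int, profile: RuleProfile
) -> Optional[str]:
    """Classify an exon's mean pext relative to the gene maximum.

    Returns one of ``low`` (ratio <= low_pext_max_ratio), ``mid``,
    ``close_to_max`` (ratio in [mid_pext_max_ratio, 0.9)) or ``at_max``
    (ratio >= 0.9); None when the exon has no pext value, and raises when the
    gene maximum is 0 (pext uninformative).
    """
    if track.gene_max <= 0:
        raise ValueError("pext uninformative: gene_max is 0")
    mean = track.exon_mean(transcript_id, exon_index)
    if mean is None:
        return None
    ratio = mean / track.gene_max
    if ratio <= profile.low_pext_max_ratio:
        return "low"
    if ratio < profile.mid_pext_max_ratio:
        return "mid"
    if ratio < 0.9:
        return "close_to_max"
    return "at_max"


def minority_of_transcripts(
    bundle: VariantBundle, coding_transcript_count: int, profile: RuleProfile
) -> bool:
    """True when the variant is pLoF in fewer than ``minority_fraction`` of
    coding transcripts (strict inequality; exactly half is not a minority)."""
    if coding_transcript_count < 1:
        raise ValueError("need at least one coding transcript")
    n_plof = len(bundle.plof_transcript_ids())
    return n_plof / coding_transcript_count < profile.minority_fraction


def is_overhang_position(
    transcript: TranscriptModel,
    other_coding_transcripts: list[TranscriptModel],
    pos: int,
    profile: RuleProfile,
) -> bool:
    """Whether ``pos`` falls in an exon extension ("overhang") of ``transcript``.

    An overhang position sits inside an exon of the assessed transcript, is
    exonic in fewer than ``minority_fraction`` of all coding transcripts, and at
    least one other transcript has an overlapping exon that excludes the
    position (i.e. the extra sequence is spliced out elsewhere, carrying the
    variant with it).
    """
    exon_i = transcript.exon_index_at(pos)
    if exon_i is None:
        return False
    es, ee = transcript.exons[exon_i]
    all_tx = [transcript] + list(other_coding_transcripts)
    covered = sum(1 for t in all_tx if t.exon_index_at(pos) is not None)
    if covered / len(all_tx) >= profile.minority_fraction:
        return False
    for t in other_coding_transcripts:
        for os_, oe in t.exons:
            if os_ < ee and es < oe and not (os_ <= pos < oe):
                return True
    return False


def weak_exon_conservation(
    conservation: dict[tuple[str, int], float], transcript_id: str, exon_index: int
) -> Optional[bool]:
    """Whether the exon's mean conservation is weak relative to its gene.

    Weak = below the 25th percentile of exon means for the gene (all entries in
    ``conservation`` are assumed to belong to one gene). Returns None when the
    exon has no score.
    """
    mean = conservation.get((transcript_id, exon_index))
    if mean is None:
        return None
    values = sorted(conservation.values())
    if len(values) < 2:
        return False
    import numpy as np

    q25 = float(np.quantile(values, 0.25))
    return mean < q25
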