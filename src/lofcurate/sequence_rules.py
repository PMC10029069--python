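"""Sequence- and haplotype-context rules.

Covers the artifact-prone sequence contexts (homopolymer runs, GC-rich and
repeat-masked regions, genotype-quality cutoffs) and the haplotype rescues:
in-phase multi-nucleotide variants that change the joint codon, and
frame-restoring indel pairs whose aggregate length change is a multiple of 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .gene_geometry import CodingMap, revcomp
from .models import QCMetrics, RuleProfile, VariantBundle

STOP_CODONS = {"TAA", "TAG", "TGA"}

# standard nuclear genetic code
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(seq: str) -> str:
    return "".join(
        CODON_TABLE.get(seq[i : i + 3].upper(), "X")
        for i in range(0, len(seq) - len(seq) % 3, 3)
    )


@dataclass
class RefContext:
    """A slice of reference sequence with its genomic anchor.

    ``start`` is the 0-based genomic position of ``seq[0]``.
    """

    seq: str
    start: int

    def base_at(self, pos: int) -> str:
        return self.seq[pos - self.start]

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass
class PhaseGroup:
    """Variants reported on the same haplotype."""

    group_id: str
    members: list[VariantBundle] = field(default_factory=list)

    def __post_init__(self) -> None:
        chroms = {m.chrom for m in self.members}
        if len(chroms) > 1:
            raise ValueError("phase group spans chromosomes")
        self.members.sort(key=lambda m: m.pos)


def homopolymer_run(
    ref_context: RefContext, variant: VariantBundle, profile: RuleProfile
) -> tuple[int, bool]:
    """Length of the homopolymer run at an indel, and whether it is flagged.

    The run is the longest stretch of one identical reference base containing
    or immediately adjacent to the inserted/deleted bases. Only indels whose
    changed unit is that same base are flagged (polymerase-slippage mechanism);
    SNVs are never homopolymer-flagged.
    """
    pos0 = variant.pos0
    if not (
        ref_context.start <= pos0 - profile.homopolymer_min_run
        and pos0 + len(variant.ref) + profile.homopolymer_min_run <= ref_context.end
    ):
        raise ValueError("reference window too small for homopolymer assessment")
    if not variant.is_simple_indel:
        return 0, False
    changed = variant.ref[1:] if len(variant.ref) > 1 else variant.alt[1:]
    bases = set(changed.upper())
    if len(bases) != 1:
        return 0, False
    base = bases.pop()

    # first reference position at/next to the changed bases (the anchor base
    # precedes them in VCF left-anchored representation)
    anchor = pos0 + 1
    best = 0
    # scan candidate run start positions near the anchor
    i = anchor
    while i - 1 >= ref_context.start and ref_context.base_at(i - 1).upper() == base:
        i -= 1
    j = i
    while j < ref_context.end and ref_context.base_at(j).upper() == base:
        j += 1
    best = j - i
    flagged = best >= profile.homopolymer_min_run
    return best, flagged


def combine_mnv(group: PhaseGroup, cmap: CodingMap, ref_seq: str) -> str:
    """Joint consequence of phased SNVs sharing one codon.

    Returns ``nonsense_retained``, ``missense``, ``synonymous`` or ``not_mnv``.
    The jointly mutated codon is translated with the standard code; a nonsense
    annotation is rescinded iff the combined codon is no longer a stop.
    """
    snvs = [m for m in group.members if m.is_snv]
    by_codon: dict[int, list[tuple[int, str]]] = {}
    for v in snvs:
        off = cmap.coding_offset(v.pos0)
        if off is None:
            continue
        alt = v.alt.upper() if cmap.strand == "+" else revcomp(v.alt.upper())
        by_codon.setdefault(off // 3, []).append((off % 3, alt))
    shared = {c: subs for c, subs in by_codon.items() if len(subs) >= 2}
    if not shared:
        return "not_mnv"
    cds = cmap.coding_sequence(ref_seq).upper()
    # a phase group rarely spans codons; assess the 5'-most shared codon
    codon_i = min(shared)
    ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
    combined = list(ref_codon)
    for phase, alt in shared[codon_i]:
        combined[phase] = alt
    combined_codon = "".join(combined)
    if combined_codon in STOP_CODONS:
        return "nonsense_retained"
    if CODON_TABLE[combined_codon] == CODON_TABLE[ref_codon]:
        return "synonymous"
    return "missense"


def net_indel_frame(group: PhaseGroup, profile: RuleProfile) -> tuple[int, bool]:
    """Aggregate frame shift of phased indels.

    ``net_shift`` is the summed length change mod 3; the group is
    frame-restoring iff the net shift is 0, at least two indels contribute, and
    the indels co-occur within ``indel_pair_window`` bases (the co-observation
    range of read-backed phasing).
    """
    indels = [m for m in group.members if m.is_indel]
    net = sum(m.length_delta for m in indels) % 3
    if len(indels) < 2:
        return net, False
    span = max(m.pos for m in indels) - min(m.pos for m in indels)
    return net, net == 0 and span <= profile.indel_pair_window


def first_inframe_atg_offset(
    cmap: CodingMap, ref_seq: str, lesion_coding_offset: int = 0
) -> Optional[int]:
    """Coding offset of the first in-frame ATG 3' of the lesion within the
    first coding exon, or None."""
    cds = cmap.coding_sequence(ref_seq).upper()
    first_exon_len = cmap.exon_cds_lengths[0]
    for off in range(0, first_exon_len - 2, 3):
        if off <= lesion_coding_offset:
            continue
        if cds[off : off + 3] == "ATG":
            return off
    return None


def reinitiation_class(
    cmap: CodingMap,
    ref_seq: str,
    transcript,
    profile: RuleProfile,
    lesion_coding_offset: int = 0,
    first_exon_conservation: Optional[float] = None,
) -> str:
    """Potential for translational reinitiation after an early truncation.

    Scans 3' of the lesion for the first in-frame ATG within the first coding
    exon. The fraction of CDS removed by restarting there is the ATG's coding
    offset / CDS length: ``strong`` when <= reinit_strong_max_fraction,
    ``removes_gt_threshold`` when > truncation_max_fraction, ``weak``
    otherwise, ``none`` with no in-frame ATG. A supplied first-exon
    conservation mean < 0.5 demotes strong to weak (a reinitiating methionine
    should be reasonably conserved to be credible).
    """
    found = first_inframe_atg_offset(cmap, ref_seq, lesion_coding_offset)
    if found is None:
        return "none"
    fraction = found / cmap.cds_length
    if fraction > profile.truncation_max_fraction:
        return "removes_gt_threshold"
    if fraction <= profile.reinit_strong_max_fraction:
        if first_exon_conservation is not None and first_exon_conservation < 0.5:
            return "weak"
        return "strong"
    return "weak"


def gc_fraction(ref_context: RefContext, center_pos: int, window: int) -> float:
    half = window // 2
    s = max(ref_context.start, center_pos - half)
    e = min(ref_context.end, center_pos + half)
    seq = ref_context.seq[s - ref_context.start : e - ref_context.start].upper()
    if not seq:
        return 0.0
    return sum(1 for b in seq if b in "GC") / len(seq)


def technical_context(
    variant: VariantBundle,
    ref_context: Optional[RefContext],
    repeat_overlap_count: int,
    profile: RuleProfile,
    in_low_complexity: bool = False,
) -> set[str]:
    """Technical subflags for one variant.

    Absent QC metrics yield no flag for that metric. Complex mapping fires
    above ``repeat_track_min`` overlapping repeat tracks, minor mapping for
    any smaller positive overlap (note the conservative profile's higher
    cutoff means it calls *minor* more often — the one rule where the two
    profiles do not nest).
    """
    qc: QCMetrics = variant.qc
    flags: set[str] = set()
    if qc.depth is not None and qc.depth < profile.depth_min:
        flags.add("low_depth")
    if qc.genotype_quality is not None and qc.genotype_quality < profile.gq_min:
        flags.add("low_gq")
    if qc.allele_balance is not None and qc.allele_balance < profile.ab_min:
        flags.add("skewed_ab")
    if (
        qc.strand_bias is not None
        and qc.depth is not None
        and qc.allele_balance is not None
    ):
        n_alt = qc.depth * qc.allele_balance
        if n_alt >= profile.strand_bias_min_alt_reads and (
            qc.strand_bias <= profile.strand_bias_extreme
            or qc.strand_bias >= 1 - profile.strand_bias_extreme
        ):
            flags.add("strand_bias")
    if ref_context is not None:
        if gc_fraction(ref_context, variant.pos0, profile.gc_window) >= profile.gc_rich_min:
            flags.add("gc_rich")
    if in_low_complexity:
        flags.add("low_complexity")
    if repeat_overlap_count > profile.repeat_track_min:
        flags.add("complex_mapping")
    elif repeat_overlap_count > 0:
        flags.add("minor_mapping")
    return flags
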