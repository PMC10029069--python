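"""Domain types shared across the curation framework.

Coordinate convention
---------------------
All intervals held in memory are **0-based, half-open** ``(start, end)`` on the
genome. Readers convert from the native convention of each format (GTF is
1-based inclusive, VCF positions are 1-based) at parse time and writers convert
back. Exon and CDS lists are ordered 5'->3' in *transcript* orientation, so for
a minus-strand transcript exon index 0 is the genomically rightmost exon, while
the interval endpoints themselves stay in genome orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

Interval = tuple[int, int]

#: Variant classes the curation engine assesses. "other" is admitted for phased
#: partner variants (e.g. the second SNV of an MNV) that are carried in phase
#: groups but never themselves curated.
PLOF_CLASSES = ("nonsense", "frameshift", "splice_donor", "splice_acceptor")
VARIANT_CLASSES = PLOF_CLASSES + ("other",)


class Verdict(str, Enum):
    """Five-level loss-of-function verdict.

    The order below is the precedence order: when several flags fire, the one
    farthest from ``LOF`` ("most impactful consequence") wins.
    """

    LOF = "LoF"
    LIKELY_LOF = "likely_LoF"
    UNCERTAIN_LOF = "uncertain_LoF"
    LIKELY_NOT_LOF = "likely_not_LoF"
    NOT_LOF = "not_LoF"

    @property
    def rank(self) -> int:
        return _VERDICT_RANK[self]


_VERDICT_RANK = {v: i for i, v in enumerate(Verdict)}


def worst_verdict(verdicts: Iterable[Verdict]) -> Verdict:
    """Maximum-impact verdict (farthest from LoF) among ``verdicts``."""
    vs = list(verdicts)
    if not vs:
        return Verdict.LOF
    return max(vs, key=lambda v: v.rank)


class FlagCategory(str, Enum):
    RESCUE = "rescue"
    BIOLOGICAL_RELEVANCE = "biological_relevance"
    TECHNICAL = "technical"


#: Fixed precedence of categories used only for primary-reason tie-breaking.
CATEGORY_ORDER = {
    FlagCategory.RESCUE: 0,
    FlagCategory.BIOLOGICAL_RELEVANCE: 1,
    FlagCategory.TECHNICAL: 2,
}


@dataclass(frozen=True)
class Flag:
    """One triggered curation rule.

    ``tier`` is the verdict this rule maps to on its own; ``data`` carries
    numeric audit values (e.g. the CDS fraction removed) that downstream
    consumers such as the PVS1 module need.
    """

    name: str
    category: FlagCategory
    tier: Verdict
    detail: str = ""
    data: tuple = ()  # tuple of (key, value) pairs; hashable audit payload

    def datum(self, key: str, default=None):
        for k, v in self.data:
            if k == key:
                return v
        return default


@dataclass
class QCMetrics:
    """Per-genotype quality metrics for the carrier genotype."""

    depth: Optional[int] = None
    genotype_quality: Optional[int] = None
    allele_balance: Optional[float] = None
    strand_bias: Optional[float] = None  # fraction of ALT reads on forward strand

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        for name in ("allele_balance", "strand_bias"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SpliceAIScores:
    """SpliceAI delta scores with signed base offsets from the variant."""

    ds_ag: float = 0.0
    ds_al: float = 0.0
    ds_dg: float = 0.0
    ds_dl: float = 0.0
    dp_ag: int = 0
    dp_al: int = 0
    dp_dg: int = 0
    dp_dl: int = 0

    def __post_init__(self) -> None:
        for name in ("ds_ag", "ds_al", "ds_dg", "ds_dl"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` and ``cds_intervals`` are 0-based half-open genomic intervals
    listed 5'->3' in transcript orientation (see module docstring).
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[Interval]
    cds_intervals: list[Interval]
    is_coding: bool = True
    tags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError("exons overlap")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if self.exons != expected:
            raise ValueError("exons not sorted 5'->3' in transcript orientation")
        for cs, ce in self.cds_intervals:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(f"CDS interval ({cs},{ce}) not contained in any exon")
        if self.is_coding and self.cds_length < 3:
            raise ValueError("coding transcript must have CDS length >= 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_index_at(self, pos: int) -> Optional[int]:
        """Transcript-orientation exon index containing 0-based ``pos``."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos < e:
                return i
        return None


@dataclass
class VariantBundle:
    """One pLoF variant plus all annotations the rules consume.

    ``pos`` keeps the VCF 1-based convention; ``pos0`` exposes the 0-based
    coordinate of the first REF base used by all internal arithmetic.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    qc: QCMetrics = field(default_factory=QCMetrics)
    spliceai: Optional[SpliceAIScores] = None
    phase_group_id: Optional[str] = None
    has_read_data: bool = True
    transcripts_hit: list[tuple[str, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.variant_class == "frameshift" and self.is_simple_indel:
            if (len(self.ref) - len(self.alt)) % 3 == 0:
                raise ValueError("frameshift indel must change length by a non-multiple of 3")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def is_simple_indel(self) -> bool:
        """Left-anchored insertion or deletion sharing the first base."""
        return self.is_indel and self.ref[0] == self.alt[0] and (
            len(self.ref) == 1 or len(self.alt) == 1
        )

    @property
    def length_delta(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def key(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    def plof_transcript_ids(self) -> list[str]:
        return [t for t, is_plof in self.transcripts_hit if is_plof]


@dataclass
class PextTrack:
    """pext (proportion expressed across transcripts) values for one gene.

    Stores per-exon means keyed by ``(transcript_id, exon_index)`` and/or
    per-base values over genomic intervals; ``gene_max`` is the maximum pext
    anywhere in the gene and is the denominator of every ratio rule.
    """

    gene_max: float = 0.0
    exon_means: dict[tuple[str, int], float] = field(default_factory=dict)
    per_base: list[tuple[str, int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = list(self.exon_means.values()) + [v for _, _, _, v in self.per_base]
        for v in vals + [self.gene_max]:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"pext value {v} outside [0, 1]")
        if vals and self.gene_max < max(vals) - 1e-12:
            raise ValueError("gene_max below a stored pext value")

    def exon_mean(self, transcript_id: str, exon_index: int) -> Optional[float]:
        return self.exon_means.get((transcript_id, exon_index))

    def mean_over(self, chrom: str, start: int, end: int) -> Optional[float]:
        """Coverage-weighted mean of per-base values over [start, end)."""
        total = 0.0
        covered = 0
        for c, s, e, v in self.per_base:
            if c != chrom:
                continue
            ov = min(e, end) - max(s, start)
            if ov > 0:
                total += v * ov
                covered += ov
        if covered == 0:
            return None
        return total / covered


@dataclass(frozen=True)
class RuleProfile:
    """Every numeric threshold used by the rules, in named fields.

    The two presets trade false-positive LoF calls against false negatives:
    the conservative profile flags more aggressively (recommended for
    population data), the lenient one discards fewer variants.
    """

    name: str
    depth_min: int
    ab_min: float
    gq_min: int
    repeat_track_min: int        # complex mapping fires when overlap count > this
    homopolymer_min_run: int
    spliceai_rescue_min: float
    spliceai_strong_margin: float
    reinit_strong_max_fraction: float
    truncation_max_fraction: float
    low_pext_max_ratio: float
    mid_pext_max_ratio: float
    minority_fraction: float
    nmd_penultimate_window: int
    gc_rich_min: float = 0.70
    gc_window: int = 100
    indel_pair_window: int = 100
    strand_bias_extreme: float = 0.05
    strand_bias_min_alt_reads: int = 10


CONSERVATIVE = RuleProfile(
    name="conservative",
    depth_min=15,
    ab_min=0.35,
    gq_min=30,
    repeat_track_min=5,
    homopolymer_min_run=5,
    spliceai_rescue_min=0.2,
    spliceai_strong_margin=0.2,
    reinit_strong_max_fraction=0.25,
    truncation_max_fraction=0.25,
    low_pext_max_ratio=0.20,
    mid_pext_max_ratio=0.50,
    minority_fraction=0.50,
    nmd_penultimate_window=50,
)

LENIENT = RuleProfile(
    name="lenient",
    depth_min=10,
    ab_min=0.25,
    gq_min=20,
    repeat_track_min=3,
    homopolymer_min_run=7,
    spliceai_rescue_min=0.2,
    spliceai_strong_margin=0.2,
    reinit_strong_max_fraction=0.10,
    truncation_max_fraction=0.10,
    low_pext_max_ratio=0.10,
    mid_pext_max_ratio=0.30,
    minority_fraction=0.50,
    nmd_penultimate_window=50,
)

PROFILES = {"conservative": CONSERVATIVE, "lenient": LENIENT}


class PVS1Strength(str, Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    NOT_APPLICABLE = "not_applicable"


class PVS1Consequence(str, Enum):
    """Per-flag PVS1 consequence, ordered by severity of the downgrade."""

    NO_CHANGE = "no_change"
    CAP_STRONG = "cap_strong"
    CAP_MODERATE = "cap_moderate"
    DO_NOT_USE = "do_not_use"

    @property
    def rank(self) -> int:
        return _CONSEQUENCE_RANK[self]


_CONSEQUENCE_RANK = {c: i for i, c in enumerate(PVS1Consequence)}

CONSEQUENCE_TO_STRENGTH = {
    PVS1Consequence.NO_CHANGE: PVS1Strength.VERY_STRONG,
    PVS1Consequence.CAP_STRONG: PVS1Strength.STRONG,
    PVS1Consequence.CAP_MODERATE: PVS1Strength.MODERATE,
    PVS1Consequence.DO_NOT_USE: PVS1Strength.NOT_APPLICABLE,
}


@dataclass
class PVS1Decision:
    """Maximum allowed PVS1 strength plus the audit trail that produced it."""

    max_strength: Optional[PVS1Strength]
    requires_analytical_confirmation: bool
    analytically_confirmed: bool
    trail: list[tuple[str, str]] = field(default_factory=list)

    @property
    def reported_strength(self) -> str:
        if self.requires_analytical_confirmation and not self.analytically_confirmed:
            return "pending_confirmation"
        assert self.max_strength is not None
        return self.max_strength.value


@dataclass
class CurationResult:
    """Flags, verdict and primary reason for one variant."""

    variant: VariantBundle
    flags: frozenset[Flag]
    verdict: Verdict
    primary_reason: str
    audit: list[str] = field(default_factory=list)

    def flag_names(self) -> set[str]:
        return {f.name for f in self.flags}
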