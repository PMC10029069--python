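"""Deterministic synthetic fixtures: one toy gene + variant per evasion mechanism.

Every scenario builds a small (600-2,000 bp) contig carrying one gene of 2-6
exons, places one curatable pLoF variant (plus phased partners where the
mechanism needs them), and attaches the annotation tracks the rules consume.
Expected flags, verdict and PVS1 outcome are fixed *by construction* for both
threshold profiles — never by running the engine — so the scenario suite is an
independent oracle for the whole pipeline.

Generation is a pure function of (scenario name, seed); written files are
byte-identical across runs. Geometric scenarios have a minus-strand twin
produced by reverse-complement mirroring of the entire contig, which exercises
every strand-dependent code path with identical expected outcomes.
"""

from __future__ import annotations

import json
import random
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Union

from .gene_geometry import revcomp
from .models import (
    PextTrack,
    QCMetrics,
    SpliceAIScores,
    TranscriptModel,
    VariantBundle,
)
from .sequence_rules import CODON_TABLE, STOP_CODONS

# codons safe for filler sequence: no stop, no ATG (reinitiation control), no
# triple-identical base (homopolymer control), at most 2 G/C (GC-rich control)
SAFE_CODONS = sorted(
    c for c in CODON_TABLE
    if c not in STOP_CODONS
    and c != "ATG"
    and len(set(c)) > 1
    and sum(b in "GC" for b in c) <= 2
)


@dataclass
class ExpectedOutcome:
    """By-construction expectation for one threshold profile."""

    flags: frozenset[str]
    verdict: str
    pvs1: str  # reported PVS1 strength, or "pending_confirmation"


@dataclass
class Scenario:
    name: str
    chrom: str
    seq: str
    gene_id: str
    transcripts: list[TranscriptModel]
    bundles: list[VariantBundle]
    pext: PextTrack
    repeat_tracks: list[tuple[str, list[tuple[int, int]]]] = field(default_factory=list)
    conservation: Optional[dict[tuple[str, int], float]] = None
    expected: dict[str, ExpectedOutcome] = field(default_factory=dict)
    files: dict[str, Path] = field(default_factory=dict)

    @property
    def primary(self) -> VariantBundle:
        return next(b for b in self.bundles if b.variant_class != "other")


def _rng(uid: str, seed: int) -> random.Random:
    return random.Random(zlib.crc32(f"{uid}:{seed}".encode()) & 0x7FFFFFFF)


def _random_seq(rng: random.Random, length: int) -> str:
    out: list[str] = []
    for _ in range(length):
        choices = [b for b in "ACGT" if not (len(out) >= 2 and out[-1] == out[-2] == b)]
        out.append(rng.choice(choices))
    return "".join(out)


def _intron(rng: random.Random, length: int, override_prefix: str = "") -> str:
    prefix = override_prefix or "GT"
    mid = _random_seq(rng, length - len(prefix) - 2)
    return prefix + mid + "AG"


def _build_gene(
    rng: random.Random,
    exon_cds: tuple[int, ...] = (120, 81, 99),
    intron_len: int = 90,
    flank: int = 50,
    codon_overrides: Optional[dict[int, str]] = None,
    intron_prefixes: Optional[dict[int, str]] = None,
) -> tuple[str, list[tuple[int, int]]]:
    """Contig sequence and exon intervals for a toy gene (exons == CDS).

    The coding sequence is ATG + filler codons + TAA with the requested codon
    overrides; introns get canonical GT..AG ends.
    """
    total = sum(exon_cds)
    assert total % 3 == 0, "toy CDS length must be a codon multiple"
    codons = ["ATG"] + [rng.choice(SAFE_CODONS) for _ in range(total // 3 - 2)] + ["TAA"]
    for i, c in (codon_overrides or {}).items():
        codons[i] = c
    cds = "".join(codons)
    pieces = [_random_seq(rng, flank)]
    exons: list[tuple[int, int]] = []
    pos = flank
    off = 0
    for i, width in enumerate(exon_cds):
        pieces.append(cds[off : off + width])
        exons.append((pos, pos + width))
        pos += width
        off += width
        if i < len(exon_cds) - 1:
            pieces.append(_intron(rng, intron_len, (intron_prefixes or {}).get(i, "")))
            pos += intron_len
    pieces.append(_random_seq(rng, flank))
    return "".join(pieces), exons


def _tx(tid: str, gid: str, exons: list[tuple[int, int]], strand: str = "+",
        tags: Optional[set[str]] = None) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid, gene_id=gid, strand=strand, exons=list(exons),
        cds_intervals=list(exons), is_coding=True, tags=set(tags or ()),
    )


def _qc(depth: int = 40, alt_reads: int = 19, gq: int = 60,
        sb: Optional[float] = None) -> QCMetrics:
    return QCMetrics(
        depth=depth, genotype_quality=gq,
        allele_balance=alt_reads / depth, strand_bias=sb,
    )


def _pext(tx_ids: list[str], n_exons: int, value: float = 0.8,
          overrides: Optional[dict[tuple[str, int], float]] = None) -> PextTrack:
    means = {(tid, i): value for tid in tx_ids for i in range(n_exons)}
    means.update(overrides or {})
    return PextTrack(gene_max=max(means.values()), exon_means=means)


def _sai(**kw) -> SpliceAIScores:
    return SpliceAIScores(**kw)


def _expect(flags, verdict, pvs1) -> ExpectedOutcome:
    return ExpectedOutcome(frozenset(flags), verdict, pvs1)


def _both(flags, verdict, pvs1) -> dict[str, ExpectedOutcome]:
    e = _expect(flags, verdict, pvs1)
    return {"conservative": e, "lenient": e}


# ---------------------------------------------------------------------------
# scenario builders (plus strand; minus twins by mirroring)
# ---------------------------------------------------------------------------
# default gene: exon CDS lengths (120, 81, 99), CDS 300 bp, introns 90 bp,
# flanks 50 bp -> exons at (50,170) (260,341) (431,530) on a 580 bp contig.

def _ids(uid: str) -> tuple[str, str, str]:
    return f"chr_{uid}", f"g_{uid}", f"t1_{uid}"


def _std_bundle(scn_seq: str, chrom: str, pos0: int, alt: str, cls: str,
                tx_hits, **kw) -> VariantBundle:
    return VariantBundle(
        chrom=chrom, pos=pos0 + 1, ref=scn_seq[pos0], alt=alt, variant_class=cls,
        qc=kw.pop("qc", _qc()), transcripts_hit=tx_hits, **kw,
    )


def _simple_nonsense_scenario(
    uid: str, rng: random.Random, *, codon_overrides: dict[int, str],
    var_offset: int, alt: str, expected: dict[str, ExpectedOutcome],
    pext_overrides: Optional[dict[int, float]] = None,
    qc: Optional[QCMetrics] = None, repeat_tracks=None,
    exon_cds: tuple[int, ...] = (120, 81, 99), tags: Optional[set[str]] = None,
) -> Scenario:
    """Shared skeleton: a single-transcript gene with one nonsense SNV."""
    chrom, gid, tid = _ids(uid)
    seq, exons = _build_gene(rng, exon_cds=exon_cds, codon_overrides=codon_overrides)
    tx = _tx(tid, gid, exons, tags=tags)
    boundaries = []
    acc = 0
    for w in exon_cds:
        boundaries.append((acc, acc + w))
        acc += w
    exon_of = next(i for i, (s, e) in enumerate(boundaries) if s <= var_offset < e)
    pos0 = exons[exon_of][0] + (var_offset - boundaries[exon_of][0])
    bundle = _std_bundle(seq, chrom, pos0, alt, "nonsense", [(tid, True)],
                         qc=qc or _qc())
    po = {(tid, i): v for i, v in (pext_overrides or {}).items()}
    return Scenario(
        name=uid, chrom=chrom, seq=seq, gene_id=gid, transcripts=[tx],
        bundles=[bundle], pext=_pext([tid], len(exon_cds), overrides=po),
        repeat_tracks=list(repeat_tracks or []), expected=expected,
    )


def _sc_clean_nonsense(rng, uid):
    # GAA codon at coding offsets 129-131; G>T makes TAA mid-gene: no rule fires
    return _simple_nonsense_scenario(
        uid, rng, codon_overrides={43: "GAA"}, var_offset=129, alt="T",
        expected=_both([], "LoF", "very_strong"),
    )


def _sc_last_exon(rng, uid):
    # termination at coding offset 285 of 300: NMD escape removing 5% of CDS
    return _simple_nonsense_scenario(
        uid, rng, codon_overrides={95: "GAA"}, var_offset=285, alt="T",
        expected=_both(["last_exon_nmd"], "likely_not_LoF", "strong"),
    )


def _sc_last_exon_moderate(rng, uid):
    # offset 255: removes 15% -> conservative flags (PVS1 capped at Moderate),
    # lenient (<10% rule) does not
    return _simple_nonsense_scenario(
        uid, rng, codon_overrides={85: "GAA"}, var_offset=255, alt="T",
        expected={
            "conservative": _expect(["last_exon_nmd"], "likely_not_LoF", "moderate"),
            "lenient": _expect([], "LoF", "very_strong"),
        },
    )


def _sc_low_pext(rng, uid):
    # middle exon mean pext 0.05 vs gene max 0.8: ratio 0.0625, low in both
    return _simple_nonsense_scenario(
        uid, rng, codon_overrides={50: "GAA"}, var_offset=150, alt="T",
        pext_overrides={1: 0.05},
        expected=_both(["low_pext"], "not_LoF", "not_applicable"),
    )


def _sc_gc_rich(rng, uid):
    # middle exon rebuilt from GC-rich codons; GGA codon hosts the G>T stop
    overrides = {i: ["GCC", "GGC", "CCG", "CGC"][i % 4] for i in range(40, 67)}
    overrides[50] = "GGA"  # -> TGA
    return _simple_nonsense_scenario(
        uid, rng, codon_overrides=overrides, var_offset=150, alt="T",
        expected=_both(["gc_rich"], "likely_not_LoF", "pending_confirmation"),
    )


def _sc_genotyping_low_depth(rng, uid):
    return _simple_nonsense_scenario(
        uid, rng, codon_overrides={43: "GAA"}, var_offset=129, alt="T",
        qc=_qc(depth=12, alt_reads=6),
        expected={
            "conservative": _expect(["low_depth"], "likely_not_LoF",
                                    "pending_confirmation"),
            "lenient": _expect([], "LoF", "very_strong"),
        },
    )


def _sc_genotyping_skewed_ab(rng, uid):
    return _simple_nonsense_scenario(
        uid, rng, codon_overrides={43: "GAA"}, var_offset=129, alt="T",
        qc=_qc(depth=40, alt_reads=12),
        expected={
            "conservative": _expect(["skewed_ab"], "likely_not_LoF",
                                    "pending_confirmation"),
            "lenient": _expect([], "LoF", "very_strong"),
        },
    )


def _sc_strand_bias(rng, uid):
    return _simple_nonsense_scenario(
        uid, rng, codon_overrides={43: "GAA"}, var_offset=129, alt="T",
        qc=_qc(sb=0.98),
        expected=_both(["strand_bias"], "likely_not_LoF", "pending_confirmation"),
    )


def _mapping_scenario(rng, uid, n_tracks, expected):
    scn = _simple_nonsense_scenario(
        uid, rng, codon_overrides={43: "GAA"}, var_offset=129, alt="T",
        expected=expected,
    )
    pos0 = scn.primary.pos0
    scn.repeat_tracks = [
        (f"rmsk{k}", [(pos0 - 5, pos0 + 5)]) for k in range(n_tracks)
    ]
    return scn


def _sc_minor_mapping(rng, uid):
    # 4 overlapping tracks: conservative (cutoff >5) calls minor, lenient
    # (cutoff >3) calls complex -- the documented threshold-ordering anomaly
    return _mapping_scenario(rng, uid, 4, {
        "conservative": _expect(["minor_mapping"], "likely_LoF",
                                "pending_confirmation"),
        "lenient": _expect(["complex_mapping"], "likely_not_LoF",
                           "pending_confirmation"),
    })


def _sc_complex_mapping(rng, uid):
    return _mapping_scenario(rng, uid, 6, _both(
        ["complex_mapping"], "likely_not_LoF", "pending_confirmation"))


def _sc_low_complexity(rng, uid):
    scn = _simple_nonsense_scenario(
        uid, rng, codon_overrides={43: "GAA"}, var_offset=129, alt="T",
        expected=_both(["low_complexity"], "likely_not_LoF",
                       "pending_confirmation"),
    )
    pos0 = scn.primary.pos0
    scn.repeat_tracks = [("low_complexity", [(pos0 - 5, pos0 + 5)])]
    return scn


def _sc_homopolymer_frameshift(rng, uid):
    # A x7 run at coding offsets 135-141; 1 bp deletion of one run A
    chrom, gid, tid = _ids(uid)
    seq, exons = _build_gene(
        rng, codon_overrides={44: "CTG", 45: "AAA", 46: "AAA", 47: "ACT"})
    tx = _tx(tid, gid, exons)
    pos0 = exons[1][0] + (134 - 120)  # anchor base before the run
    bundle = VariantBundle(
        chrom=chrom, pos=pos0 + 1, ref=seq[pos0 : pos0 + 2], alt=seq[pos0],
        variant_class="frameshift", qc=_qc(), transcripts_hit=[(tid, True)],
    )
    return Scenario(
        name=uid, chrom=chrom, seq=seq, gene_id=gid, transcripts=[tx],
        bundles=[bundle], pext=_pext([tid], 3),
        expected=_both(["homopolymer"], "likely_not_LoF", "pending_confirmation"),
    )


def _sc_frameshift_no_reads(rng, uid):
    # clean 1 bp deletion (non-homopolymer context) without read data
    chrom, gid, tid = _ids(uid)
    seq, exons = _build_gene(rng, codon_overrides={46: "ACG", 47: "TCA"})
    tx = _tx(tid, gid, exons)
    pos0 = exons[1][0] + (139 - 120)
    bundle = VariantBundle(
        chrom=chrom, pos=pos0 + 1, ref=seq[pos0 : pos0 + 2], alt=seq[pos0],
        variant_class="frameshift", qc=_qc(), transcripts_hit=[(tid, True)],
        has_read_data=False,
    )
    return Scenario(
        name=uid, chrom=chrom, seq=seq, gene_id=gid, transcripts=[tx],
        bundles=[bundle], pext=_pext([tid], 3),
        expected=_both(["no_read_data"], "uncertain_LoF", "pending_confirmation"),
    )


def _sc_mnv(rng, uid, retained: bool):
    chrom, gid, tid = _ids(uid)
    if retained:
        # GAA at offsets 156-158: G>T alone = TAA; with A>G at 158 = TAG (stop)
        seq, exons = _build_gene(rng, codon_overrides={52: "GAA"})
        off1, alt1, off2, alt2 = 156, "T", 158, "G"
        expected = _both([], "LoF", "very_strong")
    else:
        # TCA at offsets 150-152: C>G alone = TGA; with A>G at 152 = TGG (Trp)
        seq, exons = _build_gene(rng, codon_overrides={50: "TCA"})
        off1, alt1, off2, alt2 = 151, "G", 152, "G"
        expected = _both(["mnv_rescue"], "not_LoF", "not_applicable")
    tx = _tx(tid, gid, exons)
    p1 = exons[1][0] + (off1 - 120)
    p2 = exons[1][0] + (off2 - 120)
    pg = f"pg_{uid}"
    b1 = _std_bundle(seq, chrom, p1, alt1, "nonsense", [(tid, True)],
                     phase_group_id=pg)
    b2 = _std_bundle(seq, chrom, p2, alt2, "other", [(tid, False)],
                     phase_group_id=pg)
    return Scenario(
        name=uid, chrom=chrom, seq=seq, gene_id=gid, transcripts=[tx],
        bundles=[b1, b2], pext=_pext([tid], 3), expected=expected,
    )


def _sc_mnv_rescue(rng, uid):
    return _sc_mnv(rng, uid, retained=False)


def _sc_mnv_retained(rng, uid):
    return _sc_mnv(rng, uid, retained=True)


def _sc_frame_restoring_pair(rng, uid):
    # +1 insertion and -1 deletion 11 bp apart on one haplotype: net shift 0
    chrom, gid, tid = _ids(uid)
    seq, exons = _build_gene(
        rng, codon_overrides={46: "ACG", 47: "TCA", 48: "ACG", 50: "CAT", 51: "GCA"})
    tx = _tx(tid, gid, exons)
    pg = f"pg_{uid}"
    p_ins = exons[1][0] + (140 - 120)  # anchor 'G' of ACG; insert T after it
    ins = VariantBundle(
        chrom=chrom, pos=p_ins + 1, ref=seq[p_ins], alt=seq[p_ins] + "T",
        variant_class="frameshift", qc=_qc(), transcripts_hit=[(tid, True)],
        phase_group_id=pg,
    )
    p_del = exons[1][0] + (151 - 120)  # anchor 'A' of CAT; delete the T
    dele = VariantBundle(
        chrom=chrom, pos=p_del + 1, ref=seq[p_del : p_del + 2], alt=seq[p_del],
        variant_class="other", qc=_qc(), transcripts_hit=[(tid, False)],
        phase_group_id=pg,
    )
    return Scenario(
        name=uid, chrom=chrom, seq=seq, gene_id=gid, transcripts=[tx],
        bundles=[ins, dele], pext=_pext([tid], 3),
        expected=_both(["frame_restoring_indel"], "not_LoF", "not_applicable"),
    )


def _reinit_scenario(rng, uid, atg_codon: int, expected, conservation=None):
    # nonsense at coding offset 3 (codon 2) disrupts translation immediately
    # after the start; an in-frame ATG may reinitiate downstream
    scn = _simple_nonsense_scenario(
        uid, rng, codon_overrides={1: "GAA", atg_codon: "ATG"}, var_offset=3,
        alt="T", expected=expected,
    )
    scn.conservation = conservation
    return scn


def _sc_reinitiation_strong(rng, uid):
    # ATG at codon 8 (offset 24/300 = 8% removed): strong in both profiles
    return _reinit_scenario(rng, uid, 8, _both(
        ["reinitiation_strong"], "likely_not_LoF", "strong"))


def _sc_reinitiation_weak(rng, uid):
    # same geometry, but the first exon is weakly conserved (0.3 < 0.5):
    # strong reinitiation demoted to weak; the conservation track also fires
    # the weak-conservation rule at maximal pext
    scn = _reinit_scenario(rng, uid, 8, _both(
        ["reinitiation_weak", "weak_conservation_at_max"], "uncertain_LoF",
        "strong"))
    tid = scn.transcripts[0].transcript_id
    scn.conservation = {(tid, 0): 0.3, (tid, 1): 0.9, (tid, 2): 0.9}
    return scn


def _sc_reinitiation_gt_threshold(rng, uid):
    # ATG at codon 30 (offset 90/300 = 30% removed): beyond both limits
    return _reinit_scenario(rng, uid, 30, _both(
        ["reinitiation_removes_gt_threshold"], "likely_LoF", "very_strong"))


def _sc_overprinting(rng, uid):
    chrom, gid, t1 = _ids(uid)
    t2 = f"t2_{uid}"
    seq, exons = _build_gene(rng, codon_overrides={50: "GAA"})
    tx1 = _tx(t1, gid, exons, tags={"overprinted"})
    tx2 = _tx(t2, gid, exons)
    pos0 = exons[1][0] + (150 - 120)
    bundle = _std_bundle(seq, chrom, pos0, "T", "nonsense",
                         [(t1, True), (t2, False)])
    return Scenario(
        name=uid, chrom=chrom, seq=seq, gene_id=gid, transcripts=[tx1, tx2],
        bundles=[bundle], pext=_pext([t1, t2], 3),
        expected=_both(["overprinting"], "likely_not_LoF", "not_applicable"),
    )


def _minority_scenario(rng, uid, exon2_pext, expected):
    chrom, gid, t1 = _ids(uid)
    t2, t3 = f"t2_{uid}", f"t3_{uid}"
    seq, exons = _build_gene(rng, codon_overrides={50: "GAA"})
    tx1 = _tx(t1, gid, exons)
    short = [exons[0], exons[2]]  # exon-2-skipping isoforms (CDS 219, in frame)
    tx2 = _tx(t2, gid, short)
    tx3 = _tx(t3, gid, short)
    pos0 = exons[1][0] + (150 - 120)
    bundle = _std_bundle(seq, chrom, pos0, "T", "nonsense",
                         [(t1, True), (t2, False), (t3, False)])
    pext = _pext([t1], 3, overrides={(t1, 1): exon2_pext})
    pext.exon_means.update({(t2, i): 0.8 for i in range(2)})
    pext.exon_means.update({(t3, i): 0.8 for i in range(2)})
    return Scenario(
        name=uid, chrom=chrom, seq=seq, gene_id=gid,
        transcripts=[tx1, tx2, tx3], bundles=[bundle], pext=pext,
        expected=expected,
    )


def _sc_minority_at_max(rng, uid):
    return _minority_scenario(rng, uid, 0.8, _both(
        ["minority_at_max"], "LoF", "very_strong"))


def _sc_minority_mid(rng, uid):
    # ratio 0.2/0.8 = 0.25: mid band in both profiles
    return _minority_scenario(rng, uid, 0.2, _both(
        ["minority_mid"], "uncertain_LoF", "strong"))


def _sc_overhang_exon(rng, uid):
    # tx1's middle exon carries a 9 bp 3' extension absent from tx2/tx3; the
    # variant sits in the extension, which also has low pext
    chrom, gid, t1 = _ids(uid)
    t2, t3 = f"t2_{uid}", f"t3_{uid}"
    seq, exons = _build_gene(rng, exon_cds=(120, 90, 99),
                             codon_overrides={68: "GAA"})
    tx1 = _tx(t1, gid, exons)
    s2, e2 = exons[1]
    core = [exons[0], (s2, e2 - 9), exons[2]]  # 81 bp middle exon, in frame
    tx2 = _tx(t2, gid, core)
    tx3 = _tx(t3, gid, core)
    pos0 = s2 + (204 - 120)  # coding offset 204, inside the extension
    bundle = _std_bundle(seq, chrom, pos0, "T", "nonsense",
                         [(t1, True), (t2, False), (t3, False)])
    pext = _pext([t1], 3, overrides={(t1, 1): 0.05})
    for t in (t2, t3):
        pext.exon_means.update({(t, i): 0.8 for i in range(3)})
    return Scenario(
        name=uid, chrom=chrom, seq=seq, gene_id=gid,
        transcripts=[tx1, tx2, tx3], bundles=[bundle], pext=pext,
        expected=_both(["overhang_exon", "low_pext"], "not_LoF", "not_applicable"),
    )


# -- splice scenarios -------------------------------------------------------

def _splice_scenario(rng, uid, *, exon_cds=(120, 81, 99), donor_exon=1,
                     acceptor_exon=None, sai: SpliceAIScores,
                     intron_prefixes=None, pext_overrides=None, expected):
    chrom, gid, tid = _ids(uid)
    seq, exons = _build_gene(rng, exon_cds=exon_cds,
                             intron_prefixes=intron_prefixes)
    tx = _tx(tid, gid, exons)
    if acceptor_exon is not None:
        pos0 = exons[acceptor_exon][0] - 2  # the 'A' of the AG dinucleotide
        cls = "splice_acceptor"
        alt = "C"
    else:
        pos0 = exons[donor_exon][1]  # the 'G' of the GT dinucleotide
        cls = "splice_donor"
        alt = "A"
    bundle = _std_bundle(seq, chrom, pos0, alt, cls, [(tid, True)], spliceai=sai)
    po = {(tid, i): v for i, v in (pext_overrides or {}).items()}
    return Scenario(
        name=uid, chrom=chrom, seq=seq, gene_id=gid, transcripts=[tx],
        bundles=[bundle], pext=_pext([tid], len(exon_cds), overrides=po),
        expected=expected,
    )


def _sc_strong_splice_rescue(rng, uid):
    # exonic cryptic donor 9 bp upstream, gain within 0.2 of the loss
    return _splice_scenario(
        rng, uid, sai=_sai(ds_dl=0.95, dp_dl=0, ds_dg=0.80, dp_dg=-9),
        expected=_both(["splice_rescue_strong"], "not_LoF", "not_applicable"),
    )


def _sc_weak_splice_rescue(rng, uid):
    return _splice_scenario(
        rng, uid, sai=_sai(ds_dl=0.95, dp_dl=0, ds_dg=0.30, dp_dg=-9),
        expected=_both(["splice_rescue_weak"], "likely_not_LoF", "strong"),
    )


def _sc_retained_stop(rng, uid):
    # in-frame cryptic donor 9 bp into intron 1; retained GTATAA--- includes TAA
    return _splice_scenario(
        rng, uid, donor_exon=0, intron_prefixes={0: "GTATAA"},
        sai=_sai(ds_dl=0.90, dp_dl=0, ds_dg=0.80, dp_dg=9),
        expected=_both(["splice_retained_stop"], "LoF", "very_strong"),
    )


def _sc_out_of_frame_cryptic(rng, uid):
    return _splice_scenario(
        rng, uid, sai=_sai(ds_dl=0.90, dp_dl=0, ds_dg=0.80, dp_dg=-10),
        expected=_both(["splice_out_of_frame"], "LoF", "very_strong"),
    )


def _sc_intron_retention(rng, uid):
    return _splice_scenario(
        rng, uid, sai=_sai(ds_dl=0.90, dp_dl=0),
        expected=_both(["intron_retention"], "LoF", "very_strong"),
    )


def _sc_splice_uncertain(rng, uid):
    return _splice_scenario(
        rng, uid, sai=_sai(ds_dl=0.05, ds_dg=0.05, ds_al=0.05, ds_ag=0.05),
        expected=_both([], "LoF", "very_strong"),
    )


def _sc_in_frame_skip(rng, uid):
    # 30 bp in-frame middle exon of a 420 bp CDS: skip removes 7.1%
    return _splice_scenario(
        rng, uid, exon_cds=(270, 30, 120),
        sai=_sai(ds_dl=0.90, dp_dl=0, ds_al=0.60, dp_al=-31),
        expected=_both(["in_frame_exon_skip"], "not_LoF", "strong"),
    )


def _sc_out_of_frame_skip(rng, uid):
    # 80 bp middle exon: skipping shifts the frame
    return _splice_scenario(
        rng, uid, exon_cds=(120, 80, 100),
        sai=_sai(ds_dl=0.90, dp_dl=0, ds_al=0.60, dp_al=-81),
        expected=_both(["out_of_frame_exon_skip"], "LoF", "very_strong"),
    )


def _sc_mixed_splice_events(rng, uid):
    # in-frame cryptic rescue and out-of-frame exon skip both predicted
    return _splice_scenario(
        rng, uid, exon_cds=(120, 80, 100),
        sai=_sai(ds_dl=0.90, dp_dl=0, ds_dg=0.80, dp_dg=-9, ds_al=0.60, dp_al=-81),
        expected=_both(["mixed_splice_events"], "uncertain_LoF", "strong"),
    )


def _sc_splice_not_supported(rng, uid):
    # acceptor of the last exon, no SpliceAI signal, adjacent exon pext low
    return _splice_scenario(
        rng, uid, acceptor_exon=2,
        sai=_sai(ds_dl=0.05, ds_dg=0.05, ds_al=0.05, ds_ag=0.05),
        pext_overrides={2: 0.05},
        expected=_both(["splice_not_supported_by_pext"], "not_LoF",
                       "not_applicable"),
    )


# ---------------------------------------------------------------------------
# minus-strand twins by whole-contig reverse-complement mirroring
# ---------------------------------------------------------------------------

def _mirror(scn: Scenario) -> Scenario:
    L = len(scn.seq)

    def miv(iv: tuple[int, int]) -> tuple[int, int]:
        s, e = iv
        return (L - e, L - s)

    flip = {"+": "-", "-": "+"}
    transcripts = [
        TranscriptModel(
            transcript_id=t.transcript_id, gene_id=t.gene_id,
            strand=flip[t.strand], exons=[miv(iv) for iv in t.exons],
            cds_intervals=[miv(iv) for iv in t.cds_intervals],
            is_coding=t.is_coding, tags=set(t.tags),
        )
        for t in scn.transcripts
    ]
    bundles = []
    for b in scn.bundles:
        if not b.is_snv:
            raise ValueError("mirroring supports SNV scenarios only")
        sai = b.spliceai
        if sai is not None:
            sai = SpliceAIScores(
                ds_ag=sai.ds_ag, ds_al=sai.ds_al, ds_dg=sai.ds_dg,
                ds_dl=sai.ds_dl, dp_ag=-sai.dp_ag, dp_al=-sai.dp_al,
                dp_dg=-sai.dp_dg, dp_dl=-sai.dp_dl,
            )
        bundles.append(
            VariantBundle(
                chrom=b.chrom, pos=L - b.pos0, ref=revcomp(b.ref),
                alt=revcomp(b.alt), variant_class=b.variant_class, qc=b.qc,
                spliceai=sai, phase_group_id=b.phase_group_id,
                has_read_data=b.has_read_data,
                transcripts_hit=list(b.transcripts_hit),
            )
        )
    pext = PextTrack(
        gene_max=scn.pext.gene_max, exon_means=dict(scn.pext.exon_means),
        per_base=[(c, *miv((s, e)), v) for c, s, e, v in scn.pext.per_base],
    )
    return Scenario(
        name=scn.name, chrom=scn.chrom, seq=revcomp(scn.seq),
        gene_id=scn.gene_id, transcripts=transcripts, bundles=bundles,
        pext=pext,
        repeat_tracks=[(n, [miv(iv) for iv in ivs]) for n, ivs in scn.repeat_tracks],
        conservation=dict(scn.conservation) if scn.conservation else None,
        expected=dict(scn.expected),
    )


def _minus(builder: Callable) -> Callable:
    def build(rng, uid):
        return _mirror(builder(rng, uid))

    return build


CATALOG: dict[str, Callable] = {
    "clean_nonsense": _sc_clean_nonsense,
    "clean_nonsense_minus": _minus(_sc_clean_nonsense),
    "last_exon": _sc_last_exon,
    "last_exon_minus": _minus(_sc_last_exon),
    "last_exon_moderate": _sc_last_exon_moderate,
    "low_pext": _sc_low_pext,
    "low_pext_minus": _minus(_sc_low_pext),
    "gc_rich": _sc_gc_rich,
    "genotyping_low_depth": _sc_genotyping_low_depth,
    "genotyping_skewed_ab": _sc_genotyping_skewed_ab,
    "strand_bias": _sc_strand_bias,
    "minor_mapping": _sc_minor_mapping,
    "complex_mapping": _sc_complex_mapping,
    "low_complexity": _sc_low_complexity,
    "homopolymer_frameshift": _sc_homopolymer_frameshift,
    "frameshift_no_reads": _sc_frameshift_no_reads,
    "mnv_rescue": _sc_mnv_rescue,
    "mnv_retained": _sc_mnv_retained,
    "frame_restoring_pair": _sc_frame_restoring_pair,
    "reinitiation_strong": _sc_reinitiation_strong,
    "reinitiation_weak": _sc_reinitiation_weak,
    "reinitiation_gt_threshold": _sc_reinitiation_gt_threshold,
    "overprinting": _sc_overprinting,
    "minority_at_max": _sc_minority_at_max,
    "minority_at_max_minus": _minus(_sc_minority_at_max),
    "minority_mid": _sc_minority_mid,
    "overhang_exon": _sc_overhang_exon,
    "strong_splice_rescue": _sc_strong_splice_rescue,
    "strong_splice_rescue_minus": _minus(_sc_strong_splice_rescue),
    "weak_splice_rescue": _sc_weak_splice_rescue,
    "retained_stop": _sc_retained_stop,
    "retained_stop_minus": _minus(_sc_retained_stop),
    "out_of_frame_cryptic": _sc_out_of_frame_cryptic,
    "intron_retention": _sc_intron_retention,
    "splice_uncertain": _sc_splice_uncertain,
    "in_frame_skip": _sc_in_frame_skip,
    "in_frame_skip_minus": _minus(_sc_in_frame_skip),
    "out_of_frame_skip": _sc_out_of_frame_skip,
    "mixed_splice_events": _sc_mixed_splice_events,
    "splice_not_supported": _sc_splice_not_supported,
}


def generate_scenario(
    name: str, seed: int, out_dir: Optional[Union[str, Path]] = None,
    uid: Optional[str] = None,
) -> Scenario:
    """Build one scenario; optionally write its files under ``out_dir``.

    Pure function of (name, seed): repeated calls produce identical scenarios
    and byte-identical files.
    """
    if name not in CATALOG:
        raise KeyError(
            f"unknown scenario {name!r}; catalog: {', '.join(sorted(CATALOG))}"
        )
    uid = uid or name
    scn = CATALOG[name](_rng(uid, seed), uid)
    scn.name = name
    if out_dir is not None:
        scn.files = write_scenario_files(scn, Path(out_dir))
    return scn


def generate_cohort(
    n: int, mix: dict[str, float], seed: int, out_dir: Union[str, Path]
) -> dict[str, Path]:
    """Sample ``n`` variants by scenario mix and emit one combined file set.

    Allocation is stratified rounding: floor counts, remainder to the largest
    fractional parts (ties by name). The manifest records each curated
    variant's scenario and expected verdict under both profiles.
    """
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("mix proportions must sum to 1")
    for name in mix:
        if name not in CATALOG:
            raise KeyError(f"unknown scenario {name!r} in mix")
    raw = {k: n * p for k, p in mix.items()}
    counts = {k: int(v) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(mix, key=lambda k: (-(raw[k] - counts[k]), k))[:short]:
        counts[k] += 1
    scenarios = []
    for name in sorted(counts):
        for i in range(counts[name]):
            scenarios.append(generate_scenario(name, seed, uid=f"{name}_{i}"))
    return _write_file_set(scenarios, Path(out_dir), manifest=True)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def _fasta_lines(chrom: str, seq: str) -> list[str]:
    return [f">{chrom}"] + [seq[i : i + 60] for i in range(0, len(seq), 60)]


def _gtf_lines(transcripts: list[TranscriptModel], chrom: str) -> list[str]:
    lines = []
    for t in transcripts:
        tag = f' tag "{next(iter(t.tags))}";' if t.tags else ""
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";{tag}'
        for kind, ivs in (("exon", t.exons), ("CDS", t.cds_intervals)):
            for s, e in sorted(ivs):
                lines.append(
                    f"{chrom}\ttoy\t{kind}\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}"
                )
    return lines


def _spliceai_string(b: VariantBundle, gene_id: str) -> str:
    s = b.spliceai
    return (
        f"{b.alt}|{gene_id}|{s.ds_ag:.2f}|{s.ds_al:.2f}|{s.ds_dg:.2f}|"
        f"{s.ds_dl:.2f}|{s.dp_ag}|{s.dp_al}|{s.dp_dg}|{s.dp_dl}"
    )


VCF_HEADER = """##fileformat=VCFv4.2
{contigs}##INFO=<ID=CLASS,Number=.,Type=String,Description="Variant consequence class">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=TXHIT,Number=.,Type=String,Description="transcript_id:is_pLoF pairs">
##INFO=<ID=PG,Number=1,Type=String,Description="Phase group">
##INFO=<ID=READS,Number=1,Type=Integer,Description="Read data available">
##INFO=<ID=SpliceAI,Number=.,Type=String,Description="SpliceAI delta scores">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=SB_FRAC,Number=1,Type=Float,Description="Fraction of ALT reads on forward strand">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tcarrier"""


def _vcf_row(b: VariantBundle, gene_id: str) -> str:
    info = [f"CLASS={b.variant_class}", f"GENE={gene_id}"]
    if b.transcripts_hit:
        info.append(
            "TXHIT=" + ",".join(f"{t}:{1 if p else 0}" for t, p in b.transcripts_hit)
        )
    if b.phase_group_id:
        info.append(f"PG={b.phase_group_id}")
    info.append(f"READS={1 if b.has_read_data else 0}")
    if b.spliceai is not None:
        info.append(f"SpliceAI={_spliceai_string(b, gene_id)}")
    qc = b.qc
    alt_reads = round(qc.depth * qc.allele_balance)
    sb = f"{qc.strand_bias:.2f}" if qc.strand_bias is not None else "."
    sample = f"0/1:{qc.depth}:{qc.genotype_quality}:{qc.depth - alt_reads},{alt_reads}:{sb}"
    return (
        f"{b.chrom}\t{b.pos}\t.\t{b.ref}\t{b.alt}\t.\tPASS\t"
        f"{';'.join(info)}\tGT:DP:GQ:AD:SB_FRAC\t{sample}"
    )


def _tsv_row(b: VariantBundle, gene_id: str) -> str:
    sai = _spliceai_string(b, gene_id) if b.spliceai is not None else "."
    tx = ",".join(f"{t}:{1 if p else 0}" for t, p in b.transcripts_hit) or "."
    qc = b.qc
    alt_reads = round(qc.depth * qc.allele_balance)
    ab = alt_reads / qc.depth
    return "\t".join(
        [
            b.chrom, str(b.pos), b.ref, b.alt, b.variant_class, str(qc.depth),
            str(qc.genotype_quality), f"{ab:.6g}", sai,
            b.phase_group_id or ".", "1" if b.has_read_data else "0", tx,
            f"{qc.strand_bias:.2f}" if qc.strand_bias is not None else ".",
        ]
    )


def _pext_lines(gene_id: str, pext: PextTrack, chrom: str) -> list[str]:
    lines = []
    for (tid, i), v in sorted(pext.exon_means.items()):
        lines.append(f"{gene_id}\t{tid}\t{i}\t.\t.\t.\t{v:.6g}")
    for c, s, e, v in pext.per_base:
        lines.append(f"{gene_id}\t.\t.\t{c}\t{s}\t{e}\t{v:.6g}")
    return lines


def _write(path: Path, lines: list[str]) -> Path:
    path.write_text("\n".join(lines) + "\n")
    return path


def write_scenario_files(scn: Scenario, out_dir: Path) -> dict[str, Path]:
    """Emit one scenario as FASTA + GTF + VCF + TSV + pext + BED (+ expected)."""
    return _write_file_set([scn], out_dir, expected_json=True)


def _write_file_set(
    scenarios: list[Scenario], out_dir: Path, expected_json: bool = False,
    manifest: bool = False,
) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    fasta, gtf, pext_lines, cons_lines, vcf_rows, tsv_rows = [], [], [], [], [], []
    tracks: dict[str, list[str]] = {}
    manifest_rows = []
    for scn in scenarios:
        fasta += _fasta_lines(scn.chrom, scn.seq)
        gtf += _gtf_lines(scn.transcripts, scn.chrom)
        pext_lines += _pext_lines(scn.gene_id, scn.pext, scn.chrom)
        if scn.conservation:
            for (tid, i), v in sorted(scn.conservation.items()):
                cons_lines.append(f"{scn.gene_id}\t{tid}\t{i}\t{v:.6g}")
        for b in sorted(scn.bundles, key=lambda b: (b.chrom, b.pos)):
            vcf_rows.append(_vcf_row(b, scn.gene_id))
            tsv_rows.append(_tsv_row(b, scn.gene_id))
        for name, ivs in scn.repeat_tracks:
            tracks.setdefault(name, []).extend(
                f"{scn.chrom}\t{s}\t{e}\t{name}" for s, e in ivs
            )
        manifest_rows.append(
            "\t".join(
                [scn.primary.key, scn.name]
                + [scn.expected[p].verdict for p in ("conservative", "lenient")]
            )
        )
    files["fasta"] = _write(out_dir / "ref.fa", fasta)
    files["gtf"] = _write(out_dir / "genes.gtf", gtf)
    contigs = "".join(
        f"##contig=<ID={s.chrom},length={len(s.seq)}>\n" for s in scenarios
    )
    files["vcf"] = _write(
        out_dir / "variants.vcf",
        [VCF_HEADER.format(contigs=contigs)] + vcf_rows,
    )
    files["tsv"] = _write(
        out_dir / "variants.tsv", ["\t".join(
            ["chrom", "pos", "ref", "alt", "variant_class", "depth", "gq", "ab",
             "spliceai", "phase_group", "has_read_data", "transcripts_hit",
             "strand_bias"]
        )] + tsv_rows,
    )
    files["pext"] = _write(
        out_dir / "pext.tsv",
        ["gene_id\ttranscript_id\texon_index\tchrom\tstart\tend\tvalue"] + pext_lines,
    )
    if cons_lines:
        files["conservation"] = _write(
            out_dir / "conservation.tsv",
            ["gene_id\ttranscript_id\texon_index\tvalue"] + cons_lines,
        )
    for name, lines in sorted(tracks.items()):
        files[f"repeats_{name}"] = _write(out_dir / f"repeats_{name}.bed", lines)
    if expected_json:
        payload = {
            s.name: {
                prof: {
                    "flags": sorted(e.flags), "verdict": e.verdict, "pvs1": e.pvs1,
                }
                for prof, e in s.expected.items()
            }
            for s in scenarios
        }
        p = out_dir / "expected.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        files["expected"] = p
    if manifest or len(scenarios) != 1:
        files["manifest"] = _write(
            out_dir / "manifest.tsv",
            ["variant\tscenario\tverdict_conservative\tverdict_lenient"]
            + manifest_rows,
        )
    return files


def scenario_resources(scn: Scenario):
    """In-memory :class:`CohortResources` for one or more scenarios."""
    from intervaltree import IntervalTree

    from .curation_engine import CohortResources

    scns = scn if isinstance(scn, list) else [scn]
    res = CohortResources()
    for s in scns:
        res.transcripts.update({t.transcript_id: t for t in s.transcripts})
        res.ref_by_chrom[s.chrom] = s.seq
        res.pext_by_gene[s.gene_id] = s.pext
        for name, ivs in s.repeat_tracks:
            trees: dict[str, IntervalTree] = {}
            for a, b in ivs:
                trees.setdefault(s.chrom, IntervalTree()).addi(a, b)
            res.repeat_tracks.append((name, trees))
        if s.conservation:
            res.conservation_by_gene[s.gene_id] = dict(s.conservation)
    return res
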