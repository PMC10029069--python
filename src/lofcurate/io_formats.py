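"""Readers and writers for the standard formats, and the per-variant report.

Formats touched: GTF 2.2 (gene models, via gffutils), VCF 4.2 (variants, via
pysam), FASTA (reference, via pyfaidx), BED (repeat/low-complexity tracks),
TSV (flat-variant input and the report), JSON (cohort summary).

The VCF reader applies the standard population-database genotype prefilter
when asked: non-reference heterozygous genotypes with depth <10, genotype
quality <20 or allele balance <20% are excluded before curation.

Variant consequence class is an input here (annotation pipelines such as VEP
are upstream of this tool); it is read from the ``CLASS`` INFO key, alongside
``TXHIT`` (``transcript:0/1`` pairs), ``PG`` (phase group), ``READS`` (read
data available) and the standard ``SpliceAI`` annotation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import pysam
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .models import (
    CurationResult,
    PextTrack,
    PVS1Decision,
    QCMetrics,
    TranscriptModel,
    VariantBundle,
    VARIANT_CLASSES,
)
from .splice_rules import parse_spliceai_info

log = logging.getLogger(__name__)

# Methods-level genotype prefilter (fixed; distinct from RuleProfile flags)
PREFILTER_DEPTH = 10
PREFILTER_GQ = 20
PREFILTER_AB = 0.20

TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "variant_class", "depth", "gq", "ab",
    "spliceai", "phase_group", "has_read_data", "transcripts_hit",
]

REPORT_COLUMNS = [
    "variant", "variant_class", "flags", "verdict", "primary_reason",
    "pvs1_max_strength", "confirmation_required", "audit",
]


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(gtf_source: Union[str, Path]) -> list[TranscriptModel]:
    """Read transcript models from a GTF with exon and CDS features.

    Intervals are converted to 0-based half-open; exons are ordered 5'->3' in
    transcript orientation. Raises a format error naming the transcript when a
    CDS interval falls outside every exon.
    """
    import gffutils

    path = Path(gtf_source)
    text = path.read_text()
    if not text.strip():
        warnings.warn(f"empty GTF {path}", stacklevel=2)
        return []
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        rec = per_tx.setdefault(
            tid, {"gene_id": gid, "strand": feat.strand, "exons": [], "cds": [],
                  "tags": set()},
        )
        iv = (feat.start - 1, feat.end)  # GTF 1-based inclusive -> half-open
        rec["exons" if feat.featuretype == "exon" else "cds"].append(iv)
        for tag in feat.attributes.get("tag", []):
            rec["tags"].add(tag)
    models = []
    for tid, rec in per_tx.items():
        exons = sorted(set(rec["exons"]))
        cds = sorted(set(rec["cds"]))
        if rec["strand"] == "-":
            exons, cds = exons[::-1], cds[::-1]
        for cs, ce in cds:
            if not any(es <= cs and ce <= ee for es, ee in exons):
                raise ValueError(
                    f"GTF format error: CDS ({cs + 1}-{ce}) of {tid} outside all exons"
                )
        models.append(
            TranscriptModel(
                transcript_id=tid, gene_id=rec["gene_id"], strand=rec["strand"],
                exons=exons, cds_intervals=cds, is_coding=bool(cds),
                tags=rec["tags"],
            )
        )
    return models


# ---------------------------------------------------------------------------
# reference / tracks
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Contig name -> uppercase sequence."""
    fa = Fasta(str(path), rebuild=True, build_index=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def read_repeat_tracks(
    paths: list[Union[str, Path]]
) -> list[tuple[str, dict[str, IntervalTree]]]:
    """One BED file per repeat track; returns (track_name, per-chrom trees).

    The track name is the BED name column when present, else the file stem;
    a track whose name contains ``low_complexity`` marks low-complexity
    sequence rather than a repeat-masker track.
    """
    tracks = []
    for p in paths:
        p = Path(p)
        trees: dict[str, IntervalTree] = {}
        name = p.stem
        for line in p.read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if len(fields) > 3 and fields[3] != ".":
                name = fields[3]
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        tracks.append((name, trees))
    return tracks


def repeat_overlap_count(
    tracks: list[tuple[str, dict[str, IntervalTree]]], chrom: str, pos0: int
) -> int:
    """Number of repeat tracks with an interval overlapping ``pos0``."""
    n = 0
    for name, trees in tracks:
        if "low_complexity" in name:
            continue
        t = trees.get(chrom)
        if t is not None and t.overlaps(pos0):
            n += 1
    return n


def in_low_complexity(
    tracks: list[tuple[str, dict[str, IntervalTree]]], chrom: str, pos0: int
) -> bool:
    for name, trees in tracks:
        if "low_complexity" not in name:
            continue
        t = trees.get(chrom)
        if t is not None and t.overlaps(pos0):
            return True
    return False


def read_pext(path: Union[str, Path]) -> dict[str, PextTrack]:
    """Read pext values; one track per gene.

    TSV with header ``gene_id transcript_id exon_index chrom start end value``:
    per-exon rows carry transcript_id/exon_index with chrom ``.``; per-base
    rows carry chrom/start/end (0-based half-open) with transcript_id ``.``.
    ``gene_max`` is the maximum stored value for the gene.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, PextTrack] = {}
    for gid, sub in df.groupby("gene_id"):
        exon_means: dict[tuple[str, int], float] = {}
        per_base: list[tuple[str, int, int, float]] = []
        for _, row in sub.iterrows():
            v = float(row["value"])
            if row["transcript_id"] != ".":
                exon_means[(row["transcript_id"], int(row["exon_index"]))] = v
            else:
                per_base.append((row["chrom"], int(row["start"]), int(row["end"]), v))
        gene_max = max(
            [v for v in exon_means.values()] + [v for *_, v in per_base], default=0.0
        )
        out[gid] = PextTrack(gene_max=gene_max, exon_means=exon_means, per_base=per_base)
    return out


def read_conservation(path: Union[str, Path]) -> dict[str, dict[tuple[str, int], float]]:
    """Per-exon conservation means: gene_id -> {(transcript_id, exon_index): score}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, dict[tuple[str, int], float]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["gene_id"], {})[
            (row["transcript_id"], int(row["exon_index"]))
        ] = float(row["value"])
    return out


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

@dataclass
class PrefilterStats:
    total: int = 0
    excluded: int = 0

    @property
    def retained(self) -> int:
        return self.total - self.excluded


def _prefilter_fails(het: bool, qc: QCMetrics) -> bool:
    """Methods-level genotype prefilter for non-reference heterozygous calls."""
    if not het:
        return False
    if qc.depth is not None and qc.depth < PREFILTER_DEPTH:
        return True
    if qc.genotype_quality is not None and qc.genotype_quality < PREFILTER_GQ:
        return True
    if qc.allele_balance is not None and qc.allele_balance < PREFILTER_AB:
        return True
    return False


def _parse_txhit(value: Optional[str]) -> list[tuple[str, bool]]:
    if not value or value == ".":
        return []
    out = []
    for part in str(value).split(","):
        tid, flag = part.split(":")
        out.append((tid, flag == "1"))
    return out


def read_variants(
    source: Union[str, Path], prefilter: bool = False
) -> tuple[list[VariantBundle], PrefilterStats]:
    """Read variant bundles from a VCF or flat TSV (dispatch on extension)."""
    path = Path(source)
    if path.suffix in (".tsv", ".txt"):
        return read_variants_tsv(path, prefilter=prefilter)
    return read_variants_vcf(path, prefilter=prefilter)


def read_variants_vcf(
    path: Union[str, Path], prefilter: bool = False
) -> tuple[list[VariantBundle], PrefilterStats]:
    stats = PrefilterStats()
    bundles: list[VariantBundle] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            classes = _info_list(rec, "CLASS")
            txhits = _info_list(rec, "TXHIT")
            for i, alt in enumerate(rec.alts or ()):
                stats.total += 1
                cls = classes[i] if i < len(classes) else (classes[0] if classes else None)
                if cls is None or cls not in VARIANT_CLASSES:
                    warnings.warn(
                        f"record {rec.chrom}:{rec.pos} has unknown variant class "
                        f"{cls!r}; skipped", stacklevel=2,
                    )
                    stats.total -= 1
                    continue
                qc, het = _sample_qc(rec, i)
                if prefilter and _prefilter_fails(het, qc):
                    stats.excluded += 1
                    continue
                gene_id = _info_scalar(rec, "GENE")
                sai = None
                sai_raw = _info_scalar(rec, "SpliceAI")
                if sai_raw and gene_id:
                    sai = parse_spliceai_info(sai_raw, gene_id)
                reads = _info_scalar(rec, "READS")
                bundles.append(
                    VariantBundle(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        variant_class=cls, qc=qc, spliceai=sai,
                        phase_group_id=_info_scalar(rec, "PG"),
                        has_read_data=(reads != "0") if reads is not None else True,
                        transcripts_hit=_parse_txhit(
                            txhits[i] if i < len(txhits) else
                            (txhits[0] if txhits else None)
                        ),
                    )
                )
    if prefilter:
        log.info(
            "genotype prefilter: %d of %d genotypes excluded (DP<%d, GQ<%d or AB<%d%%)",
            stats.excluded, stats.total, PREFILTER_DEPTH, PREFILTER_GQ,
            int(PREFILTER_AB * 100),
        )
    return bundles, stats


def _info_scalar(rec, key) -> Optional[str]:
    v = rec.info.get(key)
    if v is None:
        return None
    if isinstance(v, tuple):
        v = ",".join(str(x) for x in v)
    return str(v)


def _info_list(rec, key) -> list[str]:
    v = _info_scalar(rec, key)
    return v.split(",") if v else []


def _sample_qc(rec, alt_index: int) -> tuple[QCMetrics, bool]:
    """QC metrics of the carrier genotype (first sample), plus het status."""
    if not rec.samples:
        return QCMetrics(), False
    s = rec.samples[0]
    gt = tuple(a for a in (s.get("GT") or ()) if a is not None)
    het = len(set(gt)) > 1 and 0 in gt
    depth = s.get("DP")
    gq = s.get("GQ")
    ab = None
    ad = s.get("AD")
    if ad is not None and len(ad) > alt_index + 1:
        ref_d, alt_d = ad[0], ad[alt_index + 1]
        if ref_d is not None and alt_d is not None and (ref_d + alt_d) > 0:
            ab = alt_d / (ref_d + alt_d)
    sb = s.get("SB_FRAC")
    # VCF floats are single precision; round away the representation noise
    return (
        QCMetrics(
            depth=depth, genotype_quality=gq, allele_balance=ab,
            strand_bias=round(float(sb), 6) if sb is not None else None,
        ),
        het,
    )


def read_variants_tsv(
    path: Union[str, Path], prefilter: bool = False
) -> tuple[list[VariantBundle], PrefilterStats]:
    """Flat-TSV equivalent of the VCF path (12 documented columns).

    All genotypes in the flat dialect are non-reference heterozygous carrier
    genotypes, matching the framework's input population.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant TSV missing columns: {missing}")
    stats = PrefilterStats()
    bundles: list[VariantBundle] = []
    for idx, row in df.iterrows():
        stats.total += 1
        cls = row["variant_class"]
        if cls not in VARIANT_CLASSES:
            warnings.warn(f"line {idx + 2}: unknown variant class {cls!r}; skipped",
                          stacklevel=2)
            stats.total -= 1
            continue

        def _opt(col, cast):
            v = row[col]
            return None if pd.isna(v) or v == "." else cast(v)

        sb = _opt("strand_bias", float) if "strand_bias" in df.columns else None
        qc = QCMetrics(
            depth=_opt("depth", int), genotype_quality=_opt("gq", int),
            allele_balance=_opt("ab", float), strand_bias=sb,
        )
        if prefilter and _prefilter_fails(True, qc):
            stats.excluded += 1
            continue
        sai_raw = _opt("spliceai", str)
        txhits = _parse_txhit(row["transcripts_hit"])
        gene_id = sai_raw.split("|")[1] if sai_raw else None
        bundles.append(
            VariantBundle(
                chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"],
                alt=row["alt"], variant_class=cls, qc=qc,
                spliceai=parse_spliceai_info(sai_raw, gene_id) if sai_raw else None,
                phase_group_id=_opt("phase_group", str),
                has_read_data=row["has_read_data"] == "1",
                transcripts_hit=txhits,
            )
        )
    return bundles, stats


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def format_flags(result: CurationResult) -> str:
    if not result.flags:
        return "."
    return ";".join(
        f"{f.name}:{f.category.value}:{f.tier.value}"
        for f in sorted(result.flags, key=lambda f: f.name)
    )


def write_report(
    results: list[tuple[CurationResult, PVS1Decision]],
    sink: Union[str, Path],
    summary_sink: Optional[Union[str, Path]] = None,
) -> int:
    """Write the per-variant TSV report plus a JSON summary block.

    Returns the number of data rows written (== number of input results).
    """
    from .summary_stats import summarize_results

    rows = []
    for res, dec in results:
        rows.append(
            {
                "variant": res.variant.key,
                "variant_class": res.variant.variant_class,
                "flags": format_flags(res),
                "verdict": res.verdict.value,
                "primary_reason": res.primary_reason,
                "pvs1_max_strength": dec.reported_strength,
                "confirmation_required": "1" if dec.requires_analytical_confirmation else "0",
                "audit": "|".join(res.audit) if res.audit else ".",
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    sink = Path(sink)
    df.to_csv(sink, sep="\t", index=False, lineterminator="\n")
    if summary_sink is not None:
        summary = summarize_results([r for r, _ in results])
        summary["pvs1_strengths"] = _count(
            d.reported_strength for _, d in results
        )
        Path(summary_sink).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return len(rows)


def _count(items) -> dict[str, int]:
    out: dict[str, int] = {}
    for it in items:
        out[it] = out.get(it, 0) + 1
    return dict(sorted(out.items()))


def read_report(path: Union[str, Path]) -> pd.DataFrame:
    """Read a report TSV back (lossless round trip of every column)."""
    return pd.read_csv(path, sep="\t", dtype=str)
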