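# Methods

## Scope and model

`lofcurate` automates a rule-based curation protocol for predicted
loss-of-function (pLoF) variants. The unit of assessment is one variant
against one coding transcript; cross-transcript evidence (pext ratios,
minority-of-transcripts, overhang exons) is evaluated on the assessed
transcript using the gene's full transcript set. When a variant is pLoF in
several coding transcripts, each is assessed and the per-transcript result
closest to the LoF end of the verdict order defines the call — the transcript
in which the variant matters most is the biologically relevant reading.

Three flag categories are evaluated:

1. **Rescue by secondary sequence properties** — MNV joint-codon
   re-translation, frame-restoring indel pairs, SpliceAI-based cryptic-site /
   exon-skip / intron-retention interpretation, translational reinitiation,
   overhang exons.
2. **Uncertain biological relevance** — pext ratio categories, minority of
   coding transcripts, weak exon conservation, overprinted reading frames,
   NMD escape (last exon / 50-bp penultimate rule).
3. **Potential technical artifacts** — genotype QC thresholds, homopolymer
   indels, repeat/low-complexity overlap, GC-rich windows, strand bias,
   missing read data.

Each triggered rule contributes a flag carrying a verdict tier; the final
verdict is the maximum-impact tier (LoF < likely LoF < uncertain LoF <
likely not LoF < not LoF). A frameshift without read data carries an
uncertain-LoF baseline (read visualization is how frame-restoring partners
are found), outranked only by higher-tier flags.

PVS1 adjustment maps each non-technical flag to a consequence
(no change / cap at Strong / cap at Moderate / do not use) and applies the
single worst consequence — downgrading is by worst consequence, never
additive. Truncation-type flags (weak splice rescue, strong reinitiation,
NMD escape, in-frame exon skip) split Strong vs Moderate at 10 % of CDS
removed, mirroring the structure of the SVI decision tree. Technical flags do
not modify PVS1; they require analytical confirmation of the call first,
because analytic validity is a separate question from pathogenicity. Once
confirmed, a technical flag has no PVS1 effect.

## Coordinates and geometry

All intervals are converted to 0-based half-open at parse time (GTF is
1-based inclusive, BED half-open, VCF positions 1-based) and converted back
on output. Exon lists are ordered 5'→3' in transcript orientation; interval
endpoints stay in genome orientation. The `CodingMap` gives a bijection
between genomic positions and coding offsets, with offset 0 at the
translation start on either strand. Every geometric rule (fraction removed,
NMD escape, reinitiation, splice frame arithmetic) runs through this map, so
strand handling is centralized and the fixture catalog exercises it with
reverse-complement-mirrored twins of the geometric scenarios.

The fraction of coding sequence removed counts the termination base and
everything 3' of it, in the assessed transcript's own CDS. For frameshifts
the termination position is approximated by the variant site (the true
premature stop lies somewhat downstream; at the 25 %/10 % granularity of the
truncation rules this is a second-order effect). For essential splice
variants the termination proxy is the first coding base of the affected exon
(acceptor) or the base after the affected exon's last coding base (donor).

## Thresholds

Every threshold is a named field of `RuleProfile`:

| field | conservative | lenient |
|---|---|---|
| depth_min | 15 | 10 |
| ab_min | 0.35 | 0.25 |
| gq_min | 30 | 20 |
| repeat_track_min (flag when count exceeds) | 5 | 3 |
| homopolymer_min_run | 5 | 7 |
| spliceai_rescue_min / strong_margin | 0.2 / 0.2 | 0.2 / 0.2 |
| reinit_strong_max_fraction | 0.25 | 0.10 |
| truncation_max_fraction | 0.25 | 0.10 |
| low_pext_max_ratio | 0.20 | 0.10 |
| mid_pext_max_ratio | 0.50 | 0.30 |
| minority_fraction | 0.50 | 0.50 |
| nmd_penultimate_window (bp) | 50 | 50 |

The conservative profile flags more aggressively and is the recommended
setting for population data, where pLoF calls are enriched for artifacts and
rescues; the lenient profile discards fewer variants. Note the repeat-track
rule is the one place the profiles do not nest: the lenient cutoff (> 3
tracks) promotes to *complex* mapping earlier than the conservative one
(> 5), so a mid-range overlap count is *minor* (likely-LoF tier) under
conservative but *complex* (likely-not-LoF tier) under lenient. This
inversion is preserved deliberately and carved out of the profile-ordering
property test.

Values without an established published cutoff were fixed once as package
defaults, all configurable: GC-rich = GC ≥ 0.70 over a 100-bp centered
window (a common capture-failure regime); strand bias = ALT forward-strand
fraction ≤ 0.05 or ≥ 0.95 with ≥ 10 ALT reads (approximated as
depth × allele balance); frame-restoring indel co-occurrence window = 100 bp
(read-length bounded, since such pairs are found by read visualization);
pext "at maximum" = ratio ≥ 0.9 and "close to maximum" = [mid ratio, 0.9);
weak exon conservation = exon mean below the 25th percentile of exon means
for the gene, and a reinitiation methionine in an exon with mean
conservation < 0.5 is demoted from strong to weak. The NMD window uses the
stricter 50-bp figure (published descriptions range 50–55 bp).

## SpliceAI interpretation

Delta-score positions (DP fields) are variant-relative; the distance between
a cryptic site and the annotated site is taken as `dp_gain − dp_loss`, the
loss position marking the annotated site (an essential splice variant sits
within 2 bp of it). Gains are compared to the loss of the same site type only
(donor gains vs donor loss, acceptor gains vs acceptor loss). A qualifying
gain (≥ 0.2) is a cryptic event, in-frame iff that distance ≡ 0 mod 3, strong
iff loss − gain ≤ 0.2. A cryptic site on the intronic side extends the exon:
the retained interval is translated in the inherited frame — including the
junction-spanning codon, reconstructed from the exon's trailing partial
codon — and any stop forces the LoF tier regardless of rescue strength.
Opposite-end loss of the same exon predicts skipping, in-frame iff the exon's
CDS length ≡ 0 mod 3 and flagged as a rescue only when it removes less than
the truncation limit; terminal exons cannot be rescued by skipping. Loss with
no rescue or skip signal is treated as intron retention (LoF tier). Mixed
in-frame and out-of-frame candidate events are classified `multiple_events`
(uncertain tier). No loss signal at all yields `non_essential_site` when the
adjacent exon's pext is low, else `uncertain`; an uncertain splice outcome
carries no flag, so absent other evidence the verdict conservatively stays
LoF. Missing pext is never used as evidence in either direction — dependent
rules are skipped with an audit note, not defaulted.

## Statistics

`fisher_exact_2x2` and `chi_square_2x2` wrap `scipy.stats`; the two-sided
Fisher p-value uses the probability-mass definition (sum over tables, with
fixed margins, whose probability does not exceed the observed table's), and
the test suite verifies it against a self-contained hypergeometric
enumeration for every table with total ≤ 30. Degenerate margins return
p = 1 by convention. A Bonferroni helper multiplies p by the test count,
capped at 1.

## Synthetic data

The fixture generator emulates the full input surface at toy scale: contigs
of ~600–900 bp carrying one gene of 2–3 exons (CDS 300–435 bp, introns
90 bp), with reference FASTA, GTF, single-sample VCF (or the equivalent flat
TSV), per-exon pext, repeat/low-complexity BED tracks, and per-exon
conservation. Filler codons exclude stops, ATG, triple-identical bases and
high-GC codons so that each mechanism is present exactly where a scenario
constructs it; canonical GT/AG dinucleotides mark intron ends. Each of the
40 scenarios fixes its expected flags, verdict and PVS1 outcome for both
profiles *by construction* — arithmetic on the planted geometry, never by
running the engine — making the catalog an independent oracle for the whole
pipeline. Geometric scenarios have minus-strand twins produced by
reverse-complement mirroring of the entire contig; indel scenarios have no
mirrored twin because VCF left-anchoring does not survive mirroring, and
minus-strand indel arithmetic is covered by unit tests instead. Generation is
a pure function of (scenario name, seed) and files are byte-identical across
runs.

What the toys do not emulate: realistic allele-frequency spectra, read-level
evidence (read data presence is an input flag), multi-sample cohort VCF
semantics, tissue-specific pext structure, genuine splice-predictor behavior
(SpliceAI scores are inputs, planted to describe each mechanism), and
genome-scale annotation noise. Passing the scenario suite therefore
demonstrates that the rules compute what they are defined to compute on
clean, unambiguous inputs — not that the thresholds are optimal for any
particular real dataset.

## Problem sizes

The test suite and the acceptance script run the 40-scenario catalog under
both profiles through the on-disk formats, a 200-genotype prefilter set, and
a 120-variant mixed cohort; the exhaustive oracles cover all 64 × 3 × 9 MNV
codon cases and all ~46,000 2×2 tables with total ≤ 30. These sizes were
chosen to enumerate the relevant case space exactly while keeping a full run
in tens of seconds.

## Known limitations

* The engine curates single heterozygous carrier genotypes; diploid
  genotype modeling, structural variants and cohort semantics are out of
  scope.
* Frameshift termination uses the variant site as proxy (above).
* Overprinting detection relies on an input transcript tag; the engine does
  not infer alternate reading frames de novo.
* The PVS1 consequence map beyond its two text-anchored cases (worst-flag
  non-additivity; low pext ⇒ do not use) is a package decision and is
  configurable; `weak_conservation_mid` is assigned cap-at-Strong as a
  moderate-evidence downgrade rather than do-not-use.
* LOFTEE, VEP, SpliceAI and pext generation are upstream tools whose outputs
  are inputs here; the package does not reimplement them.
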