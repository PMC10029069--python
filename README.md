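# lofcurate

Automated, auditable curation of **predicted loss-of-function (pLoF) variants**
— nonsense, frameshift, and essential (±1–2) splice-site variants — for
researchers and clinical curators working with population sequencing data.

Standard annotation pipelines call a variant pLoF from its local consequence
alone, yet a substantial fraction of such calls never abolish protein
expression: they are rescued by secondary sequence properties, fall in
transcripts or exons of doubtful biological relevance, or are sequencing
artifacts. `lofcurate` encodes those mechanisms as explicit, threshold-driven
rules and resolves them into a verdict and an ACMG/AMP PVS1 recommendation.

## What it computes

For each variant *v* annotated against a transcript *T* with coding length
*L* and termination (or first-lost) coding offset *o*:

* **Rescue flags** — in-phase MNVs re-translated as a joint codon;
  frame-restoring indel pairs (Σ Δlen ≡ 0 mod 3); SpliceAI-predicted cryptic
  rescues (gain ≥ 0.2; *strong* iff loss − gain ≤ 0.2; in-frame iff the
  cryptic/annotated offset ≡ 0 mod 3, with retained intronic sequence scanned
  for stop codons); in-frame exon skipping (exon length ≡ 0 mod 3, removing
  < 25 % of the CDS); translational reinitiation at a downstream in-frame ATG
  in the first coding exon; overhang exons.
* **Biological-relevance flags** — exon mean pext / gene-max pext ratio
  (low ≤ 20 %, mid < 50 % under the conservative profile); pLoF in < 50 % of
  coding transcripts; weakly conserved exons; overprinted reading frames;
  NMD escape when *o* lies in the last exon or the final 50 coding bp of the
  penultimate exon with fraction removed (L − o)/L < 25 %.
* **Technical flags** — genotype metrics (DP < 15, GQ < 30, AB < 35 %
  conservative), homopolymer indels (run ≥ 5), repeat-track overlaps,
  GC-rich windows, strand bias, low-complexity sequence, missing read data.

Flags resolve by precedence (the most impactful wins) into one of five
verdicts — **LoF, likely LoF, uncertain LoF, likely not LoF, not LoF** — and
the single worst flag consequence caps PVS1 at very strong / strong /
moderate / not applicable (never additively). Technical flags instead demand
analytical confirmation before PVS1 is assessed at all.

Every numeric threshold lives in a named `RuleProfile` field with
`conservative` and `lenient` presets; an upstream genotype prefilter
(DP < 10, GQ < 20, AB < 20 % for non-reference heterozygous calls) can be
applied at read time.

## Worked example

Generate a synthetic scenario — a splice-donor variant whose in-frame cryptic
rescue retains intronic sequence containing a stop codon — and curate it:

```sh
lofcurate fixtures generate --scenario retained_stop --seed 1 --out fx
lofcurate curate --vcf fx/retained_stop/variants.vcf \
    --gtf fx/retained_stop/genes.gtf --fasta fx/retained_stop/ref.fa \
    --pext fx/retained_stop/pext.tsv --profile conservative --out curated
lofcurate summarize --report curated/report.tsv
```

```
curated 1 variants (0 genotypes prefiltered) with the conservative profile -> curated/report.tsv
{
  "n": 1,
  "verdict_counts": { "LoF": 1 },
  "verdict_proportions": { "LoF": 1.0 },
  "flag_counts": { "splice_retained_stop": 1 },
  "primary_reasons": { "splice_retained_stop": 1 }
}
```

Although SpliceAI predicts an in-frame cryptic rescue, the retained 9-mer is
stop-scanned, the `splice_retained_stop` flag fires at the LoF tier, and the
verdict stays **LoF** with PVS1 unmodified (`very_strong` in
`curated/report.tsv`) — a rescue that splices in a termination codon is not a
rescue.

The same catalog drives library use: `lofcurate.curate_cohort(bundles,
resources, CONSERVATIVE)` returns `(CurationResult, PVS1Decision)` pairs for
any set of `VariantBundle`s.

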