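# Methods

`isoscan` re-implements, as a tested and reusable pipeline, the analysis
chain used to annotate a long-read (Iso-Seq-style) transcriptome and to
call differential alternative splicing (DAS) and differential expression
(DE) between two conditions — the setting it emulates is a comparison of
two porcine skeletal muscles (longissimus thoracis vs semitendinosus,
three animals each), but every stage is generic over "condition A vs
condition B with replicates".

## Coordinate model

All coordinates are 0-based half-open internally; GTF/GFF3 I/O converts at
the boundary (BED12 is native).  A transcript is a strand-aware exon
chain; its *splice chain* is the ordered list of internal splice sites
(terminal coordinates excluded).  Junctions are keyed by intron
coordinates — donor = intron start, acceptor = intron end in genome
space, strand-aware — matching how short-read junction evidence is
reported.

## Read filtering

Full-length non-concatemer (FLNC) reads are kept when their spliced
length lies in [50, 15 000] bp, both bounds inclusive.  The filter applies
to the spliced length (sum of exon lengths), not the genomic span: the
read is the molecule, not its projection.  Pass number (≥ 3) and predicted
accuracy (≥ 0.99) are sequencing-run properties that alignment files do
not carry; they are filtered only when supplied as per-read metadata,
otherwise skipped with a logged notice.

## Loci and isoform annotation

Two structures belong to the same locus when (i) their genomic spans
overlap by ≥ 20 % of the shorter span, (ii) at least one exon pair
overlaps by the same fraction, and (iii) they share transcriptional
direction.  Loci are the connected components (single-linkage closure) of
this pairwise relation: the pairwise rule implies transitive grouping.
The 20 % denominator is the shorter interval — the symmetric, scale-free
reading — and is configurable (`min_overlap`).

Within a locus, three ordered rules remove redundancy and false
positives:

1. **Exact-chain merge** — members with identical internal splice chains
   merge into the longest one (read support summed; the more complete 5'
   end kept).  For single-exon members the (empty) chains also merge, so a
   locus reports one representative single-exon structure.
2. **5'-suffix merge** — a member whose chain is a strict 3'-terminal
   suffix (transcription sense) of a longer member's chain, and whose 5'
   terminus lies strictly inside that member, is treated as a 5'-degraded
   fragment and merged.  Single-exon remnants merge only when they overlap
   the parent's 3'-terminal exon.  Poly(A) selection anchors the 3' end,
   so 5' degradation is the operative artifact model.
3. **Singleton filter with rescue** — remaining members supported by a
   single read are discarded, unless every one of their introns is either
   annotated in the reference or supported (count > 0 in any sample) by
   short-read junction evidence.  Single-exon singletons have no introns
   and are vacuously retained.

Merging runs before the singleton test so that support accumulates first.
The collapse is idempotent, and total read support is conserved up to the
logged singleton removals.

Each surviving isoform is classified against the reference:

- **novel gene** — no annotated gene passes the locus rule (overlap below
  threshold, or sufficient overlap on the opposite strand);
- **known** — the full internal splice chain matches an annotated
  transcript of an overlapping gene (terminal exon boundaries are ignored:
  long-read termini are degraded), or a single-exon structure contained in
  a single-exon annotated transcript;
- **novel isoform of an annotated locus** — anything else over an
  annotated gene: a splice site absent from the gene's annotation, a
  single-exon/multi-exon mismatch with the best-matching gene, or a novel
  arrangement of annotated sites.  The best match is the gene with the
  largest exonic overlap (ties to the lexicographically smaller id).

**Fusions.**  Reads aligned in several segments (shared `read_id`) are
screened before clustering: a read is a fusion when its segments overlap
≥ 2 distinct annotated gene loci, each segment overlaps its gene span by
≥ 20 % of the shorter interval, and every breakpoint junction between
consecutive segments has short-read support.  Interchromosomal
breakpoints are keyed in the junction table as `chromA~chromB` with
donor/acceptor the two segment boundary coordinates; intrachromosomal
breakpoints use the ordinary junction key.  No strand constraint is
imposed between partners.

## Alternative-splicing events

Isoform pairs of a locus are compared through their splice chains.
Anchors are splice sites shared with the same structural role (exon start
vs exon end); because chains are strictly increasing, shared sites align
without sequence alignment.  A *bubble* is a maximal run of disagreeing
sites between consecutive anchors (or a transcript terminus; a terminus
acts as a structural anchor only when both isoforms share its
coordinate).  Bubble classification:

| type | condition between anchors |
|------|---------------------------|
| ES   | donor→acceptor anchors; one side complete exon(s), other side splices straight across |
| IR   | start→end anchors inside a shared exon; one side reads through, other has exactly one intron |
| AAS  | one alternative site per side, both acceptor-role (strand-aware) |
| ADS  | as AAS with donor-role sites |
| MEE  | one complete exon per side, non-overlapping, and no isoform of the locus carries both |
| complex | anything else (incl. multi-intron retention, overlapping alternative exons) |

The *inclusion* form is the side with more exonic bases between the
anchors ("one is longer"); MEE ties break to the smaller leftmost
coordinate.  Events identical in (anchors, inclusion chain, exclusion
chain) are deduplicated across isoform pairs.  Each form is diagnosed by
its private intron set; the diagnostic multiplicities are ES (2, 1),
AAS/ADS (1, 1), MEE (2, 2).  The retained side of an IR event has no
diagnostic junction: IR events are quantified only when a separate
retention-evidence table (same schema, keyed by the retained intron) is
supplied, and are otherwise reported but flagged unquantified.

A deliberately independent re-implementation
(`isoscan.naive`) re-derives the same semantics from splice-site set
differences and direct interval queries; the test suite and the
acceptance script require event-for-event agreement on hundreds of
randomized loci.

## Differential splicing

For one event and condition, the exon-inclusion ratio pools replicates:

    EI = (ΣI / l_I) / (ΣI / l_I + ΣS / l_S)

with I, S the junction counts of the inclusion/exclusion form and
(l_I, l_S) the junction multiplicities (effective-length correction: one
exon-skipping molecule supports two inclusion junctions but one skipping
junction).  ΔEI = EI_B − EI_A throughout.

Each event is tested with a binomial likelihood-ratio test on the
length-normalized counts — H0: one shared inclusion probability across
all samples; H1: one per condition — with 2(ℓ1 − ℓ0) referred to χ²(1).
Events with zero total evidence in either condition are excluded before
multiple-testing adjustment so the family contains only testable events.
Benjamini–Hochberg FDR is computed over the tested set, and an event is
DAS when |ΔEI| > 0.05 **and** FDR < 0.05, both strict, as the decision
rule states them.  The pooled binomial model is exactly the generator's
sampling model, so its calibration (type-I error ≈ 0.04–0.06 at nominal
0.05; p-values uniform under the null) is verified by Monte-Carlo rather
than assumed.  Replicate-level counts are retained; pooling for EI
estimation is a modeling choice, made because replicate handling is
otherwise unspecified in this design.

## Expression and integration

FPKM = count · 10⁹ / (gene length · library size), with gene length the
union-exon length of the gene's collapsed isoforms (reference structure
as fallback).  A gene is *expressed* when FPKM ≥ 0.1 in at least one
sample (inclusive).

Differential expression uses median-of-ratios size factors and a
negative-binomial Wald test on the log fold-change of normalized
condition means (pseudo-count 1).  Dispersion (variance = μ + αμ²) is
estimated per gene by method of moments from the pooled within-condition
residual variance, clipped to [10⁻⁸, 10], then pooled into a single
common mean dispersion used in the Wald variance.  At 3 + 3 replicates
the gene-wise moment estimate correlates strongly with the realized
sample variance, so plugging it in gene by gene inflates the type-I error
(≈ 0.11 at nominal 0.05 in Monte-Carlo); a t(4) reference fixes
calibration but collapses BH-adjusted power.  The common-dispersion Wald
with a normal reference is calibrated (0.049–0.058) and retains
sensitivity ≥ 0.98 at |log2FC| = 2, μ = 100, α = 0.1.  Genes are DEGs
when |log2FC| > 1 and FDR < 0.05, strict.  This test deliberately stands
in for DESeq2 (whose internals are out of scope); an installed DESeq2
port is used in one test as an independent cross-check of the
fold-change estimate only.

Integration: DAS genes are the unique genes owning ≥ 1 DAS event (events
map to genes through their locus); DE-DAS = DAS genes ∩ DEGs;
DE-DAS-TF = DE-DAS ∩ a user-supplied transcription-factor list (database
searches for TF domains are out of scope — the list is an input).

## Synthetic data

The generator emulates the study design at toy scale with known ground
truth; its defaults are the conditions the emulated study fixes or
observes:

| parameter | default | basis |
|-----------|---------|-------|
| genes × chromosomes | 50 × 2 | toy-scale census with multi-isoform loci |
| exons per gene | 3–8, 100–300 bp, introns 500–2000 bp | typical mammalian multi-exon architecture |
| reference isoforms per gene | 1–3, sharing exons | annotated-isoform diversity |
| novel isoforms | 1 per basic AS type per gene | one injected AS operation each |
| novel intergenic loci | 3, single-exon fraction 2/3 | the study found novel loci overwhelmingly single-exon; 2/3 keeps both kinds represented at n = 3 |
| fusions | 2, interchromosomal fraction 18/19 | observed fusion census (18 of 19 interchromosomal) |
| 5'-truncation probability | 0.17 | ≈ 83 % of multi-exon reads matched the annotated first splice donor |
| replicates | 3 + 3 | three animals per muscle |
| junction depth | Poisson(50) per event per sample | mid-depth short-read support |
| ΔEI on differential events | ± 0.30 on 30 % of events | detectable-effect regime used for power analysis |
| gene counts | NB(μ = 100, α = 0.1), log2FC = ± 2 on 10 % of genes | typical bulk RNA-seq moments |

Injected novel isoforms apply exactly one operation (ES, IR, AAS, ADS,
MEE) to a gene's primary isoform, re-drawing the target exon if the
resulting chain collides with an annotated isoform.  Junction counts
follow depth ~ Poisson, inclusion ~ Binomial(depth, EI) per sample, with
background Poisson coverage on all non-event introns of the emitted reads
(so the singleton junction rescue is exercised) and guaranteed-positive
support on fusion breakpoints.  IR retention evidence goes to a separate
table, as described above.  Every emitted record is labeled in
`GroundTruth`.

What the generator does **not** emulate: base-level sequence and error
profiles, alignment ambiguity, 3'-end degradation, positional coverage
bias, overdispersion of junction counts beyond binomial sampling, and
genuinely complex (multi-operation) novel isoforms.  Passing recovery
tests therefore demonstrates correctness of the annotation/statistics
logic under the stated sampling models, not robustness to alignment
artifacts in real long-read data.

## Numerical and determinism choices

- All randomness flows through `numpy` `default_rng` seeded from a single
  config seed with per-stage stream offsets; outputs are byte-identical
  across reruns, which the acceptance script verifies.
- Likelihood evaluations clamp probabilities away from 0/1
  (1e-300 / 1 − 1e-16); the LRT statistic is floored at 0.
- BH adjustment uses statsmodels `multipletests`; single-test families
  reduce to the raw p-value.
- Deterministic tie-breaks everywhere: locus ordering by (chrom, start,
  strand); collapse representatives by (spliced length, 5' completeness,
  id); best reference gene by (exonic overlap, id); MEE inclusion side by
  leftmost coordinate.
- Degenerate inputs: empty annotation files parse to empty structures
  with a warning; all-zero genes are excluded from DE; zero-evidence
  events are excluded from DAS with a reason code; complex events raise
  on quantification.

## Problem sizes

The bundled studies use 500 random loci for oracle equivalence, 2 000
events/genes for null calibration, 200 for power/recovery, and the
default 50-gene simulation (~1 000 read records) for end-to-end runs —
sizes chosen so the entire suite and the acceptance script each complete
in well under a minute while keeping Monte-Carlo bands tight.

## Known limitations

- "Overlap at the origin of alignment" is interpreted as genomic-span
  overlap against the shorter span; other readings (alignment-block
  overlap) would need the raw alignments, which the pipeline does not
  consume.
- Complex bubbles are not decomposed into basic parts; they are counted
  and reported but never quantified.
- IR quantification depends entirely on the retention-evidence input;
  exon-body read counting is out of scope.
- The DE test's common dispersion is a deliberate simplification; data
  with strongly gene-dependent dispersion would need the reported
  gene-wise estimates and an empirical-Bayes treatment.
- TF status is a list lookup, not a domain search.
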