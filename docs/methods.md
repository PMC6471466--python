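# Methods

This note documents the models, statistics and design choices behind each
stage, what the synthetic world does and does not emulate, and the known
limitations.

## Coordinates, formats, merging

All internal coordinates are 0-based half-open on the forward strand; GTF
I/O converts at the boundary (GTF is 1-based inclusive) and MAF minus-strand
rows (starts counted from the reverse-complemented sequence) are normalised
on read. Only pairwise (two-row) MAF blocks are accepted; multi-way files
are rejected loudly rather than silently subset, and overlapping source
blocks are an input error rather than being chained or netted.

Per-sample assemblies are merged on exact intron-chain identity: multi-exon
transcripts with the same ordered intron boundaries (same sequence, same
strand) collapse to one record whose terminal exons take the union span;
single-exon transcripts collapse only on exact interval identity. This is
the core rule of reference-guided assembly mergers. How conflicting intron
chains from different samples *should* be reconciled is genuinely open;
exact-chain merging is the conservative stand-in and near-identical chains
(1 bp boundary shifts) deliberately stay separate records.

## Candidate filtering

Structural rule: exon count ≥ 2 and spliced (exonic, not genomic) length
≥ 200 bp — the usual operational lncRNA definition. Filters partition their
input; every removal carries a machine-readable reason.

Coding potential is a logistic regression over four classical features of
the spliced sequence: log1p of the longest-ORF length (ATG→stop, three
forward frames only, since transcripts are stranded; an open run without a
stop codon does not count), ORF coverage (ORF nt / transcript nt), mean
per-hexamer log-odds between coding and noncoding training frequencies
(pseudocount 1), and GC fraction. Features are z-scored with the training
moments stored on the model; the model serialises to flat key-value text
with hex-encoded floats and reloads bit-exactly. The default decision
threshold is 0.5 and is configurable. This is a transparent stand-in for
dedicated random-forest classifiers (FEELnc, CPAT-style tools) — adequate
for well-separated classes (held-out accuracy ≥ 0.95 on the synthetic
training benchmark), not tuned for borderline real transcripts — and is
swappable behind `CodingPotentialModel`.

A transcript is also removed when any exon overlaps an annotated
protein-coding exon on the *same* strand; antisense overlap is retained and
classified later as genic antisense.

## Genomic-context classes

Overlap is computed against gene *spans* (min start to max end over a
gene's transcripts), not exons: genic = candidate span contained in ≥ 1
coding gene span; intergenic = zero span overlap; spanning = partial
overlap. The three classes are exhaustive and mutually exclusive, so the
tally always partitions the candidate set. A candidate overlapping two genes
plus intergenic space is simply "spanning" (no multi-label). Intergenic
subtypes use the nearest gene within a 10 kb window (a common convention for
divergent/convergent annotation): divergent = the facing ends are both 5'
ends, convergent = both 3' ends, otherwise same_strand; no gene within the
window = isolated. Nearest-gene ties break by distance then lexicographic
gene id, so output is deterministic.

## Ortholog projection

Walking alignment columns across a source exon:

* a column where the source row holds a gap is not a source position — it is
  skipped entirely;
* a column where the target row holds a gap counts as an aligned non-match;
* N on either side counts as a non-match (conservative);
* identity = matches / aligned columns; coverage = aligned columns / exon
  length.

These conventions change results and are therefore stated bit-exactly and
enforced by column-counting oracle tests. The projected target interval is
the min/max of target positions hit, on the strand implied by block
orientation composed with the exon strand.

Gene-level identity is the aligned-column-weighted mean over all exon
projections; the ortholog call requires identity ≥ 0.60 (boundary inclusive)
and coverage ≥ 0.5. The identity threshold operates at the gene level, but
per-exon identities are reported so users can re-threshold. The coverage
requirement exists because a "≥ 60% identity" call over 2% of a gene is
meaningless; 0.5 is a deliberate, configurable default. Genes whose exons
project to multiple target sequences or strands are never called orthologs
(`split_projection`). Projected exons of a transcript are reassembled in
target coordinate order into a target gene model; dropped (unprojected)
exons flag the model `partial`, and models under 200 bp are flagged but
retained.

## Coding-conservation screen

Coding sequence under purifying selection accumulates substitutions
preferentially at third codon positions (mostly synonymous); neutral
noncoding sequence accumulates them uniformly. For the gapped pairwise
alignment of a transcript against its projected ortholog (gap and N columns
excluded from numerator and denominator, which makes the statistic symmetric
in species order): for each frame f ∈ {0,1,2}, counted column k is assigned
codon position ((k − f) mod 3) + 1; with S substitution columns of which
S₃ fall at position 3, the one-sided exact binomial tail
P(X ≥ S₃ | S, p₃) with p₃ = (fraction of counted columns at position 3,
≈ 1/3) tests third-position excess. The best (smallest) of the three frame
p-values is Bonferroni-corrected ×3; corrected p < α (default 0.01) flags
the locus as coding-like. Alignments with fewer than 90 ungapped columns are
untestable and never flagged. Reverse-strand frames are not scanned
(transcripts are stranded). Measured type-I error on neutral simulations is
≈ 0.003 at α = 0.01, comfortably below 1.5α.

This test captures the signal that dedicated comparative tools (dN/dS
estimation, codon-model likelihoods) capture with more machinery; those are
intentionally out of scope for a screening step. Note the flag retains the
nominal false-positive rate of any α-level test: in the planted-world
recovery, a genuinely neutral locus is occasionally lost to the screen
(about one locus per hundred tested), which is the designed behaviour of the
screen and not an implementation defect.

## Expression and differential expression

TPM: reads per kilobase rescaled so each sample sums to 10⁶; all-zero
samples stay zero rather than NaN. "Expressed" = mean raw count over the
selected samples ≥ 20 (boundary inclusive).

The DE test is a deliberately simple negative-binomial Wald test:
median-of-ratios size factors (geometric mean over features with all
positive counts); per-feature pooled method-of-moments dispersion from
var = μ + αμ², floored at 10⁻⁸; log2 fold change of normalised group means
with pseudocount 0.5; delta-method standard error; two-sided p-value from a
Student-t reference with nA + nB − 2 degrees of freedom. The t reference is
a small-sample correction: with 4–5 replicates per group the plug-in
variance makes a normal reference anti-conservative (measured null fraction
of p < 0.05 ≈ 0.089–0.105 versus 0.044–0.050 with the t reference). There
is no dispersion shrinkage, no outlier handling and no independent
filtering — the selection logic downstream, not the DE machinery, is the
point of the package, and the DEG thresholds (linear fold change strictly
> 2, i.e. |log2FC| > 1 two-sided, and FDR strictly < 0.01 via
Benjamini–Hochberg) are what the selection consumes. Both thresholds are
configurable; "fold change" is interpreted on the linear scale.

Median-of-ratios normalisation assumes differential features are a minority
and roughly balanced in direction. When 20% of features shift one way at
dispersion 0.05, measured fold changes acquire a systematic ≈ −0.2 offset —
a property of this normaliser family, shared by the tools it emulates, and
the reason the parameter-recovery simulations (and the synthetic world)
plant balanced up/down effects.

## Selection algebra

Candidates = (DE retina-vs-RPE ∩ DE native-vs-cultured) ∪ (expressed in
both native RPE and retina ∩ not DE retina-vs-RPE ∩ DE native-vs-cultured),
with DE native-vs-cultured = union over the 4- and 8-week comparisons. The
two rules are disjoint by construction (rule 2 requires *not* DE
retina-vs-RPE), so the candidate count is always the sum of the rule counts;
provenance records the admitting rule. "Expressed at the same level" is
operationalised as expressed in both and not a DEG between them — no
equivalence band is imposed beyond the DEG rule.

The final purge removes candidates whose projected target models have any
exon overlapping any exon (UTRs included) of a target protein-coding
transcript, on either strand by default — same-locus UTR transcripts are
suspect regardless of orientation — with a sense-only mode available.
Candidates without a projected model are set aside as `unprojected`, keeping
the three-way partition exact. The conservation percentage divides the
conserved count by an explicit studied-repertoire denominator (by default
the number of genes in the count matrix; configurable, never hard-coded).

## The synthetic world

The generator plants, on one source chromosome with 0.5–1.5 kb spacers:
12 protein-coding genes (long ORFs under C/G-biased codon usage,
third-position-skewed cross-species substitutions, 90% identity); 25
conserved lncRNAs at 85% identity split into 6 retina-and-culture
responsive (rule 1), 4 stable-but-culture-responsive (rule 2), 5
target-coding-overlap traps and 10 quiet; 5 coding-derived decoys (ORF-free
sequence, substitutions concentrated at third codon positions of the
transcript frame); 8 low-identity decoys at 40%; 7 source-only loci; and 8
junk loci (single-exon or < 200 bp spliced) for the structural filter.
Substitution counts are exact (realised block identity equals the planted
value within 1%) and placement is uniform for neutral loci. Chance ORFs
longer than 30 aa in planted lncRNAs are disrupted with stop codons — the
planted noncoding class is ORF-poor by construction. Counts are drawn
NB(μ, α = 0.05) at gene level over four conditions (native RPE, 4- and
8-week culture, retina) × 4 replicates, baseline means 100–500, planted
|log2FC| = 3 with alternating sign across responsive loci (see the
normalisation note above). Alignment blocks are gap-free, colinear, and
cover exactly the loci present in both genomes.

What the world does *not* emulate — and what passing tests therefore do not
show about real data: indels and alignment error, repeats and
rearrangements, fragmented or chimeric assemblies, GC/length biases in
counting, batch effects, and borderline coding potential. The world is built
to verify the pipeline's logic under planted separation (identities 25+
points from the 60% threshold, 8-fold planted changes), not to estimate its
operating characteristics on real transcriptomes.

## Problem sizes and determinism

Default problem sizes: a ~135 kb genome pair with 65 loci, 45 counted
genes × 16 samples, 2,000-feature calibration simulations and 1,000-
alignment type-I runs; the full pipeline completes in about one second and
the complete test suite in well under a minute. Every stage is deterministic
given the config and seed: reruns produce byte-identical reports, and the
generator produces byte-identical worlds per seed.

## Known limitations

* The coding-potential stand-in is linear and four-featured; real
  borderline transcripts need a richer classifier (the model interface is
  designed to be swapped).
* Exact intron-chain merging under-merges relative to assembler-specific
  heuristics.
* The ortholog caller assumes single-coverage pairwise alignments; paralogy
  and segmental duplication are unmodelled.
* The DE test has no dispersion moderation, so power at 2–3 replicates is
  below that of shrinkage-based tools; its role here is the selection logic,
  not state-of-the-art inference.
* The codon-position screen, like any α-level screen, removes a nominal
  fraction of genuinely noncoding loci and its removals should be read as
  "coding-like at α", not as proof of coding function.
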