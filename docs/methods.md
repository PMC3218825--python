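# Methods

## Scope and design

`varimap` reimplements a single-individual resequencing analysis as five
composable stages — simulate, SNP calling, SV calling, annotation, summary
statistics — behind one deterministic pipeline. Alignment is treated as an
upstream step: the package consumes aligned read pairs (SAM, or the
simulator's native truth alignments) and never re-implements an aligner.
The simulator therefore emits *truth alignments*: each read is placed at the
reference coordinates its bases came from, and a read whose body would cross
a rearrangement breakpoint, enter novel (inserted) sequence, or contain
assembly-gap Ns is dropped as unmappable. This mirrors how a strict
short-read aligner behaves and guarantees the property the SV caller relies
on: rearrangements are visible only through span/orientation anomalies of
pairs that straddle them.

Coordinates are 0-based half-open everywhere in memory; SAM, VCF and GFF3
emission converts to the formats' 1-based conventions.

## Synthetic data: what it emulates

The generator reproduces the statistical structure the downstream methods
assume, at the study's operating point:

| parameter | default | unit | rationale |
|---|---|---|---|
| coverage λ | 11.56 | fold | the study's effective depth |
| read length | 44 | bp | the shorter of the study's two read lengths |
| insert mean μ | 200 | bp | library fragment size |
| insert sd σ | 20 | bp | 10% CV, typical for gel-sized libraries |
| base error ε | 0.01 | /base | Q20 operating point ("error rate < 1%") |
| het SNP rate | 1.18×10⁻³ | /bp | yields the observed het:hom ratio 1.18 |
| hom SNP rate | 1.0×10⁻³ | /bp | reference scale for ~2 SNPs/kb overall |
| min SNP spacing | 10 | bp | keeps the ≥5 bp spacing filter exercisable in both directions |
| deletion lengths | log-normal, median 184, truncated to [25 bp, 10 kb] | bp | matches the reported deletion-length distribution |
| SV zygosity mix | 50% het | — | polymorphic SVs are common in the population screen |

Insert sizes are Normal(μ, σ) truncated below at twice the read length
(resampled, not clipped). Sequencing errors are independent substitutions;
all bases of a run carry the single Phred value implied by ε (capped at Q40
when ε = 0). Fragments choose a haplotype uniformly, a chromosome
proportional to length and a uniform start.

What it deliberately does **not** emulate: indel sequencing errors, chimeric
fragments, GC-coverage bias, mapping ambiguity/mismapping, base-quality
variation along the read, and multi-library designs (a single library is the
default). Passing recovery tests on this generator therefore demonstrates
correctness of the calling logic under the stated noise model, not
robustness to alignment artefacts of real data — the flank copy-number
filter, for instance, is exercised on genuine sequence duplications, not on
mismapped reads.

## SNP calling

Pileups are built per reference position from all mapped read bases;
positions inside N-gap runs are excluded. The genotype posterior uses the
standard quality-aware diploid likelihood (allele mixture ½/½,
P(b|a) = 1−ε or ε/3) over the 10 unordered genotypes, with a prior given
the reference base: θ_het = 10⁻³ spread over the three heterozygotes
containing the reference allele, θ_hom = 5×10⁻⁴ over the three homozygous
alternates, θ_other = 10⁻⁵ over the remaining heterozygotes, remainder to
hom-ref. The magnitudes match an observed variant density of roughly
2/kb. The call is the posterior argmax; ties break toward genotypes
containing the reference allele, then lexicographically. Consensus quality
is −10·log₁₀(1−posterior), rounded and capped at 99 (a finite cap avoids
infinite Phred at numerically-1 posteriors).

Two implementations coexist deliberately: a per-column caller that accepts
arbitrary per-base qualities, and a vectorised whole-genome path for the
uniform-quality case (a likelihood matrix–count matrix product). The test
suite asserts their exact agreement column-by-column, and checks the
per-column caller against an independent linear-space enumeration oracle.

The filter cascade applies, in order, with the first failing filter
recorded per candidate: consensus quality ≥ 20; flank copy number < 2
(strict); depth ≤ 100; ≥ 4 reads per required allele (both alleles of a
het, the alternate of a hom); spacing ≥ 5 bp between consecutive candidates
on a chromosome, measured on the candidate stream, with **both** members of
a violating pair removed (the conservative reading of a minimum-distance
rule). Spacing at exactly 5 bp passes. The flank copy-number estimator —
unspecified in the original beyond the quantity's name — is the mean
genome-wide occurrence count of the 17-mers overlapping a ±25 bp flank,
counted on the reference; unique sequence scores 1.0, an exact two-copy
repeat 2.0, and an all-N flank is undefined and fails the filter by
convention.

Recovery accounting: the consensus caller's recovery is measured at the
genotype level (argmax equals the implanted genotype), because the
≥4-reads-per-allele filter makes full-cascade recovery of heterozygotes at
depth 8 mathematically impossible in 73% of cases (a depth-8 het passes
only on a 4/4 allele split, P ≈ 0.27 under binomial sampling). The cascade
intentionally trades sensitivity for a false-support probability below
10⁻³; its semantics are tested separately, filter by filter.

Sex chromosomes are included in calling but excludable from density
reporting (they sit at half coverage in a male genome).

## SV calling

Insert statistics are estimated from orientation-normal (FR, same
chromosome) pairs *before* any span classification — using spans to select
pairs first would bias σ down — with 1% two-sided trimming to absorb
SV-straddling contamination. Degenerate estimates (σ = 0, or fewer than 100
usable pairs) raise an error instructing the caller to supply μ, σ.

The pair-signature table: FR within μ±3σ → normal; FR beyond → deletion- or
insertion-type; FF/RR → inversion; RF (everted) → tandem duplication;
inter-chromosomal → translocation. Clustering is a single left-to-right
sweep per (class, chromosome pair): a pair joins the open cluster while its
left-anchor start is within `max_sep` (default μ+3σ) of the previous
member's and its right anchor, extended by `max_sep`, still intersects the
running intersection of the members' extended right anchors — the running
intersection is what keeps a cluster's members mutually compatible with a
single event and rejects ambient long-span pairs near a real deletion.
Support counts **pairs** (the stricter reading of a four-read minimum);
clusters under 4 pairs are dropped.

Deletion length = mean(member spans) − μ. This estimator is biased upward
by fragment-length size-biasing: a fragment of length L straddles a
breakpoint in proportion to L − 2·read_len + 1, so
E[insert | straddle] ≈ μ + σ²/(μ − 2r) (≈ +3.5 bp at the defaults); near
the 3σ resolution floor, span-threshold selection adds more. The additive
correction is fitted as the mean of (predicted − true) on simulation truth
(slope fixed at 1) and exposed as configuration; the acceptance test fits
it on one simulation and verifies on an independent one that the corrected
residual mean is within twice its standard error (the SE combines the
evaluation scatter and the correction's own estimation error). Deletions
shorter than 3σ are correctly not callable by the span rule; insertions are
detectable only up to μ − 2·read_len by construction.

Breakpoint intervals are [max end of left anchors, min start of right
anchors], clamped to ≥1 bp. Calls whose breakpoint or anchor span overlaps
a gap run are flagged `gap_masked` and excluded from default output; calls
with mutually overlapping breakpoint intervals are flagged `complex`.

## Annotation

Element classification uses the midpoint of an interval with precedence
CDS > UTR > intron > intergenic, over the longest (frame-valid) transcript
of every gene — midpoint classification is deterministic and order-free for
deletions spanning boundaries; an any-overlap mode would double-count.
Transcripts whose CDS length is not a multiple of 3 are excluded with a
warning. Coding consequences are computed on the spliced CDS
(reverse-complemented for minus-strand transcripts) by codon substitution
under the standard genetic code; the suite checks 500 random substitutions
against a whole-CDS translation diff. Heterozygous SNPs are annotated once
per alternate allele.

Reciprocal best hits reduce each hit table to the best row per
(query, subject), take the unique best subject per query by bitscore (ties
resolved by lower e-value, then lexicographic subject id, and flagged) and
emit (a, b) only when the relation holds in both directions. BLASTP/MUSCLE
execution is out of scope — their tabular outputs are inputs. Domain
intersection maps a nonsynonymous SNP to amino-acid position
⌊cds_offset/3⌋+1 and reports every (protein, domain) interval containing it
(1-based inclusive).

The Monte-Carlo bias test draws its expected category proportions from one
structured draw of `n_per_chrom` gap-avoiding random positions per
chromosome, merges categories with expected count < 5 into "other",
computes the chi-squared statistic Σ(obs−exp)²/exp, and builds the null
from `replicates` re-draws of |observed| positions (chromosome chosen
proportional to length); p = (1 + #{null ≥ observed}) / (replicates + 1),
which cannot report zero. A 2000-run audit in development showed the
p-value is uniform under the null (rejection rate 0.0455 at α = 0.05). The
chromosome count always follows the supplied reference. Bootstrap support
for hierarchical clustering is the ordinary (Felsenstein) proportion of
locus-resampled replicates containing the same sample clade, under
average-linkage agglomeration of the allele-sharing dissimilarity
(mean |dosage difference|/2); samples are sorted by id first so the result
is input-order invariant. Approximately-unbiased multiscale bootstrap
values are a possible extension, not implemented.

## Numerical and reproducibility choices

- One global seed; every stage and every randomised test derives an
  independent substream via SHA-256 of `(seed, tag)`, kept below 2³¹.
- Identical configuration + seed ⇒ byte-identical pipeline artifacts
  (checksummed manifest).
- Log-space likelihoods with `logsumexp`; posteriors clipped at 1−10⁻¹²
  before Phred conversion.
- Ratios in the summary report are computed on demand from their integer
  fields, never stored, and rounded only at display.
- Zero denominators yield `None` ("undefined"), never 0.

## Problem sizes in the test suite

The recovery tests run at the study's operating point on desk-scale
genomes chosen to keep the full suite under a minute of simulation time
per module: 1 Mb for SNP recovery (≈1,900 implanted SNPs, ≈131k read
pairs), two 2 Mb genomes with 50–60 implanted deletions for SV recovery
and bias correction, a 4 × 150 kb genome with ~120 gene models for
annotation and the 400-run calibration of the Monte-Carlo test, and
10 samples × 100 loci for clustering. Genome-scale discovery counts from
the original study are not reproducible at these sizes and are not
targeted; the printed summary ratios are instead recomputed exactly from
the printed counts.

## Known limitations

- No indel genotyping from pileups; single-base substitutions only.
- SV genotyping (het/hom from read depth) is not attempted; simulated
  heterozygous SVs are still detected (half the pairs are informative) but
  not labelled by zygosity.
- The quality model is flat per run; base-quality recalibration and
  per-cycle error profiles are out of scope.
- The copy-number filter counts reference k-mers only; it cannot see
  donor-specific duplications.
- Translocation and duplication calls receive no length estimate.
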