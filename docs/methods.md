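# Methods

This note records the models, rules and numerical choices behind each
stage, what the synthetic generators do and do not emulate, and the
design decisions taken where the underlying conventions were genuinely
open.

## Gene model and expression normalization

A gene's length `L` is the size in bases of the union of its exon
intervals (overlaps merged, strand ignored), computed from GTF `gene` /
`exon` features on 1-based inclusive coordinates. The union definition is
our choice — an exon-level read-counting denominator matches a merged
exon union better than any single transcript — and is recorded as such,
not asserted as the only convention in use. Genes whose exons span
multiple chromosomes are rejected rather than silently split.

FPKM and FPKM-UQ use the sum of counts over *protein-coding* genes (not
all genes) as the library denominator. For FPKM-UQ, `RC_g75` is the 75th
percentile — linear interpolation, numpy's default — of the sample's
protein-coding counts **excluding zero counts**; whether zeros belong in
the base set is ambiguous, so `include_zeros=True` exposes the
alternative. Both statistics are invariant under uniform scaling of a
sample's counts, which the tests exploit as a free oracle.

Quartile groups Q1–Q4 cut the per-feature mean expression at its
25/50/75 percentiles; a mean exactly on a cut goes to the *lower* group,
making the assignment deterministic (all-equal means collapse to Q1).
Spearman correlations use average ranks for ties (scipy); pairs with
fewer than two observations or zero variance are reported as NaN rather
than dropped, so the caller can see them.

miRNA normalization is reads-per-million. Mature miRNAs have
near-constant length, so a per-kilobase correction would only rescale
every value by a near-common factor; the unit label is carried in
`DataFrame.attrs` and configurable where written out.

## Somatic variants

Multi-allelic VCF records are split into one call per alt allele before
any filtering. The only *removing* filter is the SomaticSniper somatic
score: calls with `SSC < 25` (strictly) are dropped; everything else is
*tagged* in a separate `GDC_FILTER`-style label set so downstream users
can make their own trade-offs. Panel-of-normals tagging is an exact
(chrom, pos, alt) membership test. Strand-bias tagging runs a two-sided
Fisher exact test on the 2×2 table (ref fwd, ref rev) × (alt fwd,
alt rev); p < alpha (default 0.05) adds the label, and all-zero tables
are logged and never tagged.

Matching modes: *strict* equality of (chromosome, position, alt allele);
*loose* overlap of the reference spans `[pos, pos + len(ref) − 1]` on
the same chromosome, insertions occupying their anchor base. Loose
matching tolerates indels that point-mutation-only callers represent as
SNVs at a shifted position. Loose matching is not transitive, so
concordance counting matches each union variant against each caller set
independently, without clustering.

The MAF table is a minimal, analysis-oriented subset of the full
aggregated mutation format (chrom, start, end, ref, alt, class, caller,
filter columns); variant class is SNP when both alleles are single
bases, INS/DEL by length difference. The open-access tier applies
germline-masking rules that are **deliberately labelled
non-authoritative**: production criteria for open release are not
public, so the defaults here — drop non-PASS rows, drop any tagged row,
drop rows with ≥ 2 alt reads or ≥ 2% VAF in the matched normal — are a
stringent, configurable stand-in. The open table is always a subset of
the controlled table, and each removal is attributed to a rule in the
log. Stringency costs sensitivity: true somatic variants over
low-coverage normals will be masked.

Recall analysis reports, per caller and per caller *combination* (union
over subsets), the fraction of validated truth variants recovered, plus
the distribution of truth variants by the number of callers recalling
them including the zero bin. Samples with empty truth sets are excluded
and logged. Union recall is monotone non-decreasing in the combination
size, which the tests assert.

## Copy-number segmentation

CBS here is the classical recursive formulation: for a chromosome's
probe vector, compute the t-like statistic
`|mean(arc) − mean(complement)| / sqrt(s² (1/k + 1/(n−k)))` over all
circular arcs `(i, j]` with both sides at least `min_width` probes, take
the maximum, and accept the split if the permutation p-value is below
`alpha`. Accepted arcs contribute their interior boundaries as
changepoints and the algorithm recurses on each piece. Defaults:
`alpha = 0.01`, 1000 permutations, `min_width = 2`, no undo-splits pass
— the common defaults of the reference R implementation of CBS.
Numerical details: the overall segment variance `s²` is constant across
arcs and under permutation, so it affects neither the argmax nor the
test decision; a segment with (near-)zero variance never splits, which
guarantees exactly one segment on constant input for any seed. The
permutation loop stops early once the exceedance count already exceeds
`floor(alpha·(B+1))`, at which point significance is impossible — the
decision is identical to full enumeration. Segment means are the
arithmetic means of member probes, so segments exactly reconstruct the
probe-level averages.

Segment means are reported on the `log2(copy-number/2)` scale. Probe
masking: the regular output removes pseudo-autosomal-region probes in
males only (X/Y homology would double-count them); the masked output
additionally removes all chrY probes and a supplied germline-CNV probe
exclusion list. Gene-level values are overlap-weighted averages of
segment means over the gene's full genomic extent — segment overlap is a
genomic-interval notion, so the exon union is deliberately *not* used
here. Genes overlapping no segment are NaN and logged.

## Methylation

Beta values are `M/(M+U)`, in [0, 1], missing where `M + U = 0`;
negative intensities are an error. Probe masking after re-mapping:
Type II probes need mapping quality ≥ 10; Type I probes additionally
require both bead probes on the same locus and both above the quality
bar. Masked probes get chrom `*`, pos −1; the filter is idempotent.
Annotation reports all overlapping transcripts (semicolon-joined, with
signed distances, 0 when overlapping) and both the overlapping and the
nearest CpG island — "associated island" is ambiguous between the two
readings, so both columns are emitted. Distance sign convention:
negative upstream of the feature start on the feature's strand (islands
are unstranded and use the + convention); nearest-island ties break
toward the lower-coordinate island.

## Multi-omic integration

Per-type preprocessing: count features are dropped when ≥ 99% of samples
have ≤ 1 count; methylation probes are dropped when missing in > 5% of
samples (strictly), remaining gaps imputed with the probe mean, then a
seeded random 25% of probes retained to cut dimensionality. All filters
are idempotent. PCA runs per type on centered, unscaled values (betas
and log-ratio CNV are already bounded; scaling would distort the count
PCs relative to them), samples as observations, components capped at
`min(features, samples − 1)` with numerically-zero components dropped.

The pooled components are re-ranked by **per-type fraction of variance
explained** — absolute variances are incomparable across data types with
different units — with absolute-variance ranking available as a config
switch. The top 200 survive, and only then are the surviving score
columns multiplied by their type weight (default 3 : 3 : 1 : 1 for
mRNA : methylation : miRNA : CNV; weighting after selection follows the
pipeline's stated order, the alternative is a switch). miRNA and CNV get
lower weight because they separate tumor types less sharply. t-SNE
(perplexity 30, capped below the sample count; random initialization) is
run N times with consecutive seeds and the embedding with the lowest
final KL divergence wins; production-scale use runs 1000 restarts, the
CLI default is 50, and tests use 3–10, which is already enough for a
well-separated cohort.

## Synthetic generators

All generators are pure functions of a `SimConfig`; named sub-streams
are derived deterministically from the one seed, so identical configs
give identical outputs. They emulate the *statistical* structure each
stage consumes and nothing below it:

- **Caller calls**: a shared truth set of random SNVs/indels (10%
  indels) on a toy 22-contig genome; each caller emits each truth
  variant independently with its sensitivity — defaults (0.9, 0.8, 0.7,
  0.6) across the four callers — plus false positives at 2% of the truth
  size. Real callers err neither independently nor uniformly, so
  concordance fractions here characterize the generator, not any real
  cohort.
- **Counts**: negative-binomial with log-normal per-feature means and
  dispersion 0.2 (a typical bulk RNA-seq value); group structure
  multiplies a seeded feature subset's mean in one group.
- **Copy number**: piecewise-constant means with Gaussian noise
  (default one step of 1.0 at probe 50 of 100, sd 0.1 — a strong,
  desk-checkable breakpoint).
- **Cohort**: three projects with project-level shifts in all four data
  types; methylation gets ~2% scattered missingness plus a 5% subset of
  probes pushed above the 5% missingness threshold so the filter has
  work to do.

Passing tests therefore demonstrate correctness of the computations and
recovery of planted structure; they do not certify performance on real
tumor data, where caller errors correlate, copy-number noise is heavy-
tailed, and batch effects exist (no batch correction is attempted
anywhere in this toolkit, matching its production counterpart).

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 50×10
normalization oracles, 10,000 random variant pairs, a 5,000-variant
truth set, 200 CBS replicates of 100 probes, and a 90-sample three-
project cohort with best-of-10 t-SNE — sizes chosen so the planted
effects are overwhelmingly detectable (binomial/permutation error well
inside the asserted bounds) while a full run stays in the low minutes.
Every stochastic step is seeded; CLI runs derive all per-stage streams
from a single `--seed`, and re-runs produce byte-identical outputs.

## Known limitations

Alignment, read counting, the four callers' internals, tangent
normalization, probe re-alignment and variant-effect annotation are out
of scope: their outputs are this toolkit's inputs. The germline-masking
defaults are a labelled stand-in, not the production criteria. CBS here
has no undo-splits pass and no hybrid tail approximation, so very long
probe series pay the full permutation cost. Loose matching is pairwise
and non-transitive by design; consumers needing an equivalence relation
must cluster on top of it.
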