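# Methods

This note documents the models and procedures implemented in `scaprna`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions made where
the design was genuinely open.

## Coordinates and data model

All genomic coordinates are 0-based half-open in memory and BED-style on
disk. The 5′ position of a minus-strand feature is `end − 1`, so single-base
5′-end observations are symmetric between strands. Tag observations are TSV
records (`sample assay chrom strand pos5 count multimapped [first_base]`);
paired 5′/3′ fragments additionally carry their transcript-space size.
Unknown chromosome names are tolerated (and logged); bounds are checked only
when a genome sequence is available.

## Semi-global alignment and the classification cascade

Reads are annotated against ordered reference RNA sets with a semi-global
("glocal") variant of Needleman–Wunsch: the full query aligns against a
substring of the target; gaps before or after the query (target overhangs)
cost nothing, every other gap and mismatch costs −1, matches score +1.
Non-ACGT symbols never match anything — including another copy of the same
ambiguity code — which is the conservative choice for IUPAC codes in
references.

The dynamic program carries, per cell, the best score together with the
largest achievable alignment start on the target (encoded in one integer per
cell so the whole row updates vectorise). For each end point the largest
start yields the smallest extent; the final answer maximises score, then
minimises extent, then start. Degenerate zero-extent optima (query aligned
entirely against gaps) are reported only when no positive-extent alignment
achieves the same score.

An alignment passes when `score ≥ 0.8 × query length` — the comparison is
inclusive, i.e. "strictly less" is discarded — and the cascade assigns the
first reference set containing a passing alignment; within a set ties break
to highest score, shortest target, smallest extent, smallest target start.
The separate genome/transcript mapping step uses the same aligner with a 0.9
floor; at the toy scales this package targets, one aligner serves both roles.
Remaining reads receive priority-ordered genomic categories (short-RNA
precursor windows first, then enhancer-type regions, then sense and
antisense gene overlap, falling back to `other_intergenic`), evaluated
first-overlap-wins and strand-aware only for the two gene categories.
Downstream stages exclude multimapping reads and reads classed to known
short-RNA families or their ±500 bp precursor windows.

The unencoded-G profile reports, per assay, the fraction of reads whose
sequenced first base is a G that mismatches the (strand-adjusted) genome
base at the mapped 5′ position — the signature of the cap-derived
guanosine added during template switching.

## Density clustering of initiation peaks

Tag 5′ positions, pooled over samples (and assays, when a combined peak set
is wanted), are clustered per chromosome and strand with a hierarchical
density formulation. The density of a run of sites is its total tag count
divided by its genomic span (`last − first + 1` bp). A segment is *valid at
density d* when every prefix and every suffix delimited by sites — the whole
segment included — has density ≥ d; single-site segments are unconditionally
valid. For a given d, the cluster set is obtained by splitting the full site
range at its weakest internal boundary until every segment is valid; a
cluster is a segment that appears this way for some d ≥ 0 and is reported
with the density interval `(d_min, d_max]` over which it persists (`+∞` for
single sites). The implementation computes the full hierarchy in one
recursion; the test suite checks it against an independent per-density
re-evaluation on random instances. A practical note: the common
gap-denominator density variant produces slightly different `d_max` values;
the inclusive-span convention used here is fixed by the package's own
documented examples and is applied consistently.

Peaks are clusters with ≥ 10 tags (the only filter applied by default;
maximum-length and density-stability filters exist but are off unless
configured). Nested retained clusters resolve to the largest non-nested set
by keeping, within any chain, the innermost (highest `d_min`) cluster — the
densest reading of "peak"; the outermost representative is available by
configuration. A peak's mode is its highest-count position (ties to the
5′-most); a peak is sense-associated with a gene when its mode falls within
±500 bp of a same-strand transcript TSS (nearest TSS wins). The 500 bp
promoter half-width is the same TSS-proximal constant used by the exclusion
masks, the only promoter-scale constant in the analysis.

## Short/long enrichment model

Counts per peak and library column follow a negative binomial with
variance μ + αμ². Size factors are median-of-ratios over rows with positive
geometric mean, then rescaled by their median. Dispersion is estimated per
assay by the per-row method of moments, `max(0, (var − mean)/mean²)` on
normalised counts, aggregated by the **mean** over rows and then averaged
between assays. The mean aggregate was chosen over the median because, at
three replicates, the sampling distribution of the row-wise estimate is
strongly right-skewed: its median sits near 0.65× the true dispersion,
which in turn inflates the Wald test's type-I rate to ~0.09 at nominal
0.05, while the mean aggregate is approximately unbiased (the `max(0,·)`
truncation adds a slight upward, i.e. conservative, bias). Both aggregates
are available.

Each peak is tested with a Wald test on the assay coefficient of the NB
log-linear model `log μ = log s_j + β₀ + β₁·[assay = short]`, fitted by
Fisher scoring vectorised across peaks with the plug-in dispersion, followed
by Benjamini–Hochberg adjustment; a peak is short- or long-enriched by the
sign of β₁ when the adjusted p < 0.05. Log ratios of normalised means use a
pseudocount of 0.5 so zero cells stay finite; all-zero peaks are flagged and
reported as non-significant with ratio 0. Columns with an all-zero assay
drive β₁ toward infinity with an exploding standard error, so their Wald
statistic degrades toward 0 rather than producing spurious significance.
"Expressed" (the Venn outer circles) means ≥ 1 retained tag pooled over the
assay's libraries — the weakest consistent threshold, exposed as a
parameter.

The variance-stabilising transform defaults to
`x → (2·arcsinh(√(ax)) − ln a − ln 4)/ln 2`, whose large-x asymptote is
log2(x), making downstream differences interpretable as log2 fold changes;
the variant without the square root (asymptote 2·log2 x) is provided as an
option because both forms circulate for this transform family. At x = 0
either variant equals −2 − log2(a). Per-timepoint values are VST means over
replicates, centred by their across-timepoint average; the time-course
filter keeps a peak when a classical one-way ANOVA reaches p < 0.05 in
either assay, with the conventions p = 0 for separated constant groups and
p = 1 for all-identical values.

## Splice-site termination

The background size distribution is built from paired fragments aligning to
mRNA/lncRNA transcripts, excluding alignments extending over strictly more
than 90% of the transcript's spliced length. For each gene, `n` counts
fragments aligned (in transcript space) to its transcripts and `k` those
whose 3′ end equals the last base of a non-terminal exon (tolerance 0 by
default — the observed offset distribution is sharply peaked at 0 —
configurable, with acceptor sites optional). The per-gene background
probability anchors each fragment's 5′ end and sums the size mass landing
exactly on a splice site within the transcript (`a + s − 1`, off-transcript
landings contribute zero rather than renormalising), averaged over
fragments. Significance is the one-sided upper-tail binomial
`P(X ≥ k | n, p₀)`; per-gene calls use raw p < 0.05 without multiplicity
adjustment, and a global statistic combines genes by Fisher's method with
underflow reported in log space. A fragment matching several transcripts of
one gene counts once, credited to a transcript on which it terminates at a
splice site when one exists. Because the binomial test is discrete, its
null p-values are super-uniform; calibration tests therefore use the
standard randomized p-value `P(X > k) + U·P(X = k)`, which is exactly
uniform under the null, while reported p-values remain the conservative
tail probability.

## Enhancer prediction

The exclusion mask merges all exons with TSS ± 500 bp windows of every
transcript except snRNA, scRNA and snoRNA genes. Tags surviving the
categorization exclusions are pre-clustered per strand with the same density
clusterer (≥ 5 tags per cluster); a candidate locus is a divergent pair —
reverse-strand cluster left of a forward-strand cluster — whose inner edges
lie ≤ 400 bp apart, centred at the midpoint of those edges. Forward tags
within +200 bp and reverse tags within −200 bp of the center give F and R;
a locus is reported when F + R ≥ 5, directionality |F − R|/(F + R) < 0.8,
and its ±200 bp window does not intersect the mask. Overlapping loci merge
keeping the most balanced. The defaults (pair window 400, flank 200,
directionality < 0.8, ≥ 5 tags) follow the published balanced-bidirectional
enhancer-calling description and are all configurable. Enhancer sets from
different assays merge transitively at ≥ 1 bp overlap with provenance
labels; per-enhancer expression counts tags on either strand, feeding the
same NB enrichment test and Venn classification as promoters. Saturation
curves thin tag counts binomially per fraction and re-run the caller;
fraction 1.0 bypasses resampling so it reproduces the full-data count
exactly.

## Association statistics

Mark signal is the length-weighted mean of a bedGraph track over a ±5000 bp
window around the enhancer center (absent positions count 0; windows are
clipped at chromosome bounds with a log message). The proportionality
constant between the two marks is a through-origin least-squares slope
(`Σxy/Σx²`, residual-based standard error on n−1 degrees of freedom) — the
literal reading of a "constant of proportionality" — with a with-intercept
variant available. The class comparison uses
`Z = (b₁ − b₂)/√((sd₁² + sd₂²)/2)` — the root-mean-square denominator as
specified, which calibration tests document to be anti-conservative by √2
relative to the conventional `√(sd₁² + sd₂²)` variant that is also
provided. GWAS enrichment counts SNP loci (single dbSNP-style positions, no
LD clumping) inside a region set, takes the genome-wide GWAS fraction of
the same table as background, and reports the enrichment factor with a
binomial upper-tail p-value and a binomial-proportion standard deviation.

## Synthetic-data generator

The generator lays out one or more chromosomes (default 2 × 300 kb) of
uniform random sequence, places intron-containing gene models (default 60
genes, 2–5 exons of 80–300 bp, introns 150–800 bp, 20% lncRNA) and
single-exon short-RNA genes left to right with random intergenic gaps, and
places enhancer loci in intergenic space ≥ 1 kb from every TSS and ≥ 300 bp
from every exon; infeasible packing raises an explicit capacity error. The
±2 nt initiator region of each gene is forced to non-G transcribed bases so
unencoded cap guanosines are identifiable; the generator adds a cap-derived
G to a read's first base with probability 0.25 by default.

Promoter tag counts per (sample, assay) column are NB(s_j·λ·π, α) with
λ = 80 tags per peak, α = 0.1, and a lognormal per-column depth s_j
(sd 0.2); π is the assay's share of the gene's composition class (default
20% short-only, 30% long-only, the rest balanced at π = 0.5). Tag positions
spread over ±2 nt around the TSS with a fixed profile; 2% of tags are
flagged multimapped. Paired fragments anchor within 5 nt of the TSS, draw
sizes from a bimodal background table over 72–272 nt (echoing the
protocol's size-selection window, with modes near the two abundant small-RNA
size classes; fully overridable), and snap their 3′ end to the nearest
downstream splice site with probability θ (default 0.5); intronless genes
get θ = 0 by construction. Enhancers emit divergent tags at ±100 bp from
their center with per-strand rates split by directionality δ (default 0,
i.e. balanced). ChIP tracks assign each enhancer a lognormal
H3K4me3-like level over its ±5 kb window and an H3K4me1-like level
β·level + Gaussian noise (β 3.0 / 1.5 for short-/long-enriched classes,
clipped at zero), overlaps summing; SNPs are uniform over the genome with
GWAS-flag probability multiplied by γ (default 2) inside enhancer windows.
Randomness is one global stream per seed, forked per sample by a stable
hash of the sample id, so adding samples leaves existing ones unchanged and
identical seeds give byte-identical outputs.

What the generator does **not** emulate: sequencing errors and quality
scores, PCR duplicates, mappability structure (multimapping is an i.i.d.
flag), realistic promoter shapes and expression distributions across genes,
intron signal, or correlated replicate structure beyond the NB dispersion.
Passing recovery tests therefore demonstrates the correctness and
calibration of the estimators under the assumed generative model, not
robustness to every artefact of real libraries.

## Problem sizes and calibration conventions

The test suite and the acceptance script run on desk-scale problems chosen
to make sampling error small relative to the tested tolerances: 2 000 peaks
for test calibration and power, 1 000–2 000 genes × 20 fragments for
termination calibration, 30–60 enhancers for recovery, and SNP tables sized
so that roughly 10⁴ SNP loci fall inside the scored regions — with the
background taken from the same table, the region set must stay a small
fraction of the genome (here ~5%) or the background becomes contaminated
and the expected factor shrinks toward γ/(1 + f(γ − 1)); both effects are
documented in the tests. The mark-proportionality analyses space enhancers
≥ 12 kb apart so neighbouring ±5 kb windows do not blend the per-class
slopes.

## Known limitations

- The aligner is quadratic per query/target pair and intended for reads and
  reference sets of small-RNA scale, not genome-wide mapping.
- The NB Wald test uses a single plug-in dispersion shared across peaks; no
  shrinkage toward a mean–dispersion trend, no outlier handling, and no
  independent filtering are performed.
- Per-gene termination significance deliberately uses unadjusted p-values;
  the gene-level discovery list is therefore a screening set, with
  significance controlled only at the single-gene level.
- Enhancer calling reports point loci from single divergent pairs; complex
  multi-cluster architectures resolve through the merge step rather than a
  joint model.
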