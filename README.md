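# scaprna

Comparative analysis of **short** and **long 5′-capped RNA** tag data.

RNA polymerase II products carry a 5′ cap: long transcripts (mRNAs, lncRNAs)
are routinely profiled by CAGE-style 5′-end sequencing, while short capped
RNAs — spliceosomal RNAs, snoRNAs, enhancer RNAs, and truncated
gene-associated transcripts of roughly 72–272 nt — are largely missed by
protocols that select for longer products. `scaprna` implements the
computational side of a paired short/long capped RNA experiment as a tested,
reusable pipeline:

- **RNA-class categorization** — a semi-global (free target end-gap)
  Needleman–Wunsch aligner (match +1, mismatch −1, gap −1, end gaps on the
  target free) applied in an ordered cascade of reference RNA sets
  (mitochondrial genome, rRNA, tRNA, snRNA, …). An alignment is kept when its
  score is at least 0.8× the query length; ties resolve to the highest score,
  then the shortest target, then the smallest target extent. The first set
  with a passing alignment wins, and priority-ordered genomic region
  categories handle the remainder.
- **Transcription-initiation peak clustering** — hierarchical density
  clustering of pooled 5′-end tag positions (clusters are segments maximal
  over a range of density thresholds, reported with their `[d_min, d_max)`
  range), followed by a ≥10-tag filter and nested-cluster resolution.
- **Short/long enrichment** — median-of-ratios size factors, method-of-moments
  NB dispersion (variance = μ + αμ²), a per-peak Wald test on the assay
  coefficient of an NB log-linear model with Benjamini–Hochberg adjustment,
  Venn classification of expressed peaks, the variance-stabilising transform
  x → (2·arcsinh(√(ax)) − ln a − ln 4)/ln 2, per-timepoint fold changes and a
  one-way ANOVA time-course filter.
- **Splice-site termination statistic** — for each gene, the number of paired
  5′/3′ fragments whose 3′ end coincides with an exon 3′ boundary is compared
  with a background probability obtained by anchoring each fragment's 5′ end
  and resampling its size from the background size distribution
  (near-full-length alignments excluded); significance by one-sided binomial
  test, combined across genes with Fisher's method.
- **Bidirectional enhancer prediction** — divergent pairs of strand-specific
  tag clusters outside an exclusion mask (exons plus TSS ± 500 bp windows,
  snRNA/scRNA/snoRNA exempted) with directionality |F−R|/(F+R) below 0.8,
  set merging with provenance, per-enhancer expression, and down-sampling
  saturation curves.
- **Association statistics** — ±5 kb ChIP-mark window means, per-class
  proportionality slopes with a Z-test on their difference, GWAS-SNP overlap
  enrichment with a binomial test, Fisher-exact and Mann–Whitney helpers.
- **Synthetic data** — a first-class generator that emulates the study design
  (multi-sample two-assay NB tag counts with controllable short:long
  composition, paired fragments with termination rate θ, divergent enhancer
  transcription, proportional ChIP marks, GWAS-enriched SNPs) with full
  ground truth, so every stage is testable without downloads.

## Worked example

```python
from scaprna.simulate import SimulationParams
from scaprna.pipeline import run_end_to_end

metrics = run_end_to_end(SimulationParams(seed=1))
print(metrics["peak_fractions"])         # detected gene-peak composition
print(metrics["peak_truth_fractions"])   # simulated truth
print(round(metrics["gwas_enrichment_factor"], 2))
```

prints

```
{'both': 0.5333333333333333, 'short_only': 0.16666666666666666, 'long_only': 0.3}
{'both': 0.5333333333333333, 'short_only': 0.16666666666666666, 'long_only': 0.3}
1.95
```

i.e. the pipeline recovers, per gene-associated peak, whether the promoter
emits both short and long capped RNAs or only one of the two (here exactly
matching the simulated truth), and recovers the simulated two-fold GWAS-SNP
enrichment inside enhancers up to binomial noise.

The same stages are available from the shell:

```bash
scaprna simulate --seed 1 --out data/
scaprna peaks --tags data/tags.tsv --out peaks/
scaprna enrich --counts peaks/counts.tsv --out enrich/
scaprna spliceterm --fragments data/fragments.tsv \
    --transcripts data/transcripts.bed12 --out spliceterm/
scaprna enhancers --tags data/tags.tsv \
    --transcripts data/transcripts.bed12 --out enhancers/
```

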