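"""End-to-end orchestration: simulate -> categorize -> peaks -> enrichment ->
splice termination -> enhancers -> association statistics.

Used by the command-line interface and by parameter-recovery checks; each
stage is the public function of its module, so the pipeline is also a usage
example of the library API.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import assoc as assoc_mod
from .categorize import EXCLUDED_CLASSES
from .core import CappedTag, GenomicInterval, IntervalLookup
from .enhancers import (
    build_exclusion_mask,
    call_bidirectional,
    enhancer_expression,
    merge_enhancer_sets,
)
from .enrichment import (
    mean_assay_dispersion,
    nb_enrichment_test,
    size_factors,
    venn_classify,
)
from .peaks import assign_peaks_to_genes, build_count_matrix, cluster_tags, filter_peaks
from .simulate import (
    Annotation,
    GroundTruth,
    SimulationParams,
    generate_genome_and_annotation,
    simulate_chip_and_snps,
    simulate_tags,
)
from .spliceterm import gene_termination_analysis


def exclude_known_short_rna_tags(
    tags: list[CappedTag],
    annotation: Annotation,
    precursor_halfwidth: int = 500,
) -> list[CappedTag]:
    """Drop multimapped tags and tags over known short-RNA genes or their
    precursor windows (the downstream-exclusion rule)."""
    windows = [
        GenomicInterval(iv.chrom, max(0, iv.start - precursor_halfwidth),
                        iv.end + precursor_halfwidth, ".")
        for iv in annotation.short_rna_loci
    ]
    lookup = IntervalLookup(windows) if windows else None
    out = []
    for t in tags:
        if t.multimapped:
            continue
        if lookup is not None and lookup.contains(t.chrom, t.pos5):
            continue
        out.append(t)
    return out


def run_end_to_end(params: SimulationParams) -> dict:
    """Full pipeline on one simulated dataset; returns recovery metrics."""
    annotation = generate_genome_and_annotation(params)
    tags, fragments, truth = simulate_tags(params, annotation)
    retained = exclude_known_short_rna_tags(tags, annotation)

    genes = [t for t in annotation.transcripts if t.biotype in ("mRNA", "lncRNA")]

    # --- peaks and short/long enrichment over gene promoters -------------
    peaks = filter_peaks(cluster_tags(retained, assays={"short", "long"}),
                         min_tags=10)
    counts, dropped = build_count_matrix(peaks, retained)
    associations, offset_hist = assign_peaks_to_genes(peaks, genes, retained)
    gene_peak_rows = {
        a.peak_id: a.gene_id for a in associations if a.gene_id is not None
    }
    gene_counts = counts.loc[[pid for pid in counts.index if pid in gene_peak_rows]]

    s = size_factors(gene_counts.to_numpy())
    alpha_hat = mean_assay_dispersion(gene_counts, s)
    results = nb_enrichment_test(gene_counts, s, alpha_hat)
    venn = venn_classify(results)
    total = max(venn["total_expressed"], 1)
    peak_fractions = {
        "both": venn["both"] / total,
        "short_only": venn["short_only"] / total,
        "long_only": venn["long_only"] / total,
    }

    truth_classes = [truth.peak_classes[g] for g in
                     (gene_peak_rows[pid] for pid in gene_counts.index)]
    n_truth = max(len(truth_classes), 1)
    truth_fractions = {
        cls: sum(c == cls for c in truth_classes) / n_truth
        for cls in ("both", "short_only", "long_only")
    }

    # --- splice-site termination -----------------------------------------
    term_results, combined = gene_termination_analysis(fragments, genes)
    spliced = [r for r in term_results
               if any(t.gene_id == r.gene_id and t.n_introns > 0 for t in genes)]
    frac_sig = (
        sum(r.pval < 0.05 for r in spliced) / len(spliced) if spliced else 0.0
    )
    mean_term_fraction = (
        float(np.mean([r.fraction for r in spliced])) if spliced else 0.0
    )

    # --- enhancers --------------------------------------------------------
    mask = build_exclusion_mask(annotation.transcripts)
    short_tags = [t for t in retained if t.assay == "short"]
    long_tags = [t for t in retained if t.assay == "long"]
    enh_short = call_bidirectional(short_tags, mask)
    enh_long = call_bidirectional(long_tags, mask)
    joint = merge_enhancer_sets(
        {
            "short": [l.interval for l in enh_short],
            "long": [l.interval for l in enh_long],
        }
    )
    enh_counts = enhancer_expression(joint, retained)
    enh_results = nb_enrichment_test(enh_counts) if len(enh_counts) else []
    enh_venn = venn_classify(enh_results)
    enh_total = max(enh_venn["total_expressed"], 1)
    enh_fractions = {
        "both": enh_venn["both"] / enh_total,
        "short_only": enh_venn["short_only"] / enh_total,
        "long_only": enh_venn["long_only"] / enh_total,
    }
    truth_enh = list(truth.enhancer_classes.values())
    truth_enh_fractions = {
        cls: sum(c == cls for c in truth_enh) / max(len(truth_enh), 1)
        for cls in ("both", "short_only", "long_only")
    }
    # recovery: a truth locus is recovered when a joint region overlaps its
    # center +/- 200 window
    joint_lookup = IntervalLookup([iv for iv, _ in joint]) if joint else None
    recovered = 0
    for key in truth.enhancer_classes:
        chrom, center = key.rsplit(":", 1)
        center = int(center)
        if joint_lookup is not None and joint_lookup.intersects(
            chrom, center - 200, center + 200
        ):
            recovered += 1
    enh_recall = recovered / max(len(truth.enhancer_classes), 1)

    # --- marks and SNPs ---------------------------------------------------
    me1, me3, snps = simulate_chip_and_snps(params, annotation,
                                            truth.enhancer_classes)
    by_class: dict[str, tuple[list[float], list[float]]] = {
        "short_only": ([], []),
        "long_only": ([], []),
    }
    for key, cls in truth.enhancer_classes.items():
        if cls not in by_class:
            continue
        chrom, center = key.rsplit(":", 1)
        center = int(center)
        x3 = assoc_mod.window_mean_signal(me3, chrom, center,
                                          chrom_length=annotation.chrom_lengths[chrom])
        x1 = assoc_mod.window_mean_signal(me1, chrom, center,
                                          chrom_length=annotation.chrom_lengths[chrom])
        by_class[cls][0].append(x3)
        by_class[cls][1].append(x1)
    slope_z = None
    slopes = {}
    if all(len(v[0]) >= 3 for v in by_class.values()):
        res_s = assoc_mod.proportionality_slope(*by_class["short_only"])
        res_l = assoc_mod.proportionality_slope(*by_class["long_only"])
        slopes = {"short": res_s.slope, "long": res_l.slope}
        slope_z = assoc_mod.slope_z_test(res_s.slope, res_s.sd,
                                         res_l.slope, res_l.sd)
    enh_windows = []
    for key in truth.enhancer_classes:
        chrom, center = key.rsplit(":", 1)
        enh_windows.append(
            GenomicInterval(chrom, max(0, int(center) - 500),
                            int(center) + 500, ".")
        )
    gwas = assoc_mod.gwas_enrichment(snps, enh_windows)

    return {
        "n_peaks": len(peaks),
        "n_gene_associated_peaks": len(gene_counts),
        "alpha_hat": alpha_hat,
        "peak_fractions": peak_fractions,
        "peak_truth_fractions": truth_fractions,
        "splice_frac_genes_significant": frac_sig,
        "splice_mean_termination_fraction": mean_term_fraction,
        "splice_combined_log10_p": combined.log10_pvalue,
        "n_enhancers_short": len(enh_short),
        "n_enhancers_long": len(enh_long),
        "n_enhancers_joint": len(joint),
        "enhancer_recall": enh_recall,
        "enhancer_fractions": enh_fractions,
        "enhancer_truth_fractions": truth_enh_fractions,
        "mark_slopes": slopes,
        "mark_slope_z": None if slope_z is None else slope_z.z,
        "gwas_enrichment_factor": gwas.enrichment_factor,
        "gwas_p": gwas.p,
    }
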