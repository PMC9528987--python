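"""Generator contracts: determinism, placement geometry, count model,
termination rate, mark proportionality and GWAS flag enrichment."""

import numpy as np
import pytest

from scaprna.core import IntervalLookup
from scaprna.simulate import (
    Annotation,
    CapacityError,
    SimulationParams,
    default_size_distribution,
    generate_genome_and_annotation,
    simulate_chip_and_snps,
    simulate_tags,
)
from scaprna.spliceterm import count_splice_terminations


def small_params(**kw):
    defaults = dict(
        seed=5,
        n_chroms=1,
        chrom_length=150_000,
        n_genes=12,
        n_short_rna_genes={"snRNA": 1, "tRNA": 1},
        n_enhancers=6,
        n_timepoints=1,
        n_replicates=2,
        lam=40.0,
    )
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestGenome:
    def test_deterministic_given_seed(self):
        p = small_params()
        a1 = generate_genome_and_annotation(p)
        a2 = generate_genome_and_annotation(p)
        assert a1.genome == a2.genome
        assert [t.transcript_id for t in a1.transcripts] == \
            [t.transcript_id for t in a2.transcripts]
        assert a1.enhancer_truth == a2.enhancer_truth
        t1, f1, g1 = simulate_tags(p, a1)
        t2, f2, g2 = simulate_tags(p, a2)
        assert t1 == t2 and f1 == f2 and g1.peak_classes == g2.peak_classes

    def test_no_features_degenerate(self):
        p = small_params(n_genes=0, n_short_rna_genes={}, n_enhancers=3)
        ann = generate_genome_and_annotation(p)
        assert ann.transcripts == []
        assert set(ann.genome["chr1"]) <= set("ACGT")
        assert len(ann.genome["chr1"]) == p.chrom_length

    def test_enhancers_respect_tss_distance(self):
        p = small_params(n_enhancers=8, enhancer_tss_distance=1000)
        ann = generate_genome_and_annotation(p)
        tss = [(t.chrom, t.tss) for t in ann.transcripts]
        for enh in ann.enhancer_truth:
            dists = [abs(enh["center"] - pos) for c, pos in tss
                     if c == enh["chrom"]]
            assert min(dists) >= 1000

    def test_infeasible_packing_raises(self):
        with pytest.raises(CapacityError):
            generate_genome_and_annotation(
                small_params(chrom_length=20_000, n_genes=40)
            )

    def test_gene_models_have_introns(self):
        ann = generate_genome_and_annotation(small_params())
        genes = [t for t in ann.transcripts if t.biotype in ("mRNA", "lncRNA")]
        assert all(t.n_introns >= 1 for t in genes)
        assert {cls for _, cls, _ in ann.short_rna_refs} == {"snRNA", "tRNA"}

    def test_size_distribution_sums_to_one(self):
        sizes, probs = default_size_distribution()
        assert sizes[0] == 72 and sizes[-1] == 272
        assert probs.sum() == pytest.approx(1.0)


class TestTagModel:
    def test_mean_counts_match_expectation(self):
        # Poisson limit: pooled promoter counts over many peak-columns
        p = small_params(
            n_chroms=2, chrom_length=400_000, n_genes=120, alpha=0.0,
            lam=50.0, multimapped_fraction=0.0, n_enhancers=2,
        )
        ann = generate_genome_and_annotation(p)
        tags, _, truth = simulate_tags(p, ann)
        genes = {t.gene_id: t for t in ann.transcripts
                 if t.biotype in ("mRNA", "lncRNA")}
        tss_index = {(t.chrom, t.strand, t.tss): g for g, t in genes.items()}
        observed = 0
        expected = 0.0
        for sample_assay, s_j in truth.size_factors.items():
            sample, assay = sample_assay.split(":")
            for gid, tx in genes.items():
                cls = truth.peak_classes[gid]
                pi = {"short_only": {"short": 1.0, "long": 0.0},
                      "long_only": {"short": 0.0, "long": 1.0},
                      "both": {"short": 0.5, "long": 0.5}}[cls][assay]
                expected += s_j * p.lam * pi
        promoter_positions = set()
        for tx in genes.values():
            for off in range(-2, 3):
                promoter_positions.add((tx.chrom, tx.strand, tx.tss + off))
        for t in tags:
            if (t.chrom, t.strand, t.pos5) in promoter_positions:
                observed += t.count
        assert abs(observed / expected - 1.0) < 0.02

    def test_theta_one_forces_splice_termination(self):
        p = small_params(theta_term=1.0, fragments_per_gene=40.0)
        ann = generate_genome_and_annotation(p)
        _, fragments, truth = simulate_tags(p, ann)
        genes = [t for t in ann.transcripts if t.biotype in ("mRNA", "lncRNA")
                 and t.n_introns > 0]
        total_n = total_k = 0
        for tx in genes:
            n, k, *_ = count_splice_terminations(fragments, tx)
            total_n += n
            total_k += k
        assert total_n > 0 and total_k == total_n

    def test_theta_recovered_at_stated_tolerance(self):
        p = small_params(
            n_chroms=2, chrom_length=300_000, n_genes=60,
            theta_term=0.6, fragments_per_gene=150.0,
        )
        ann = generate_genome_and_annotation(p)
        _, fragments, _ = simulate_tags(p, ann)
        assert len(fragments) >= 5000
        genes = [t for t in ann.transcripts if t.biotype in ("mRNA", "lncRNA")]
        total_n = total_k = 0
        for tx in genes:
            n, k, *_ = count_splice_terminations(fragments, tx)
            total_n += n
            total_k += k
        frac = total_k / total_n
        assert 0.57 <= frac <= 0.63

    def test_cap_g_rate_recovered(self):
        from scaprna.categorize import first_base_g_profile

        p = small_params(n_genes=30, chrom_length=250_000, cap_g_rate=0.3,
                         lam=60.0)
        ann = generate_genome_and_annotation(p)
        tags, _, _ = simulate_tags(p, ann)
        prof = first_base_g_profile(tags, ann.genome)
        assert 0.27 <= prof["short"]["unencoded_g"] <= 0.33
        assert 0.27 <= prof["long"]["unencoded_g"] <= 0.33


class TestChipAndSnps:
    def test_noiseless_marks_recover_slope_exactly(self):
        from scaprna.assoc import proportionality_slope, window_mean_signal

        p = small_params(
            n_enhancers=8, enhancer_spacing=15_000, mark_noise_sd=0.0,
            mark_beta_short=2.0, mark_beta_long=2.0,
        )
        ann = generate_genome_and_annotation(p)
        me1, me3, _ = simulate_chip_and_snps(p, ann)
        x, y = [], []
        for enh in ann.enhancer_truth:
            x.append(window_mean_signal(me3, enh["chrom"], enh["center"],
                                        chrom_length=p.chrom_length))
            y.append(window_mean_signal(me1, enh["chrom"], enh["center"],
                                        chrom_length=p.chrom_length))
        res = proportionality_slope(x, y)
        assert res.slope == pytest.approx(2.0, abs=1e-9)
        assert res.sd == pytest.approx(0.0, abs=1e-9)

    def test_gamma_one_null_fractions_equal(self):
        from scaprna.core import GenomicInterval

        p = small_params(gamma=1.0, n_snps=20_000)
        ann = generate_genome_and_annotation(p)
        _, _, snps = simulate_chip_and_snps(p, ann)
        windows = [
            GenomicInterval(e["chrom"], e["center"] - 500, e["center"] + 500, ".")
            for e in ann.enhancer_truth
        ]
        lookup = IntervalLookup(windows)
        inside = np.array([lookup.contains(c, int(pos))
                           for c, pos in zip(snps.chroms, snps.positions)])
        f_in = snps.gwas[inside].mean()
        f_out = snps.gwas[~inside].mean()
        pooled_sd = np.sqrt(
            0.05 * 0.95 * (1 / inside.sum() + 1 / (~inside).sum())
        )
        assert abs(f_in - f_out) <= 3.5 * pooled_sd

    def test_multimapped_fraction_flagged(self):
        p = small_params(multimapped_fraction=0.2, lam=80.0)
        ann = generate_genome_and_annotation(p)
        tags, _, _ = simulate_tags(p, ann)
        total = sum(t.count for t in tags)
        mm = sum(t.count for t in tags if t.multimapped)
        assert 0.15 <= mm / total <= 0.25
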