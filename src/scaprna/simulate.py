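"""Synthetic genomes, annotations and tag data with the statistical structure
the analysis assumes.

The generator emulates a two-assay (short and long capped RNA) multi-sample
tag experiment over a toy genome: gene promoters emit 5'-end tags with a
controllable short:long composition, paired-end short RNA fragments draw
their sizes from a background distribution and terminate at splice sites
with probability theta_term, enhancers transcribe divergently with a
controllable directionality, ChIP marks are proportional between two tracks,
and SNPs carry a GWAS flag enriched inside enhancers by a factor gamma.
Everything is deterministic given the seed; per-sample streams are forked by
a stable hash of the sample id so adding samples does not perturb existing
ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (
    CappedTag,
    GenomicInterval,
    PairedFragment,
    SignalTrack,
    SNPTable,
    TranscriptModel,
    ValidationError,
)


class CapacityError(ValueError):
    """Requested features do not fit in the genome."""


def default_size_distribution() -> tuple[np.ndarray, np.ndarray]:
    """Background fragment-size table: a bimodal mixture over 72-272 nt
    (the short capped RNA selection window), peaked near the two abundant
    spliceosomal/snoRNA size modes."""
    sizes = np.arange(72, 273)
    comp1 = np.exp(-0.5 * ((sizes - 120) / 25.0) ** 2)
    comp2 = np.exp(-0.5 * ((sizes - 215) / 30.0) ** 2)
    probs = 0.5 * comp1 / comp1.sum() + 0.5 * comp2 / comp2.sum()
    return sizes, probs / probs.sum()


@dataclass
class SimulationParams:
    seed: int = 0
    # genome geometry
    n_chroms: int = 2
    chrom_length: int = 300_000
    # gene models
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_size: tuple[int, int] = (80, 300)
    intron_size: tuple[int, int] = (150, 800)
    lncRNA_fraction: float = 0.2
    intergenic_gap: tuple[int, int] = (2000, 4500)
    # short RNA genes (single exon) per class
    n_short_rna_genes: dict = field(
        default_factory=lambda: {"snRNA": 3, "snoRNA": 3, "tRNA": 3, "scaRNA": 2}
    )
    short_rna_size: tuple[int, int] = (80, 200)
    # enhancers
    n_enhancers: int = 30
    enhancer_tss_distance: int = 1000  # minimum distance to any gene TSS
    enhancer_exon_margin: int = 300
    enhancer_spacing: int = 3000
    # expression
    lam: float = 80.0  # mean tags per promoter peak per sample column
    lam_enhancer: float = 40.0  # mean tags per enhancer per sample (both strands)
    pi_short_balanced: float = 0.5
    fraction_short_only: float = 0.2
    fraction_long_only: float = 0.3
    fraction_enh_short_only: float = 0.1
    fraction_enh_long_only: float = 0.3
    alpha: float = 0.1  # NB dispersion, var = mu + alpha*mu^2
    multimapped_fraction: float = 0.02
    cap_g_rate: float = 0.25  # unencoded cap-derived G at the read 5' end
    size_factor_sd: float = 0.2  # lognormal spread of per-column library depth
    # paired-end fragments and splice-site termination
    theta_term: float = 0.5
    fragments_per_gene: float = 30.0
    size_dist: Optional[tuple[np.ndarray, np.ndarray]] = None
    # enhancer transcription
    delta: float = 0.0  # directionality of enhancer transcription
    # ChIP marks
    mark_beta_short: float = 3.0  # me1:me3 proportionality, short-enriched class
    mark_beta_long: float = 1.5
    mark_noise_sd: float = 0.05
    # SNPs
    n_snps: int = 10_000
    gwas_base_rate: float = 0.05
    gamma: float = 2.0
    # design
    n_timepoints: int = 3
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.theta_term <= 1:
            raise ValidationError("theta_term must be in [0,1]")
        if not 0 <= self.pi_short_balanced <= 1:
            raise ValidationError("pi_short_balanced must be in [0,1]")
        if self.lam <= 0 or self.gamma <= 0:
            raise ValidationError("lam and gamma must be positive")
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if self.size_dist is None:
            self.size_dist = default_size_distribution()
        sizes, probs = self.size_dist
        if not np.isclose(np.sum(probs), 1.0):
            raise ValidationError("size distribution must sum to 1")

    def sample_ids(self) -> list[str]:
        return [
            f"t{t}_r{r}"
            for t in range(self.n_timepoints)
            for r in range(self.n_replicates)
        ]

    def timepoint_map(self) -> dict[str, int]:
        return {s: int(s.split("_")[0][1:]) for s in self.sample_ids()}


@dataclass
class Annotation:
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    short_rna_refs: list[tuple[str, str, str]]  # (id, class, sequence)
    short_rna_loci: list[GenomicInterval]
    enhancer_truth: list[dict]  # chrom, center, cls
    chrom_lengths: dict[str, int]


@dataclass
class GroundTruth:
    peak_classes: dict[str, str]  # gene_id -> both | short_only | long_only
    gene_theta: dict[str, float]
    enhancer_classes: dict[str, str]  # "chrom:center" -> class
    gamma: float
    delta: float
    size_factors: dict[str, float]  # "sample:assay" -> depth factor


def _sample_rng(seed: int, sample_id: str, salt: str = "") -> np.random.Generator:
    """Fork a per-sample stream from the global seed by stable hashing."""
    h = zlib.crc32(f"{sample_id}:{salt}".encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed & 0x7FFFFFFF, h])


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def generate_genome_and_annotation(params: SimulationParams) -> Annotation:
    """Lay out a toy genome with gene models, short-RNA genes and enhancer
    truth loci.

    Genes are placed left to right with random intergenic gaps; enhancers are
    placed in intergenic space at least ``enhancer_tss_distance`` from every
    TSS and ``enhancer_exon_margin`` from every exon.  Infeasible packing
    raises CapacityError rather than silently truncating.  The genomic base
    at each gene TSS is set to A (initiator convention) so unencoded cap
    guanosines are identifiable.
    """
    rng = np.random.default_rng(params.seed & 0x7FFFFFFF)
    genome_codes = {
        f"chr{i + 1}": _random_seq(rng, params.chrom_length)
        for i in range(params.n_chroms)
    }
    chroms = list(genome_codes)

    transcripts: list[TranscriptModel] = []
    short_refs: list[tuple[str, str, str]] = []
    short_loci: list[GenomicInterval] = []

    # interleave gene and short-RNA gene placement across chromosomes
    short_queue: list[str] = []
    for cls, n in sorted(params.n_short_rna_genes.items()):
        short_queue.extend([cls] * n)
    rng.shuffle(short_queue)

    gene_idx = 0
    short_idx = 0
    cursors = {c: 2000 for c in chroms}
    n_placed = 0
    total_features = params.n_genes + len(short_queue)
    chrom_cycle = 0
    stall = 0
    while n_placed < total_features:
        chrom = chroms[chrom_cycle % len(chroms)]
        chrom_cycle += 1
        cursor = cursors[chrom]
        gap = int(rng.integers(*params.intergenic_gap))
        start = cursor + gap
        place_gene = gene_idx < params.n_genes and (
            short_idx >= len(short_queue) or (n_placed % 4 != 3)
        )
        if place_gene:
            n_exons = int(rng.integers(params.exons_per_gene[0],
                                       params.exons_per_gene[1] + 1))
            exon_lens = rng.integers(*params.exon_size, size=n_exons)
            intron_lens = rng.integers(*params.intron_size, size=max(0, n_exons - 1))
            footprint = int(exon_lens.sum() + intron_lens.sum())
        else:
            footprint = int(rng.integers(*params.short_rna_size))
        if start + footprint + 2000 > params.chrom_length:
            stall += 1
            if stall > 4 * len(chroms):
                raise CapacityError(
                    f"cannot place {total_features} features in "
                    f"{params.n_chroms} x {params.chrom_length} bp"
                )
            continue
        stall = 0
        if place_gene:
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = "lncRNA" if rng.random() < params.lncRNA_fraction else "mRNA"
            exons = []
            pos = start
            for k in range(n_exons):
                exons.append(
                    GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand)
                )
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            gid = f"gene{gene_idx:04d}"
            tx = TranscriptModel(f"{gid}.t1", gid, biotype, exons)
            transcripts.append(tx)
            # non-G initiator region (+/-2 nt around the TSS, strand-aware)
            # so unencoded cap guanosines are identifiable at the read 5' end
            non_g = np.array([0, 1, 3]) if strand == "+" else np.array([0, 2, 3])
            for off in range(-2, 3):
                pos = tx.tss + off
                if 0 <= pos < params.chrom_length:
                    genome_codes[chrom][pos] = int(rng.choice(non_g))
            gene_idx += 1
        else:
            cls = short_queue[short_idx]
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, start, start + footprint, strand)
            sid = f"{cls}{short_idx:03d}"
            seq_codes = genome_codes[chrom][start:start + footprint]
            seq = _to_str(seq_codes)
            if strand == "-":
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                seq = "".join(comp[b] for b in reversed(seq))
            short_refs.append((sid, cls, seq))
            short_loci.append(iv)
            transcripts.append(TranscriptModel(f"{sid}.t1", sid, cls, [iv]))
            short_idx += 1
        cursors[chrom] = start + footprint
        n_placed += 1

    # enhancer placement: grid scan of intergenic space
    tss_list: dict[str, list[int]] = {c: [] for c in chroms}
    exon_ivs: list[GenomicInterval] = []
    for tx in transcripts:
        tss_list[tx.chrom].append(tx.tss)
        exon_ivs.extend(tx.exons)
    from .core import IntervalLookup, merge_intervals

    margin = params.enhancer_exon_margin
    padded = [
        GenomicInterval(e.chrom, max(0, e.start - margin), e.end + margin, ".")
        for e in exon_ivs
    ]
    exon_lookup = IntervalLookup(padded)

    enhancer_truth: list[dict] = []
    n_each = params.n_enhancers
    cls_draws = rng.random(n_each)
    placed = 0
    for chrom in chroms:
        pos = 3000
        tss_sorted = np.array(sorted(tss_list[chrom]), dtype=np.int64)
        while pos < params.chrom_length - 3000 and placed < n_each:
            ok_tss = (
                len(tss_sorted) == 0
                or np.min(np.abs(tss_sorted - pos)) >= params.enhancer_tss_distance
            )
            window_ok = not exon_lookup.intersects(chrom, pos - 400, pos + 400)
            if ok_tss and window_ok:
                u = cls_draws[placed]
                if u < params.fraction_enh_short_only:
                    cls = "short_only"
                elif u < params.fraction_enh_short_only + params.fraction_enh_long_only:
                    cls = "long_only"
                else:
                    cls = "both"
                enhancer_truth.append({"chrom": chrom, "center": int(pos), "cls": cls})
                placed += 1
                pos += params.enhancer_spacing
            else:
                pos += 200
        if placed >= n_each:
            break
    if placed < n_each:
        raise CapacityError(
            f"placed only {placed}/{n_each} enhancers; genome too crowded"
        )

    genome = {c: _to_str(codes) for c, codes in genome_codes.items()}
    return Annotation(
        genome=genome,
        transcripts=transcripts,
        short_rna_refs=short_refs,
        short_rna_loci=short_loci,
        enhancer_truth=enhancer_truth,
        chrom_lengths={c: len(s) for c, s in genome.items()},
    )


#: 5'-end position profile around the TSS (offset in transcription direction).
_PEAK_OFFSETS = np.array([-2, -1, 0, 1, 2])
_PEAK_PROBS = np.array([0.08, 0.15, 0.5, 0.17, 0.1])


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float, size=None):
    if mean <= 0:
        return np.zeros(size or 1, dtype=np.int64) if size else 0
    if alpha <= 0:
        return rng.poisson(mean, size)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def simulate_tags(
    params: SimulationParams,
    annotation: Annotation,
) -> tuple[list[CappedTag], list[PairedFragment], GroundTruth]:
    """Emit per-sample short/long 5'-end tags, paired fragments and truth.

    Promoter tag counts per (sample, assay) column follow NB(depth * lam * pi,
    alpha) where pi is the assay share of the gene's composition class.
    Paired fragments anchor near the TSS, draw sizes from the background
    distribution and snap their 3' end to the nearest downstream splice site
    with probability theta_term (intronless genes get theta 0 with a warning
    by construction).  Enhancer tags are emitted divergently with
    directionality delta.  A fraction of tags is flagged multimapped.
    """
    rng = np.random.default_rng((params.seed + 1) & 0x7FFFFFFF)
    genes = [t for t in annotation.transcripts
             if t.biotype in ("mRNA", "lncRNA")]

    # per-gene composition class, in gene order (deterministic)
    peak_classes: dict[str, str] = {}
    for tx in genes:
        u = rng.random()
        if u < params.fraction_short_only:
            peak_classes[tx.gene_id] = "short_only"
        elif u < params.fraction_short_only + params.fraction_long_only:
            peak_classes[tx.gene_id] = "long_only"
        else:
            peak_classes[tx.gene_id] = "both"

    gene_theta = {
        tx.gene_id: (params.theta_term if tx.n_introns > 0 else 0.0)
        for tx in genes
    }

    samples = params.sample_ids()
    depth: dict[str, float] = {}
    tags: list[CappedTag] = []
    sizes_tbl, probs_tbl = params.size_dist

    def pi_for(cls: str, assay: str) -> float:
        if cls == "short_only":
            return 1.0 if assay == "short" else 0.0
        if cls == "long_only":
            return 0.0 if assay == "short" else 1.0
        return params.pi_short_balanced if assay == "short" else \
            1.0 - params.pi_short_balanced

    for sample in samples:
        for assay in ("short", "long"):
            srng = _sample_rng(params.seed, sample, salt=assay)
            s_j = float(np.exp(srng.normal(0.0, params.size_factor_sd)))
            depth[f"{sample}:{assay}"] = s_j
            # promoter tags
            for tx in genes:
                cls = peak_classes[tx.gene_id]
                mean = s_j * params.lam * pi_for(cls, assay)
                total = int(_nb_draw(srng, mean, params.alpha))
                if total == 0:
                    continue
                alloc = srng.multinomial(total, _PEAK_PROBS)
                sign = 1 if tx.strand == "+" else -1
                for off, cnt in zip(_PEAK_OFFSETS, alloc):
                    if cnt == 0:
                        continue
                    pos = tx.tss + sign * int(off)
                    n_mm = int(srng.binomial(cnt, params.multimapped_fraction))
                    n_capg = int(srng.binomial(cnt - n_mm, params.cap_g_rate))
                    n_plain = int(cnt) - n_mm - n_capg
                    base = annotation.genome[tx.chrom][pos]
                    if tx.strand == "-":
                        base = {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
                    for count, mm, fb in (
                        (n_plain, False, base),
                        (n_capg, False, "G"),
                        (n_mm, True, base),
                    ):
                        if count > 0:
                            tags.append(
                                CappedTag(sample, assay, tx.chrom, tx.strand,
                                          pos, count, mm, fb)
                            )
            # enhancer tags (divergent)
            for enh in annotation.enhancer_truth:
                cls = enh["cls"]
                expressed = (
                    cls == "both"
                    or (cls == "short_only" and assay == "short")
                    or (cls == "long_only" and assay == "long")
                )
                if not expressed:
                    continue
                lam_f = s_j * params.lam_enhancer * (1.0 + params.delta) / 2.0
                lam_r = s_j * params.lam_enhancer * (1.0 - params.delta) / 2.0
                for strand, lam_s, anchor in (
                    ("+", lam_f, enh["center"] + 100),
                    ("-", lam_r, enh["center"] - 100),
                ):
                    total = int(_nb_draw(srng, lam_s, params.alpha))
                    if total == 0:
                        continue
                    jitter = srng.integers(-10, 11, size=total)
                    positions, counts = np.unique(anchor + jitter,
                                                  return_counts=True)
                    for pos, cnt in zip(positions, counts):
                        n_mm = int(srng.binomial(cnt, params.multimapped_fraction))
                        if cnt - n_mm > 0:
                            tags.append(
                                CappedTag(sample, assay, enh["chrom"], strand,
                                          int(pos), int(cnt - n_mm), False)
                            )
                        if n_mm > 0:
                            tags.append(
                                CappedTag(sample, assay, enh["chrom"], strand,
                                          int(pos), n_mm, True)
                            )

    # paired-end fragments (short capped RNA paired libraries)
    fragments: list[PairedFragment] = []
    frng = _sample_rng(params.seed, "paired", salt="fragments")
    for tx in genes:
        cls = peak_classes[tx.gene_id]
        if cls == "long_only":
            continue
        n_frag = int(frng.poisson(params.fragments_per_gene))
        if n_frag == 0:
            continue
        donors = np.array(tx.splice_sites_tx(), dtype=np.int64)
        theta = gene_theta[tx.gene_id]
        length = tx.spliced_length
        anchors = frng.integers(0, min(5, length), size=n_frag)
        drawn_sizes = frng.choice(sizes_tbl, size=n_frag, p=probs_tbl)
        snap = frng.random(n_frag) < theta
        for a, s, do_snap in zip(anchors, drawn_sizes, snap):
            a = int(a)
            if do_snap and len(donors):
                downstream = donors[donors >= a]
                if len(downstream):
                    end_tx = int(downstream[np.argmin(downstream - a)])
                else:
                    end_tx = min(a + int(s) - 1, length - 1)
            else:
                end_tx = min(a + int(s) - 1, length - 1)
                # avoid accidental splice-site coincidence inflating theta=0
                # runs is left to chance, as in real data
            pos5 = tx.tx_to_genomic(a)
            pos3 = tx.tx_to_genomic(end_tx)
            fragments.append(
                PairedFragment("paired", tx.chrom, tx.strand, pos5, pos3,
                               end_tx - a + 1)
            )

    enhancer_classes = {
        f"{e['chrom']}:{e['center']}": e["cls"] for e in annotation.enhancer_truth
    }
    truth = GroundTruth(
        peak_classes=peak_classes,
        gene_theta=gene_theta,
        enhancer_classes=enhancer_classes,
        gamma=params.gamma,
        delta=params.delta,
        size_factors=depth,
    )
    return tags, fragments, truth


def simulate_chip_and_snps(
    params: SimulationParams,
    annotation: Annotation,
    enhancer_classes: Optional[dict[str, str]] = None,
    window_halfwidth: int = 5000,
    snp_window_halfwidth: int = 500,
) -> tuple[SignalTrack, SignalTrack, SNPTable]:
    """Two proportional ChIP tracks over enhancers, and a SNP table.

    The H3K4me3-like track gets a lognormal level per enhancer over its
    +/- ``window_halfwidth`` window; the H3K4me1-like track is beta * that
    level plus Gaussian noise (clipped at 0), with beta depending on the
    enhancer's composition class.  SNPs are uniform over the genome with
    GWAS-flag probability gamma-fold higher inside enhancer windows
    (center +/- ``snp_window_halfwidth``).
    """
    rng = np.random.default_rng((params.seed + 2) & 0x7FFFFFFF)
    me3_events: dict[str, list[tuple[int, int, float]]] = {}
    me1_events: dict[str, list[tuple[int, int, float]]] = {}
    if params.gamma != 1.0 and not annotation.enhancer_truth:
        raise ValidationError("gamma != 1 requires enhancer truth loci")
    for enh in annotation.enhancer_truth:
        cls = (enhancer_classes or {}).get(
            f"{enh['chrom']}:{enh['center']}", enh["cls"]
        )
        beta = params.mark_beta_short if cls == "short_only" else \
            params.mark_beta_long
        if cls == "both":
            beta = (params.mark_beta_short + params.mark_beta_long) / 2.0
        v3 = float(np.exp(rng.normal(0.0, 0.4)))
        v1 = beta * v3 + float(rng.normal(0.0, params.mark_noise_sd))
        if v1 < 0:
            v1 = 0.0
        chrom = enh["chrom"]
        lo = max(0, enh["center"] - window_halfwidth)
        hi = min(annotation.chrom_lengths[chrom], enh["center"] + window_halfwidth)
        me3_events.setdefault(chrom, []).append((lo, hi, v3))
        me1_events.setdefault(chrom, []).append((lo, hi, v1))

    def build(events: dict[str, list[tuple[int, int, float]]]) -> SignalTrack:
        records = []
        for chrom, evs in events.items():
            # breakpoint accumulation: overlapping windows sum
            points = sorted({p for lo, hi, _ in evs for p in (lo, hi)})
            for a, b in zip(points, points[1:]):
                val = sum(v for lo, hi, v in evs if lo <= a and b <= hi)
                if val > 0:
                    records.append((chrom, a, b, val))
        return SignalTrack.from_records(records)

    me3 = build(me3_events)
    me1 = build(me1_events)

    # SNPs
    enh_windows = [
        GenomicInterval(e["chrom"], max(0, e["center"] - snp_window_halfwidth),
                        e["center"] + snp_window_halfwidth, ".")
        for e in annotation.enhancer_truth
    ]
    from .core import IntervalLookup

    lookup = IntervalLookup(enh_windows)
    chroms_arr: list[str] = []
    pos_arr: list[int] = []
    chrom_names = sorted(annotation.chrom_lengths)
    seen: set[tuple[str, int]] = set()
    while len(pos_arr) < params.n_snps:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(annotation.chrom_lengths[chrom]))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        chroms_arr.append(chrom)
        pos_arr.append(pos)
    inside = np.array([lookup.contains(c, p) for c, p in zip(chroms_arr, pos_arr)])
    p_in = min(1.0, params.gwas_base_rate * params.gamma)
    probs = np.where(inside, p_in, params.gwas_base_rate)
    gwas = rng.random(params.n_snps) < probs
    return me1, me3, SNPTable(chroms_arr, np.array(pos_arr), gwas)


def write_dataset(
    out_dir: str | Path,
    params: SimulationParams,
) -> GroundTruth:
    """Generate a complete dataset directory with a ground-truth manifest."""
    from . import io as scio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = generate_genome_and_annotation(params)
    tags, fragments, truth = simulate_tags(params, annotation)
    me1, me3, snps = simulate_chip_and_snps(params, annotation,
                                            truth.enhancer_classes)

    scio.write_fasta(out / "genome.fa", annotation.genome)
    scio.write_transcripts(out / "transcripts.bed12", annotation.transcripts)
    scio.write_fasta(
        out / "short_rna_refs.fa",
        {sid: seq for sid, _, seq in annotation.short_rna_refs},
        {sid: f"class={cls}" for sid, cls, _ in annotation.short_rna_refs},
    )
    scio.write_bed6(
        out / "enhancer_truth.bed",
        [
            (GenomicInterval(e["chrom"], e["center"] - 200, e["center"] + 200, "."), 0)
            for e in annotation.enhancer_truth
        ],
        names=[e["cls"] for e in annotation.enhancer_truth],
    )
    scio.write_tags(out / "tags.tsv", tags)
    scio.write_fragments(out / "fragments.tsv", fragments)
    scio.write_bedgraph(out / "h3k4me1.bedgraph", me1)
    scio.write_bedgraph(out / "h3k4me3.bedgraph", me3)
    scio.write_snps(out / "snps.tsv", snps)
    manifest = {
        "peak_classes": truth.peak_classes,
        "gene_theta": truth.gene_theta,
        "enhancer_classes": truth.enhancer_classes,
        "gamma": truth.gamma,
        "delta": truth.delta,
        "size_factors": truth.size_factors,
        "seed": params.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return truth
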