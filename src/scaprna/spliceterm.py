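"""Splice-site termination analysis of paired 5'/3'-end short RNA fragments.

Gene-associated short capped RNAs often end precisely at exon 3' boundaries.
For each gene this module counts fragments whose 3' end coincides with a
splice site, computes a per-gene background probability by resampling
fragment sizes from a background size distribution with the 5' end anchored,
and tests enrichment with a one-sided upper-tail binomial test.  Gene-level
p-values combine across genes with Fisher's method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .core import PairedFragment, TranscriptModel, ValidationError


@dataclass
class SizeDistribution:
    """Empirical fragment-size distribution (probability mass over nt)."""

    sizes: np.ndarray  # int, ascending
    probs: np.ndarray
    n_fragments: int
    n_excluded_full_length: int = 0

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0) or not math.isclose(self.probs.sum(), 1.0,
                                                      rel_tol=1e-9):
            raise ValidationError("size distribution must be a probability mass")


@dataclass
class GeneTerminationResult:
    gene_id: str
    n: int  # fragments aligned to the gene's transcripts
    k: int  # fragments terminating at a splice site
    p0: float  # background termination probability
    pval: float

    @property
    def fraction(self) -> float:
        return self.k / self.n if self.n else float("nan")


def _fragment_tx_coords(
    frag: PairedFragment, tx: TranscriptModel
) -> Optional[tuple[int, int]]:
    """Map a fragment's 5' and 3' ends into transcript coordinates.

    Returns None when either end misses the transcript's exons or the ends
    are inverted in transcript space (fragment not colinear with the mature
    transcript).
    """
    if frag.chrom != tx.chrom or frag.strand != tx.strand:
        return None
    a = tx.genomic_to_tx(frag.pos5)
    b = tx.genomic_to_tx(frag.pos3)
    if a is None or b is None or b < a:
        return None
    return a, b


def background_size_distribution(
    fragments: Iterable[PairedFragment],
    transcripts: Sequence[TranscriptModel],
    full_length_fraction: float = 0.9,
) -> SizeDistribution:
    """Background size distribution of fragments aligning to mRNA/lncRNA
    transcripts, excluding near-full-length alignments.

    A fragment is excluded as full-length when its alignment extends over
    strictly more than ``full_length_fraction`` of the transcript's spliced
    length (a fragment at exactly the threshold is retained).  A fragment
    aligning to several transcripts contributes once, via the first transcript
    (in input order) it maps onto.
    """
    eligible = [t for t in transcripts if t.biotype in ("mRNA", "lncRNA")]
    sizes: list[int] = []
    n_excluded = 0
    for frag in fragments:
        for tx in eligible:
            coords = _fragment_tx_coords(frag, tx)
            if coords is None:
                continue
            extent = coords[1] - coords[0] + 1
            if extent > full_length_fraction * tx.spliced_length:
                n_excluded += 1
            else:
                sizes.append(frag.size)
            break
    if not sizes:
        raise ValidationError(
            "no fragments retained for the background size distribution"
        )
    values, counts = np.unique(np.asarray(sizes, dtype=np.int64),
                               return_counts=True)
    return SizeDistribution(values, counts / counts.sum(), len(sizes), n_excluded)


def count_splice_terminations(
    fragments: Iterable[PairedFragment],
    tx: TranscriptModel,
    tolerance: int = 0,
    include_acceptors: bool = False,
) -> tuple[int, int, dict[int, int], list[int]]:
    """Count fragments of one transcript terminating at its splice sites.

    Returns (n aligned, k terminating, offset histogram, sizes of terminating
    fragments).  Termination means the fragment's 3' end, in transcript
    coordinates, equals the last base of a non-terminal exon within
    ``tolerance`` nt; exon-start (acceptor) positions count only when
    ``include_acceptors``.  The offset histogram records 3' end minus the
    nearest splice site for all aligned fragments of spliced transcripts.
    """
    sites = tx.splice_sites_tx()
    if include_acceptors:
        sites = sorted(set(sites) | set(tx.acceptor_sites_tx()))
    n = k = 0
    offsets: dict[int, int] = {}
    term_sizes: list[int] = []
    for frag in fragments:
        coords = _fragment_tx_coords(frag, tx)
        if coords is None:
            continue
        n += 1
        if not sites:
            continue
        end3 = coords[1]
        nearest = min(sites, key=lambda s: abs(end3 - s))
        off = end3 - nearest
        offsets[off] = offsets.get(off, 0) + 1
        if abs(off) <= tolerance:
            k += 1
            term_sizes.append(frag.size)
    return n, k, offsets, term_sizes


def background_probability(
    anchors: Sequence[int],
    tx: TranscriptModel,
    background: SizeDistribution,
    tolerance: int = 0,
    include_acceptors: bool = False,
) -> float:
    """Mean probability that an anchored fragment would terminate at a splice
    site if its size were drawn from the background distribution.

    For a fragment with 5' anchor a (transcript coordinates), a size s lands
    its 3' end at a + s - 1; landings beyond the transcript end contribute
    probability zero (the size mass is not renormalised).
    """
    sites = tx.splice_sites_tx()
    if include_acceptors:
        sites = sorted(set(sites) | set(tx.acceptor_sites_tx()))
    if not anchors:
        raise ValidationError("background probability needs >=1 anchor")
    if not sites:
        return 0.0
    site_arr = np.asarray(sites, dtype=np.int64)
    length = tx.spliced_length
    p_each = []
    for a in anchors:
        ends = a + background.sizes - 1
        within = ends < length
        if tolerance == 0:
            hits = np.isin(ends, site_arr)
        else:
            dist = np.min(np.abs(ends[:, None] - site_arr[None, :]), axis=1)
            hits = dist <= tolerance
        p_each.append(float(background.probs[within & hits].sum()))
    return float(np.mean(p_each))


def gene_termination_test(n: int, k: int, p0: float,
                          alternative: str = "greater") -> float:
    """Binomial test of splice-site termination enrichment.

    One-sided upper tail by default: p = P(X >= k | n, p0).
    """
    if n < 1:
        raise ValidationError("binomial test needs n >= 1")
    if not 0 <= p0 <= 1:
        raise ValidationError("p0 must be in [0, 1]")
    if not 0 <= k <= n:
        raise ValidationError("need 0 <= k <= n")
    if alternative == "greater":
        if p0 == 0.0:
            return 0.0 if k > 0 else 1.0
        if p0 == 1.0:
            return 1.0
        return float(stats.binom.sf(k - 1, n, p0))
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def randomized_binomial_pvalue(n: int, k: int, p0: float, u: float) -> float:
    """Randomized upper-tail binomial p-value, exactly Uniform(0,1) under the
    null: P(X > k) + u * P(X = k) with u ~ Uniform(0,1).

    The discrete test's conservative p-value P(X >= k) is super-uniform; this
    randomized version is the standard device for calibration checks of
    discrete tests (the reported per-gene p-value stays the conservative one).
    """
    if p0 <= 0.0:
        return u if k == 0 else 0.0
    if p0 >= 1.0:
        return u if k == n else 1.0
    return float(stats.binom.sf(k, n, p0) + u * stats.binom.pmf(k, n, p0))


@dataclass
class CombinedSignificance:
    statistic: float  # chi-square = -2 * sum(log p)
    df: int
    pvalue: float  # 0.0 on underflow or when any input p is 0
    log10_pvalue: float  # exact log-scale value (meaningful under underflow)
    pvalue_str: str
    any_zero: bool = False


def combined_significance(pvals: Sequence[float]) -> CombinedSignificance:
    """Fisher's combined probability over per-gene binomial p-values."""
    pvals = list(pvals)
    if not pvals:
        raise ValidationError("need >=1 p-value to combine")
    if any(p < 0 or p > 1 for p in pvals):
        raise ValidationError("p-values must be in [0, 1]")
    if any(p == 0 for p in pvals):
        return CombinedSignificance(math.inf, 2 * len(pvals), 0.0, -math.inf,
                                    "0", any_zero=True)
    chi2 = -2.0 * float(np.sum(np.log(pvals)))
    df = 2 * len(pvals)
    log_p = float(stats.chi2.logsf(chi2, df))
    p = float(stats.chi2.sf(chi2, df))
    log10_p = log_p / math.log(10.0)
    p_str = f"{p:.4g}" if p > 0 else "< 1e-300"
    return CombinedSignificance(chi2, df, p, log10_p, p_str)


def gene_termination_analysis(
    fragments: Iterable[PairedFragment],
    transcripts: Sequence[TranscriptModel],
    background: Optional[SizeDistribution] = None,
    tolerance: int = 0,
    full_length_fraction: float = 0.9,
    p_threshold: float = 0.05,
) -> tuple[list[GeneTerminationResult], CombinedSignificance]:
    """Per-gene splice-termination test over all genes with aligned fragments.

    A fragment aligning to multiple transcripts of one gene is counted once,
    against a transcript giving it a splice-site termination when one exists.
    Per-gene significance uses the raw binomial p against ``p_threshold``
    (no multiplicity adjustment); the combined statistic aggregates all genes.
    """
    fragments = list(fragments)
    if background is None:
        background = background_size_distribution(
            fragments, transcripts, full_length_fraction
        )
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    # bucket fragments by chrom/strand, sorted by leftmost coordinate, so each
    # gene only inspects fragments inside its genomic footprint
    import bisect as _bisect

    frag_index: dict[tuple[str, str], tuple[list[int], list[PairedFragment]]] = {}
    for frag in fragments:
        key = (frag.chrom, frag.strand)
        frag_index.setdefault(key, ([], []))
    for key in frag_index:
        matching = [f for f in fragments if (f.chrom, f.strand) == key]
        matching.sort(key=lambda f: min(f.pos5, f.pos3))
        frag_index[key] = ([min(f.pos5, f.pos3) for f in matching], matching)

    results: list[GeneTerminationResult] = []
    for gene_id, txs in by_gene.items():
        n = k = 0
        anchors_by_tx: dict[str, list[int]] = {}
        lo = min(t.start for t in txs)
        hi = max(t.end for t in txs)
        starts, bucket = frag_index.get((txs[0].chrom, txs[0].strand), ([], []))
        i0 = _bisect.bisect_left(starts, lo)
        i1 = _bisect.bisect_right(starts, hi)
        for frag in bucket[i0:i1]:
            hit = None  # (tx, coords, terminated)
            for tx in txs:
                coords = _fragment_tx_coords(frag, tx)
                if coords is None:
                    continue
                sites = tx.splice_sites_tx()
                terminated = any(abs(coords[1] - s) <= tolerance for s in sites)
                if hit is None or (terminated and not hit[2]):
                    hit = (tx, coords, terminated)
                if terminated:
                    break
            if hit is None:
                continue
            n += 1
            k += int(hit[2])
            anchors_by_tx.setdefault(hit[0].transcript_id, []).append(hit[1][0])
        if n == 0:
            continue
        p_parts = []
        tx_by_id = {t.transcript_id: t for t in txs}
        for tid, anchors in anchors_by_tx.items():
            tx = tx_by_id[tid]
            p_tx = background_probability(anchors, tx, background, tolerance)
            p_parts.extend([p_tx] * len(anchors))
        p0 = float(np.mean(p_parts))
        pval = gene_termination_test(n, k, p0)
        results.append(GeneTerminationResult(gene_id, n, k, p0, pval))
    combined = combined_significance([r.pval for r in results]) if results else \
        CombinedSignificance(0.0, 0, 1.0, 0.0, "1")
    return results, combined
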