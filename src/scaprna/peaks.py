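"""Density-based clustering of 5'-end tag positions into transcription
initiation peaks, peak filtering, gene association, and count-matrix assembly.

The clustering follows the classic hierarchical density formulation: a segment
of tag sites is valid at density d when every prefix and every suffix of the
segment (delimited by sites, inclusive of the whole segment) has tag density
>= d, where the density of a site run is its total tag count divided by its
genomic span in bp.  Single-site segments are unconditionally valid.  A
cluster is a segment that is the maximal valid segment for some d >= 0, and is
reported with the density range [d_min, d_max) over which it is maximal.
Clusters are nested; nesting is resolved after the tag-count filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CappedTag, GenomicInterval, TranscriptModel, ValidationError


@dataclass
class Cluster:
    """A strand-specific tag cluster with its density range."""

    chrom: str
    strand: str
    start: int  # genomic start (position of first site)
    end: int  # half-open end (last site + 1)
    total: int
    n_sites: int
    d_min: float
    d_max: float  # may be +inf for single-site clusters

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def density(self) -> float:
        return self.total / (self.end - self.start)


def paraclu_clusters(
    sites: Sequence[tuple[int, float]],
    chrom: str = "chr",
    strand: str = "+",
) -> list[Cluster]:
    """Cluster sorted (position, count) sites on one chromosome and strand.

    Returns every maximal-at-some-density segment with its density range,
    including nested clusters, ordered by (start, -length).
    """
    if not sites:
        return []
    positions = np.array([p for p, _ in sites], dtype=np.int64)
    counts = np.array([c for _, c in sites], dtype=float)
    if np.any(counts < 1):
        raise ValidationError("site counts must be >= 1")
    if np.any(np.diff(positions) <= 0):
        raise ValidationError("site positions must be strictly increasing")
    csum = np.concatenate([[0.0], np.cumsum(counts)])

    out: list[Cluster] = []

    def seg_total(i: int, j: int) -> float:
        return csum[j + 1] - csum[i]

    def weakest(i: int, j: int) -> tuple[float, int]:
        """Min density over all prefixes/suffixes of sites i..j (inclusive of
        the whole segment) and the split index after which the weakest proper
        prefix ends (or before which the weakest proper suffix starts)."""
        # prefixes i..k
        ks = np.arange(i, j + 1)
        pref = (csum[ks + 1] - csum[i]) / (positions[ks] - positions[i] + 1)
        suff = (csum[j + 1] - csum[ks]) / (positions[j] - positions[ks] + 1)
        d_max = float(min(pref.min(), suff.min()))
        # split at the weakest proper boundary
        pref_prop = pref[:-1]
        suff_prop = suff[1:]
        pmin = pref_prop.min() if len(pref_prop) else math.inf
        smin = suff_prop.min() if len(suff_prop) else math.inf
        if pmin <= smin:
            split = i + int(np.argmin(pref_prop))  # last site of the left part
        else:
            split = i + int(np.argmin(suff_prop))  # split before this suffix
        return d_max, split

    # iterative DFS to avoid recursion limits on long chains
    stack = [(0, len(sites) - 1, 0.0)]
    while stack:
        i, j, d_min = stack.pop()
        if i == j:
            out.append(
                Cluster(
                    chrom,
                    strand,
                    int(positions[i]),
                    int(positions[i]) + 1,
                    int(round(seg_total(i, j))),
                    1,
                    d_min,
                    math.inf,
                )
            )
            continue
        d_max, split = weakest(i, j)
        if d_max > d_min:
            out.append(
                Cluster(
                    chrom,
                    strand,
                    int(positions[i]),
                    int(positions[j]) + 1,
                    int(round(seg_total(i, j))),
                    j - i + 1,
                    d_min,
                    d_max,
                )
            )
            child_min = d_max
        else:
            child_min = d_min
        stack.append((i, split, child_min))
        stack.append((split + 1, j, child_min))

    out.sort(key=lambda c: (c.start, -(c.end - c.start)))
    return out


def cluster_tags(
    tags: Iterable[CappedTag],
    assays: Optional[set[str]] = None,
) -> list[Cluster]:
    """Pool tag counts by (chrom, strand, pos5) and cluster each group."""
    pooled: dict[tuple[str, str], dict[int, float]] = {}
    for tag in tags:
        if assays is not None and tag.assay not in assays:
            continue
        key = (tag.chrom, tag.strand)
        sites = pooled.setdefault(key, {})
        sites[tag.pos5] = sites.get(tag.pos5, 0) + tag.count
    out: list[Cluster] = []
    for (chrom, strand), sites in sorted(pooled.items()):
        ordered = sorted(sites.items())
        out.extend(paraclu_clusters(ordered, chrom, strand))
    return out


def filter_peaks(
    clusters: list[Cluster],
    min_tags: int = 10,
    max_length: Optional[int] = None,
    max_density_ratio: Optional[float] = None,
) -> list[Cluster]:
    """Keep clusters with at least ``min_tags`` tags and resolve nesting.

    Optional maximum-length and density-stability (d_max/d_min) filters are
    off by default.  Nested retained clusters are resolved to the largest
    non-nested set by keeping, within any nested chain, the cluster with the
    highest d_min.
    """
    if min_tags < 1:
        raise ValidationError("min_tags must be >= 1")
    kept = [c for c in clusters if c.total >= min_tags]
    if max_length is not None:
        kept = [c for c in kept if (c.end - c.start) <= max_length]
    if max_density_ratio is not None:
        kept = [
            c
            for c in kept
            if c.d_min > 0 and c.d_max / c.d_min <= max_density_ratio
        ]
    # drop any cluster that strictly contains another retained cluster on the
    # same chrom/strand; survivors are the innermost (highest d_min) and are
    # mutually non-nested
    result = []
    for c in kept:
        contains_other = any(
            o is not c
            and o.chrom == c.chrom
            and o.strand == c.strand
            and c.start <= o.start
            and o.end <= c.end
            and (o.start, o.end) != (c.start, c.end)
            for o in kept
        )
        if not contains_other:
            result.append(c)
    result.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return result


def build_count_matrix(
    peaks: list[Cluster],
    tags: Iterable[CappedTag],
) -> tuple[pd.DataFrame, int]:
    """Count tags per peak per (sample, assay) column.

    A tag contributes to the unique same-strand peak containing its 5'
    position; tags outside all peaks are dropped and tallied.  Returns the
    counts DataFrame (rows = peak ids "chrom:start-end(strand)") and the
    number of dropped tags.
    """
    peak_ids = [f"{p.chrom}:{p.start}-{p.end}({p.strand})" for p in peaks]
    index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, list[int]]] = {}
    by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for i, p in enumerate(peaks):
        by_key.setdefault((p.chrom, p.strand), []).append((p.start, p.end, i))
    for key, ivs in by_key.items():
        ivs.sort()
        starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
        idxs = [i for _, _, i in ivs]
        index[key] = (starts, ends, idxs)

    cells: dict[tuple[int, tuple[str, str]], int] = {}
    columns: set[tuple[str, str]] = set()
    dropped = 0
    for tag in tags:
        columns.add((tag.sample_id, tag.assay))
        entry = index.get((tag.chrom, tag.strand))
        if entry is None:
            dropped += tag.count
            continue
        starts, ends, idxs = entry
        k = int(np.searchsorted(starts, tag.pos5, side="right")) - 1
        if k >= 0 and tag.pos5 < ends[k]:
            cell = (idxs[k], (tag.sample_id, tag.assay))
            cells[cell] = cells.get(cell, 0) + tag.count
        else:
            dropped += tag.count
    cols = pd.MultiIndex.from_tuples(sorted(columns), names=["sample", "assay"])
    mat = pd.DataFrame(0, index=peak_ids, columns=cols, dtype=np.int64)
    for (row, col), value in cells.items():
        mat.loc[peak_ids[row], col] = value
    return mat, dropped


@dataclass
class GeneAssociation:
    peak_id: str
    gene_id: Optional[str]
    orientation: Optional[str]  # "sense" (antisense associations not assigned)
    offset: Optional[int]  # peak 5' mode - gene TSS, strand-aware (downstream > 0)


def peak_mode(
    peak: Cluster, tags: Iterable[CappedTag]
) -> int:
    """Position with the highest pooled tag count inside the peak; ties go to
    the 5'-most position (strand-aware)."""
    counts: dict[int, int] = {}
    for tag in tags:
        if (
            tag.chrom == peak.chrom
            and tag.strand == peak.strand
            and peak.start <= tag.pos5 < peak.end
        ):
            counts[tag.pos5] = counts.get(tag.pos5, 0) + tag.count
    if not counts:
        return peak.start if peak.strand == "+" else peak.end - 1
    best = max(counts.values())
    modes = [p for p, c in counts.items() if c == best]
    return min(modes) if peak.strand == "+" else max(modes)


def assign_peaks_to_genes(
    peaks: list[Cluster],
    transcripts: list[TranscriptModel],
    tags: Iterable[CappedTag],
    promoter_halfwidth: int = 500,
) -> tuple[list[GeneAssociation], np.ndarray]:
    """Sense-associate peaks with genes through promoter-proximal 5' modes.

    A peak is associated with a gene when its modal 5' position lies within
    +/- ``promoter_halfwidth`` of any of the gene's transcript TSSs on the
    same strand; the nearest TSS wins ties.  Offsets are strand-aware with
    downstream positive.  Also returns the offset histogram over
    [-halfwidth, +halfwidth].
    """
    tags = list(tags)
    tss_by_key: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for tx in transcripts:
        tss_by_key.setdefault((tx.chrom, tx.strand), []).append((tx.tss, tx.gene_id))
    for entries in tss_by_key.values():
        entries.sort()

    out: list[GeneAssociation] = []
    offsets: list[int] = []
    for peak in peaks:
        pid = f"{peak.chrom}:{peak.start}-{peak.end}({peak.strand})"
        entries = tss_by_key.get((peak.chrom, peak.strand), [])
        mode = peak_mode(peak, tags)
        best: Optional[tuple[int, int, str]] = None  # (|offset|, offset, gene)
        for tss, gene_id in entries:
            dist = abs(mode - tss)
            if dist > promoter_halfwidth:
                continue
            offset = mode - tss if peak.strand == "+" else tss - mode
            cand = (dist, offset, gene_id)
            if best is None or cand < best:
                best = cand
        if best is None:
            out.append(GeneAssociation(pid, None, None, None))
        else:
            out.append(GeneAssociation(pid, best[2], "sense", best[1]))
            offsets.append(best[1])
    hist = np.zeros(2 * promoter_halfwidth + 1, dtype=np.int64)
    for off in offsets:
        hist[off + promoter_halfwidth] += 1
    return out, hist
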