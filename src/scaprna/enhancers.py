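"""Bidirectional enhancer prediction from 5'-end tag data.

Enhancers are called as divergent pairs of strand-specific tag clusters
(reverse-strand cluster to the left, forward-strand cluster to the right)
outside an exclusion mask of exons and TSS-proximal windows.  The
directionality score |F - R| / (F + R) of forward/reverse tag counts around
the locus midpoint must stay below a balance threshold.  Down-sampling
saturation curves re-run the caller on binomially thinned tag sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CappedTag,
    GenomicInterval,
    IntervalLookup,
    TranscriptModel,
    ValidationError,
    merge_intervals,
)
from .peaks import Cluster, cluster_tags, filter_peaks


#: Biotypes whose TSS-proximal windows are NOT excluded from enhancer calling.
TSS_WINDOW_EXEMPT = frozenset({"snRNA", "scRNA", "snoRNA"})


@dataclass
class EnhancerLocus:
    chrom: str
    center: int
    start: int  # center - flank
    end: int  # center + flank
    forward: int  # forward tags right of center
    reverse: int  # reverse tags left of center
    provenance: frozenset[str] = frozenset()

    @property
    def directionality(self) -> float:
        total = self.forward + self.reverse
        return abs(self.forward - self.reverse) / total if total else 1.0

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, ".")


def build_exclusion_mask(
    transcripts: Sequence[TranscriptModel],
    tss_halfwidth: int = 500,
) -> list[GenomicInterval]:
    """Merged union of all exons plus TSS +/- ``tss_halfwidth`` windows.

    TSS windows of snRNA, scRNA and snoRNA genes are omitted; their exons are
    still masked.
    """
    pieces: list[GenomicInterval] = []
    for tx in transcripts:
        pieces.extend(
            GenomicInterval(e.chrom, e.start, e.end, ".") for e in tx.exons
        )
        if tx.biotype not in TSS_WINDOW_EXEMPT:
            start = max(0, tx.tss - tss_halfwidth)
            pieces.append(GenomicInterval(tx.chrom, start, tx.tss + tss_halfwidth + 1, "."))
    return merge_intervals(pieces) if pieces else []


def call_bidirectional(
    tags: Iterable[CappedTag],
    mask: Sequence[GenomicInterval] = (),
    pair_window: int = 400,
    center_flank: int = 200,
    directionality_max: float = 0.8,
    min_tags: int = 5,
    cluster_min_tags: int = 5,
) -> list[EnhancerLocus]:
    """Call balanced bidirectional loci from (already filtered) tags.

    Tags are pre-clustered per strand with the density clusterer; divergent
    cluster pairs whose inner edges are at most ``pair_window`` apart define
    candidate centers at the midpoint of the inner edges.  Forward tags in
    (center, center+flank] and reverse tags in [center-flank, center) are
    counted; a locus is reported when F + R >= min_tags, directionality
    < directionality_max, and its +/- flank window misses the mask.
    Overlapping loci are merged keeping the most balanced one.
    """
    tags = [t for t in tags if not t.multimapped]
    lookup = IntervalLookup(mask) if mask else None
    clusters = filter_peaks(cluster_tags(tags), min_tags=cluster_min_tags)
    by_chrom: dict[str, dict[str, list[Cluster]]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, {"+": [], "-": []})[c.strand].append(c)

    # per-chromosome position->count maps per strand for flank counting
    pos_counts: dict[tuple[str, str], dict[int, int]] = {}
    for t in tags:
        d = pos_counts.setdefault((t.chrom, t.strand), {})
        d[t.pos5] = d.get(t.pos5, 0) + t.count

    def window_count(chrom: str, strand: str, lo: int, hi: int) -> int:
        d = pos_counts.get((chrom, strand), {})
        return sum(c for p, c in d.items() if lo <= p < hi)

    candidates: list[EnhancerLocus] = []
    for chrom, strands in by_chrom.items():
        rev = sorted(strands["-"], key=lambda c: c.start)
        fwd = sorted(strands["+"], key=lambda c: c.start)
        for rc in rev:
            for fc in fwd:
                gap = fc.start - rc.end
                if gap < 0:
                    continue
                if gap > pair_window:
                    break  # fwd sorted by start: later pairs are wider
                center = (rc.end + fc.start) // 2
                start = center - center_flank
                end = center + center_flank
                if start < 0:
                    continue
                if lookup is not None and lookup.intersects(chrom, start, end):
                    continue
                forward = window_count(chrom, "+", center, end)
                reverse = window_count(chrom, "-", start, center)
                locus = EnhancerLocus(chrom, center, start, end, forward, reverse)
                if forward + reverse < min_tags:
                    continue
                if locus.directionality >= directionality_max:
                    continue
                candidates.append(locus)

    # merge overlapping loci, keeping the most balanced (then most tags)
    candidates.sort(key=lambda l: (l.chrom, l.start))
    merged: list[EnhancerLocus] = []
    for locus in candidates:
        if merged and merged[-1].chrom == locus.chrom and locus.start < merged[-1].end:
            prev = merged[-1]
            best = min(
                (prev, locus),
                key=lambda l: (l.directionality, -(l.forward + l.reverse)),
            )
            merged[-1] = best
        else:
            merged.append(locus)
    return merged


def merge_enhancer_sets(
    sets: dict[str, Sequence[GenomicInterval]],
) -> list[tuple[GenomicInterval, frozenset[str]]]:
    """Merge labelled enhancer region sets into a joint set with provenance.

    Regions overlapping by >=1 bp (transitively) unify into one region whose
    provenance is the union of the contributing labels.
    """
    tagged: list[tuple[str, int, int, str]] = []
    for label, regions in sets.items():
        for iv in regions:
            tagged.append((iv.chrom, iv.start, iv.end, label))
    tagged.sort()
    out: list[tuple[GenomicInterval, frozenset[str]]] = []
    cur: Optional[tuple[str, int, int, set[str]]] = None
    for chrom, start, end, label in tagged:
        if cur is not None and cur[0] == chrom and start < cur[2]:
            cur = (chrom, cur[1], max(cur[2], end), cur[3] | {label})
        else:
            if cur is not None:
                out.append((GenomicInterval(cur[0], cur[1], cur[2], "."),
                            frozenset(cur[3])))
            cur = (chrom, start, end, {label})
    if cur is not None:
        out.append((GenomicInterval(cur[0], cur[1], cur[2], "."),
                    frozenset(cur[3])))
    return out


def provenance_counts(
    joint: Sequence[tuple[GenomicInterval, frozenset[str]]],
) -> dict[frozenset[str], int]:
    """Count joint regions per provenance label combination."""
    out: dict[frozenset[str], int] = {}
    for _, labels in joint:
        out[labels] = out.get(labels, 0) + 1
    return out


def enhancer_expression(
    joint: Sequence[tuple[GenomicInterval, frozenset[str]]],
    tags: Iterable[CappedTag],
) -> pd.DataFrame:
    """Strand-agnostic tag counts per joint enhancer per (sample, assay).

    A tag contributes to a region when its 5' position lies inside it,
    regardless of strand.  Rows are "chrom:start-end" region ids.
    """
    regions = [iv for iv, _ in joint]
    ids = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in regions]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(regions):
        per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        by_chrom[chrom] = (
            np.array([s for s, _, _ in ivs], dtype=np.int64),
            np.array([e for _, e, _ in ivs], dtype=np.int64),
            [i for _, _, i in ivs],
        )
    cells: dict[tuple[int, tuple[str, str]], int] = {}
    columns: set[tuple[str, str]] = set()
    for tag in tags:
        columns.add((tag.sample_id, tag.assay))
        entry = by_chrom.get(tag.chrom)
        if entry is None:
            continue
        starts, ends, idxs = entry
        k = int(np.searchsorted(starts, tag.pos5, side="right")) - 1
        if k >= 0 and tag.pos5 < ends[k]:
            cell = (idxs[k], (tag.sample_id, tag.assay))
            cells[cell] = cells.get(cell, 0) + tag.count
    cols = pd.MultiIndex.from_tuples(sorted(columns), names=["sample", "assay"])
    mat = pd.DataFrame(0, index=ids, columns=cols, dtype=np.int64)
    for (row, col), value in cells.items():
        mat.loc[ids[row], col] = value
    return mat


def saturation_curve(
    tags: Sequence[CappedTag],
    fractions: Sequence[float],
    n_reps: int = 3,
    seed: int = 0,
    mask: Sequence[GenomicInterval] = (),
    **call_kwargs,
) -> pd.DataFrame:
    """Down-sampling saturation of enhancer discovery.

    Tags are thinned binomially per fraction and the caller re-run; fraction
    1.0 uses the full tag set exactly (no resampling).  Returns a table with
    columns fraction, mean_enhancers, sd_enhancers.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValidationError("fractions must lie in (0, 1]")
        counts_per_rep = []
        reps = 1 if frac == 1.0 else n_reps
        for _ in range(reps):
            if frac == 1.0:
                thinned = list(tags)
            else:
                thinned = []
                for t in tags:
                    kept = int(rng.binomial(t.count, frac))
                    if kept > 0:
                        thinned.append(
                            CappedTag(t.sample_id, t.assay, t.chrom, t.strand,
                                      t.pos5, kept, t.multimapped, t.first_base)
                        )
            loci = call_bidirectional(thinned, mask, **call_kwargs)
            counts_per_rep.append(len(loci))
        rows.append(
            {
                "fraction": frac,
                "mean_enhancers": float(np.mean(counts_per_rep)),
                "sd_enhancers": float(np.std(counts_per_rep, ddof=1))
                if len(counts_per_rep) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
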