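"""RNA-class assignment via the ordered alignment cascade, priority-ordered
genomic categorization, downstream exclusion sets, and the unencoded-5'-G
profile.

The cascade aligns each query against reference RNA sets in a fixed order
(mitochondrial genome, rRNA, tRNA, snRNA, scRNA, snoRNA, Ro-associated,
histone mRNA, RMRP, scaRNA, RPPH1, snaR, TERC, vault RNA, MALAT1 isoforms,
host genes).  The first set containing a passing alignment wins; a query that
passes no set is "unassigned" and falls through to genomic categorization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .align import AlignParams, AlignmentResult, best_alignment
from .core import CappedTag, GenomicInterval, IntervalLookup, ValidationError

logger = logging.getLogger(__name__)

#: Default cascade order of reference target sets.
CASCADE_ORDER = (
    "chrM",
    "rRNA",
    "tRNA",
    "snRNA",
    "scRNA",
    "snoRNA",
    "roRNA",
    "histone_mRNA",
    "RMRP",
    "scaRNA",
    "RPPH1",
    "snaR",
    "TERC",
    "vaultRNA",
    "MALAT1",
    "host_gene",
)

#: RNA classes whose reads (and precursor reads) are excluded from peak
#: quantification and enhancer prediction.
EXCLUDED_CLASSES = frozenset(
    {
        "chrM",
        "rRNA",
        "tRNA",
        "snoRNA",
        "scaRNA",
        "snRNA",
        "scRNA",
        "roRNA",
        "vaultRNA",
        "snaR",
        "histone_mRNA",
        "short_rna_precursor",
    }
)


@dataclass
class ClassAssignment:
    query_id: str
    rna_class: str  # target-set label or "unassigned"
    genomic_category: Optional[str] = None
    alignment: Optional[AlignmentResult] = None


def cascade_classify(
    query: str,
    ordered_target_sets: Sequence[tuple[str, list[tuple[str, str]]]],
    params: AlignParams = AlignParams(),
    query_id: str = "query",
) -> ClassAssignment:
    """Assign a query sequence to the first reference set it aligns to.

    ``ordered_target_sets`` is a list of (set_label, [(target_id, sequence)]).
    Within the winning set, ties are broken by highest score, then shortest
    target, then shortest extent along the target, then smallest start.
    """
    if not ordered_target_sets:
        raise ValidationError("cascade needs at least one target set")
    for label, targets in ordered_target_sets:
        res = best_alignment(query, targets, params, query_id)
        if res is not None:
            return ClassAssignment(query_id, label, alignment=res)
    return ClassAssignment(query_id, "unassigned")


class RegionSet:
    """A labelled interval set for priority-ordered categorization.

    ``strand_mode`` is None for strand-agnostic sets, "sense" to require the
    tag on the region strand, and "antisense" to require the opposite strand.
    """

    def __init__(
        self,
        label: str,
        intervals: Iterable[GenomicInterval],
        strand_mode: Optional[str] = None,
    ) -> None:
        self.label = label
        self.strand_mode = strand_mode
        if strand_mode is None:
            self._lookup = {None: IntervalLookup(intervals)}
        else:
            by_strand: dict[str, list[GenomicInterval]] = {"+": [], "-": []}
            for iv in intervals:
                if iv.strand not in ("+", "-"):
                    raise ValidationError(
                        f"{label}: stranded region set needs +/- strands"
                    )
                by_strand[iv.strand].append(iv)
            self._lookup = {s: IntervalLookup(ivs) for s, ivs in by_strand.items()}

    def contains_tag(self, tag: CappedTag) -> bool:
        if self.strand_mode is None:
            return self._lookup[None].contains(tag.chrom, tag.pos5)
        region_strand = tag.strand
        if self.strand_mode == "antisense":
            region_strand = "-" if tag.strand == "+" else "+"
        lookup = self._lookup.get(region_strand)
        return lookup is not None and lookup.contains(tag.chrom, tag.pos5)


def region_categorize(
    tag: CappedTag,
    region_sets: Sequence[RegionSet],
    fallback: str = "other_intergenic",
) -> str:
    """First-overlap-wins category assignment over an ordered region list."""
    for rset in region_sets:
        if rset.contains_tag(tag):
            return rset.label
    return fallback


def categorize_tags(
    tags: Iterable[CappedTag],
    region_sets: Sequence[RegionSet],
) -> list[str]:
    return [region_categorize(tag, region_sets) for tag in tags]


def build_exclusion_set(
    assignments: dict[str, ClassAssignment],
    multimapped_ids: Iterable[str] = (),
    excluded_classes: frozenset[str] = EXCLUDED_CLASSES,
) -> set[str]:
    """Ids excluded from peak quantification and enhancer prediction:
    multimapping reads plus reads assigned to the excluded RNA classes."""
    excluded = set(multimapped_ids)
    for qid, assignment in assignments.items():
        if assignment.rna_class in excluded_classes:
            excluded.add(qid)
    return excluded


def filter_tags(
    tags: Iterable[CappedTag],
    tag_classes: Optional[dict[int, str]] = None,
    excluded_classes: frozenset[str] = EXCLUDED_CLASSES,
) -> list[CappedTag]:
    """Drop multimapped tags and tags of excluded RNA classes.

    ``tag_classes`` maps the index of a tag in the input iterable to its RNA
    class; tags without an entry are treated as unassigned (retained).
    """
    out = []
    for i, tag in enumerate(tags):
        if tag.multimapped:
            continue
        cls = (tag_classes or {}).get(i)
        if cls is not None and cls in excluded_classes:
            continue
        out.append(tag)
    return out


def first_base_g_profile(
    tags: Iterable[CappedTag],
    genome: dict[str, str],
) -> dict[str, dict[str, float]]:
    """Per-assay fraction of reads whose first base is an unencoded G.

    A read contributes to the unencoded-G fraction when its sequenced first
    base is G but the genome at its 5' position is not G (strand-aware);
    the genome-matching fraction is reported alongside.  Tags without a
    recorded first base or beyond the chromosome end are skipped.
    """
    totals: dict[str, int] = {}
    unencoded_g: dict[str, int] = {}
    matching: dict[str, int] = {}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for tag in tags:
        if tag.first_base is None:
            continue
        seq = genome.get(tag.chrom)
        if seq is None or tag.pos5 >= len(seq):
            logger.warning("tag at %s:%d beyond chromosome end; skipped",
                           tag.chrom, tag.pos5)
            continue
        ref = seq[tag.pos5].upper()
        if tag.strand == "-":
            ref = comp.get(ref, "N")
        totals[tag.assay] = totals.get(tag.assay, 0) + tag.count
        if tag.first_base == ref:
            matching[tag.assay] = matching.get(tag.assay, 0) + tag.count
        elif tag.first_base == "G":
            unencoded_g[tag.assay] = unencoded_g.get(tag.assay, 0) + tag.count
    out: dict[str, dict[str, float]] = {}
    for assay, n in totals.items():
        out[assay] = {
            "unencoded_g": unencoded_g.get(assay, 0) / n,
            "genome_match": matching.get(assay, 0) / n,
            "n": float(n),
        }
    return out
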