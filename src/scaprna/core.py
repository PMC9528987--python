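"""Core genomic domain types shared by every pipeline stage.

All coordinates are 0-based, half-open ([start, end)) everywhere in memory,
matching BED on disk.  The 5' position of a minus-strand feature is ``end - 1``
so that single-base 5'-end observations are symmetric between strands.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

#: Controlled vocabulary of transcript biotypes.  Unknown labels map to "other".
BIOTYPES = (
    "mRNA",
    "lncRNA",
    "snRNA",
    "snoRNA",
    "scaRNA",
    "scRNA",
    "tRNA",
    "histone_mRNA",
    "roRNA",
    "vaultRNA",
    "snaR",
    "host_gene",
    "other",
)

ASSAYS = ("short", "long", "startseq")


class ValidationError(ValueError):
    """Raised when a record violates a format or domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    @property
    def pos5(self) -> int:
        """Genomic position of the 5'-most base (strand-aware)."""
        return self.start if self.strand != "-" else self.end - 1

    @property
    def pos3(self) -> int:
        return self.end - 1 if self.strand != "-" else self.start


@dataclass
class TranscriptModel:
    """A stranded exon-chain transcript annotation.

    Exons are non-overlapping, sorted by genomic start, and all on one
    chromosome and strand.  ``tss`` is the genomic position of the 5'-most
    transcribed base; splice-site coordinates are derived from the exon chain.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >=1 exon")
        if self.biotype not in BIOTYPES:
            self.biotype = "other"
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValidationError(
                f"{self.transcript_id}: exons must share one chrom and strand"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def splice_sites_tx(self) -> list[int]:
        """Transcript-space positions of the last base of each non-terminal exon
        (donor sites), in transcript orientation."""
        lengths = [len(e) for e in self.exons]
        if self.strand == "-":
            lengths = lengths[::-1]
        out, cum = [], 0
        for length in lengths[:-1]:
            cum += length
            out.append(cum - 1)
        return out

    def acceptor_sites_tx(self) -> list[int]:
        """Transcript-space positions of the first base of each non-initial exon."""
        lengths = [len(e) for e in self.exons]
        if self.strand == "-":
            lengths = lengths[::-1]
        out, cum = [], 0
        for length in lengths[:-1]:
            cum += length
            out.append(cum)
        return out

    def genomic_to_tx(self, pos: int) -> Optional[int]:
        """Map a genomic position to a transcript-space offset.

        Returns ``None`` when the position falls in an intron or outside the
        transcript footprint.
        """
        cum = 0
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for exon in exons:
            if exon.start <= pos < exon.end:
                if self.strand == "+":
                    return cum + (pos - exon.start)
                return cum + (exon.end - 1 - pos)
            cum += len(exon)
        return None

    def tx_to_genomic(self, offset: int) -> int:
        """Map a transcript-space offset to a genomic position."""
        if not 0 <= offset < self.spliced_length:
            raise ValidationError(
                f"{self.transcript_id}: transcript offset {offset} out of range"
            )
        cum = 0
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for exon in exons:
            if offset < cum + len(exon):
                within = offset - cum
                if self.strand == "+":
                    return exon.start + within
                return exon.end - 1 - within
            cum += len(exon)
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class CappedTag:
    """One aligned 5'-end observation (possibly aggregated over reads)."""

    sample_id: str
    assay: str
    chrom: str
    strand: str
    pos5: int
    count: int = 1
    multimapped: bool = False
    first_base: Optional[str] = None  # sequenced first base, for cap-G profiling

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"tag strand must be +/-, got {self.strand!r}")
        if self.count < 1:
            raise ValidationError("tag count must be >= 1")
        if self.pos5 < 0:
            raise ValidationError("pos5 must be >= 0")


@dataclass(frozen=True)
class PairedFragment:
    """A paired 5'/3'-end observation with its transcript-space size."""

    sample_id: str
    chrom: str
    strand: str
    pos5: int
    pos3: int
    size: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"fragment strand must be +/-, got {self.strand!r}")
        if self.strand == "+" and self.pos5 > self.pos3:
            raise ValidationError("plus-strand fragment needs pos5 <= pos3")
        if self.strand == "-" and self.pos3 > self.pos5:
            raise ValidationError("minus-strand fragment needs pos3 <= pos5")
        if self.size < 1:
            raise ValidationError("fragment size must be >= 1")


class SignalTrack:
    """Piecewise-constant non-negative signal with bedGraph semantics.

    Positions absent from the track have value 0.  Intervals are stored merged
    and sorted per chromosome.
    """

    def __init__(self) -> None:
        # chrom -> (starts, ends, values) as sorted numpy arrays
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if start < 0 or end <= start:
                raise ValidationError(f"bad track interval {chrom}:{start}-{end}")
            if value < 0:
                raise ValidationError("track values must be >= 0")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        track = cls()
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1, _), (s2, e2, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"overlapping track intervals on {chrom}: "
                        f"[{s1},{e1}) and [{s2},{e2})"
                    )
            starts = np.array([iv[0] for iv in ivs], dtype=np.int64)
            ends = np.array([iv[1] for iv in ivs], dtype=np.int64)
            values = np.array([iv[2] for iv in ivs], dtype=float)
            track._data[chrom] = (starts, ends, values)
        return track

    def chroms(self) -> list[str]:
        return sorted(self._data)

    def records(self) -> list[tuple[str, int, int, float]]:
        out = []
        for chrom in self.chroms():
            starts, ends, values = self._data[chrom]
            out.extend(
                (chrom, int(s), int(e), float(v))
                for s, e, v in zip(starts, ends, values)
            )
        return out

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base values over [start, end)."""
        if chrom not in self._data or end <= start:
            return 0.0
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        overlap = np.maximum(e - s, 0)
        return float(np.sum(overlap * values[lo:hi]))


@dataclass
class SNPTable:
    """Positions of SNP loci with a GWAS-trait association flag."""

    chroms: list[str]
    positions: np.ndarray  # int64
    gwas: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.gwas = np.asarray(self.gwas, dtype=bool)
        if not (len(self.chroms) == len(self.positions) == len(self.gwas)):
            raise ValidationError("SNP table columns must have equal length")
        seen: dict[str, set[int]] = {}
        for c, p in zip(self.chroms, self.positions):
            bucket = seen.setdefault(c, set())
            if int(p) in bucket:
                raise ValidationError(f"duplicate SNP position {c}:{p}")
            bucket.add(int(p))

    def __len__(self) -> int:
        return len(self.positions)


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Union of intervals, merged per chromosome (strand-agnostic)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end, "."))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end, "."))
    return out


class IntervalLookup:
    """Fast point/interval overlap queries against a merged interval set."""

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for iv in merge_intervals(intervals):
            starts, ends = self._by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def contains(self, chrom: str, pos: int) -> bool:
        if chrom not in self._by_chrom:
            return False
        starts, ends = self._by_chrom[chrom]
        i = bisect.bisect_right(starts, pos) - 1
        return i >= 0 and pos < ends[i]

    def intersects(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._by_chrom or end <= start:
            return False
        starts, ends = self._by_chrom[chrom]
        i = bisect.bisect_left(starts, end)
        return i > 0 and ends[i - 1] > start
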