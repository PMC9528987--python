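"""Readers and writers for the on-disk formats the pipeline touches.

BED6/BED12 and bedGraph follow the usual UCSC conventions (0-based half-open).
Tag files are a TSV dialect with the header::

    sample  assay  chrom  strand  pos5  [pos3]  count  multimapped  [first_base]

Single-end files omit the ``pos3`` column; paired-end files include it.
Identical records are aggregated on read by summing their counts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    CappedTag,
    GenomicInterval,
    PairedFragment,
    SignalTrack,
    SNPTable,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def read_bed6(path: PathLike) -> list[tuple[GenomicInterval, float]]:
    """Read a BED6 file into (interval, score) pairs."""
    out: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValidationError(
                    f"{path}:{lineno}: expected >=6 tab-separated fields"
                )
            chrom, start, end, _name, score, strand = fields[:6]
            try:
                interval = GenomicInterval(chrom, int(start), int(end), strand)
                score_val = float(score)
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            out.append((interval, score_val))
    return out


def write_bed6(
    path: PathLike,
    records: Iterable[tuple[GenomicInterval, float]],
    names: Optional[Iterable[str]] = None,
) -> None:
    records = list(records)
    if names is None:
        names = [f"region_{i}" for i in range(len(records))]
    with open(path, "w") as fh:
        for name, (iv, score) in zip(names, records):
            score_str = f"{int(score)}" if float(score).is_integer() else f"{score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score_str}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Transcript models (BED12 dialect; biotype and gene id in the name field)
# ---------------------------------------------------------------------------

def read_transcripts(path: PathLike) -> list[TranscriptModel]:
    """Read transcript models from a BED12 file.

    The name column encodes ``transcript_id|gene_id|biotype``.  Exon blocks
    follow BED12 blockStarts/blockSizes; unknown biotypes map to "other" with
    a warning.
    """
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValidationError(
                    f"{path}:{lineno}: expected 12 tab-separated fields"
                )
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            name, strand = fields[3], fields[5]
            block_count = int(fields[9])
            block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(block_sizes) != block_count or len(block_starts) != block_count:
                raise ValidationError(f"{path}:{lineno}: inconsistent block fields")
            parts = name.split("|")
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: name must be transcript_id|gene_id|biotype"
                )
            tid, gid, biotype = parts
            exons = []
            for bs, sz in zip(block_starts, block_sizes):
                estart = start + bs
                eend = estart + sz
                if eend > end:
                    raise ValidationError(
                        f"{path}:{lineno}: exon block extends past transcript end"
                    )
                exons.append(GenomicInterval(chrom, estart, eend, strand))
            from .core import BIOTYPES

            if biotype not in BIOTYPES:
                logger.warning(
                    "%s:%d: unknown biotype %r mapped to 'other'", path, lineno, biotype
                )
            try:
                out.append(TranscriptModel(tid, gid, biotype, exons))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_transcripts(path: PathLike, transcripts: Iterable[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            sizes = ",".join(str(len(e)) for e in tx.exons)
            starts = ",".join(str(e.start - tx.start) for e in tx.exons)
            name = f"{tx.transcript_id}|{tx.gene_id}|{tx.biotype}"
            fh.write(
                f"{tx.chrom}\t{tx.start}\t{tx.end}\t{name}\t0\t{tx.strand}\t"
                f"{tx.start}\t{tx.end}\t0\t{len(tx.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# Tag files
# ---------------------------------------------------------------------------

_SINGLE_COLS = ["sample", "assay", "chrom", "strand", "pos5", "count", "multimapped"]
_PAIRED_COLS = ["sample", "chrom", "strand", "pos5", "pos3", "size", "count"]


def read_tags(path: PathLike) -> list[CappedTag]:
    """Read a single-end tag TSV, aggregating identical records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SINGLE_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    has_fb = "first_base" in df.columns
    agg: dict[tuple, list] = {}
    for row in df.itertuples(index=False):
        fb = getattr(row, "first_base", None) if has_fb else None
        if isinstance(fb, float):  # NaN
            fb = None
        key = (
            row.sample,
            row.assay,
            row.chrom,
            row.strand,
            int(row.pos5),
            row.multimapped in ("True", "true", "1"),
            fb,
        )
        agg.setdefault(key, [0])[0] += int(row.count)
    out = []
    for (sample, assay, chrom, strand, pos5, mm, fb), (count,) in agg.items():
        out.append(CappedTag(sample, assay, chrom, strand, pos5, count, mm, fb))
    return out


def write_tags(path: PathLike, tags: Iterable[CappedTag]) -> None:
    tags = list(tags)
    has_fb = any(t.first_base is not None for t in tags)
    cols = _SINGLE_COLS + (["first_base"] if has_fb else [])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in sorted(tags, key=lambda t: (t.sample_id, t.assay, t.chrom, t.strand, t.pos5)):
            row = [t.sample_id, t.assay, t.chrom, t.strand, str(t.pos5), str(t.count),
                   str(t.multimapped)]
            if has_fb:
                row.append(t.first_base or "")
            fh.write("\t".join(row) + "\n")


def read_fragments(path: PathLike) -> list[PairedFragment]:
    """Read a paired-end fragment TSV (one row per fragment occurrence)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _PAIRED_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out: list[PairedFragment] = []
    for row in df.itertuples(index=False):
        frag = PairedFragment(
            row.sample, row.chrom, row.strand, int(row.pos5), int(row.pos3),
            int(row.size),
        )
        out.extend([frag] * int(row.count))
    return out


def write_fragments(path: PathLike, fragments: Iterable[PairedFragment]) -> None:
    agg: dict[PairedFragment, int] = {}
    for frag in fragments:
        agg[frag] = agg.get(frag, 0) + 1
    with open(path, "w") as fh:
        fh.write("\t".join(_PAIRED_COLS) + "\n")
        for frag in sorted(agg, key=lambda f: (f.sample_id, f.chrom, f.strand, f.pos5, f.pos3)):
            fh.write(
                f"{frag.sample_id}\t{frag.chrom}\t{frag.strand}\t{frag.pos5}\t"
                f"{frag.pos3}\t{frag.size}\t{agg[frag]}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: PathLike) -> SignalTrack:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 fields")
            records.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return SignalTrack.from_records(records)


def write_bedgraph(path: PathLike, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# FASTA (genome and class-labelled reference RNA sets)
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: PathLike, sequences: dict[str, str],
                descriptions: Optional[dict[str, str]] = None) -> None:
    records = []
    for name, seq in sequences.items():
        desc = (descriptions or {}).get(name, "")
        records.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_reference_rnas(path: PathLike) -> list[tuple[str, str, str]]:
    """Read a class-labelled reference RNA FASTA.

    Headers carry ``class=<label>``; returns (id, class_label, sequence).
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = "other"
        for token in rec.description.split():
            if token.startswith("class="):
                label = token[len("class="):]
        out.append((rec.id, label, str(rec.seq).upper()))
    return out


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

def read_snps(path: PathLike) -> SNPTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "gwas": str})
    for col in ("chrom", "pos", "gwas"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col}")
    gwas = df["gwas"].isin(["True", "true", "1"]).to_numpy()
    return SNPTable(list(df["chrom"]), df["pos"].to_numpy(), gwas)


def write_snps(path: PathLike, snps: SNPTable) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tgwas\n")
        for chrom, pos, flag in zip(snps.chroms, snps.positions, snps.gwas):
            fh.write(f"{chrom}\t{pos}\t{bool(flag)}\n")


# ---------------------------------------------------------------------------
# Count matrices (rows = peaks, columns = sample:assay)
# ---------------------------------------------------------------------------

def write_count_matrix(path: PathLike, counts: pd.DataFrame) -> None:
    out = counts.copy()
    out.columns = [f"{s}:{a}" for s, a in out.columns]
    out.to_csv(path, sep="\t", index_label="peak_id")


def read_count_matrix(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="peak_id")
    df.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split(":", 1)) for c in df.columns], names=["sample", "assay"]
    )
    return df
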