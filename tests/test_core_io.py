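"""Domain-type invariants and round-trip fidelity of the file formats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scaprna import io as scio
from scaprna.core import (
    CappedTag,
    GenomicInterval,
    PairedFragment,
    SignalTrack,
    SNPTable,
    TranscriptModel,
    ValidationError,
    merge_intervals,
)
from conftest import make_transcript


class TestGenomicInterval:
    def test_rejects_inverted_and_empty(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 20, 10, "+")
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 5, 5, "+")
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -1, 5, "+")

    def test_rejects_bad_strand(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 0, 5, "x")

    def test_five_prime_position_is_strand_aware(self):
        assert GenomicInterval("chr1", 100, 200, "+").pos5 == 100
        assert GenomicInterval("chr1", 100, 200, "-").pos5 == 199


class TestTranscriptModel:
    def test_tss_conventions(self):
        assert make_transcript(blocks=((100, 200),)).tss == 100
        assert make_transcript(strand="-", blocks=((100, 200),)).tss == 199

    def test_spliced_length_sums_blocks(self):
        tx = make_transcript(blocks=((1000, 1050), (1100, 1150)))
        assert tx.spliced_length == 100

    def test_rejects_overlapping_exons(self):
        with pytest.raises(ValidationError):
            make_transcript(blocks=((100, 200), (150, 250)))

    def test_unknown_biotype_maps_to_other(self):
        assert make_transcript(biotype="weird").biotype == "other"

    def test_splice_sites_in_transcript_orientation(self):
        plus = make_transcript(blocks=((0, 100), (200, 250), (300, 400)))
        assert plus.splice_sites_tx() == [99, 149]
        minus = make_transcript(strand="-", blocks=((0, 100), (200, 250), (300, 400)))
        assert minus.splice_sites_tx() == [99, 149]

    def test_coordinate_round_trip(self):
        tx = make_transcript(strand="-", blocks=((100, 150), (300, 400)))
        for off in range(tx.spliced_length):
            assert tx.genomic_to_tx(tx.tx_to_genomic(off)) == off
        assert tx.genomic_to_tx(200) is None  # intron


class TestTags:
    def test_paired_fragment_strand_ordering(self):
        with pytest.raises(ValidationError):
            PairedFragment("s", "chr1", "+", 10, 5, 6)
        with pytest.raises(ValidationError):
            PairedFragment("s", "chr1", "-", 40, 100, 61)
        frag = PairedFragment("s", "chr1", "-", 100, 40, 61)
        assert frag.size == 61

    def test_tag_count_positive(self):
        with pytest.raises(ValidationError):
            CappedTag("s", "short", "chr1", "+", 5, 0)


class TestRoundTrips:
    def test_bed6(self, tmp_path, rng):
        path = tmp_path / "x.bed"
        records = []
        for i in range(100):
            start = int(rng.integers(0, 10_000))
            end = start + int(rng.integers(1, 500))
            strand = "+-."[int(rng.integers(3))]
            records.append(
                (GenomicInterval(f"chr{1 + i % 3}", start, end, strand),
                 float(int(rng.integers(0, 100))))
            )
        scio.write_bed6(path, records)
        assert scio.read_bed6(path) == records

    def test_bed6_rejects_inverted(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t20\t10\tx\t5\t+\n")
        with pytest.raises(ValidationError, match="1"):
            scio.read_bed6(path)

    def test_bed6_parses_interval_and_score(self, tmp_path):
        path = tmp_path / "one.bed"
        path.write_text("chr1\t10\t20\tx\t5\t+\n")
        ((iv, score),) = scio.read_bed6(path)
        assert (iv.chrom, iv.start, iv.end, iv.strand, score) == \
            ("chr1", 10, 20, "+", 5.0)

    def test_transcripts(self, tmp_path):
        txs = [
            make_transcript("t1", "g1", "mRNA", blocks=((1000, 1050), (1100, 1150))),
            make_transcript("t2", "g2", "snoRNA", strand="-", blocks=((5000, 5120),)),
        ]
        path = tmp_path / "tx.bed12"
        scio.write_transcripts(path, txs)
        back = scio.read_transcripts(path)
        assert [(t.transcript_id, t.gene_id, t.biotype, t.exons) for t in back] == \
            [(t.transcript_id, t.gene_id, t.biotype, t.exons) for t in txs]

    def test_tags_aggregate_identical_records(self, tmp_path):
        path = tmp_path / "tags.tsv"
        path.write_text(
            "sample\tassay\tchrom\tstrand\tpos5\tcount\tmultimapped\n"
            "s1\tshort\tchr1\t+\t100\t1\tFalse\n"
            "s1\tshort\tchr1\t+\t100\t1\tFalse\n"
        )
        (tag,) = scio.read_tags(path)
        assert tag.count == 2

    def test_tags_round_trip(self, tmp_path, rng):
        tags = [
            CappedTag(f"s{i % 2}", "short" if i % 3 else "long", "chr1",
                      "+-"[i % 2], int(rng.integers(0, 1000)) + i * 1000,
                      int(rng.integers(1, 9)), bool(i % 5 == 0),
                      "ACGT"[i % 4])
            for i in range(40)
        ]
        path = tmp_path / "tags.tsv"
        scio.write_tags(path, tags)
        back = scio.read_tags(path)
        assert sorted(back, key=lambda t: (t.sample_id, t.assay, t.pos5)) == \
            sorted(tags, key=lambda t: (t.sample_id, t.assay, t.pos5))

    def test_fragments_round_trip(self, tmp_path):
        frags = [
            PairedFragment("s1", "chr1", "+", 100, 250, 120),
            PairedFragment("s1", "chr1", "+", 100, 250, 120),
            PairedFragment("s2", "chr2", "-", 900, 700, 180),
        ]
        path = tmp_path / "frags.tsv"
        scio.write_fragments(path, frags)
        back = scio.read_fragments(path)
        assert sorted(back, key=str) == sorted(frags, key=str)

    def test_bedgraph_round_trip(self, tmp_path):
        track = SignalTrack.from_records(
            [("chr1", 0, 100, 2.5), ("chr1", 200, 300, 1.0), ("chr2", 50, 60, 7.0)]
        )
        path = tmp_path / "x.bedgraph"
        scio.write_bedgraph(path, track)
        assert scio.read_bedgraph(path).records() == track.records()

    def test_fasta_round_trip_with_class_labels(self, tmp_path):
        path = tmp_path / "refs.fa"
        scio.write_fasta(path, {"u1": "ACGTACGT", "t5": "GGGTTTCC"},
                         {"u1": "class=snRNA", "t5": "class=tRNA"})
        refs = scio.read_reference_rnas(path)
        assert ("u1", "snRNA", "ACGTACGT") in refs
        assert ("t5", "tRNA", "GGGTTTCC") in refs

    def test_count_matrix_round_trip(self, tmp_path, rng):
        import pandas as pd

        cols = pd.MultiIndex.from_product(
            [["s1", "s2"], ["short", "long"]], names=["sample", "assay"]
        )
        mat = pd.DataFrame(rng.integers(0, 50, size=(5, 4)),
                           index=[f"p{i}" for i in range(5)], columns=cols)
        path = tmp_path / "counts.tsv"
        scio.write_count_matrix(path, mat)
        back = scio.read_count_matrix(path)
        assert (back.to_numpy() == mat.to_numpy()).all()
        assert list(back.columns) == list(mat.columns)


@given(
    st.lists(
        st.tuples(st.integers(0, 5000), st.integers(1, 300)),
        min_size=1,
        max_size=30,
    )
)
@settings(max_examples=50, deadline=None)
def test_merge_intervals_covers_input_and_is_disjoint(raw):
    intervals = [GenomicInterval("chr1", s, s + l) for s, l in raw]
    merged = merge_intervals(intervals)
    for a, b in zip(merged, merged[1:]):
        assert a.end < b.start  # disjoint with gaps
    for iv in intervals:
        assert any(m.start <= iv.start and iv.end <= m.end for m in merged)


class TestSignalTrack:
    def test_window_sum_on_boundaries(self):
        track = SignalTrack.from_records([("chr1", 10, 20, 3.0)])
        assert track.window_sum("chr1", 0, 10) == 0.0
        assert track.window_sum("chr1", 10, 20) == 30.0
        assert track.window_sum("chr1", 15, 25) == 15.0
        assert track.window_sum("chr2", 0, 100) == 0.0

    def test_rejects_overlaps_and_negative(self):
        with pytest.raises(ValidationError):
            SignalTrack.from_records([("chr1", 0, 10, 1.0), ("chr1", 5, 15, 1.0)])
        with pytest.raises(ValidationError):
            SignalTrack.from_records([("chr1", 0, 10, -1.0)])


def test_snp_table_rejects_duplicates():
    with pytest.raises(ValidationError):
        SNPTable(["chr1", "chr1"], np.array([5, 5]), np.array([True, False]))
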