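"""Annotation parsing, downstream-window derivation, and interval I/O."""
import pytest

from rtchimera.annotation_io import (
    AnnotationParseError,
    AnnotationSet,
    GeneModel,
    derive_downstream_windows,
    parse_annotation,
    parse_state_intervals,
    read_windows_bed,
    write_windows_bed,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestParseAnnotation:
    def test_gtf_coordinates_become_zero_based_half_open(self, tmp_path):
        path = _write(
            tmp_path, "a.gtf",
            'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "g1";\n',
        )
        ann = parse_annotation(path, "gtf")
        g = ann["g1"]
        assert (g.start, g.end, g.strand) == (100, 200, "+")

    def test_empty_file_gives_empty_set(self, tmp_path):
        path = _write(tmp_path, "empty.gtf", "# just a comment\n")
        assert len(parse_annotation(path, "gtf")) == 0

    def test_transcripts_merge_to_union_span(self, tmp_path):
        # brute-force union of [100,200] and [150,300] (1-based) is [100,300]
        intervals = [(100, 200), (150, 300)]
        lo = min(s for s, _ in intervals)
        hi = max(e for _, e in intervals)
        path = _write(
            tmp_path, "two_tx.gtf",
            'chr1\tsrc\ttranscript\t100\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tsrc\ttranscript\t150\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t2";\n'
            'chr1\tsrc\texon\t150\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t2";\n',
        )
        ann = parse_annotation(path, "gtf")
        assert len(ann) == 1
        g = ann["g1"]
        assert (g.start, g.end) == (lo - 1, hi)

    def test_gff3_gene_features(self, tmp_path):
        path = _write(
            tmp_path, "a.gff3",
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t11\t500\t.\t-\t.\tID=gY\n"
            "chr1\tsrc\tgene\t600\t900\t.\t+\t.\tID=gX\n",
        )
        ann = parse_annotation(path, "gff3")
        assert ann.gene_ids() == ["gY", "gX"]  # sorted by start
        assert ann["gY"].strand == "-"

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = _write(
            tmp_path, "bad.gtf",
            'chr1\tsrc\tgene\t1\t100\t.\t+\t.\tgene_id "g1";\n'
            "chr1\tonly three fields\n",
        )
        with pytest.raises(AnnotationParseError, match="line 2"):
            parse_annotation(path, "gtf")

    def test_end_before_start_rejected(self, tmp_path):
        path = _write(
            tmp_path, "bad.gtf", 'chr1\tsrc\tgene\t200\t100\t.\t+\t.\tgene_id "g1";\n'
        )
        with pytest.raises(AnnotationParseError, match="end < start"):
            parse_annotation(path, "gtf")


class TestGeneModel:
    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", 100, 100, "+")

    def test_invalid_strand_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", 0, 10, ".")

    def test_duplicate_ids_rejected(self):
        genes = [GeneModel("g", "chr1", 0, 10, "+"), GeneModel("g", "chr1", 20, 30, "+")]
        with pytest.raises(ValueError, match="duplicate"):
            AnnotationSet(genes)


class TestDownstreamWindows:
    def test_plus_strand_window_follows_gene_end(self):
        ann = AnnotationSet([GeneModel("g", "chr1", 0, 1000, "+")])
        (w,) = derive_downstream_windows(ann, 500)
        assert (w.start, w.end) == (1000, 1500)

    def test_minus_strand_window_precedes_gene_start(self):
        ann = AnnotationSet([GeneModel("g", "chr1", 1000, 2000, "-")])
        (w,) = derive_downstream_windows(ann, 500)
        assert (w.start, w.end) == (500, 1000)

    def test_minus_strand_clipped_at_chromosome_origin(self):
        ann = AnnotationSet([GeneModel("g", "chr1", 300, 600, "-")])
        (w,) = derive_downstream_windows(ann, 500)
        assert (w.start, w.end) == (0, 300)

    def test_plus_strand_clipped_at_chromosome_end(self):
        ann = AnnotationSet(
            [GeneModel("g", "chr1", 100, 900, "+")], chrom_lengths={"chr1": 1000}
        )
        (w,) = derive_downstream_windows(ann, 500)
        assert (w.start, w.end) == (900, 1000)

    def test_fully_clipped_window_is_zero_length_but_emitted(self):
        ann = AnnotationSet(
            [GeneModel("g", "chr1", 100, 1000, "+")], chrom_lengths={"chr1": 1000}
        )
        (w,) = derive_downstream_windows(ann, 500)
        assert w.is_empty

    def test_window_count_equals_gene_count_and_no_gene_overlap(self, toy_annotation):
        windows = derive_downstream_windows(toy_annotation, 500)
        assert len(windows) == len(toy_annotation)
        by_id = {w.gene_id: w for w in windows}
        for g in toy_annotation:
            w = by_id[g.gene_id]
            assert w.strand == g.strand
            assert w.end <= g.start or w.start >= g.end  # never overlaps its gene

    def test_invalid_window_length(self, toy_annotation):
        with pytest.raises(ValueError):
            derive_downstream_windows(toy_annotation, 0)


class TestBedRoundTrip:
    def test_windows_survive_bed_round_trip(self, toy_annotation, tmp_path):
        windows = derive_downstream_windows(toy_annotation, 500)
        path = tmp_path / "w.bed"
        write_windows_bed(windows, path)
        assert read_windows_bed(path) == windows


class TestStateIntervals:
    def test_parse_bed4(self, tmp_path):
        path = _write(tmp_path, "s.bed", "chr1\t0\t1000\tCS2\n")
        (iv,) = parse_state_intervals(path)
        assert (iv.chrom, iv.start, iv.end, iv.state) == ("chr1", 0, 1000, "CS2")

    def test_empty_file(self, tmp_path):
        path = _write(tmp_path, "s.bed", "")
        assert parse_state_intervals(path) == []

    def test_unsorted_input_is_sorted(self, tmp_path):
        rows = [("chr2", 50, 60, "CS1"), ("chr1", 500, 900, "CS3"),
                ("chr1", 0, 100, "CS2")]
        path = _write(
            tmp_path, "s.bed", "".join(f"{c}\t{s}\t{e}\t{l}\n" for c, s, e, l in rows)
        )
        got = [(iv.chrom, iv.start) for iv in parse_state_intervals(path)]
        assert got == sorted((c, s) for c, s, _, _ in rows)

    def test_non_integer_coordinates_rejected(self, tmp_path):
        path = _write(tmp_path, "s.bed", "chr1\tzero\t100\tCS1\n")
        with pytest.raises(AnnotationParseError, match="non-integer"):
            parse_state_intervals(path)
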