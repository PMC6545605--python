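"""Gene annotations, downstream windows, and interval I/O.

Internal coordinates are 0-based half-open throughout.  GFF3/GTF input
(1-based inclusive) is converted on read; BED is read and written natively.
Multi-transcript genes collapse to the union span of all their features,
since readthrough is quantified per gene, not per transcript.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils


class AnnotationParseError(ValueError):
    """Raised when an annotation or interval file cannot be parsed."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: the union span of its transcripts.

    Coordinates are 0-based half-open; ``strand`` is ``'+'`` or ``'-'``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicWindow:
    """Strand-aware window downstream of a gene (0-based half-open).

    A window clipped entirely off the chromosome has ``start == end`` and is
    kept (flagged via :attr:`is_empty`) so window count equals gene count.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window {self.gene_id}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_empty(self) -> bool:
        return self.start == self.end


class AnnotationSet:
    """Ordered collection of :class:`GeneModel` with optional chromosome sizes.

    Iteration order is deterministic: sorted by (chrom, start, gene_id).
    """

    def __init__(
        self,
        genes: Iterable[GeneModel],
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self.genes: list[GeneModel] = sorted(
            genes, key=lambda g: (g.chrom, g.start, g.gene_id)
        )
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None
        self._by_id = {g.gene_id: g for g in self.genes}

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass(frozen=True)
class StateInterval:
    """A labelled genomic interval (e.g., a chromatin state segment)."""

    chrom: str
    start: int
    end: int
    state: str


def _validate_feature_lines(path: str | os.PathLike) -> tuple[int, set[str]]:
    """Pre-validate a GFF/GTF file; return (feature count, feature types).

    Raises :class:`AnnotationParseError` naming the offending line number.
    """
    n = 0
    types: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected >= 8 tab-separated fields"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if end < start:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: end < start ({end} < {start})"
                )
            types.add(fields[2])
            n += 1
    return n, types


def _gene_key(feature: gffutils.Feature) -> str | None:
    for attr in ("gene_id", "ID", "Name"):
        if attr in feature.attributes:
            return feature.attributes[attr][0]
    return None


def _biotype(feature: gffutils.Feature) -> str:
    for attr in ("gene_biotype", "biotype", "gene_type"):
        if attr in feature.attributes:
            return feature.attributes[attr][0]
    return "protein_coding"


def parse_annotation(
    path: str | os.PathLike,
    format: str | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> AnnotationSet:
    """Parse a GFF3 or GTF file into an :class:`AnnotationSet`.

    All features sharing a gene identifier are merged to their union span,
    converted to 0-based half-open coordinates.  ``format`` is inferred from
    the file extension when omitted.
    """
    if format is None:
        format = "gtf" if str(path).lower().endswith((".gtf", ".gtf.gz")) else "gff3"
    if format not in ("gff3", "gtf"):
        raise ValueError(f"unknown annotation format: {format!r}")
    n_features, feature_types = _validate_feature_lines(path)
    if n_features == 0:
        return AnnotationSet([], chrom_lengths=chrom_lengths)

    # skip GTF gene/transcript inference when they are already explicit
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=(format == "gff3" or "gene" in feature_types),
        disable_infer_transcripts=(format == "gff3" or "transcript" in feature_types),
    )

    gene_feats = list(db.features_of_type("gene"))
    genes: list[GeneModel] = []
    if gene_feats:
        for g in gene_feats:
            start, end = g.start, g.end
            for child in db.children(g.id):
                start = min(start, child.start)
                end = max(end, child.end)
            gid = _gene_key(g) or g.id
            genes.append(
                GeneModel(gid, g.seqid, start - 1, end, g.strand, _biotype(g))
            )
    else:
        # No explicit gene features: group everything by gene identifier.
        spans: dict[str, list] = {}
        for f in db.all_features():
            gid = _gene_key(f)
            if gid is None:
                continue
            rec = spans.setdefault(gid, [f.seqid, f.start, f.end, f.strand, _biotype(f)])
            if rec[0] != f.seqid:
                raise AnnotationParseError(
                    f"gene {gid}: features on multiple chromosomes"
                )
            rec[1] = min(rec[1], f.start)
            rec[2] = max(rec[2], f.end)
        for gid, (chrom, start, end, strand, biotype) in spans.items():
            genes.append(GeneModel(gid, chrom, start - 1, end, strand, biotype))
    return AnnotationSet(genes, chrom_lengths=chrom_lengths)


def derive_downstream_windows(
    ann: AnnotationSet, window_length: int = 500
) -> list[GenomicWindow]:
    """Derive the fixed-length window immediately downstream of each gene.

    For a ``+`` gene the window is ``[end, end + L)``; for a ``-`` gene it is
    ``[start - L, start)``.  Windows are clipped to ``[0, chrom_length)`` when
    chromosome lengths are known; a window falling entirely off the
    chromosome is emitted with zero length.  Exactly one window per gene.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    lengths = ann.chrom_lengths or {}
    out: list[GenomicWindow] = []
    for g in ann:
        if g.strand == "+":
            s, e = g.end, g.end + window_length
        else:
            s, e = g.start - window_length, g.start
        s = max(s, 0)
        e = max(e, s)
        if g.chrom in lengths:
            clen = lengths[g.chrom]
            e = min(e, clen)
            s = min(s, e)
        out.append(GenomicWindow(g.gene_id, g.chrom, s, e, g.strand))
    return out


def parse_state_intervals(path: str | os.PathLike) -> list[StateInterval]:
    """Parse a BED4 file of labelled intervals, sorted by (chrom, start).

    Column 4 is the state label (any string); coordinates are BED-native
    0-based half-open.
    """
    intervals: list[StateInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected >= 4 columns (BED4)"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            intervals.append(StateInterval(fields[0], start, end, fields[3]))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.state))
    return intervals


def write_windows_bed(windows: Sequence[GenomicWindow], path: str | os.PathLike) -> None:
    """Write windows as BED6 (name = gene_id, score = 0, strand in col 6)."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.gene_id}\t0\t{w.strand}\n")


def read_windows_bed(path: str | os.PathLike) -> list[GenomicWindow]:
    """Read BED6 windows written by :func:`write_windows_bed`."""
    out: list[GenomicWindow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected BED6"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            out.append(GenomicWindow(fields[3], fields[0], start, end, fields[5]))
    return out
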