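"""Readthrough calling from strand-specific coverage.

The caller quantifies strand-matched coverage in each gene body and in the
fixed-length window immediately downstream, normalizes to reads per million
(rpm), and flags a gene as a readthrough candidate when the mutant/wild-type
downstream fold change clears a cutoff while the gene itself is expressed,
not differentially expressed, and backed by a raw-count floor in the mutant
window.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import AnnotationSet, GenomicWindow, derive_downstream_windows


@dataclass
class CoverageTrack:
    """Strand-resolved per-base coverage for one sample.

    ``plus``/``minus`` map chromosome name to a per-base count vector;
    ``library_size`` is the total number of mapped reads used for rpm/RPKM
    normalization.
    """

    sample_id: str
    library_size: int
    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")

    def strand_depth(self, strand: str) -> dict[str, np.ndarray]:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    @classmethod
    def from_bedgraph(
        cls,
        sample_id: str,
        plus_path: str | os.PathLike,
        minus_path: str | os.PathLike,
        library_size: int,
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> "CoverageTrack":
        """Build a track from one bedGraph per strand."""
        plus = _read_bedgraph(plus_path, chrom_lengths)
        minus = _read_bedgraph(minus_path, chrom_lengths)
        return cls(sample_id, library_size, plus, minus)


def _read_bedgraph(
    path: str | os.PathLike, chrom_lengths: Mapping[str, int] | None = None
) -> dict[str, np.ndarray]:
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split()[:4]
            rows.append((chrom, int(start), int(end), float(value)))
    sizes: dict[str, int] = dict(chrom_lengths) if chrom_lengths else {}
    if not chrom_lengths:
        for chrom, _, end, _ in rows:
            sizes[chrom] = max(sizes.get(chrom, 0), end)
    arrays = {chrom: np.zeros(size, dtype=float) for chrom, size in sizes.items()}
    for chrom, start, end, value in rows:
        if chrom not in arrays:
            arrays[chrom] = np.zeros(end, dtype=float)
        arr = arrays[chrom]
        if end > arr.size:
            arr = np.concatenate([arr, np.zeros(end - arr.size)])
            arrays[chrom] = arr
        arr[start:end] += value
    return arrays


def pool_tracks(tracks: Sequence[CoverageTrack], sample_id: str | None = None) -> CoverageTrack:
    """Pool replicate tracks by summing per-base counts and library sizes."""
    if not tracks:
        raise ValueError("no tracks to pool")
    if len(tracks) == 1:
        return tracks[0]
    plus: dict[str, np.ndarray] = {}
    minus: dict[str, np.ndarray] = {}
    for track in tracks:
        for dest, src in ((plus, track.plus), (minus, track.minus)):
            for chrom, arr in src.items():
                if chrom not in dest:
                    dest[chrom] = arr.astype(float).copy()
                else:
                    n = max(dest[chrom].size, arr.size)
                    merged = np.zeros(n)
                    merged[: dest[chrom].size] = dest[chrom]
                    merged[: arr.size] += arr
                    dest[chrom] = merged
    lib = sum(t.library_size for t in tracks)
    return CoverageTrack(sample_id or "+".join(t.sample_id for t in tracks), lib, plus, minus)


def count_interval(
    track: CoverageTrack, chrom: str, start: int, end: int, strand: str
) -> float:
    """Sum per-base counts over ``[start, end)`` on the requested strand.

    A zero-length interval yields 0.  The interval is clipped to the stored
    vector length (positions with no recorded coverage count as zero).
    """
    depth = track.strand_depth(strand)
    if chrom not in depth:
        raise KeyError(f"unknown chromosome {chrom!r} in sample {track.sample_id}")
    if start < 0 or end < start:
        raise ValueError(f"invalid interval [{start}, {end})")
    arr = depth[chrom]
    return float(arr[start : min(end, arr.size)].sum())


def rpm(count: float, library_size: int) -> float:
    """Reads per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count * 1e6 / library_size


def rpkm(count: float, library_size: int, feature_length_bp: int) -> float:
    """Reads per kilobase per million mapped reads."""
    if feature_length_bp <= 0:
        raise ValueError("feature_length_bp must be > 0")
    return count * 1e9 / (library_size * feature_length_bp)


def downstream_fold_change(rpm_mut: float, rpm_wt: float) -> float:
    """Mutant/wild-type ratio of normalized downstream counts.

    Returns ``+inf`` when the wild type is silent but the mutant is not, and
    ``nan`` (undefined; never a candidate by fold change alone) when both
    are zero.
    """
    if rpm_mut < 0 or rpm_wt < 0:
        raise ValueError("rpm values must be >= 0")
    if rpm_wt == 0.0:
        return math.inf if rpm_mut > 0 else math.nan
    return rpm_mut / rpm_wt


@dataclass
class ReadthroughCall:
    """Per-gene readthrough record; ``candidate`` is re-derivable from fields."""

    gene_id: str
    window: GenomicWindow
    count_wt: float
    count_mut: float
    rpm_wt: float
    rpm_mut: float
    fold_change: float
    gene_rpkm_wt: float
    gene_rpkm_mut: float
    expressed_pass: bool
    de_excluded: bool
    min_reads_pass: bool
    candidate: bool


TrackLike = CoverageTrack | Sequence[CoverageTrack]


def _as_track(track: TrackLike, label: str) -> CoverageTrack:
    if isinstance(track, CoverageTrack):
        return track
    return pool_tracks(list(track), sample_id=label)


def call_readthrough(
    ann: AnnotationSet,
    wt: TrackLike,
    mut: TrackLike,
    *,
    window_length: int = 500,
    fc_threshold: float = 2.0,
    min_rpkm: float = 1.0,
    min_mut_window_reads: float = 10.0,
    de_exclusion: Iterable[str] | None = (),
) -> list[ReadthroughCall]:
    """Call readthrough candidates for every gene in ``ann``.

    A gene is a candidate when all of the following hold:

    * downstream-window fold change (mut/wt rpm) >= ``fc_threshold``;
    * gene-body RPKM >= ``min_rpkm`` in *both* samples (low-expressed genes
      in either library are filtered out);
    * the gene is not in the differential-expression exclusion list;
    * raw mutant window count >= ``min_mut_window_reads`` (guards the
      infinite fold change arising from a silent wild-type window).

    ``de_exclusion`` is an explicit gene-id collection; pass ``None`` to use
    the internal fallback rule that excludes genes whose body rpm fold
    change falls outside ``[1/fc_threshold, fc_threshold]``.  Replicates may
    be supplied as a sequence of tracks; they are pooled (counts and library
    sizes summed) before normalization.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be > 0")
    wt_track = _as_track(wt, "wt")
    mut_track = _as_track(mut, "mut")
    windows = {w.gene_id: w for w in derive_downstream_windows(ann, window_length)}

    body: dict[str, tuple[float, float]] = {}
    for g in ann:
        c_wt = count_interval(wt_track, g.chrom, g.start, g.end, g.strand)
        c_mut = count_interval(mut_track, g.chrom, g.start, g.end, g.strand)
        body[g.gene_id] = (c_wt, c_mut)

    if de_exclusion is None:
        excluded = set()
        for g in ann:
            c_wt, c_mut = body[g.gene_id]
            fc = downstream_fold_change(
                rpm(c_mut, mut_track.library_size), rpm(c_wt, wt_track.library_size)
            )
            if math.isnan(fc):
                continue
            if not (1.0 / fc_threshold <= fc <= fc_threshold):
                excluded.add(g.gene_id)
    else:
        excluded = set(de_exclusion)

    calls: list[ReadthroughCall] = []
    for g in ann:
        w = windows[g.gene_id]
        cw_wt = count_interval(wt_track, w.chrom, w.start, w.end, g.strand)
        cw_mut = count_interval(mut_track, w.chrom, w.start, w.end, g.strand)
        r_wt = rpm(cw_wt, wt_track.library_size)
        r_mut = rpm(cw_mut, mut_track.library_size)
        fc = downstream_fold_change(r_mut, r_wt)
        b_wt, b_mut = body[g.gene_id]
        k_wt = rpkm(b_wt, wt_track.library_size, g.length)
        k_mut = rpkm(b_mut, mut_track.library_size, g.length)
        expressed = k_wt >= min_rpkm and k_mut >= min_rpkm
        de_excl = g.gene_id in excluded
        min_reads = cw_mut >= min_mut_window_reads
        fc_pass = (not math.isnan(fc)) and fc >= fc_threshold
        calls.append(
            ReadthroughCall(
                gene_id=g.gene_id,
                window=w,
                count_wt=cw_wt,
                count_mut=cw_mut,
                rpm_wt=r_wt,
                rpm_mut=r_mut,
                fold_change=fc,
                gene_rpkm_wt=k_wt,
                gene_rpkm_mut=k_mut,
                expressed_pass=expressed,
                de_excluded=de_excl,
                min_reads_pass=min_reads,
                candidate=fc_pass and expressed and not de_excl and min_reads,
            )
        )
    return calls


def calls_to_dataframe(calls: Sequence[ReadthroughCall]) -> pd.DataFrame:
    """Flatten calls to a tidy table (one row per gene)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_id": c.gene_id,
                "chrom": c.window.chrom,
                "window_start": c.window.start,
                "window_end": c.window.end,
                "strand": c.window.strand,
                "count_wt": c.count_wt,
                "count_mut": c.count_mut,
                "rpm_wt": c.rpm_wt,
                "rpm_mut": c.rpm_mut,
                "fold_change": c.fold_change,
                "gene_rpkm_wt": c.gene_rpkm_wt,
                "gene_rpkm_mut": c.gene_rpkm_mut,
                "expressed_pass": c.expressed_pass,
                "de_excluded": c.de_excluded,
                "min_reads_pass": c.min_reads_pass,
                "candidate": c.candidate,
            }
        )
    return pd.DataFrame(rows)


def candidate_set(calls: Sequence[ReadthroughCall]) -> set[str]:
    """Gene ids flagged as readthrough candidates."""
    return {c.gene_id for c in calls if c.candidate}


def write_calls(calls: Sequence[ReadthroughCall], tsv_path: str | os.PathLike,
                bed_path: str | os.PathLike | None = None) -> None:
    """Write the full call table as TSV and, optionally, candidate windows as BED6."""
    calls_to_dataframe(calls).to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for c in calls:
                if c.candidate:
                    w = c.window
                    fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.gene_id}\t0\t{w.strand}\n")
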