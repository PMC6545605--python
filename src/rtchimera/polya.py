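"""PolyA-site mapping from 3' RACE clone ends and qPCR-style quantities.

Clone-end genomic coordinates are converted to positions relative to the
stop codon of the upstream gene: position 1 is the first base downstream of
the stop codon's last base (position 0 marks a clone ending exactly at the
stop).  Relative quantification helpers implement the 2^-ddCt fold change
and the two-step IP/input enrichment ratio used for m6A-IP-qPCR.
"""
from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd


@dataclass(frozen=True)
class PolyASite:
    """A tallied polyA site: position relative to the stop codon + clone count."""

    gene_id: str
    rel_pos: int
    clone_count: int


@dataclass(frozen=True)
class RelQuant:
    """A derived relative quantity together with its four input components."""

    value: float
    components: tuple[float, float, float, float]


def map_polya_site(clone_last_base: int, stop_last_base: int, strand: str) -> int:
    """Relative polyA position of one clone end.

    ``clone_last_base`` is the genomic coordinate of the last templated
    nucleotide before the polyA tail; ``stop_last_base`` that of the last
    base of the stop codon.  Negative results (clone ends inside the CDS)
    are returned as-is for the caller to flag.
    """
    if strand == "+":
        return clone_last_base - stop_last_base
    if strand == "-":
        return stop_last_base - clone_last_base
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def tally_sites(
    rel_positions: Iterable[int], cluster_window: int = 0, gene_id: str = ""
) -> list[PolyASite]:
    """Tally clone positions into polyA sites.

    With ``cluster_window = 0`` (default) the tally is exact per position.
    Otherwise positions are greedily merged onto modal positions: the most
    supported position (ties broken toward the stop codon) absorbs every
    position within ``cluster_window`` bp, and the process repeats on the
    remainder.  Total clone count is conserved either way.
    """
    counts = Counter(rel_positions)
    if cluster_window <= 0:
        return [
            PolyASite(gene_id, pos, n) for pos, n in sorted(counts.items())
        ]
    sites: list[PolyASite] = []
    while counts:
        mode = min(counts, key=lambda p: (-counts[p], p))
        absorbed = [p for p in counts if abs(p - mode) <= cluster_window]
        sites.append(PolyASite(gene_id, mode, sum(counts[p] for p in absorbed)))
        for p in absorbed:
            del counts[p]
    sites.sort(key=lambda s: s.rel_pos)
    return sites


def ddct_fold(
    ct_target_cond: float,
    ct_ref_cond: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> RelQuant:
    """Relative transcript accumulation by the ddCt method: 2^-(dCt_cond - dCt_ctrl)."""
    dct_cond = ct_target_cond - ct_ref_cond
    dct_ctrl = ct_target_ctrl - ct_ref_ctrl
    return RelQuant(
        2.0 ** -(dct_cond - dct_ctrl),
        (ct_target_cond, ct_ref_cond, ct_target_ctrl, ct_ref_ctrl),
    )


def m6a_enrichment(
    ip_target: float, ip_ref: float, input_target: float, input_ref: float
) -> RelQuant:
    """IP enrichment: target normalized to an internal control in IP, then to input."""
    vals = (ip_target, ip_ref, input_target, input_ref)
    if min(vals) <= 0:
        raise ValueError("all abundances must be > 0")
    return RelQuant((ip_target / ip_ref) / (input_target / input_ref), vals)


def map_clone_table(
    clones: pd.DataFrame, cluster_window: int = 0
) -> pd.DataFrame:
    """Map and tally a clone table into per-gene polyA site histograms.

    Expects columns gene_id, clone_last_base, stop_last_base, strand; returns
    a table with gene_id, rel_pos, clone_count.
    """
    required = {"gene_id", "clone_last_base", "stop_last_base", "strand"}
    missing = required - set(clones.columns)
    if missing:
        raise ValueError(f"clone table missing columns: {sorted(missing)}")
    rows = []
    for gene_id, sub in clones.groupby("gene_id", sort=True):
        positions = [
            map_polya_site(int(r.clone_last_base), int(r.stop_last_base), str(r.strand))
            for r in sub.itertuples(index=False)
        ]
        for site in tally_sites(positions, cluster_window, gene_id=str(gene_id)):
            rows.append(
                {"gene_id": site.gene_id, "rel_pos": site.rel_pos,
                 "clone_count": site.clone_count}
            )
    return pd.DataFrame(rows)


def read_clone_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
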