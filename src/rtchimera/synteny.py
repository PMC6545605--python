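"""Cross-genome gene-pair adjacency classification.

For each upstream/downstream gene pair (GENE1/GENE2) and each target
genome, homolog hits (e-value-filtered, e.g. tblastn tabular output) are
classified into one of five scenarios: *adjacent* (some GENE1 hit and some
GENE2 hit share a scaffold with a closest-edge gap of at most 5 kb),
*distant* (both present, never that close), *g1_only* / *g2_only* (one side
has no hit), or *absent* (neither does).  Percentages per pair over
informative genomes form the conservation matrix used for heat-map views.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

SCENARIOS = ("adjacent", "distant", "g1_only", "g2_only", "absent")
HIT_COLUMNS = ["pair_id", "gene_role", "genome_id", "scaffold", "start", "end", "evalue"]


@dataclass(frozen=True)
class HomologHit:
    """One homolog hit of a query gene in a target genome (0-based half-open)."""

    query_gene: str
    genome_id: str
    scaffold: str
    start: int
    end: int
    evalue: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"hit {self.query_gene}: start >= end")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class PairScenario:
    pair_id: str
    genome_id: str
    scenario: str
    min_gap_bp: int | None = None


def filter_hits(hits: Iterable[HomologHit], evalue_max: float = 1e-10) -> list[HomologHit]:
    """Keep hits with e-value <= ``evalue_max`` (inclusive), order preserved."""
    return [h for h in hits if h.evalue <= evalue_max]


def _gap(a: HomologHit, b: HomologHit) -> int:
    """Closest-edge distance between two hit intervals; 0 when they overlap."""
    return max(b.start - a.end, a.start - b.end, 0)


def classify_pair(
    hits_g1: Sequence[HomologHit],
    hits_g2: Sequence[HomologHit],
    max_gap_bp: int = 5000,
    pair_id: str = "",
    genome_id: str = "",
) -> PairScenario:
    """Classify one gene pair in one genome from its (pre-filtered) hits.

    Any co-scaffold GENE1/GENE2 hit combination with gap <= ``max_gap_bp``
    makes the pair *adjacent*; the minimum co-scaffold gap is reported for
    adjacent and distant calls when one exists.
    """
    if not hits_g1 and not hits_g2:
        return PairScenario(pair_id, genome_id, "absent")
    if not hits_g2:
        return PairScenario(pair_id, genome_id, "g1_only")
    if not hits_g1:
        return PairScenario(pair_id, genome_id, "g2_only")
    min_gap: int | None = None
    for h1 in hits_g1:
        for h2 in hits_g2:
            if h1.scaffold != h2.scaffold or h1.genome_id != h2.genome_id:
                continue
            g = _gap(h1, h2)
            if min_gap is None or g < min_gap:
                min_gap = g
    scenario = "adjacent" if (min_gap is not None and min_gap <= max_gap_bp) else "distant"
    return PairScenario(pair_id, genome_id, scenario, min_gap)


def read_hit_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a homolog hit table (TSV with header).

    Required columns: pair_id, gene_role ('g1'|'g2'), genome_id, scaffold,
    start, end, evalue — a BLAST outfmt-6-like layout with explicit pair,
    role, and genome columns.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hit table {path} missing columns: {missing}")
    bad = set(df["gene_role"]) - {"g1", "g2"}
    if bad:
        raise ValueError(f"gene_role must be 'g1' or 'g2', found {sorted(bad)}")
    return df


def classify_table(
    hits: pd.DataFrame,
    *,
    evalue_max: float = 1e-10,
    max_gap_bp: int = 5000,
    pair_ids: Sequence[str] | None = None,
    genome_ids: Sequence[str] | None = None,
) -> list[PairScenario]:
    """Classify every (pair, genome) cell of a hit table.

    Pairs/genomes absent from the table after filtering are classified
    *absent*; supply ``pair_ids``/``genome_ids`` to fix the classification
    universe explicitly (otherwise taken from the unfiltered table).
    """
    pairs = list(pair_ids) if pair_ids is not None else sorted(hits["pair_id"].unique())
    genomes = (
        list(genome_ids) if genome_ids is not None else sorted(hits["genome_id"].unique())
    )
    kept = hits[hits["evalue"] <= evalue_max]
    grouped: dict[tuple[str, str, str], list[HomologHit]] = {}
    for row in kept.itertuples(index=False):
        key = (row.pair_id, row.genome_id, row.gene_role)
        grouped.setdefault(key, []).append(
            HomologHit(
                query_gene=f"{row.pair_id}:{row.gene_role}",
                genome_id=row.genome_id,
                scaffold=str(row.scaffold),
                start=int(row.start),
                end=int(row.end),
                evalue=float(row.evalue),
            )
        )
    out: list[PairScenario] = []
    for pair in pairs:
        for genome in genomes:
            out.append(
                classify_pair(
                    grouped.get((pair, genome, "g1"), []),
                    grouped.get((pair, genome, "g2"), []),
                    max_gap_bp=max_gap_bp,
                    pair_id=pair,
                    genome_id=genome,
                )
            )
    return out


def scenario_matrix(classifications: Iterable[PairScenario]) -> pd.DataFrame:
    """Per-pair percentages over the four informative scenarios.

    Genomes where the pair is *absent* are excluded from the percentage
    denominator and reported separately (``n_absent``); a pair absent
    everywhere has NaN percentages and ``n_informative = 0``.
    """
    rows: dict[str, dict[str, int]] = {}
    for c in classifications:
        rows.setdefault(c.pair_id, {s: 0 for s in SCENARIOS})[c.scenario] += 1
    records = []
    for pair_id in sorted(rows):
        counts = rows[pair_id]
        informative = sum(counts[s] for s in SCENARIOS[:4])
        rec: dict[str, object] = {"pair_id": pair_id}
        for s in SCENARIOS[:4]:
            rec[f"pct_{s}"] = (100.0 * counts[s] / informative) if informative else float("nan")
        rec["n_informative"] = informative
        rec["n_absent"] = counts["absent"]
        records.append(rec)
    return pd.DataFrame(records)
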