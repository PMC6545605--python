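"""Chromatin-state assignment and distribution testing.

Each gene receives the state label whose intervals overlap the gene span by
the most base pairs (ties broken by natural label order, so CS1 beats CS2).
A gene-set state distribution is compared against a reference distribution
with Pearson's chi-square statistic; because gene sets are small, the
p-value is obtained by Monte-Carlo simulation under the multinomial null
rather than from the asymptotic chi-square tail.
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .annotation_io import AnnotationSet, GeneModel, StateInterval

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class StateAssignment:
    gene_id: str
    state: str
    overlap_bp: int


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square statistic with a Monte-Carlo (add-one) p-value."""

    statistic: float
    df: int
    p_monte_carlo: float
    n_simulations: int
    seed: int


def _natural_key(label: str) -> tuple:
    # "CS2" < "CS10"; plain strings fall back to lexicographic
    return tuple(int(t) if t.isdigit() else t for t in re.split(r"(\d+)", label))


class StateIndex:
    """Chromosome-indexed interval lookup for state segments."""

    def __init__(self, intervals: Iterable[StateInterval]) -> None:
        self._trees: dict[str, IntervalTree] = {}
        labels: set[str] = set()
        for iv in intervals:
            if iv.end <= iv.start:
                continue
            tree = self._trees.setdefault(iv.chrom, IntervalTree())
            tree.addi(iv.start, iv.end, iv.state)
            labels.add(iv.state)
        self.labels = sorted(labels, key=_natural_key)

    def overlaps(self, chrom: str, start: int, end: int) -> dict[str, int]:
        """Total overlapped bp per state label for a query span."""
        out: dict[str, int] = {}
        tree = self._trees.get(chrom)
        if tree is None:
            return out
        for hit in tree.overlap(start, end):
            bp = min(end, hit.end) - max(start, hit.begin)
            if bp > 0:
                out[hit.data] = out.get(hit.data, 0) + bp
        return out


def assign_state(gene: GeneModel, states: StateIndex) -> StateAssignment:
    """Assign a gene the state with maximal bp overlap over its span."""
    overlaps = states.overlaps(gene.chrom, gene.start, gene.end)
    if not overlaps:
        return StateAssignment(gene.gene_id, UNASSIGNED, 0)
    # deterministic tie-break: among max-overlap labels take the natural-order lowest
    top_bp = max(overlaps.values())
    winners = sorted((k for k, v in overlaps.items() if v == top_bp), key=_natural_key)
    return StateAssignment(gene.gene_id, winners[0], top_bp)


def assign_states(
    ann: AnnotationSet | Iterable[GeneModel], states: StateIndex
) -> list[StateAssignment]:
    return [assign_state(g, states) for g in ann]


def state_distribution(
    assignments: Iterable[StateAssignment | str],
) -> tuple[dict[str, int], dict[str, float]]:
    """Tally assignments into per-label counts and percentages."""
    labels = [a.state if isinstance(a, StateAssignment) else a for a in assignments]
    counts = Counter(labels)
    total = sum(counts.values())
    ordered = dict(sorted(counts.items(), key=lambda kv: _natural_key(kv[0])))
    pct = {k: 100.0 * v / total for k, v in ordered.items()} if total else {}
    return ordered, pct


def chisq_montecarlo(
    observed: Mapping[str, int] | Sequence[int],
    reference: Mapping[str, float] | Sequence[float],
    B: int = 10_000,
    seed: int = 0,
) -> ChiSquareResult:
    """Pearson chi-square of observed counts vs a reference distribution,
    with a Monte-Carlo p-value.

    ``reference`` may be probabilities or reference counts (normalized
    internally).  Labels with zero reference mass and zero observed count
    are dropped; a positive observation on a zero-mass label makes the
    statistic infinite and the p-value its floor 1/(B+1).  The null draws
    ``B`` multinomial samples of the observed total from the reference
    probabilities; the add-one estimator p = (b + 1)/(B + 1) never returns
    zero.  Bit-reproducible for a fixed seed.
    """
    if isinstance(observed, Mapping):
        if not isinstance(reference, Mapping):
            raise ValueError("observed and reference must both be mappings or both sequences")
        labels = sorted(set(observed) | set(reference), key=_natural_key)
        obs = np.array([float(observed.get(l, 0)) for l in labels])
        ref = np.array([float(reference.get(l, 0)) for l in labels])
    else:
        obs = np.asarray(observed, dtype=float)
        ref = np.asarray(reference, dtype=float)
        if obs.shape != ref.shape:
            raise ValueError("observed and reference alphabets differ in length")
    if B < 1:
        raise ValueError("B must be >= 1")
    if (obs < 0).any() or (ref < 0).any():
        raise ValueError("counts and probabilities must be non-negative")
    n = obs.sum()
    if n < 1:
        raise ValueError("total observed count must be >= 1")
    if ref.sum() <= 0:
        raise ValueError("reference distribution has no mass")
    p = ref / ref.sum()

    impossible = (p == 0) & (obs > 0)
    keep = ~((p == 0) & (obs == 0))
    obs_k, p_k = obs[keep], p[keep]
    df = obs_k.size - 1

    if impossible.any():
        return ChiSquareResult(float("inf"), df, 1.0 / (B + 1), B, seed)

    expected = n * p_k
    stat = float(((obs_k - expected) ** 2 / expected).sum())

    rng = np.random.default_rng(seed)
    sims = rng.multinomial(int(round(n)), p_k, size=B).astype(float)
    sim_stats = ((sims - expected) ** 2 / expected).sum(axis=1)
    b = int((sim_stats >= stat).sum())
    return ChiSquareResult(stat, df, (b + 1) / (B + 1), B, seed)
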