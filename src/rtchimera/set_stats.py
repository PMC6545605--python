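"""Set-overlap statistics between candidate gene sets.

Enrichment of the overlap between two gene sets drawn from a common
universe is tested with the hypergeometric upper tail, P[X >= k] for
X ~ Hypergeom(N, n_a, n_b), the standard test for genotype-to-genotype
candidate-set comparisons.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Collection

from scipy.stats import hypergeom


@dataclass(frozen=True)
class OverlapSummary:
    """Counts, percentages, and enrichment p-value for a two-set overlap."""

    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    pct_of_a: float
    pct_of_b: float
    p_value: float

    @property
    def pct_of_a_int(self) -> int:
        """Integer percentage as quoted in 'about NN%' statements.

        Quoted percentages drop the fractional part (81.6% is cited as
        'about 81%'), so this truncates rather than rounds.
        """
        return math.floor(self.pct_of_a)

    @property
    def pct_of_b_int(self) -> int:
        return math.floor(self.pct_of_b)


def _validate_counts(n_universe: int, n_a: int, n_b: int, n_overlap: int) -> None:
    if min(n_universe, n_a, n_b, n_overlap) < 0:
        raise ValueError("all counts must be non-negative")
    if n_a > n_universe or n_b > n_universe:
        raise ValueError("set sizes cannot exceed the universe size")
    if n_overlap > min(n_a, n_b):
        raise ValueError("overlap cannot exceed the smaller set")
    if n_overlap < max(0, n_a + n_b - n_universe):
        raise ValueError("overlap below the minimum forced by the universe size")


def hypergeom_upper_tail(n_universe: int, n_a: int, n_b: int, n_overlap: int) -> float:
    """P[X >= n_overlap] for X ~ Hypergeom(n_universe, n_a, n_b).

    Computed via the survival function (log-space internally), so small
    tails are accurate.  ``n_overlap = 0`` gives exactly 1.
    """
    _validate_counts(n_universe, n_a, n_b, n_overlap)
    if n_overlap == 0:
        return 1.0
    return float(hypergeom.sf(n_overlap - 1, n_universe, n_a, n_b))


def overlap_summary(
    set_a: Collection[str], set_b: Collection[str], universe: Collection[str]
) -> OverlapSummary:
    """Summarize the overlap of two gene sets within a universe.

    Both percentage views are reported (overlap as % of each set) together
    with the hypergeometric upper-tail p-value.  Elements outside the
    universe are an error (listed in the message).
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    strays = sorted((a | b) - u)
    if strays:
        raise ValueError(f"elements outside the universe: {strays[:10]}"
                         + ("..." if len(strays) > 10 else ""))
    if not a or not b:
        raise ValueError("both sets must be non-empty")
    k = len(a & b)
    return OverlapSummary(
        n_universe=len(u),
        n_a=len(a),
        n_b=len(b),
        n_overlap=k,
        pct_of_a=100.0 * k / len(a),
        pct_of_b=100.0 * k / len(b),
        p_value=hypergeom_upper_tail(len(u), len(a), len(b), k),
    )


def overlap_from_counts(
    n_universe: int, n_a: int, n_b: int, n_overlap: int
) -> OverlapSummary:
    """Build an :class:`OverlapSummary` directly from printed counts."""
    _validate_counts(n_universe, n_a, n_b, n_overlap)
    if n_a == 0 or n_b == 0:
        raise ValueError("both sets must be non-empty")
    return OverlapSummary(
        n_universe=n_universe,
        n_a=n_a,
        n_b=n_b,
        n_overlap=n_overlap,
        pct_of_a=100.0 * n_overlap / n_a,
        pct_of_b=100.0 * n_overlap / n_b,
        p_value=hypergeom_upper_tail(n_universe, n_a, n_b, n_overlap),
    )


def read_gene_set(path: str | os.PathLike) -> set[str]:
    """Read a one-id-per-line gene set file (blank lines and # comments skipped)."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
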