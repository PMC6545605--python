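"""Ka/Ks (dN/dS) estimation for codon-aligned sequence pairs.

Implements the Nei-Gojobori (1986) counting method: synonymous and
nonsynonymous *sites* are counted per codon as the expected fraction of the
nine possible point mutations that are synonymous; *differences* between a
codon pair are averaged over all minimal substitution pathways (pathways
passing through a stop codon are excluded, unless no pathway avoids one).
The raw proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits
with the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).  A Ka/Ks ratio near
1 indicates absence of selective constraint; values below 1 indicate
purifying selection.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

_BASES = "ACGT"


def _standard_code() -> dict[str, str]:
    table = unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


STANDARD_CODE: dict[str, str] = _standard_code()
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in STANDARD_CODE.items() if aa != "*")
)


@dataclass(frozen=True)
class KaKsResult:
    """Site/difference counts and corrected rates for one sequence pair.

    ``S``/``N`` are synonymous/nonsynonymous site counts averaged over the
    two sequences; ``Sd``/``Nd`` are pathway-averaged observed differences.
    ``ratio`` is NaN when Ks is zero or a proportion saturates the
    Jukes-Cantor correction (p >= 3/4).
    """

    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float


def count_sites(codon: str, code: dict[str, str] | None = None) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) for one sense codon.

    Each of the nine single-nucleotide mutations contributes 1/3 of a site;
    mutations creating a stop codon count as nonsynonymous.  s + n = 3.
    """
    code = code or STANDARD_CODE
    codon = codon.upper()
    aa = code.get(codon)
    if aa is None:
        raise ValueError(f"not a codon over ACGT: {codon!r}")
    if aa == "*":
        raise ValueError(f"stop codon has no site counts: {codon}")
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if code[mutant] == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


def count_differences(
    codon_a: str, codon_b: str, code: dict[str, str] | None = None
) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences (sd, nd).

    All orderings of the differing positions are enumerated; pathways with a
    stop-codon intermediate are discarded, and if every pathway passes
    through a stop they are all retained with steps to/from stops counted
    as nonsynonymous.  sd + nd equals the number of differing positions.
    """
    code = code or STANDARD_CODE
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if code.get(c) in (None, "*"):
            raise ValueError(f"not a sense codon: {c!r}")
    diff_positions = [i for i in range(3) if a[i] != b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        sd = nd = 0.0
        through_stop = False
        current = a
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            aa_from, aa_to = code[current], code[nxt]
            if aa_to == "*" or aa_from == "*":
                # final codon is sense, so any stop here is an intermediate
                through_stop = True
                nd += 1.0
            elif aa_from == aa_to:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return sd, nd, through_stop

    results = [walk(order) for order in permutations(diff_positions)]
    valid = [(sd, nd) for sd, nd, stop in results if not stop]
    if not valid:
        valid = [(sd, nd) for sd, nd, _ in results]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def _clean_codon_pairs(seq_a: str, seq_b: str, code: dict[str, str]) -> list[tuple[str, str]]:
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be equal length")
    if len(a) % 3:
        raise ValueError("alignment length must be divisible by 3")
    pairs = []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(base not in _BASES for base in ca + cb):
            continue  # gap or ambiguity: drop the codon pairwise
        if code[ca] == "*" or code[cb] == "*":
            continue
        pairs.append((ca, cb))
    return pairs


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(seq_a: str, seq_b: str, code: dict[str, str] | None = None) -> KaKsResult:
    """Nei-Gojobori Ka/Ks for one codon-aligned pair of sequences.

    Codons containing gaps, ambiguity codes, or stops are dropped pairwise.
    Symmetric in its arguments.
    """
    code = code or STANDARD_CODE
    pairs = _clean_codon_pairs(seq_a, seq_b, code)
    if not pairs:
        raise ValueError("no comparable codons after filtering")
    S_a = S_b = 0.0
    Sd = Nd = 0.0
    for ca, cb in pairs:
        sa, _ = count_sites(ca, code)
        sb, _ = count_sites(cb, code)
        S_a += sa
        S_b += sb
        sd, nd = count_differences(ca, cb, code)
        Sd += sd
        Nd += nd
    n_codons = len(pairs)
    S = (S_a + S_b) / 2.0
    N = 3.0 * n_codons - S
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    Ks = _jukes_cantor(pS) if not math.isnan(pS) else math.nan
    Ka = _jukes_cantor(pN) if not math.isnan(pN) else math.nan
    if math.isnan(Ks) or math.isnan(Ka) or Ks == 0.0:
        ratio = math.nan
    else:
        ratio = Ka / Ks
    return KaKsResult(n_codons, S, N, Sd, Nd, pS, pN, Ks, Ka, ratio)


def load_codon_pair_fasta(path: str | os.PathLike) -> tuple[str, str]:
    """Read a pairwise codon alignment from a two-record FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, found {len(records)}")
    return str(records[0].seq), str(records[1].seq)


def kaks_table(pairs: Iterable[tuple[str, str, str]]) -> "pd.DataFrame":
    """Run NG86 over (pair_id, seq_a, seq_b) triples; returns a tidy table."""
    import pandas as pd

    rows = []
    for pair_id, a, b in pairs:
        r = ng86(a, b)
        rows.append({"pair_id": pair_id, **r.__dict__})
    return pd.DataFrame(rows)
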