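"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (exact fractions, full
enumeration) kept separate from the implementation they check.
"""
from __future__ import annotations

from fractions import Fraction
from itertools import permutations
from math import comb, log

BASES = "ACGT"

# Standard genetic code, written out independently of the package.
_CODE_BLOCKS = {
    "F": ["TTT", "TTC"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"], "M": ["ATG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "A": ["GCT", "GCC", "GCA", "GCG"], "Y": ["TAT", "TAC"],
    "H": ["CAT", "CAC"], "Q": ["CAA", "CAG"], "N": ["AAT", "AAC"],
    "K": ["AAA", "AAG"], "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "C": ["TGT", "TGC"], "W": ["TGG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "*": ["TAA", "TAG", "TGA"],
}
CODE = {codon: aa for aa, codons in _CODE_BLOCKS.items() for codon in codons}
SENSE = sorted(c for c, aa in CODE.items() if aa != "*")


def hypergeom_upper_tail_exact(N: int, n_a: int, n_b: int, k: int) -> Fraction:
    """P[X >= k] for X ~ Hypergeom(N, n_a, n_b) by exact pmf summation."""
    total = comb(N, n_b)
    acc = Fraction(0)
    for j in range(k, min(n_a, n_b) + 1):
        if n_b - j > N - n_a:
            continue
        acc += Fraction(comb(n_a, j) * comb(N - n_a, n_b - j), total)
    return acc


def count_sites_enum(codon: str) -> tuple[Fraction, Fraction]:
    """Synonymous site count by enumerating all 9 point mutations."""
    aa = CODE[codon]
    s = Fraction(0)
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if CODE[mutant] == aa:
                s += Fraction(1, 3)
    return s, 3 - s


def count_differences_enum(a: str, b: str) -> tuple[Fraction, Fraction]:
    """Pathway-averaged differences by enumerating position orderings."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return Fraction(0), Fraction(0)
    paths = []
    for order in permutations(diff):
        sd = nd = 0
        cur = a
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if CODE[nxt] == "*":
                hit_stop = True
                nd += 1
            elif CODE[cur] == "*":
                nd += 1
            elif CODE[cur] == CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, hit_stop))
    valid = [(sd, nd) for sd, nd, stop in paths if not stop]
    if not valid:
        valid = [(sd, nd) for sd, nd, _ in paths]
    n = len(valid)
    return (Fraction(sum(v[0] for v in valid), n), Fraction(sum(v[1] for v in valid), n))


def ng86_oracle(seq_a: str, seq_b: str) -> dict:
    """Full independent NG86 + Jukes-Cantor computation."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S_a = S_b = Fraction(0)
    Sd = Nd = Fraction(0)
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3].upper(), seq_b[i:i + 3].upper()
        if any(x not in BASES for x in ca + cb) or CODE[ca] == "*" or CODE[cb] == "*":
            continue
        n_codons += 1
        S_a += count_sites_enum(ca)[0]
        S_b += count_sites_enum(cb)[0]
        sd, nd = count_differences_enum(ca, cb)
        Sd += sd
        Nd += nd
    S = (S_a + S_b) / 2
    N = 3 * n_codons - S
    pS, pN = float(Sd / S), float(Nd / N)
    jc = lambda p: float("nan") if p >= 0.75 else -0.75 * log(1 - 4 * p / 3)
    Ks, Ka = jc(pS), jc(pN)
    return {"n_codons": n_codons, "S": float(S), "N": float(N),
            "Sd": float(Sd), "Nd": float(Nd), "pS": pS, "pN": pN,
            "Ks": Ks, "Ka": Ka}
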