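"""Synthetic data generators with planted ground truth.

Every generator is a pure function of its seed and configuration: rerunning
with the same inputs produces byte-identical files.  The readthrough
generator lays out upstream/downstream gene pairs on one chromosome and
plants elevated strand-matched coverage across the intergenic region of a
chosen fraction of pairs in the "mutant" sample, emulating defective
transcription termination; homolog-hit, codon-pair, and chromatin-state
generators plant adjacency scenarios, a known dN/dS, and a distribution
shift, respectively, each alongside a machine-readable truth table.
"""
from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import AnnotationSet, GeneModel
from .detect import CoverageTrack
from .kaks import SENSE_CODONS, STANDARD_CODE, _BASES

SCENARIOS_INFORMATIVE = ("adjacent", "distant", "g1_only", "g2_only")


@dataclass(frozen=True)
class SimConfig:
    """Configuration for the planted-readthrough coverage simulator.

    Depth units are per-base coverage; ``readthrough_ratio`` multiplies the
    intergenic background depth in the mutant at planted pairs.  Library
    sizes default to the total emitted coverage of each sample.
    """

    seed: int = 0
    n_gene_pairs: int = 100
    gene1_length: tuple[int, int] = (1000, 3000)
    gene2_length: tuple[int, int] = (500, 2000)
    intergenic_gap: tuple[int, int] = (200, 2000)
    pair_spacing: int = 5000
    base_depth: float = 20.0
    background_depth: float = 2.0
    readthrough_fraction: float = 0.2
    readthrough_ratio: float = 6.0
    noise: str = "poisson"  # "none" | "poisson"
    library_size_wt: int | None = None
    library_size_mut: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.readthrough_fraction <= 1.0):
            raise ValueError("readthrough_fraction must be in [0, 1]")
        if self.base_depth <= 0 or self.background_depth <= 0:
            raise ValueError("depths must be > 0")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")


@dataclass
class ReadthroughDataset:
    """In-memory simulated dataset plus writers for the on-disk layout."""

    config: SimConfig
    annotation: AnnotationSet
    wt: CoverageTrack
    mut: CoverageTrack
    truth: pd.DataFrame  # columns: pair_id, gene1_id, gene2_id, strand, planted

    def planted_gene1_ids(self) -> set[str]:
        return set(self.truth.loc[self.truth["planted"], "gene1_id"])

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Write GTF, four bedGraphs, truth table, and a manifest; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": outdir / "genes.gtf",
            "wt_plus": outdir / "wt.plus.bedgraph",
            "wt_minus": outdir / "wt.minus.bedgraph",
            "mut_plus": outdir / "mut.plus.bedgraph",
            "mut_minus": outdir / "mut.minus.bedgraph",
            "truth": outdir / "truth.tsv",
            "libsizes": outdir / "library_sizes.json",
        }
        write_gtf(self.annotation, paths["annotation"])
        write_bedgraph(self.wt.plus, paths["wt_plus"])
        write_bedgraph(self.wt.minus, paths["wt_minus"])
        write_bedgraph(self.mut.plus, paths["mut_plus"])
        write_bedgraph(self.mut.minus, paths["mut_minus"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["libsizes"], "w") as fh:
            json.dump(
                {"wt": self.wt.library_size, "mut": self.mut.library_size},
                fh, indent=0, sort_keys=True,
            )
            fh.write("\n")
        write_manifest(outdir, asdict(self.config), list(paths.values()))
        return {k: str(v) for k, v in paths.items()}


def write_gtf(ann: AnnotationSet, path: str | os.PathLike) -> None:
    """Write gene spans as minimal GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for g in ann:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_bedgraph(depth: Mapping[str, np.ndarray], path: str | os.PathLike) -> None:
    """Run-length encode per-base depth vectors as bedGraph (zeros omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(depth):
            arr = np.asarray(depth[chrom])
            if arr.size == 0:
                continue
            changes = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], changes])
            ends = np.concatenate([changes, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    v_repr = int(v) if float(v).is_integer() else float(v)
                    fh.write(f"{chrom}\t{s}\t{e}\t{v_repr}\n")


def write_manifest(
    outdir: str | os.PathLike, config: dict, files: Sequence[os.PathLike]
) -> str:
    """Write a manifest recording the config and sha256 of each output file."""
    outdir = Path(outdir)
    hashes = {}
    for f in files:
        f = Path(f)
        hashes[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = {"config": config, "sha256": hashes}
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return str(path)


def simulate_readthrough_dataset(cfg: SimConfig) -> ReadthroughDataset:
    """Simulate stranded WT/mutant coverage over gene pairs with planted readthrough.

    Geometry: each pair occupies GENE1, an intergenic gap, then GENE2 in the
    gene orientation (mirrored for minus-strand pairs), with dead space
    between pairs so downstream windows never touch a neighboring pair.
    Expected depth: GENE1 bodies at ``base_depth`` in both samples; GENE2
    bodies and intergenic gaps at ``background_depth``.  At planted pairs
    the mutant intergenic depth is ``readthrough_ratio x background`` over
    the first 90% of the gap, decaying linearly back to background over the
    final 10%.  Per-base Poisson noise is applied when enabled.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"
    n_planted = int(round(cfg.n_gene_pairs * cfg.readthrough_fraction))
    planted_idx = set(
        rng.choice(cfg.n_gene_pairs, size=n_planted, replace=False).tolist()
    )

    genes: list[GeneModel] = []
    truth_rows = []
    # expected-depth vectors, then noise at the end
    segments = []  # (strand, start, end, depth_wt, depth_mut) or callables
    cursor = cfg.pair_spacing
    for i in range(cfg.n_gene_pairs):
        strand = "+" if rng.random() < 0.5 else "-"
        g1_len = int(rng.integers(cfg.gene1_length[0], cfg.gene1_length[1] + 1))
        g2_len = int(rng.integers(cfg.gene2_length[0], cfg.gene2_length[1] + 1))
        gap = int(rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1))
        planted = i in planted_idx
        g1_id, g2_id = f"pair{i:04d}_g1", f"pair{i:04d}_g2"
        if strand == "+":
            g1 = GeneModel(g1_id, chrom, cursor, cursor + g1_len, "+")
            gap_start, gap_end = g1.end, g1.end + gap
            g2 = GeneModel(g2_id, chrom, gap_end, gap_end + g2_len, "+")
            last_end = g2.end
        else:
            g2 = GeneModel(g2_id, chrom, cursor, cursor + g2_len, "-")
            gap_start, gap_end = g2.end, g2.end + gap
            g1 = GeneModel(g1_id, chrom, gap_end, gap_end + g1_len, "-")
            last_end = g1.end
        genes.append(g1)
        genes.append(g2)
        truth_rows.append(
            {"pair_id": f"pair{i:04d}", "gene1_id": g1_id, "gene2_id": g2_id,
             "strand": strand, "planted": planted, "intergenic_gap": gap}
        )
        segments.append((strand, g1.start, g1.end, cfg.base_depth, cfg.base_depth))
        segments.append(
            (strand, g2.start, g2.end, cfg.background_depth, cfg.background_depth)
        )
        # intergenic gap: background in WT; elevated + decaying tail if planted
        mut_gap = _intergenic_profile(
            gap, strand, planted, cfg.background_depth, cfg.readthrough_ratio
        )
        segments.append((strand, gap_start, gap_end, cfg.background_depth, mut_gap))
        cursor = last_end + cfg.pair_spacing

    chrom_len = cursor
    expected = {
        "wt": {"+": np.zeros(chrom_len), "-": np.zeros(chrom_len)},
        "mut": {"+": np.zeros(chrom_len), "-": np.zeros(chrom_len)},
    }
    for strand, start, end, d_wt, d_mut in segments:
        expected["wt"][strand][start:end] += d_wt
        expected["mut"][strand][start:end] += d_mut

    def realize(exp: np.ndarray) -> np.ndarray:
        if cfg.noise == "poisson":
            return rng.poisson(exp).astype(float)
        return np.round(exp)

    depth = {
        sample: {s: realize(expected[sample][s]) for s in ("+", "-")}
        for sample in ("wt", "mut")
    }
    lib_wt = cfg.library_size_wt or max(
        1, int(depth["wt"]["+"].sum() + depth["wt"]["-"].sum())
    )
    lib_mut = cfg.library_size_mut or max(
        1, int(depth["mut"]["+"].sum() + depth["mut"]["-"].sum())
    )
    ann = AnnotationSet(genes, chrom_lengths={chrom: chrom_len})
    wt = CoverageTrack("wt", lib_wt, {chrom: depth["wt"]["+"]}, {chrom: depth["wt"]["-"]})
    mut = CoverageTrack(
        "mut", lib_mut, {chrom: depth["mut"]["+"]}, {chrom: depth["mut"]["-"]}
    )
    truth = pd.DataFrame(truth_rows)
    return ReadthroughDataset(cfg, ann, wt, mut, truth)


def _intergenic_profile(
    gap: int, strand: str, planted: bool, background: float, ratio: float
) -> np.ndarray:
    """Expected mutant depth across the intergenic gap, oriented genomically.

    Planted pairs carry ratio x background over the first 90% of the gap
    (reading away from GENE1), then a linear decay back to background over
    the final 10%.
    """
    if not planted:
        return np.full(gap, background)
    profile = np.full(gap, ratio * background)
    n_decay = max(1, int(round(gap * 0.1)))
    decay = np.linspace(ratio * background, background, n_decay + 1)[1:]
    profile[gap - n_decay :] = decay
    if strand == "-":
        profile = profile[::-1].copy()  # GENE1 sits genomically after the gap
    return profile


def simulate_homolog_hits(
    pair_ids: Sequence[str],
    genome_ids: Sequence[str],
    scenario_probs: Mapping[str, float],
    seed: int = 0,
    max_gap_bp: int = 5000,
    decoy_prob: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a homolog hit table realizing planted adjacency scenarios.

    ``scenario_probs`` covers the five scenarios (missing keys mean 0).
    Adjacent cells draw a closest-edge gap uniformly in [0, max_gap_bp]
    (the boundary is inclusive, matching the classifier); distant cells
    place the genes either far apart on one scaffold or on different
    scaffolds.  With probability ``decoy_prob`` a cell also receives a weak
    decoy hit (e-value above the 1e-10 cutoff) that the filter must remove.
    Returns (hit table, truth table).
    """
    names = list(scenario_probs)
    probs = np.array([scenario_probs[k] for k in names], dtype=float)
    if probs.sum() <= 0 or (probs < 0).any():
        raise ValueError("scenario probabilities must be non-negative and sum > 0")
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    hit_rows = []
    truth_rows = []

    def strong_evalue() -> float:
        return float(10.0 ** -rng.uniform(10.0, 60.0))

    for pair in pair_ids:
        for genome in genome_ids:
            scenario = names[int(rng.choice(len(names), p=probs))]
            truth_rows.append(
                {"pair_id": pair, "genome_id": genome, "scenario": scenario}
            )
            g1_start = int(rng.integers(1000, 50_000))
            g1_len = int(rng.integers(300, 2000))
            g2_len = int(rng.integers(300, 2000))
            emit_g1 = scenario in ("adjacent", "distant", "g1_only")
            emit_g2 = scenario in ("adjacent", "distant", "g2_only")
            scaffold_g1 = "scaf1"
            if scenario == "adjacent":
                gap = int(rng.integers(0, max_gap_bp + 1))
                g2_start, scaffold_g2 = g1_start + g1_len + gap, scaffold_g1
            elif scenario == "distant":
                if rng.random() < 0.5:
                    gap = int(rng.integers(max_gap_bp + 1, max_gap_bp * 20))
                    g2_start, scaffold_g2 = g1_start + g1_len + gap, scaffold_g1
                else:
                    g2_start, scaffold_g2 = int(rng.integers(1000, 50_000)), "scaf2"
            else:
                g2_start, scaffold_g2 = int(rng.integers(1000, 50_000)), "scaf1"
            if emit_g1:
                hit_rows.append(
                    {"pair_id": pair, "gene_role": "g1", "genome_id": genome,
                     "scaffold": scaffold_g1, "start": g1_start,
                     "end": g1_start + g1_len, "evalue": strong_evalue()}
                )
            if emit_g2:
                hit_rows.append(
                    {"pair_id": pair, "gene_role": "g2", "genome_id": genome,
                     "scaffold": scaffold_g2, "start": g2_start,
                     "end": g2_start + g2_len, "evalue": strong_evalue()}
                )
            if rng.random() < decoy_prob:
                role = "g1" if rng.random() < 0.5 else "g2"
                s = int(rng.integers(1000, 50_000))
                hit_rows.append(
                    {"pair_id": pair, "gene_role": role, "genome_id": genome,
                     "scaffold": "scaf_decoy", "start": s, "end": s + 500,
                     "evalue": float(10.0 ** -rng.uniform(1.0, 9.0))}
                )
    return pd.DataFrame(hit_rows, columns=[
        "pair_id", "gene_role", "genome_id", "scaffold", "start", "end", "evalue"
    ]), pd.DataFrame(truth_rows)


def simulate_codon_pair(
    n_codons: int,
    omega: float,
    expected_subs_per_codon: float,
    seed: int = 0,
) -> tuple[str, str, int]:
    """Evolve a codon sequence at a known dN/dS; returns (ancestor, derived, n_subs).

    The ancestor is a uniform draw of sense codons.  The derived sequence
    accumulates ``Poisson(n_codons * expected_subs_per_codon)`` accepted
    single-nucleotide substitutions: a random site/base proposal is rejected
    if it creates a stop codon, accepted with probability 1 when synonymous
    and ``omega`` when nonsynonymous.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if expected_subs_per_codon < 0:
        raise ValueError("expected_subs_per_codon must be >= 0")
    rng = np.random.default_rng(seed)
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    ancestor = "".join(codons)
    seq = list(ancestor)
    n_target = int(rng.poisson(n_codons * expected_subs_per_codon))
    accepted = 0
    max_tries = 1000 * max(1, n_target)
    tries = 0
    while accepted < n_target and tries < max_tries:
        tries += 1
        pos = int(rng.integers(0, len(seq)))
        base = _BASES[int(rng.integers(0, 4))]
        if seq[pos] == base:
            continue
        c0 = pos - pos % 3
        old_codon = "".join(seq[c0 : c0 + 3])
        new_codon = old_codon[: pos - c0] + base + old_codon[pos - c0 + 1 :]
        if STANDARD_CODE[new_codon] == "*":
            continue
        synonymous = STANDARD_CODE[new_codon] == STANDARD_CODE[old_codon]
        if synonymous or rng.random() < omega:
            seq[pos] = base
            accepted += 1
    return ancestor, "".join(seq), accepted


def simulate_state_assignments(
    n_genes: int,
    probs_null: Mapping[str, float],
    probs_shifted: Mapping[str, float],
    n_shifted: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-gene state labels: ``n_shifted`` genes from the shifted
    distribution, the rest from the null.  Returns gene_id, state, shifted.
    """
    if set(probs_null) != set(probs_shifted):
        raise ValueError("null and shifted distributions must share labels")
    if not (0 <= n_shifted <= n_genes):
        raise ValueError("n_shifted must be in [0, n_genes]")
    labels = sorted(probs_null)
    p0 = np.array([probs_null[l] for l in labels], dtype=float)
    p1 = np.array([probs_shifted[l] for l in labels], dtype=float)
    p0, p1 = p0 / p0.sum(), p1 / p1.sum()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_genes):
        shifted = i < n_shifted
        p = p1 if shifted else p0
        state = labels[int(rng.choice(len(labels), p=p))]
        rows.append({"gene_id": f"gene{i:05d}", "state": state, "shifted": shifted})
    return pd.DataFrame(rows)
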