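# Methods

This note documents the models, conventions, defaults, and numerical
choices behind `rtchimera`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and annotation handling

All internal coordinates are 0-based half-open; GFF3/GTF input (1-based
inclusive) is converted on read and BED is handled natively, so interval
arithmetic carries no off-by-one adjustments. Multi-transcript genes are
collapsed to the union span of their features because readthrough is
quantified per gene. The downstream window of a `+` gene is
`[end, end + L)` and of a `-` gene `[start − L, start)`, with `L = 500` bp
by default. Windows are clipped to chromosome bounds when chromosome
lengths are known; a window falling entirely off the chromosome is emitted
with zero length rather than dropped, so there is always exactly one window
per gene. Windows are deliberately **not** truncated at neighboring genes:
the readthrough signal extends into the downstream gene, and truncation
would erase exactly the signal being measured.

## Readthrough calling

For each gene, strand-matched per-base coverage is summed over the gene
body and the downstream window in wild type and mutant. Counts are
normalized as rpm = count × 10⁶ / library size and
RPKM = count × 10⁹ / (library size × length). The downstream fold change is
FC = rpm_mut / rpm_wt, defined as +∞ when the wild-type window is silent
but the mutant is not, and as an undefined sentinel (NaN; never a candidate
by FC alone) when both are silent. A gene is a readthrough candidate when:

| filter | default | purpose |
| --- | --- | --- |
| FC ≥ `fc_threshold` | 2.0 | the readthrough signal itself |
| gene RPKM ≥ `min_rpkm` in both samples | 1.0 | drop loci too weakly expressed to interpret |
| gene not differentially expressed | explicit id list | an apparent downstream increase can simply track an upregulated gene |
| mutant window count ≥ `min_mut_window_reads` | 10 | a raw-count floor so that +∞ fold changes on near-empty windows do not become calls |

The twofold default reflects the headline analysis; analyses that use a
log₂ FC ≥ 2 cutoff are served by passing `fc_threshold=4`. Differential-
expression exclusion is normally an externally produced gene-id list (any
DE tool); a fallback mode (`de_exclusion=None`) excludes genes whose
body-rpm fold change falls outside `[1/fc_threshold, fc_threshold]`.
Replicate tracks are pooled by summing counts and library sizes before
normalization. All quantities are invariant to jointly rescaling counts and
library sizes.

## Overlap statistics

Candidate-set overlaps between genotypes use the hypergeometric upper tail
P[X ≥ k] computed through SciPy's survival function (log-space internally);
a grid comparison against exact rational-arithmetic enumeration (N ≤ 60)
verifies 1e-12 relative agreement. The universe defaults to the supplied
annotation's gene count and is overridable, since published overlap tests
rarely state N; note the p-value depends on N but the percentage summaries
do not. Quoted integer percentages truncate the fractional part
(e.g. 142/174 = 81.6% is cited as "about 81%"); both the exact and the
truncated forms are exposed.

## Chromatin states

Genes are assigned the state label with maximal total base-pair overlap
over the gene span (fragmented segments of one label accumulate); ties
break to the naturally lowest label (CS2 before CS7) for determinism, and
zero overlap yields `unassigned`. Distribution comparison uses Pearson's
X² = Σ (Oᵢ − Eᵢ)²/Eᵢ with Eᵢ = n·pᵢ from an explicit reference distribution
or a reference gene set tallied on the fly. Because the tested gene sets
are small, the p-value is Monte-Carlo: B multinomial draws of size n from
p, with the add-one estimator p = (b + 1)/(B + 1), which is never zero and
is bit-reproducible for a fixed seed. Labels with pᵢ = 0 and Oᵢ = 0 are
dropped; observed mass on a zero-probability label makes the statistic +∞
with the floor p-value. At the package's own worked example (observed
[10, 0] against a fair split), the estimator's target is the exact
finite-sample tail 2·0.5¹⁰ = 0.001953; the asymptotic df = 1 tail
(0.001565) is close but not the correct reference at n = 10, which the
tests reflect.

## Microsynteny classification

Homolog hits are filtered at e-value ≤ 10⁻¹⁰ (boundary inclusive). A pair
is *adjacent* in a genome when **any** combination of one GENE1 hit and one
GENE2 hit shares a scaffold with a closest-edge gap ≤ 5000 bp (overlapping
hits have gap 0); *distant* when both genes have hits but never that close;
*g1_only*/*g2_only*/*absent* by hit-set emptiness. "Distance" is the
closest-edge gap rather than a midpoint distance because hit lengths vary
widely across genomes. Per-pair scenario percentages exclude absent genomes
from the denominator (reported separately), since a genome lacking both
genes is uninformative about their arrangement.

## Ka/Ks (Nei–Gojobori)

Synonymous sites per codon are counted as the expected synonymous fraction
of the nine single-nucleotide mutations (mutations to stops count as
nonsynonymous), so s + n = 3 for every sense codon. Differences between a
codon pair are averaged over all minimal substitution pathways; pathways
through stop codons are excluded, falling back to all pathways (stop steps
counted nonsynonymous) if none survive. Site counts are averaged over the
two sequences; codons containing gaps, ambiguity codes, or stops are
dropped pairwise. Proportions pS = Sd/S and pN = Nd/N receive the
Jukes–Cantor correction d = −(3/4) ln(1 − 4p/3), undefined (NaN) at
saturation p ≥ 3/4, and the ratio is NaN when Ks = 0. NG86 was chosen over
ML codon models (GY94 etc.) for transparency: every intermediate quantity
is checkable against brute-force enumeration, which the test suite does,
alongside a cross-check against Biopython's independent NG86 implementation.
Only the standard genetic code ships, but the code table is injectable.

## PolyA sites and relative quantification

Clone-end positions map to rel_pos = clone − stop on `+` (mirrored on `-`),
with 1 the first base downstream of the stop codon's last base; 0 (a clone
ending exactly at the stop) is flagged rather than rejected, and negative
values mark clones ending inside the CDS. Tallying is exact by default;
an optional cluster window greedily merges positions onto modal positions
(ties toward the stop codon), conserving total clone count — exposed
because published "polyA site clusters" imply some merging without stating
a rule. ΔΔCt fold change is 2^−((Ct_t,cond − Ct_ref,cond) − (Ct_t,ctrl −
Ct_ref,ctrl)); IP enrichment is (IP_target/IP_ref)/(input_target/input_ref),
scale-invariant in all four inputs.

## Synthetic data: what it emulates and what it does not

The readthrough generator defines the study conditions for the caller:
100 gene pairs by default, GENE1 bodies at mean depth 20×, GENE2 bodies and
intergenic gaps (uniform 200–2000 bp) at background 2× — emulating an
expressed upstream gene and a silent/lowly expressed downstream partner —
with 20% of pairs planted: mutant intergenic coverage at 6× background
across the first 90% of the gap, decaying linearly to background over the
final 10%, so detection is dominated by window placement rather than decay
modeling. Depths approximate a deeply covered compact genome; per-base
Poisson noise is the only stochasticity. Library sizes default to the total
emitted coverage of each sample. Pairs are separated by 5 kb of dead space
so windows never touch a neighboring pair.

Real data differ in ways the simulation does not model: mappability gaps,
fragment-level (not base-level) noise correlation, 3′ coverage bias,
antisense leakage in stranded protocols, replicate overdispersion, and
genes whose own expression shifts in the mutant. Passing the planted-
recovery tests therefore demonstrates the correctness of the counting,
normalization, and filtering logic under the stated signal model — not the
expected sensitivity/precision on a real mutant transcriptome.

The codon-pair generator draws a random sense-codon ancestor and applies a
Poisson number of accepted single-nucleotide substitutions (target
0.3/codon by default, below saturation), accepting synonymous proposals
always and nonsynonymous ones with probability ω, rejecting stop-creating
changes; under this process NG86 recovers ω ≈ 1 for neutral evolution,
which the tests verify at 500 codons × 50 replicates. The homolog-hit
generator realizes each drawn scenario geometrically (adjacent gaps uniform
in [0, 5000], inclusive of the boundary) and adds occasional weak decoy
hits above the e-value cutoff to exercise filtering. All generators are
pure functions of seed and config; reruns are byte-identical.

## Problem sizes and determinism

Default analysis/test sizes — 100 gene pairs per simulated dataset, 20
noise seeds for caller recovery, B = 10⁴–10⁵ Monte-Carlo draws, 50 codon
replicates of 500 codons — were chosen so that planted-truth checks have
negligible sampling ambiguity while the whole suite runs in seconds. Every
stochastic routine takes an explicit seed (NumPy `default_rng`), and the
CLI writes a manifest with the configuration and sha256 of each output, so
any reported number is reproducible from its manifest.

## Known limitations

- The caller quantifies a fixed downstream window; it does not assemble
  chimera structure, detect splice junctions across the gene–gene
  junction, or locate readthrough breakpoints.
- The internal DE-exclusion fallback is a crude fold-change rule, not a
  replacement for a proper differential-expression test with dispersion
  modeling.
- The hypergeometric p-value is reported per overlap; no multiple-testing
  correction is applied across many pairwise comparisons.
- NG86 ignores transition/transversion bias and codon-frequency structure;
  for strongly biased sequences a model-based estimator will differ.
- Chromatin-state assignment reduces a gene to a single modal label; genes
  straddling two states lose that information.
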