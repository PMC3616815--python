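# Methods

This note documents the models, conventions and numerical choices
behind `isoprime`, and what the synthetic-data suites do and do not
demonstrate about real data.

## Data model and coordinates

Sequences carry an explicit `(gene_id, allele_id)` label; every
analysis distinguishes variation *between* genes (paralogy) from
variation *within* a gene (allelism). FASTA headers parse as
`>geneID|alleleID|sourceID` (configurable regex with named groups).
Ungapped positions are 1-based inclusive — a primer panel's `start`
column is the forward primer's 5′ end on the reference coding
sequence — while alignment columns are 0-based internally. Coordinate
maps are the identity on every non-gap column (property-tested).

A Ct of "Undetermined" is parsed as a censored observation
(no signal within `max_cycle` cycles, default 40, the usual cycling
protocol length). Censoring is carried as an explicit flag and
propagates as NaN through quantification; it is never treated as a
measured zero.

## SNP classification

For a column and gene *g*:

* *gene-differentiating for g*: no allele of *g* is gapped or
  ambiguous, all agree on a concrete residue *x*, and no allele of any
  other gene could carry *x*. IUPAC ambiguity codes are expanded on the
  competitor side — an `N` in any other gene defeats the claim — and
  rejected on the target side: a specificity claim is never built on
  ambiguous evidence. A gap is not a residue, so a gene with an indel
  at the column cannot be gene-differentiating there (indel-based
  discrimination is out of scope).
* *allele-differentiating in g*: *g*'s own alleles show ≥ 2 distinct
  non-gap residues.

The two sets are mutually exclusive per gene per column by
construction, and the classification is invariant under record order.
A single-gene family has no competitors, so no column is
gene-differentiating (rather than vacuously all).

`snp_cons` counts footprint positions where the design template differs
from the family-wide majority consensus (gaps and ambiguity codes do
not vote; ties break alphabetically — a stated rule because any
consensus needs one).

## Phenetics

Pairwise identity uses pairwise deletion: columns where either sequence
is gapped are excluded from numerator and denominator; this convention
is stated explicitly so that results are auditable. p-distance is
`1 − identity/100`. Neighbour joining follows the Saitou–Nei
agglomeration with the standard Q-criterion and three-point
branch-length formulas; ties in the Q-matrix break on the lowest index
pair (determinism), and negative branch-length estimates are clamped to
zero with a warning. On additive matrices the algorithm provably
recovers the generating topology and path lengths; the test suite
verifies this against brute-force topology enumeration (n = 5, 6) and
random additive trees up to n = 8. Subfamily assignment cuts the k−1
longest internal branches and numbers the components by their
alphabetically first leaf; this is a defined proxy for the visual
clade cut a human makes on a drawn tree, not a clustering claim.

## Primer thermodynamics

`primer_tm` is a two-state nearest-neighbour calculation with the
unified dinucleotide parameter set, terminal-initiation terms and a
symmetry correction for self-complementary oligos. Entropy is
salt-corrected by `0.368·(N−1)·ln[Na+]` and
`Tm = 1000·ΔH / (ΔS + R·ln(C_T/4)) − 273.15` (C_T the total strand
concentration, x = 1 instead of 4 for self-complementary sequences).
Defaults: 250 nM oligo, 50 mM monovalent. The implementation is
cross-checked in the tests against an independent nearest-neighbour
engine under matched conventions to 0.01 °C.

`dimer_score` measures the worst ungapped antiparallel complementarity
run between two oligos over all offsets: +1 per complementary pair, +2
when the pair involves either oligo's 3′-terminal base, because
3′-extensible dimers are the ones that amplify. The default pair
threshold of 10 allows the short incidental complementarity any two
20-mers show while rejecting extensible 3′ overlaps of ~5 bp or more.

## Design rules and their defaults

* primer length 18–24 nt, GC 20–80 %, amplicon 80–200 bp — the
  standard envelope for SYBR-green RT-PCR assays of this kind;
* anchor window 1 nt: the gene-differentiating SNP sits under the
  3′-terminal base, the position with the strongest extension-blocking
  effect; configurable, since some chemistries discriminate well with
  the SNP at position −2;
* allele window 2 nt: allele-differentiating SNPs are tolerated only in
  the two outermost 5′ bases, and only in one primer of a pair, so
  every allele of the target still amplifies;
* amplicon range is a *soft* constraint with a ±15 % warn band, because
  an otherwise-perfect anchored pair a few bp outside the nominal range
  is usually preferable to no assay at all (hard rejection beyond the
  band);
* Tm spread within a pair ≤ 3 °C;
* recommended Ta = min(Tm) − 2 °C clamped to 61–63 °C, the range in
  which such assays are typically optimised for specificity;
* ranking is lexicographic: fewest allele SNPs, most gene SNPs,
  smallest Tm spread, shortest amplicon, leftmost position — a stated
  total order so designs are reproducible.

Pairs must contain ≥ 1 anchored primer; a primer shared between two
close paralogs is legitimate exactly when its partner carries the
discrimination. Single-gene families waive the anchoring requirement
(there is nothing to discriminate against) and the report records the
waiver. Candidate windows containing degenerate template bases are
skipped. Per-gene rejection tallies (length, Tm spread, dimers,
anchoring, allele rule) are reported whenever no pair survives.

## In-silico PCR model

A binding site is *productive* when it has zero mismatches in the
3′-terminal window (default 4 nt) and at most `max_mm` (default 2)
elsewhere. These are model parameters, not measured constants: the real
mismatch tolerance of a polymerase under a given Ta is not knowable
from sequence alone, so the model is deliberately parameterised and the
defaults chosen to be conservative for specificity screening.
Near-miss sites (one mismatch over tolerance) are reported unproductive
so reports show what was close. Amplicons require a convergent
productive site pair within 1500 bp; both primer-role orientations are
scanned. Partial 3′-overhang priming is not modelled. The verdict
"specific" demands every allele of the target amplify and no allele of
any other gene amplify; a shared-primer note is attached when a single
primer matches a non-target that the pair does not co-amplify.

Product Tm uses the long-product heuristic
`81.5 + 0.41·%GC − 675/len + 16.6·log10([Na+])` — an estimate for
comparing expected melt peaks, not a thermodynamic computation. Melt QC
smooths fluorescence (moving average, window 3), takes −dF/dT by
central differences and requires exactly one peak with prominence
≥ 5 % of the derivative range; two peaks mean a nonspecific product or
dimer, none means no product.

## Quantification

Standard curves regress Ct on log₁₀ of *relative* input (top dilution
= 1), since arbitrary-unit output needs no absolute copy numbers. All
wells enter the regression (duplicates are not pre-averaged; both
conventions are supported). `E = 10^(−1/slope) − 1`; slope −3.3219 ⇔
E = 1 exactly. Technical replicates are averaged on the Ct scale —
the instrument convention — before conversion to quantity through the
assay's own curve; normalisation to the reference gene happens within
each sample, and biological replicates are summarised as mean ± SEM
(sd/√n, ddof = 1).

The expression call requires at least one biological replicate with all
technical replicates detected and a median Ct ≥ 3 cycles below any NTC
signal; the 3-cycle guard is a stated, configurable default (≈ an
8-fold quantity margin over contamination/dimer signal), as no numeric
call rule is standard. Non-expressed genes report 0 A.U. with the flag,
never a back-transformed censored value.

Reference-gene stability is scored as the SD of mean Ct across
(tissue × cultivar) groups, ascending — the simplest defensible
stability index; multi-reference geometric-mean schemes are out of
scope. ANOVA is a fixed-effects OLS decomposition (type-II sums of
squares) on main effects; its type-I error is verified at α = 0.05 on
2000 null simulations.

## Synthetic data: what it does and does not show

Families are simulated on a *star* phylogeny: an ancestral sequence
(GC bias 0.5 by default) mutated independently per gene, then alleles
mutated from each gene's reference. Substitution is uniform across
sites with equal exchange among the three alternative bases. For
per-branch substitution probability q, two genes differ at a site with
probability `2q(1−q) + (2/3)q²`; the generator inverts this
(`q = ¾(1 − √(1 − 4d/3))`) so `gene_divergence` *is* the expected
between-gene p-distance. `allele_divergence` is the expected
reference-vs-variant p-distance (a single branch). Defaults — 5 genes,
2 alleles, 480 bp, 10 % between-gene and 0.5 % within-gene
divergence — mirror a compact allergen-family coding sequence with the
published identity ranges (roughly 90 % between genes, > 99 % within).
The truth record stores every placed mutation, so expected SNP
classifications are checkable without re-deriving them from output.

Simulated qPCR uses `Ct = baseline − log₁₀(q)/log₁₀(1+E) + N(0, sd)`
with censoring at 40 cycles, 6 × 1:10 standards in duplicate,
triplicate unknowns and duplicate NTCs — the bench design of a typical
study — with 0.15 Ct noise as a realistic instrument sd.

What passing these suites shows: the pipeline is internally consistent
(designed panels are specific on their source families; known ratios
are recovered within stochastic bounds; estimators converge as noise
vanishes). What they do not show: robustness to indels, codon
structure, subfamily-correlated divergence (available behind the
simulator's star-topology default), secondary-structure failures,
inhibitors, or real polymerase mismatch tolerance. Bench validation
(end-point PCR, amplicon sequencing) has no computational counterpart
here.

## Problem sizes

The shipped test and acceptance runs use 5-gene, 480-bp families
(20 replicate seeds for the specificity study), 12 replicate plates for
the ratio-recovery study, and 2000 null simulations for the ANOVA
calibration — sizes chosen to make each stochastic estimate's Monte
Carlo error small relative to the bound being checked.

## Known limitations

* No indel-aware discrimination, probe design, multiplexing or
  thermodynamic off-target ranking.
* The in-silico specificity model's mismatch parameters are assumptions;
  verdicts are screening evidence, not validation.
* Final primer concentrations (e.g. 70 vs 100 nM per assay) are user
  inputs, not predictions: no model links concentration to specificity.
* The subfamily cut (k−1 longest internal branches) is one defensible
  formalisation of a visual clade count; other cut rules give other
  partitions.
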