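# isoprime

Paralog-discriminating qPCR assay design and quantification for
multigene families.

## The problem

Many traits of interest — plant allergens among them — are encoded by
families of near-identical paralogous genes, each segregating slightly
different alleles across cultivars. Measuring the expression of *each
individual gene* by qRT-PCR requires primer pairs that amplify one
locus, all of its alleles, and nothing else, even when family members
share > 95 % sequence identity. Off-the-shelf primer design does not
solve this: the discriminating signal is one or a few single-nucleotide
differences, and their *placement within the primer* is what creates
specificity.

`isoprime` implements the full computational workflow around such an
assay:

1. **SNP classification** — every polymorphic column of a labelled
   family alignment is classified per gene as *gene-differentiating*
   (all alleles of gene *g* share a residue no other gene can carry) or
   *allele-differentiating* (alleles of *g* disagree). The two are
   mutually exclusive for a gene at a column.
2. **Phenetics** — pairwise identity and amino-acid substitution
   statistics with pairwise gap deletion, Saitou–Nei neighbour-joining
   trees from p-distances, and subfamily assignment by cutting the
   longest internal branches.
3. **Primer design** — candidates are enumerated under length
   (18–24 nt), GC (20–80 %) and amplicon (80–200 bp) constraints; a
   primer is *anchored* when a gene-differentiating SNP sits under its
   3′-terminal base, where a template mismatch blocks extension. Pairs
   need at least one anchored primer; allele-differentiating SNPs are
   tolerated only in the outermost 5′ bases of at most one primer,
   so that every allele of the target is still amplified.
4. **In-silico PCR** — mismatch-aware binding-site search on both
   strands (productive = zero 3′-window mismatches, ≤ 2 elsewhere),
   amplicon prediction, per-family cross-reactivity verdicts, a
   heuristic product Tm, and melt-curve QC (single −dF/dT peak).
5. **Quantification** — the standard-curve method: per-assay OLS of Ct
   on log₁₀ input over a 6 × 1:10 dilution series gives the efficiency
   `E = 10^(−1/slope) − 1`; unknowns are converted through their own
   assay's curve (neutralising efficiency differences), normalised to a
   reference gene and reported in arbitrary units (A.U.) with mean and
   SEM over biological replicates. The ΔΔCt shortcut is vetted by the
   dCt-slope rule: it is permissible only when the slope of
   (Ct_target − Ct_reference) vs log input is within ±0.1.
6. **Simulation** — synthetic families with controlled between-gene and
   within-gene divergence, and synthetic qPCR plates with known
   efficiencies, quantities and Ct noise, so every stage is testable
   against ground truth.

The package ships a transcription of a published 31-pair primer panel
for the apple Mal d 1 allergen family (`isoprime.make_fixture_panel()`),
used as a realistic fixture throughout the tests.

## Worked example

Design a panel on a simulated 3-gene family and screen it:

```python
import isoprime as ip

spec = ip.FamilySimSpec(n_genes=3, alleles_per_gene=2, seq_length=480,
                        gene_divergence=0.10, allele_divergence=0.005, seed=7)
fam, _ = ip.simulate_family(spec)
rows, report = ip.design_panel(fam)
for r in rows:
    verdict = ip.specificity_report(r.seq_f, r.seq_r, r.gene_id, fam).verdict
    print(f"{r.gene_id}  {r.seq_f}  {r.seq_r}  start={r.start} "
          f"len={r.amplicon_length} Ta={r.ta:.1f} "
          f"snp_gene={r.snp_gene_f + r.snp_gene_r} "
          f"snp_allele={r.snp_allele_f + r.snp_allele_r}  {verdict}")
```

prints

```
g01  AATATTTGTTGCATGTGCTAGTTA  CGACCAGTTTTCTCCGAA  start=384 len=69 Ta=61.0 snp_gene=8 snp_allele=0  specific
g02  CGGTAATGGTTTTCGTTTGACCT  GGTTCTACTCGATGGACCAGAAA  start=287 len=142 Ta=61.0 snp_gene=6 snp_allele=0  specific
g03  AAAGACATAATGTTGAGGTCGA  CCTAACGAACCCCCTTAATAAA  start=32 len=206 Ta=61.0 snp_gene=6 snp_allele=0  specific
```

Each row is one gene-specific pair: `snp_gene` counts
gene-differentiating SNPs under the two primer footprints (the source of
specificity), `snp_allele` counts allele-differentiating SNPs (kept at
zero or confined to 5′ ends so all alleles amplify), `Ta` is the
recommended annealing temperature, and the verdict is the closed-loop
in-silico PCR screen of the pair against every record of its own family.
Lengths slightly outside 80–200 bp are accepted with a warning (soft
±15 % band).

The same workflow is available from a shell:

```
isoprime simulate family --out fam.fa --n-genes 4 --seed 17
isoprime snps --fasta fam.fa --out snps.tsv
isoprime tree --fasta fam.fa --out tree.nwk --subfamilies 2
isoprime design --fasta fam.fa --out panel.tsv
isoprime specificity --panel panel.tsv --fasta fam.fa --out spec.tsv
isoprime simulate qpcr --out ct.csv --assays target,actin --seed 23
isoprime quantify --ct ct.csv --reference actin --out expression.tsv
```

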