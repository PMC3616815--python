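"""SNP discovery and gene-vs-allele classification over a labelled alignment.

The central distinction for paralog-specific assay design:

* a **gene-differentiating** site for gene *g* is an alignment column
  where every allele of *g* carries one concrete residue that no allele
  of any other gene can carry — the residue is diagnostic for *g*;
* an **allele-differentiating** site in *g* is a column where *g*'s own
  alleles disagree — placing a primer 3' end there would make the assay
  allele-biased instead of gene-specific.

The two are mutually exclusive for a given gene at a given column: a
diagnostic residue requires within-gene unanimity.

Gaps are not residues: a gene with a gap in any allele at a column is
not gene-differentiating there (indel discrimination is out of scope).
IUPAC ambiguity codes are handled conservatively — an ambiguous residue
in the target gene can never support a diagnostic claim, while an
ambiguous residue in a competitor blocks any diagnostic claim it could
overlap.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .records import Alignment, GAP

__all__ = ["SnpSite", "discover_snps", "classify_site",
           "majority_consensus", "annotate_primer_snps"]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class SnpSite:
    """A polymorphic alignment column and its per-gene classification."""

    column: int  # 0-based aligned index
    residues_by_gene: dict[str, Counter]  # non-gap residues per gene
    gaps_by_gene: dict[str, int] = field(default_factory=dict)
    gene_differentiating_for: set[str] = field(default_factory=set)
    allele_differentiating_in: set[str] = field(default_factory=set)

    def __post_init__(self):
        overlap = self.gene_differentiating_for & self.allele_differentiating_in
        if overlap:
            raise ValueError(
                f"column {self.column}: genes {sorted(overlap)} cannot be both "
                "gene- and allele-differentiating")


def classify_site(site: SnpSite) -> SnpSite:
    """Fill the classification sets of a site from its residue distributions.

    Gene *g* is gene-differentiating iff: no allele of *g* is gapped or
    ambiguous here, all its alleles agree on residue *x*, and no allele
    of any other gene could carry *x* (ambiguity expanded).  Gene *g* is
    allele-differentiating iff its own alleles show >= 2 distinct
    non-gap residues.
    """
    gene_diff: set[str] = set()
    allele_diff: set[str] = set()
    for g, residues in site.residues_by_gene.items():
        if len(residues) == 0:
            continue
        distinct = set(residues)
        if len(distinct) >= 2:
            allele_diff.add(g)
            continue
        x = next(iter(distinct))
        if site.gaps_by_gene.get(g, 0) > 0:
            continue  # gap in some allele: cannot be diagnostic
        if x not in "ACGT":
            continue  # ambiguous evidence never supports specificity
        has_competitor = any(len(other) > 0
                             for h, other in site.residues_by_gene.items()
                             if h != g)
        if not has_competitor:
            continue  # nothing to differentiate from
        others_can_carry = False
        for h, other in site.residues_by_gene.items():
            if h == g:
                continue
            for y in other:
                if x in IUPAC.get(y, y):
                    others_can_carry = True
                    break
            if others_can_carry:
                break
        if not others_can_carry:
            gene_diff.add(g)
    site.gene_differentiating_for = gene_diff
    site.allele_differentiating_in = allele_diff
    return site


def discover_snps(alignment: Alignment) -> list[SnpSite]:
    """Return one classified :class:`SnpSite` per polymorphic column.

    A column is polymorphic when it holds >= 2 distinct non-gap
    residues across the whole alignment; all-gap and monomorphic
    columns are excluded.
    """
    if len(alignment) < 2:
        raise ValueError("need >= 2 records to discover SNPs")
    genes = alignment.gene_ids
    gene_rows = {g: [i for i, r in enumerate(alignment.records) if r.gene_id == g]
                 for g in genes}
    sites = []
    for col in range(alignment.n_columns):
        column = alignment.column(col)
        nongap = column[column != GAP]
        if len(set(nongap)) < 2:
            continue
        residues_by_gene = {}
        gaps_by_gene = {}
        for g, rows in gene_rows.items():
            vals = column[rows]
            residues_by_gene[g] = Counter(v for v in vals if v != GAP)
            gaps_by_gene[g] = int((vals == GAP).sum())
        site = SnpSite(column=col, residues_by_gene=residues_by_gene,
                       gaps_by_gene=gaps_by_gene)
        sites.append(classify_site(site))
    return sites


def majority_consensus(alignment: Alignment) -> str:
    """Column-wise majority residue over all records.

    Gaps and ambiguity codes do not vote; ties break alphabetically.
    An all-gap column yields '-'.
    """
    out = []
    for col in range(alignment.n_columns):
        column = alignment.column(col)
        votes = Counter(v for v in column if v in "ACGT")
        if not votes:
            out.append(GAP)
            continue
        best = max(votes.values())
        out.append(min(b for b, n in votes.items() if n == best))
    return "".join(out)


def annotate_primer_snps(alignment: Alignment, target_gene: str,
                         footprint_start: int, footprint_length: int,
                         sites: list[SnpSite] | None = None,
                         consensus: str | None = None,
                         ) -> tuple[int, int, int]:
    """Count (snp_cons, snp_gene, snp_allele) over a primer footprint.

    The footprint is given in 1-based ungapped coordinates on the target
    gene's reference record (the family design template); it must be
    contiguous there.  ``snp_cons`` counts footprint columns where the
    reference residue differs from the family majority consensus,
    ``snp_gene`` counts columns gene-differentiating for the target, and
    ``snp_allele`` counts columns allele-differentiating within the
    target.
    """
    ref = next(r for r in alignment.records if r.gene_id == target_gene)
    n_ungapped = len(ref.ungapped)
    end = footprint_start + footprint_length - 1
    if footprint_start < 1 or end > n_ungapped:
        raise IndexError(
            f"footprint {footprint_start}..{end} outside reference 1..{n_ungapped}")
    if sites is None:
        sites = discover_snps(alignment)
    if consensus is None:
        consensus = majority_consensus(alignment)
    gene_cols = {s.column for s in sites if target_gene in s.gene_differentiating_for}
    allele_cols = {s.column for s in sites if target_gene in s.allele_differentiating_in}
    snp_cons = snp_gene = snp_allele = 0
    for pos in range(footprint_start, end + 1):
        col = alignment.ungapped_to_aligned(ref.record_id, pos)
        res = ref.residues[col].upper()
        if consensus[col] != GAP and res != consensus[col]:
            snp_cons += 1
        if col in gene_cols:
            snp_gene += 1
        if col in allele_cols:
            snp_allele += 1
    return snp_cons, snp_gene, snp_allele
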