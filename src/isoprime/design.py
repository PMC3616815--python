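"""Gene-specific primer design over a labelled gene-family alignment.

Candidates are enumerated from the target gene's reference sequence
(the design template) and filtered by length, GC content, and the
SNP-placement rules that make a primer paralog-specific:

* a candidate is **anchored** when a gene-differentiating SNP sits
  within ``three_prime_anchor_window`` nt of its 3' terminus — the
  mismatch position with the strongest discrimination against the
  other genes;
* allele-differentiating SNPs (positions where the target gene's own
  alleles disagree) are tolerated only within
  ``five_prime_allele_window`` nt of the 5' terminus, where a mismatch
  does not impair extension; candidates carrying one anywhere else are
  discarded.

Pairs must contain at least one anchored primer, at most one primer
bearing allele-differentiating SNPs, an amplicon length within range,
compatible melting temperatures and acceptable dimer scores.  Ranking
is lexicographic: fewest allele SNPs, most gene SNPs, smallest Tm
spread, shortest amplicon, leftmost position.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .records import Alignment, GeneFamily, PrimerPanelRow, GAP
from .snps import SnpSite, discover_snps, majority_consensus
from .thermo import dimer_score, gc_content, primer_tm, revcomp
from .pcr import amplicon_tm

__all__ = ["DesignConstraints", "PrimerCandidate", "PrimerPair",
           "DesignReport", "enumerate_candidates", "pair_primers",
           "design_panel", "as_alignment"]


@dataclass
class DesignConstraints:
    """Tunable physico-chemical and placement constraints.

    Defaults: primers 18-24 nt, GC 20-80 %, amplicons 80-200 bp with a
    soft +/-15 % overrun band (warn, don't reject), Tm spread within a
    pair <= 3 deg C, dimer run-score <= 10, gene-SNP anchored on the
    3'-terminal base, allele-SNPs tolerated in the 2 outermost 5' bases.
    """

    primer_len_min: int = 18
    primer_len_max: int = 24
    gc_min: float = 20.0
    gc_max: float = 80.0
    amplicon_min: int = 80
    amplicon_max: int = 200
    amplicon_soft_frac: float = 0.15  # warn-band beyond nominal range
    tm_window: float = 3.0
    dimer_score_max: int = 10
    three_prime_anchor_window: int = 1
    five_prime_allele_window: int = 2
    oligo_conc_nm: float = 250.0
    monovalent_mm: float = 50.0
    ta_clamp: tuple[float, float] = (61.0, 63.0)

    def __post_init__(self):
        if self.primer_len_min > self.primer_len_max:
            raise ValueError("empty primer length range")
        if self.amplicon_min > self.amplicon_max:
            raise ValueError("empty amplicon length range")
        if self.three_prime_anchor_window < 1 or self.five_prime_allele_window < 1:
            raise ValueError("windows must be >= 1")

    @property
    def amplicon_hard_min(self) -> int:
        return int(np.floor(self.amplicon_min * (1 - self.amplicon_soft_frac)))

    @property
    def amplicon_hard_max(self) -> int:
        return int(np.ceil(self.amplicon_max * (1 + self.amplicon_soft_frac)))


@dataclass
class PrimerCandidate:
    sequence: str  # 5'->3'
    strand: str  # forward | reverse
    start: int  # 1-based on target reference cds (leftmost footprint base)
    length: int
    tm: float
    gc: float
    snp_cons: int
    snp_gene: int
    snp_allele: int
    anchored: bool

    @property
    def end(self) -> int:
        """Rightmost footprint position, 1-based inclusive."""
        return self.start + self.length - 1

    @property
    def three_prime_pos(self) -> int:
        """Template position under the 3'-terminal base."""
        return self.end if self.strand == "forward" else self.start


@dataclass
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    amplicon_start: int
    amplicon_length: int
    anchored_ok: bool
    allele_rule_ok: bool
    length_in_range: bool
    homodimer_f: int
    homodimer_r: int
    heterodimer: int
    recommended_ta: float
    predicted_amplicon_tm: float

    @property
    def rank_key(self):
        return (self.forward.snp_allele + self.reverse.snp_allele,
                -(self.forward.snp_gene + self.reverse.snp_gene),
                abs(self.forward.tm - self.reverse.tm),
                self.amplicon_length,
                self.amplicon_start)


@dataclass
class DesignReport:
    """Per-gene design outcome plus rejection tallies."""

    designed: dict[str, PrimerPair] = field(default_factory=dict)
    undesignable: dict[str, str] = field(default_factory=dict)
    rejections: dict[str, dict[str, int]] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"designed: {len(self.designed)} gene(s)"]
        for g, reason in self.undesignable.items():
            lines.append(f"undesignable {g}: {reason}")
        for g, tallies in self.rejections.items():
            pretty = ", ".join(f"{k}={v}" for k, v in tallies.items() if v)
            if pretty:
                lines.append(f"{g} pair rejections: {pretty}")
        return "\n".join(lines)


def as_alignment(family: GeneFamily | Alignment) -> Alignment:
    if isinstance(family, Alignment):
        return family
    lengths = {len(r) for r in family.records}
    if len(lengths) != 1:
        raise ValueError(
            "family records have unequal lengths; align them first "
            "(design operates on an alignment)")
    return Alignment(family.records)


def _position_masks(alignment: Alignment, target_gene: str,
                    sites: list[SnpSite], consensus: str,
                    reference_id: str | None = None):
    """Boolean masks over 1-based ungapped reference positions."""
    if reference_id is None:
        ref = next(r for r in alignment.records if r.gene_id == target_gene)
    else:
        ref = alignment.record(reference_id)
    seq = ref.ungapped.upper()
    n = len(seq)
    gene_cols = {s.column for s in sites if target_gene in s.gene_differentiating_for}
    allele_cols = {s.column for s in sites if target_gene in s.allele_differentiating_in}
    is_gene = np.zeros(n + 1, dtype=bool)
    is_allele = np.zeros(n + 1, dtype=bool)
    is_cons_mm = np.zeros(n + 1, dtype=bool)
    for pos in range(1, n + 1):
        col = alignment.ungapped_to_aligned(ref.record_id, pos)
        if col in gene_cols:
            is_gene[pos] = True
        if col in allele_cols:
            is_allele[pos] = True
        if consensus[col] != GAP and seq[pos - 1] != consensus[col]:
            is_cons_mm[pos] = True
    return ref, seq, is_gene, is_allele, is_cons_mm


def enumerate_candidates(target_gene: str, alignment: Alignment,
                         sites: list[SnpSite] | None = None,
                         constraints: DesignConstraints | None = None,
                         consensus: str | None = None,
                         reference_id: str | None = None,
                         ) -> list[PrimerCandidate]:
    """All length/GC/allele-rule-valid candidates on the target reference.

    Returns both anchored and unanchored candidates (pairing requires at
    least one anchored primer per pair).  Windows containing degenerate
    template bases are skipped.
    """
    c = constraints or DesignConstraints()
    if sites is None:
        sites = discover_snps(alignment)
    if consensus is None:
        consensus = majority_consensus(alignment)
    ref, seq, is_gene, is_allele, is_cons_mm = _position_masks(
        alignment, target_gene, sites, consensus, reference_id)
    n = len(seq)
    ok_base = np.zeros(n + 1, dtype=bool)
    for pos in range(1, n + 1):
        ok_base[pos] = seq[pos - 1] in "ACGT"
    cg = np.concatenate([[0], np.cumsum(is_gene[1:])])
    ca = np.concatenate([[0], np.cumsum(is_allele[1:])])
    cm = np.concatenate([[0], np.cumsum(is_cons_mm[1:])])
    cb = np.concatenate([[0], np.cumsum(ok_base[1:])])

    def window_count(arr, lo, hi):  # inclusive 1-based
        return int(arr[hi] - arr[lo - 1])

    out = []
    w3 = c.three_prime_anchor_window
    w5 = c.five_prime_allele_window
    for length in range(c.primer_len_min, c.primer_len_max + 1):
        for start in range(1, n - length + 2):
            end = start + length - 1
            if window_count(cb, start, end) != length:
                continue  # degenerate base inside the window
            sub = seq[start - 1:end]
            gc = gc_content(sub)
            if not (c.gc_min <= gc <= c.gc_max):
                continue
            snp_cons = window_count(cm, start, end)
            snp_gene = window_count(cg, start, end)
            snp_allele = window_count(ca, start, end)
            for strand in ("forward", "reverse"):
                if strand == "forward":
                    five_lo, five_hi = start, min(end, start + w5 - 1)
                    three_lo, three_hi = max(start, end - w3 + 1), end
                    primer_seq = sub
                else:
                    five_lo, five_hi = max(start, end - w5 + 1), end
                    three_lo, three_hi = start, min(end, start + w3 - 1)
                    primer_seq = revcomp(sub)
                allele_in_5p = window_count(ca, five_lo, five_hi)
                if snp_allele > allele_in_5p:
                    continue  # allele SNP outside the tolerated 5' window
                anchored = window_count(cg, three_lo, three_hi) > 0
                out.append(PrimerCandidate(
                    sequence=primer_seq, strand=strand, start=start,
                    length=length,
                    tm=primer_tm(primer_seq, c.oligo_conc_nm, c.monovalent_mm),
                    gc=gc, snp_cons=snp_cons, snp_gene=snp_gene,
                    snp_allele=snp_allele, anchored=anchored))
    return out


def _recommend_ta(tm_f: float, tm_r: float, c: DesignConstraints) -> float:
    ta = min(tm_f, tm_r) - 2.0
    lo, hi = c.ta_clamp
    return float(min(max(ta, lo), hi))


def pair_primers(candidates: list[PrimerCandidate],
                 constraints: DesignConstraints | None = None,
                 require_anchor: bool = True,
                 max_pairs: int = 10,
                 monovalent_mm: float = 50.0,
                 template: str | None = None,
                 ) -> tuple[list[PrimerPair], dict[str, int]]:
    """Assemble and rank valid primer pairs.

    Returns the top ``max_pairs`` pairs by the lexicographic ranking and
    a tally of per-constraint rejections (useful when the list is
    empty).  ``template`` (the ungapped reference sequence) is needed to
    compute the predicted amplicon Tm; without it the prediction is NaN.
    """
    c = constraints or DesignConstraints()
    tallies = {"no_forward": 0, "no_reverse": 0, "not_anchored": 0,
               "both_allele": 0, "length": 0, "tm_spread": 0, "dimer": 0}
    fwd = [x for x in candidates if x.strand == "forward"]
    rev = [x for x in candidates if x.strand == "reverse"]
    if not fwd:
        tallies["no_forward"] = 1
        return [], tallies
    if not rev:
        tallies["no_reverse"] = 1
        return [], tallies
    if require_anchor and not any(x.anchored for x in fwd + rev):
        tallies["not_anchored"] = len(fwd) * len(rev)
        return [], tallies
    rev_sorted = sorted(rev, key=lambda x: x.start)
    rev_starts = [x.start for x in rev_sorted]
    rev_anch = [x for x in rev_sorted if x.anchored]
    rev_anch_starts = [x.start for x in rev_anch]
    lo_len, hi_len = c.amplicon_hard_min, c.amplicon_hard_max

    prelim = []
    for f in fwd:
        # an unanchored forward can only partner an anchored reverse
        if require_anchor and not f.anchored:
            pool, pool_starts = rev_anch, rev_anch_starts
        else:
            pool, pool_starts = rev_sorted, rev_starts
        # reverse primer must end within [f.start + lo_len - 1, f.start + hi_len - 1]
        i0 = bisect.bisect_left(pool_starts, f.start)
        i1 = bisect.bisect_right(pool_starts, f.start + hi_len - 1)
        for r in pool[i0:i1]:
            amplen = r.end - f.start + 1
            if amplen < lo_len or amplen > hi_len:
                tallies["length"] += 1
                continue
            if r.start <= f.end:
                continue  # physically overlapping primers
            if f.snp_allele > 0 and r.snp_allele > 0:
                tallies["both_allele"] += 1
                continue
            if abs(f.tm - r.tm) > c.tm_window:
                tallies["tm_spread"] += 1
                continue
            prelim.append((f, r, amplen))

    prelim.sort(key=lambda t: (
        t[0].snp_allele + t[1].snp_allele,
        -(t[0].snp_gene + t[1].snp_gene),
        abs(t[0].tm - t[1].tm),
        t[2], t[0].start))

    homo_cache: dict[str, int] = {}

    def homod(seq: str) -> int:
        if seq not in homo_cache:
            homo_cache[seq] = dimer_score(seq, seq)
        return homo_cache[seq]

    pairs: list[PrimerPair] = []
    for f, r, amplen in prelim:
        hf, hr = homod(f.sequence), homod(r.sequence)
        het = dimer_score(f.sequence, r.sequence)
        if max(hf, hr, het) > c.dimer_score_max:
            tallies["dimer"] += 1
            continue
        in_range = c.amplicon_min <= amplen <= c.amplicon_max
        if not in_range:
            warnings.warn(
                f"amplicon length {amplen} bp outside nominal range "
                f"{c.amplicon_min}-{c.amplicon_max} bp (within soft band)")
        amp_tm = float("nan")
        if template is not None:
            amp_seq = template[f.start - 1: r.end]
            amp_tm = amplicon_tm(amp_seq, monovalent_mm)
        pairs.append(PrimerPair(
            forward=f, reverse=r, amplicon_start=f.start,
            amplicon_length=amplen,
            anchored_ok=f.anchored or r.anchored,
            allele_rule_ok=not (f.snp_allele > 0 and r.snp_allele > 0),
            length_in_range=in_range,
            homodimer_f=hf, homodimer_r=hr, heterodimer=het,
            recommended_ta=_recommend_ta(f.tm, r.tm, c),
            predicted_amplicon_tm=amp_tm))
        if len(pairs) >= max_pairs:
            break
    return pairs, tallies


def design_panel(family: GeneFamily | Alignment,
                 constraints: DesignConstraints | None = None,
                 primer_conc_nm: float = 100.0,
                 ) -> tuple[list[PrimerPanelRow], DesignReport]:
    """Design at most one best primer pair per gene of the family.

    Single-gene families have no competitor sequences, so the anchoring
    (gene-SNP) requirement is waived there and recorded in the report.
    """
    c = constraints or DesignConstraints()
    alignment = as_alignment(family)
    genes = alignment.gene_ids
    if not genes:
        raise ValueError("empty family")
    sites = discover_snps(alignment) if len(alignment) >= 2 else []
    consensus = majority_consensus(alignment)
    report = DesignReport()
    rows: list[PrimerPanelRow] = []
    single_gene = len(genes) == 1
    for gene in genes:
        ref = next(r for r in alignment.records if r.gene_id == gene)
        template = ref.ungapped.upper()
        if sites:
            cands = enumerate_candidates(gene, alignment, sites, c, consensus)
        else:
            cands = enumerate_candidates(gene, _single_gene_alignment(alignment),
                                         [], c, GAP * alignment.n_columns)
        require_anchor = not single_gene
        if single_gene:
            report.undesignable.setdefault(
                "_note", "single-gene family: uniqueness check waived")
        if require_anchor and not any(x.anchored for x in cands):
            report.undesignable[gene] = "no gene-differentiating SNP available"
            continue
        pairs, tallies = pair_primers(cands, c, require_anchor=require_anchor,
                                      max_pairs=1, monovalent_mm=c.monovalent_mm,
                                      template=template)
        report.rejections[gene] = tallies
        if not pairs:
            report.undesignable[gene] = "no valid pair under constraints"
            continue
        best = pairs[0]
        report.designed[gene] = best
        tag = gene.replace(" ", "")
        rows.append(PrimerPanelRow(
            gene_id=gene,
            primer_name_f=f"q{tag}F", seq_f=best.forward.sequence,
            snp_cons_f=best.forward.snp_cons, snp_gene_f=best.forward.snp_gene,
            snp_allele_f=best.forward.snp_allele,
            primer_name_r=f"q{tag}R", seq_r=best.reverse.sequence,
            snp_cons_r=best.reverse.snp_cons, snp_gene_r=best.reverse.snp_gene,
            snp_allele_r=best.reverse.snp_allele,
            start=best.forward.start, amplicon_length=best.amplicon_length,
            primer_conc=primer_conc_nm, ta=best.recommended_ta,
            tm_amplicon=best.predicted_amplicon_tm,
            dct_slope=float("nan")))
    return rows, report


def _single_gene_alignment(alignment: Alignment) -> Alignment:
    return alignment
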