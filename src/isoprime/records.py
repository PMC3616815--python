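"""Data model and I/O for labelled gene-family sequences, alignments,
primer panels and Ct tables.

Gene families here are sets of paralogous loci ("genes"), each represented
by one or more allelic sequences.  Records carry an explicit
``(gene_id, allele_id)`` label because every downstream step — SNP
classification, primer design, specificity screening — hinges on the
distinction between variation *between* genes and variation *within* a
gene.

FASTA headers are parsed as ``>geneID|alleleID|sourceID`` by default; the
separator-based scheme is configurable via a regex with named groups.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "GeneFamily",
    "Alignment",
    "PrimerPanelRow",
    "CtTable",
    "FormatError",
    "DEFAULT_LABEL_SCHEME",
    "read_labelled_fasta",
    "write_labelled_fasta",
    "read_primer_panel",
    "write_panel_report",
    "read_ct_table",
    "write_ct_table",
    "read_newick",
    "write_newick",
]

DNA_ALPHABET = set("ACGTRYSWKMBDHVN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
GAP = "-"

#: header scheme: geneID|alleleID|sourceID
DEFAULT_LABEL_SCHEME = r"^(?P<gene>[^|]+)\|(?P<allele>[^|]+)(?:\|(?P<source>.*))?$"


class FormatError(ValueError):
    """Raised for malformed input files or label schemes."""


@dataclass(frozen=True)
class SequenceRecord:
    """One labelled sequence: a specific allele of a specific gene."""

    record_id: str
    gene_id: str
    allele_id: str
    residues: str
    molecule: str = "cds"  # cds | gdna | protein

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.record_id}: empty sequence")
        if self.molecule not in ("cds", "gdna", "protein"):
            raise ValueError(f"unknown molecule type {self.molecule!r}")
        alphabet = PROTEIN_ALPHABET if self.molecule == "protein" else DNA_ALPHABET
        bad = set(self.residues.upper()) - alphabet - {GAP}
        if bad:
            raise ValueError(
                f"{self.record_id}: invalid residues {sorted(bad)} for {self.molecule}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneFamily:
    """A collection of labelled records grouped by gene.

    ``reference_allele`` names, per gene, the record used as the design
    template (e.g. the reference-cultivar sequence).  Defaults to the
    first record of each gene in input order.
    """

    records: list[SequenceRecord]
    reference_allele: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.records:
            raise FormatError("no records")
        seen = set()
        for r in self.records:
            key = (r.gene_id, r.allele_id, r.record_id)
            if key in seen:
                raise FormatError(f"duplicate record {key}")
            seen.add(key)
        for g in self.gene_ids:
            self.reference_allele.setdefault(g, self.alleles_of(g)[0].record_id)
        ids = {r.record_id for r in self.records}
        for g, rid in self.reference_allele.items():
            if rid not in ids:
                raise ValueError(f"reference allele {rid!r} of {g!r} not in family")

    @property
    def gene_ids(self) -> list[str]:
        out = []
        for r in self.records:
            if r.gene_id not in out:
                out.append(r.gene_id)
        return out

    def alleles_of(self, gene_id: str) -> list[SequenceRecord]:
        return [r for r in self.records if r.gene_id == gene_id]

    def reference_of(self, gene_id: str) -> SequenceRecord:
        rid = self.reference_allele[gene_id]
        return next(r for r in self.records if r.record_id == rid)

    def __len__(self) -> int:
        return len(self.records)


class Alignment:
    """Equal-length gapped records plus aligned<->ungapped coordinate maps.

    Ungapped positions are 1-based; aligned columns are 0-based indices
    into the alignment.  The maps round-trip on every non-gap column.
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        if not records:
            raise FormatError("no records")
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            raise FormatError(f"unequal aligned lengths: {sorted(lengths)}")
        self.records = list(records)
        self.n_columns = lengths.pop()
        self._by_id = {r.record_id: r for r in self.records}
        if len(self._by_id) != len(self.records):
            raise FormatError("duplicate record ids in alignment")
        # matrix of residues for column access
        self.matrix = np.array([list(r.residues.upper()) for r in self.records])
        # per record: aligned col -> ungapped pos (0 where gap), and inverse
        self._a2u: dict[str, np.ndarray] = {}
        self._u2a: dict[str, np.ndarray] = {}
        for r in self.records:
            arr = np.array(list(r.residues))
            nongap = arr != GAP
            a2u = np.where(nongap, np.cumsum(nongap), 0)
            self._a2u[r.record_id] = a2u
            self._u2a[r.record_id] = np.flatnonzero(nongap)

    def record(self, record_id: str) -> SequenceRecord:
        return self._by_id[record_id]

    def column(self, col: int) -> np.ndarray:
        return self.matrix[:, col]

    def aligned_to_ungapped(self, record_id: str, col: int) -> int:
        """1-based ungapped position at aligned column, 0 if the record is gapped there."""
        return int(self._a2u[record_id][col])

    def ungapped_to_aligned(self, record_id: str, pos: int) -> int:
        """Aligned column (0-based) holding 1-based ungapped position ``pos``."""
        u2a = self._u2a[record_id]
        if not 1 <= pos <= len(u2a):
            raise IndexError(f"position {pos} outside {record_id} (1..{len(u2a)})")
        return int(u2a[pos - 1])

    @property
    def gene_ids(self) -> list[str]:
        out = []
        for r in self.records:
            if r.gene_id not in out:
                out.append(r.gene_id)
        return out

    def alleles_of(self, gene_id: str) -> list[SequenceRecord]:
        return [r for r in self.records if r.gene_id == gene_id]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PrimerPanelRow:
    """One gene-specific primer pair with its annotation columns.

    SNP counts follow the panel-report convention: ``snp_cons`` counts
    footprint positions where the target reference differs from the
    family-wide majority consensus; ``snp_gene`` counts
    gene-differentiating positions; ``snp_allele`` counts
    allele-differentiating positions (within the target gene).
    ``start`` is the 1-based position of the forward primer's 5' end on
    the reference cds.  ``dct_slope`` is the measured log-input vs
    (Ct_target - Ct_reference) regression slope, NaN when not measured.
    """

    gene_id: str
    primer_name_f: str
    seq_f: str
    snp_cons_f: int
    snp_gene_f: int
    snp_allele_f: int
    primer_name_r: str
    seq_r: str
    snp_cons_r: int
    snp_gene_r: int
    snp_allele_r: int
    start: int
    amplicon_length: int
    primer_conc: float = 100.0  # nM
    ta: float = 61.0  # degrees C
    tm_amplicon: float = float("nan")  # degrees C
    dct_slope: float = float("nan")

    def __post_init__(self):
        for seq in (self.seq_f, self.seq_r):
            if not re.fullmatch("[ACGT]+", seq):
                raise ValueError(f"primer sequence not uppercase ACGT: {seq!r}")
        if self.amplicon_length <= max(len(self.seq_f), len(self.seq_r)):
            raise ValueError("amplicon shorter than a primer")
        for name in ("snp_cons_f", "snp_gene_f", "snp_allele_f",
                     "snp_cons_r", "snp_gene_r", "snp_allele_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative")

    @property
    def has_allele_snp(self) -> bool:
        return self.snp_allele_f + self.snp_allele_r > 0


PANEL_COLUMNS = [
    "gene_id", "primer_name_f", "seq_f", "snp_cons_f", "snp_gene_f", "snp_allele_f",
    "primer_name_r", "seq_r", "snp_cons_r", "snp_gene_r", "snp_allele_r",
    "start", "amplicon_length", "primer_conc", "ta", "tm_amplicon", "dct_slope",
]

CT_COLUMNS = ["sample_id", "tissue", "cultivar", "assay_id",
              "replicate_type", "dilution_step", "ct"]

REPLICATE_TYPES = {"technical", "biological", "standard", "ntc"}


class CtTable:
    """Sample x assay Ct values with replicate structure.

    Wraps a DataFrame with columns ``sample_id, tissue, cultivar,
    assay_id, replicate_type, dilution_step, ct``.  A Ct reported by the
    instrument as "Undetermined" is a censored observation: no signal
    within ``max_cycle`` cycles.  It is stored as ``ct = NaN`` with
    ``censored = True``; quantification code treats it as
    censored-at-``max_cycle``.
    """

    CENSORED_SENTINEL = "Undetermined"

    def __init__(self, df: pd.DataFrame, max_cycle: float = 40.0):
        missing = set(CT_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"Ct table missing columns: {sorted(missing)}")
        bad = set(df["replicate_type"]) - REPLICATE_TYPES
        if bad:
            raise FormatError(f"unknown replicate_type values: {sorted(bad)}")
        df = df.copy()
        if "censored" not in df.columns:
            df["censored"] = df["ct"].isna()
        self.df = df
        self.max_cycle = float(max_cycle)

    def standards(self, assay_id: str) -> pd.DataFrame:
        d = self.df
        return d[(d.assay_id == assay_id) & (d.replicate_type == "standard")]

    def unknowns(self, assay_id: str) -> pd.DataFrame:
        d = self.df
        return d[(d.assay_id == assay_id)
                 & d.replicate_type.isin(["technical", "biological"])]

    def ntc(self, assay_id: str) -> pd.DataFrame:
        d = self.df
        return d[(d.assay_id == assay_id) & (d.replicate_type == "ntc")]

    @property
    def assay_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df.assay_id))

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# FASTA

def _parse_header(header: str, scheme: str) -> tuple[str, str, str]:
    m = re.match(scheme, header)
    if not m:
        raise FormatError(f"header {header!r} does not match label scheme")
    d = m.groupdict()
    gene, allele = d["gene"], d["allele"]
    source = d.get("source") or header
    return gene, allele, source


def read_labelled_fasta(stream, label_scheme: str = DEFAULT_LABEL_SCHEME,
                        molecule: str = "cds",
                        aligned: bool = False) -> GeneFamily:
    """Read a labelled multi-FASTA into a :class:`GeneFamily`.

    Headers must parse under ``label_scheme`` (a regex with named groups
    ``gene``, ``allele`` and optionally ``source``).  When
    ``aligned=False`` any gap characters are stripped.
    """
    if isinstance(stream, (str,)):
        import os
        if os.path.exists(stream):
            stream = open(stream)
        else:
            stream = io.StringIO(stream)
    # tolerate ';'/'#' provenance comment lines, which strict FASTA forbids
    text = "".join(ln for ln in stream
                   if not ln.lstrip().startswith((";", "#")))
    stream = io.StringIO(text)
    records = []
    for rec in SeqIO.parse(stream, "fasta"):
        gene, allele, _ = _parse_header(rec.id, label_scheme)
        residues = str(rec.seq).upper()
        if not aligned:
            residues = residues.replace(GAP, "")
        records.append(SequenceRecord(record_id=rec.id, gene_id=gene,
                                      allele_id=allele, residues=residues,
                                      molecule=molecule))
    if not records:
        raise FormatError("no records")
    return GeneFamily(records=records)


def read_alignment_fasta(stream, label_scheme: str = DEFAULT_LABEL_SCHEME,
                         molecule: str = "cds") -> Alignment:
    """Read an aligned labelled FASTA straight into an :class:`Alignment`."""
    fam = read_labelled_fasta(stream, label_scheme, molecule, aligned=True)
    return Alignment(fam.records)


def write_labelled_fasta(family: GeneFamily | Alignment, stream) -> None:
    close = False
    if isinstance(stream, str):
        stream = open(stream, "w")
        close = True
    try:
        recs = [_BioSeqRecord(Seq(r.residues), id=r.record_id, description="")
                for r in family.records]
        SeqIO.write(recs, stream, "fasta")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# primer panel TSV

def read_primer_panel(stream) -> list[PrimerPanelRow]:
    """Read a tab-separated primer panel (columns as in PANEL_COLUMNS)."""
    if isinstance(stream, str):
        import os
        if not os.path.exists(stream):
            stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", dtype=str, comment="#")
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"primer panel missing columns: {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        try:
            rows.append(PrimerPanelRow(
                gene_id=r.gene_id,
                primer_name_f=r.primer_name_f, seq_f=r.seq_f,
                snp_cons_f=int(r.snp_cons_f), snp_gene_f=int(r.snp_gene_f),
                snp_allele_f=int(r.snp_allele_f),
                primer_name_r=r.primer_name_r, seq_r=r.seq_r,
                snp_cons_r=int(r.snp_cons_r), snp_gene_r=int(r.snp_gene_r),
                snp_allele_r=int(r.snp_allele_r),
                start=int(r.start), amplicon_length=int(r.amplicon_length),
                primer_conc=float(r.primer_conc), ta=float(r.ta),
                tm_amplicon=float(r.tm_amplicon), dct_slope=float(r.dct_slope),
            ))
        except (TypeError, ValueError) as e:
            raise FormatError(f"bad panel row for {r.get('gene_id')!r}: {e}") from e
    return rows


def write_panel_report(rows: Iterable[PrimerPanelRow], stream,
                       header_comment: str | None = None) -> None:
    close = False
    if isinstance(stream, str):
        stream = open(stream, "w")
        close = True
    try:
        if header_comment:
            for line in header_comment.splitlines():
                stream.write(f"# {line}\n")
        df = pd.DataFrame([{c: getattr(r, c) for c in PANEL_COLUMNS}
                           for r in rows], columns=PANEL_COLUMNS)
        df.to_csv(stream, sep="\t", index=False)
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Ct table CSV

def read_ct_table(stream, max_cycle: float = 40.0) -> CtTable:
    """Read the Ct CSV.  "Undetermined" parses as a censored observation."""
    if isinstance(stream, str):
        import os
        if not os.path.exists(stream):
            stream = io.StringIO(stream)
    df = pd.read_csv(stream, comment="#",
                     dtype={"sample_id": str, "tissue": str,
                            "cultivar": str, "assay_id": str,
                            "replicate_type": str})
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"Ct table missing columns: {sorted(missing)}")
    raw = df["ct"].astype(str).str.strip()
    censored = raw.str.casefold() == CtTable.CENSORED_SENTINEL.casefold()
    ct = pd.to_numeric(raw.mask(censored), errors="raise")
    df = df.assign(ct=ct, censored=censored)
    return CtTable(df, max_cycle=max_cycle)


def write_ct_table(table: CtTable, stream) -> None:
    df = table.df.copy()
    ct = df["ct"].astype(object)
    ct[df["censored"]] = CtTable.CENSORED_SENTINEL
    df["ct"] = ct
    df[CT_COLUMNS].to_csv(stream, index=False)


# ---------------------------------------------------------------------------
# newick

def write_newick(tree) -> str:
    """Serialize a dendropy tree to newick with branch lengths."""
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(text: str):
    import dendropy
    return dendropy.Tree.get(data=text, schema="newick")
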