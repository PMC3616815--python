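"""Synthetic gene families and qPCR experiments with known ground truth.

The family generator emulates the structure of a multigene family with
allelic variation: genes radiate from a common ancestor on a star
phylogeny (keeping expected pairwise distances analytic), and alleles
radiate from each gene's reference sequence.  Substitutions are uniform
across sites with equal exchange among the three alternative bases, so
only the divergence *levels* — the quantities that matter to the primer
design problem — are modelled, not codon structure or indels.

For a per-branch substitution probability q, two genes differ at a site
with probability 2q(1-q) + (2/3)q^2; the generator inverts this so that
``gene_divergence`` is the *expected pairwise p-distance between genes*:
q = (3/4)(1 - sqrt(1 - 4d/3)).  ``allele_divergence`` is the expected
p-distance between a gene's reference and each variant allele (a single
branch, so the branch probability is the divergence itself).

The qPCR generator produces Ct tables under the instrument model

    Ct = baseline - log10(quantity) / log10(1 + E) + N(0, sd)

with per-assay efficiency E, serial-dilution standards, technical
triplicates on unknowns, no-template controls, and censoring at
``max_cycle``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .records import (CtTable, GeneFamily, PrimerPanelRow, SequenceRecord,
                      read_primer_panel)

__all__ = ["FamilySimSpec", "FamilyTruth", "QpcrSimSpec",
           "simulate_family", "simulate_qpcr", "make_fixture_panel",
           "FIXTURE_PANEL_RESOURCE"]

BASES = np.array(list("ACGT"))
FIXTURE_PANEL_RESOURCE = "mald1_panel.tsv"


@dataclass
class FamilySimSpec:
    n_genes: int = 5
    alleles_per_gene: int = 2
    seq_length: int = 480
    gene_divergence: float = 0.10   # expected pairwise p-distance between genes
    allele_divergence: float = 0.005  # expected reference-vs-variant p-distance
    gc_bias: float = 0.5            # P(G or C) per ancestral site
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.allele_divergence < self.gene_divergence <= 0.75:
            raise ValueError(
                "need 0 <= allele_divergence < gene_divergence <= 0.75")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def branch_prob(self) -> float:
        """Per-gene branch substitution probability giving the requested
        expected between-gene p-distance."""
        d = self.gene_divergence
        return 0.75 * (1.0 - np.sqrt(1.0 - 4.0 * d / 3.0))

    def expected_pairwise_distance(self) -> float:
        q = self.branch_prob
        return 2 * q * (1 - q) + (2.0 / 3.0) * q * q


@dataclass
class FamilyTruth:
    """Every mutation placed by the generator, for oracle-style checks."""

    ancestor: str
    gene_mutations: dict[str, dict[int, str]]  # gene -> {0-based col -> new base}
    allele_mutations: dict[tuple[str, str], dict[int, str]] = field(
        default_factory=dict)


def _mutate(rng: np.random.Generator, seq: np.ndarray, prob: float,
            ) -> tuple[np.ndarray, dict[int, str]]:
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < prob)
    muts = {}
    for i in hit:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[rng.integers(3)]
        muts[int(i)] = str(out[i])
    return out, muts


def simulate_family(spec: FamilySimSpec) -> tuple[GeneFamily, FamilyTruth]:
    """Generate a labelled family; same seed gives byte-identical output."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_bias
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    ancestor = rng.choice(BASES, size=spec.seq_length, p=probs)
    q = spec.branch_prob
    records = []
    gene_muts = {}
    allele_muts = {}
    for gi in range(1, spec.n_genes + 1):
        gene = f"g{gi:02d}"
        gseq, muts = _mutate(rng, ancestor, q)
        gene_muts[gene] = muts
        for ai in range(1, spec.alleles_per_gene + 1):
            allele = f"a{ai}"
            if ai == 1:
                aseq, amuts = gseq, {}
            else:
                aseq, amuts = _mutate(rng, gseq, spec.allele_divergence)
            allele_muts[(gene, allele)] = amuts
            records.append(SequenceRecord(
                record_id=f"{gene}|{allele}|sim",
                gene_id=gene, allele_id=allele,
                residues="".join(aseq), molecule="cds"))
    family = GeneFamily(records=records)
    truth = FamilyTruth(ancestor="".join(ancestor),
                        gene_mutations=gene_muts,
                        allele_mutations=allele_muts)
    return family, truth


@dataclass
class QpcrSimSpec:
    """Design of a simulated qPCR run with known truth.

    ``sample_quantities`` maps sample_id -> assay_id -> true relative
    quantity (on the same scale as the standards, whose top dilution is
    1.0).  ``efficiency`` maps assay_id -> true E in (0.5, 1.1].
    """

    efficiency: dict[str, float]
    sample_quantities: dict[str, dict[str, float]]
    sample_meta: dict[str, tuple[str, str]] = field(default_factory=dict)
    baseline_ct: float = 20.0   # Ct at unit quantity
    noise_sd: float = 0.15
    n_dilutions: int = 6
    dilution_factor: float = 10.0
    standard_replicates: int = 2
    technical_replicates: int = 3
    ntc_replicates: int = 2
    max_cycle: float = 40.0
    seed: int = 0

    def __post_init__(self):
        for assay, e in self.efficiency.items():
            if not 0.5 < e <= 1.1:
                raise ValueError(f"efficiency {e} of {assay!r} outside (0.5, 1.1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def _true_ct(quantity: float, e: float, baseline: float) -> float:
    return baseline - np.log10(quantity) / np.log10(1.0 + e)


def simulate_qpcr(spec: QpcrSimSpec) -> CtTable:
    """Simulate a full plate: standards, unknowns, and NTCs per assay."""
    rng = np.random.default_rng(spec.seed)
    rows = []

    def emit(sample_id, tissue, cultivar, assay, rtype, dilution, true_ct):
        ct = true_ct + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
        censored = ct > spec.max_cycle
        rows.append(dict(sample_id=sample_id, tissue=tissue, cultivar=cultivar,
                         assay_id=assay, replicate_type=rtype,
                         dilution_step=dilution,
                         ct=(np.nan if censored else ct),
                         censored=censored))

    for assay, e in spec.efficiency.items():
        for step in range(spec.n_dilutions):
            quantity = spec.dilution_factor ** (-step)
            for rep in range(spec.standard_replicates):
                emit(f"std{step}_{rep}", "standard", "standard", assay,
                     "standard", step, _true_ct(quantity, e, spec.baseline_ct))
        for sample, per_assay in spec.sample_quantities.items():
            if assay not in per_assay:
                continue
            tissue, cultivar = spec.sample_meta.get(sample, ("na", "na"))
            quantity = per_assay[assay]
            if quantity <= 0:
                true = np.inf
            else:
                true = _true_ct(quantity, e, spec.baseline_ct)
            for rep in range(spec.technical_replicates):
                emit(sample, tissue, cultivar, assay, "technical", np.nan, true)
        for rep in range(spec.ntc_replicates):
            emit(f"ntc_{rep}", "ntc", "ntc", assay, "ntc", np.nan, np.inf)

    df = pd.DataFrame(rows)
    return CtTable(df, max_cycle=spec.max_cycle)


def make_fixture_panel() -> list[PrimerPanelRow]:
    """The packaged 31-pair gene-family primer panel (byte-stable)."""
    ref = resources.files("isoprime").joinpath("data", FIXTURE_PANEL_RESOURCE)
    with ref.open() as fh:
        return read_primer_panel(fh)
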