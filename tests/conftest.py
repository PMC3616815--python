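import numpy as np
import pytest

from isoprime.records import Alignment, SequenceRecord


def make_alignment(seqs_by_record, molecule="cds"):
    """Build an Alignment from {(gene, allele): sequence} mappings."""
    records = []
    for (gene, allele), seq in seqs_by_record.items():
        records.append(SequenceRecord(
            record_id=f"{gene}|{allele}|t", gene_id=gene, allele_id=allele,
            residues=seq, molecule=molecule))
    return Alignment(records)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def two_gene_alignment():
    """Two genes x two alleles, 8 columns, with engineered sites.

    col (0-based):   01234567
    g1/a1:           AATTCGGA
    g1/a2:           AATTCGGC   <- col 7 allele-differentiating in g1
    g2/a1:           AGTTCGGA
    g2/a2:           AGTTCGGA   <- col 1 gene-differentiating (A vs G)
    """
    return make_alignment({
        ("g1", "a1"): "AATTCGGA",
        ("g1", "a2"): "AATTCGGC",
        ("g2", "a1"): "AGTTCGGA",
        ("g2", "a2"): "AGTTCGGA",
    })
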