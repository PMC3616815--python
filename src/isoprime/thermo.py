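"""Oligo physical chemistry: GC content, nearest-neighbour duplex melting
temperature, and primer-dimer complementarity scoring.

``primer_tm`` uses the unified nearest-neighbour parameter set
(two-state model): duplex dH/dS are summed over dinucleotide stacks
plus terminal-initiation terms, with a symmetry correction for
self-complementary oligos.  Entropy is salt-corrected by
``0.368 * (N-1) * ln[Na+]`` (N = oligo length) and

    Tm(K) = 1000 * dH / (dS + R * ln(C_T / x))

with R = 1.987 cal/(K mol), C_T the oligo concentration and x = 4 for
non-self-complementary duplexes (x = 1 with symmetry correction for
self-complementary ones).
"""

from __future__ import annotations

import math

__all__ = ["gc_content", "primer_tm", "dimer_score", "revcomp",
           "is_self_complementary"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# unified NN set: stack -> (dH kcal/mol, dS cal/(mol K))
NN_UNIFIED = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)
SYMMETRY = (0.0, -1.4)
R_GAS = 1.987  # cal / (K mol)


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def is_self_complementary(seq: str) -> bool:
    seq = seq.upper()
    return seq == revcomp(seq)


def gc_content(seq: str) -> float:
    """Percent G+C of a sequence."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


def primer_tm(seq: str, oligo_conc_nm: float = 250.0,
              monovalent_mm: float = 50.0) -> float:
    """Nearest-neighbour melting temperature of a primer, in deg C.

    Parameters
    ----------
    seq : ACGT oligo, length >= 8 (ambiguity codes rejected).
    oligo_conc_nm : total single-strand concentration in nM.
    monovalent_mm : monovalent cation concentration in mM.
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("primer too short for nearest-neighbour model (< 8 nt)")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous bases in {seq!r}")
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = NN_UNIFIED[seq[i:i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = INIT_GC if terminal in "GC" else INIT_AT
        dh += h
        ds += s
    selfcomp = is_self_complementary(seq)
    if selfcomp:
        dh += SYMMETRY[0]
        ds += SYMMETRY[1]
    # entropy salt correction
    ds += 0.368 * (len(seq) - 1) * math.log(monovalent_mm / 1000.0)
    x = 1.0 if selfcomp else 4.0
    ct = oligo_conc_nm * 1e-9
    tm_k = 1000.0 * dh / (ds + R_GAS * math.log(ct / x))
    return tm_k - 273.15


def dimer_score(seq_a: str, seq_b: str) -> int:
    """Maximum antiparallel complementarity run-score between two oligos.

    Both inputs are 5'->3'.  Every ungapped antiparallel offset is
    scanned; within an offset, the score of each maximal run of
    consecutive complementary base pairs is the sum of per-pair weights:
    +1 per pair, doubled to +2 when the pair involves the 3'-terminal
    base of either oligo (3'-extensible dimers are the dangerous ones).
    The returned score is the maximum over all runs and offsets.
    """
    a = seq_a.upper()
    b3to5 = seq_b.upper()[::-1]  # b read 3'->5', left to right
    la, lb = len(a), len(b3to5)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    best = 0
    # offset o: a[i] pairs with b3to5[i - o]
    for o in range(-(lb - 1), la):
        run = 0
        for i in range(max(0, o), min(la, o + lb)):
            j = i - o
            if comp.get(a[i]) == b3to5[j]:
                w = 1
                if i == la - 1 or j == 0:  # 3' terminus of a or of b
                    w = 2
                run += w
                best = max(best, run)
            else:
                run = 0
    return best
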