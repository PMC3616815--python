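"""In-silico PCR: mismatch-aware binding-site search, amplicon
prediction, cross-reactivity verdicts, amplicon melting estimates and
melt-curve QC.

This is the computational stand-in for bench validation of primer
specificity.  A binding site is *productive* (able to prime extension)
when it has no mismatch in the 3'-terminal window and at most
``max_mm`` mismatches overall — the same mechanism the design stage
exploits by anchoring a gene-differentiating SNP at the 3' terminus.
Near-miss sites (one mismatch over the tolerance) are reported
unproductive so cross-reactivity reports show what was close.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy.signal import find_peaks

from .records import GeneFamily
from .thermo import gc_content, revcomp

__all__ = ["PcrSettings", "BindingSite", "Amplicon", "MeltCurve",
           "find_sites", "predict_amplicons", "specificity_report",
           "SpecificityReport", "amplicon_tm", "melt_peaks", "single_peak_qc"]


@dataclass
class PcrSettings:
    max_mm: int = 2                # mismatches tolerated outside the 3' window
    three_prime_window: int = 4    # nt from the 3' terminus with zero tolerance
    length_cap: int = 1500         # bp; longer products do not amplify
    monovalent_mm: float = 50.0


@dataclass(frozen=True)
class BindingSite:
    record_id: str
    strand: str           # plus: primer anneals so extension runs rightward
    start: int            # 1-based leftmost template position of the footprint
    mismatches: int
    three_prime_mismatches: int
    productive: bool
    primer_length: int

    @property
    def end(self) -> int:
        return self.start + self.primer_length - 1


@dataclass(frozen=True)
class Amplicon:
    record_id: str
    start: int
    length: int
    sequence: str
    predicted_tm: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def find_sites(primer: str, template: str, record_id: str = "",
               max_mm: int = 2, three_prime_window: int = 4,
               ) -> list[BindingSite]:
    """Scan both template strands for primer binding sites.

    Sites with up to ``max_mm + 1`` total mismatches are reported
    (near-misses included, flagged unproductive).  On the plus strand
    the primer matches the template slice directly (3' end rightmost);
    on the minus strand it matches the reverse complement of the slice
    (3' end leftmost on forward-strand coordinates).  Ambiguous
    template bases count as mismatches.
    """
    if len(primer) < 10:
        raise ValueError("primer too short for site search (< 10 nt)")
    lp, lt = len(primer), len(template)
    if lt < lp:
        return []
    sites = []
    for strand in ("plus", "minus"):
        probe = primer.upper() if strand == "plus" else revcomp(primer)
        p = _encode(probe)
        t = _encode(template)
        # mism[o] = number of mismatching positions at offset o
        n_off = lt - lp + 1
        mism = np.zeros(n_off, dtype=np.int32)
        for j in range(lp):
            mism += (t[j:j + n_off] != p[j]).astype(np.int32)
        w = three_prime_window
        if strand == "plus":
            # 3'-terminal bases are the last w of the probe
            tp_idx = range(lp - w, lp)
        else:
            tp_idx = range(0, w)
        tp_mism = np.zeros(n_off, dtype=np.int32)
        for j in tp_idx:
            if 0 <= j < lp:
                tp_mism += (t[j:j + n_off] != p[j]).astype(np.int32)
        hits = np.flatnonzero(mism <= max_mm + 1)
        for o in hits:
            total = int(mism[o])
            tpm = int(tp_mism[o])
            sites.append(BindingSite(
                record_id=record_id, strand=strand, start=int(o) + 1,
                mismatches=total, three_prime_mismatches=tpm,
                productive=(total <= max_mm and tpm == 0),
                primer_length=lp))
    return sites


def predict_amplicons(seq_f: str, seq_r: str, templates: dict[str, str],
                      settings: PcrSettings | None = None) -> list[Amplicon]:
    """Predict products of a primer pair over a set of templates.

    One amplicon per convergent (productive plus-strand forward site,
    productive minus-strand reverse site) combination within the length
    cap.  Primer pairs also amplify with roles swapped (reverse primer
    binding plus strand); both orientations are scanned.
    """
    s = settings or PcrSettings()
    out = []
    for rid, template in templates.items():
        for left, right in ((seq_f, seq_r), (seq_r, seq_f)):
            if left == right and (seq_f == seq_r):
                pass  # identical primers: single orientation suffices below
            f_sites = [x for x in find_sites(left, template, rid, s.max_mm,
                                             s.three_prime_window)
                       if x.productive and x.strand == "plus"]
            r_sites = [x for x in find_sites(right, template, rid, s.max_mm,
                                             s.three_prime_window)
                       if x.productive and x.strand == "minus"]
            for fs in f_sites:
                for rs in r_sites:
                    length = rs.end - fs.start + 1
                    if length <= max(fs.primer_length, rs.primer_length):
                        continue
                    if length > s.length_cap:
                        continue
                    amp_seq = template[fs.start - 1: rs.end]
                    out.append(Amplicon(
                        record_id=rid, start=fs.start, length=length,
                        sequence=amp_seq,
                        predicted_tm=amplicon_tm(amp_seq, s.monovalent_mm)))
            if seq_f == seq_r:
                break
    # deduplicate identical products found in both orientations
    uniq = {(a.record_id, a.start, a.length): a for a in out}
    return sorted(uniq.values(), key=lambda a: (a.record_id, a.start, a.length))


@dataclass
class SpecificityReport:
    target_gene: str
    verdict: str                      # specific | cross-reactive | no-amplification
    amplification: dict[str, int]     # record_id -> number of products
    notes: list[str] = field(default_factory=list)


def specificity_report(seq_f: str, seq_r: str, target_gene: str,
                       family: GeneFamily,
                       settings: PcrSettings | None = None) -> SpecificityReport:
    """Closed-loop specificity check of a pair against its whole family.

    Verdict "specific" iff every allele of the target gene yields at
    least one productive amplicon and no allele of any other gene yields
    any.  When a single primer matches a non-target but the pair does
    not co-amplify it (as with a primer shared between close paralogs),
    a note records the shared-primer situation.
    """
    s = settings or PcrSettings()
    if not family.records:
        raise ValueError("empty family")
    templates = {r.record_id: r.ungapped.upper() for r in family.records}
    amps = predict_amplicons(seq_f, seq_r, templates, s)
    by_record: dict[str, int] = {rid: 0 for rid in templates}
    for a in amps:
        by_record[a.record_id] += 1
    notes = []
    target_ids = {r.record_id for r in family.alleles_of(target_gene)}
    on_target = all(by_record[rid] >= 1 for rid in target_ids)
    off_target = [rid for rid in by_record
                  if rid not in target_ids and by_record[rid] > 0]
    for r in family.records:
        if r.record_id in target_ids or by_record[r.record_id] > 0:
            continue
        for primer in (seq_f, seq_r):
            hits = [x for x in find_sites(primer, templates[r.record_id],
                                          r.record_id, s.max_mm,
                                          s.three_prime_window) if x.productive]
            if hits:
                notes.append(
                    f"primer matches non-target {r.record_id} but the pair "
                    "does not co-amplify it (shared primer)")
                break
    if off_target:
        verdict = "cross-reactive"
    elif not on_target:
        verdict = "no-amplification"
    else:
        verdict = "specific"
    return SpecificityReport(target_gene=target_gene, verdict=verdict,
                             amplification=by_record, notes=notes)


def amplicon_tm(sequence: str, monovalent_mm: float = 50.0) -> float:
    """Heuristic product melting temperature (deg C).

    Tm = 81.5 + 0.41 * %GC - 675 / length + 16.6 * log10([monovalent]).
    A long-product approximation, not a thermodynamic calculation.
    """
    if not sequence:
        raise ValueError("empty sequence")
    pct_gc = gc_content(sequence)
    return (81.5 + 0.41 * pct_gc - 675.0 / len(sequence)
            + 16.6 * math.log10(monovalent_mm / 1000.0))


@dataclass
class MeltCurve:
    """A dissociation trace: fluorescence sampled over ascending temperature."""

    temperature: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence grids differ in length")
        if len(self.temperature) < 5:
            raise ValueError("melt curve needs >= 5 grid points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly ascending")


def melt_peaks(curve: MeltCurve, smoothing_window: int = 3,
               min_prominence: float = 0.05) -> list[tuple[float, float]]:
    """Peaks of the negative-derivative melt profile.

    Fluorescence is smoothed with a centered moving average, -dF/dT is
    taken by central differences, and peaks are local maxima with
    prominence >= ``min_prominence`` (as a fraction of the derivative
    range).  Returns (temperature, height) sorted by temperature.
    """
    f = curve.fluorescence
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        fpad = np.pad(f, pad, mode="edge")
        f = np.convolve(fpad, kernel, mode="valid")[:len(curve.fluorescence)]
    neg_dfdt = -np.gradient(f, curve.temperature)
    span = np.ptp(neg_dfdt)
    if span <= 0:
        return []
    idx, _ = find_peaks(neg_dfdt, prominence=min_prominence * span)
    return [(float(curve.temperature[i]), float(neg_dfdt[i])) for i in idx]


def single_peak_qc(curve: MeltCurve, smoothing_window: int = 3,
                   min_prominence: float = 0.05) -> bool:
    """Pass iff the -dF/dT profile shows exactly one peak.

    A single peak indicates one homogeneous product; extra peaks signal
    nonspecific products or primer dimers, a flat profile signals no
    product at all.
    """
    return len(melt_peaks(curve, smoothing_window, min_prominence)) == 1
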