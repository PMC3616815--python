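"""Standard-curve qPCR quantification.

Each assay runs a serial-dilution standard curve; ordinary least
squares of Ct on log10(input) gives slope and intercept, and the
amplification efficiency follows as

    E = 10 ** (-1 / slope) - 1

(E = 1 means perfect doubling per cycle, slope = -3.3219).  Unknowns
are converted to quantities through their own assay's curve — this is
what neutralises efficiency differences between assays — then
normalised to the reference-gene quantity of the same sample and
reported in arbitrary units (A.U.).

The comparative ddCt shortcut is only valid when target and reference
efficiencies match; the dCt-slope rule quantifies that: regress
(Ct_target - Ct_reference) on log10 input and require |slope| <= 0.1.

Censoring: a reaction with no signal within ``max_cycle`` cycles is a
censored observation, not a measurement of zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import CtTable

__all__ = ["StandardCurve", "ExpressionResult", "fit_standard_curve",
           "efficiency_from_slope", "slope_from_efficiency",
           "relative_efficiency_slope", "quantity_from_ct", "normalize",
           "call_expressed", "reference_stability", "summarize", "anova",
           "quantify_experiment"]

DDCT_SLOPE_LIMIT = 0.1


def efficiency_from_slope(slope: float) -> float:
    return 10.0 ** (-1.0 / slope) - 1.0


def slope_from_efficiency(e: float) -> float:
    return -1.0 / np.log10(1.0 + e)


@dataclass
class StandardCurve:
    slope: float        # Ct per log10 input
    intercept: float    # Ct at unit input
    r2: float
    efficiency: float   # fraction; 1.0 = 100 %
    n_points: int
    valid: bool = True


@dataclass
class ExpressionResult:
    gene: str
    tissue: str
    cultivar: str
    au_mean: float      # normalized expression, arbitrary units
    au_sem: float
    n_biological: int
    expressed: bool


def fit_standard_curve(quantities, cts) -> StandardCurve:
    """OLS of Ct on log10(quantity) over a dilution series.

    Requires >= 3 distinct dilution levels and no censored wells.
    A non-negative slope marks the curve invalid (efficiency NaN).
    """
    q = np.asarray(quantities, dtype=float)
    y = np.asarray(cts, dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("censored Ct values in standard curve")
    if len(np.unique(q)) < 3:
        raise ValueError("need >= 3 distinct dilution levels")
    x = np.log10(q)
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue ** 2)
    if slope >= 0:
        warnings.warn("non-negative standard-curve slope; curve invalid")
        return StandardCurve(slope, intercept, r2, float("nan"),
                             len(y), valid=False)
    return StandardCurve(slope, intercept, r2,
                         efficiency_from_slope(slope), len(y), valid=True)


def relative_efficiency_slope(log10_input, ct_target, ct_reference,
                              limit: float = DDCT_SLOPE_LIMIT,
                              ) -> tuple[float, str]:
    """Slope of (Ct_target - Ct_reference) vs log10 input, plus verdict.

    |slope| <= ``limit`` means the two assays amplify with matched
    efficiency and the comparative ddCt method is permissible;
    otherwise the standard-curve method is required.
    """
    x = np.asarray(log10_input, dtype=float)
    d = np.asarray(ct_target, dtype=float) - np.asarray(ct_reference, dtype=float)
    slope = float(stats.linregress(x, d).slope)
    if abs(slope) <= limit:
        return slope, "comparative ddCt permissible"
    return slope, "standard-curve method required"


def quantity_from_ct(ct: float, curve: StandardCurve) -> float:
    """Invert a standard curve; censored (NaN) Ct propagates as NaN."""
    if not curve.valid:
        raise ValueError("invalid standard curve")
    if np.isnan(ct):
        return float("nan")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def normalize(q_target: float, q_reference: float) -> float:
    """Arbitrary units: target quantity over reference quantity."""
    if not q_reference > 0:
        raise ValueError("reference quantity must be positive")
    return q_target / q_reference


def call_expressed(bio_rep_cts: list[list[float]], max_cycle: float = 40.0,
                   ntc_cts: list[float] | None = None,
                   ntc_guard_cycles: float = 3.0) -> bool:
    """Expression call from replicate Cts.

    Expressed iff at least one biological replicate has *all* technical
    replicates detected (Ct < max_cycle, not NaN) with median Ct at
    least ``ntc_guard_cycles`` below any no-template-control signal.
    Censored NTCs (NaN) impose no constraint.
    """
    ntc_floor = float("inf")
    for v in (ntc_cts or []):
        if not np.isnan(v):
            ntc_floor = min(ntc_floor, v)
    for rep in bio_rep_cts:
        arr = np.asarray(rep, dtype=float)
        if len(arr) == 0:
            continue
        detected = np.all(~np.isnan(arr) & (arr < max_cycle))
        if detected and np.median(arr) <= ntc_floor - ntc_guard_cycles:
            return True
    return False


def reference_stability(ct_by_candidate: dict[str, pd.DataFrame],
                        ) -> list[tuple[str, float]]:
    """Rank candidate reference genes by cross-condition Ct stability.

    Each candidate's frame needs columns tissue, cultivar, ct.  Mean Ct
    is taken per (tissue, cultivar) group and the standard deviation of
    those group means (ddof=1) is the instability score; ranking is
    ascending (most stable first).
    """
    scored = []
    for name, df in ct_by_candidate.items():
        means = df.groupby(["tissue", "cultivar"], sort=True)["ct"].mean()
        sd = float(means.std(ddof=1)) if len(means) > 1 else 0.0
        scored.append((name, sd))
    scored.sort(key=lambda t: (t[1], t[0]))
    return scored


def summarize(values) -> tuple[float, float]:
    """Mean and SEM (sd/sqrt(n), ddof=1) over biological replicates."""
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    if n == 0:
        raise ValueError("no values")
    mean = float(arr.mean())
    sem = 0.0 if n == 1 else float(arr.std(ddof=1) / np.sqrt(n))
    return mean, sem


def anova(df: pd.DataFrame, response: str = "au",
          factors: tuple[str, ...] = ("gene", "tissue", "cultivar"),
          ) -> pd.DataFrame:
    """Fixed-effects ANOVA of ``response`` on categorical main effects.

    Standard sum-of-squares decomposition via an OLS fit; returns the
    statsmodels ANOVA table (F and PR(>F) per factor).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    present = [f for f in factors if f in df.columns and df[f].nunique() > 1]
    if not present:
        raise ValueError("no usable factors")
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in present)
    model = smf.ols(formula, data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def quantify_experiment(table: CtTable, reference_assay: str,
                        ntc_guard_cycles: float = 3.0,
                        ) -> tuple[list[ExpressionResult], dict[str, StandardCurve]]:
    """Full standard-curve quantification of a Ct table.

    Per assay: fit the standard curve from its dilution-series wells
    (dilution_step d = relative input 10**-d).  Per biological sample:
    average technical-replicate Cts on the Ct scale, convert to quantity
    through the assay's own curve, and normalise to the reference-gene
    quantity of the same sample.  Biological replicates are then
    summarised as mean and SEM.  Genes failing the expression call are
    reported as 0 A.U. with ``expressed=False``.
    """
    curves: dict[str, StandardCurve] = {}
    for assay in table.assay_ids:
        std = table.standards(assay)
        if len(std) == 0:
            raise ValueError(f"no standard-curve wells for assay {assay!r}")
        q = 10.0 ** (-std["dilution_step"].astype(float))
        curves[assay] = fit_standard_curve(q.to_numpy(), std["ct"].to_numpy())
    if reference_assay not in curves:
        raise ValueError(f"reference assay {reference_assay!r} not in table")

    # per (assay, sample): technical-mean Ct -> quantity
    unk = table.df[table.df.replicate_type.isin(["technical", "biological"])]
    qty: dict[tuple[str, str], float] = {}
    meta: dict[str, tuple[str, str]] = {}
    grouped = unk.groupby(["assay_id", "sample_id"], sort=True)
    for (assay, sample), g in grouped:
        meta[sample] = (str(g["tissue"].iloc[0]), str(g["cultivar"].iloc[0]))
        cts = g["ct"].to_numpy(dtype=float)
        if np.any(np.isnan(cts)):
            qty[(assay, sample)] = float("nan")
        else:
            qty[(assay, sample)] = quantity_from_ct(float(cts.mean()),
                                                    curves[assay])

    results: list[ExpressionResult] = []
    target_assays = [a for a in table.assay_ids if a != reference_assay]
    for assay in target_assays:
        ntc = table.ntc(assay)["ct"].to_numpy(dtype=float).tolist()
        # group samples by condition
        by_cond: dict[tuple[str, str], list[str]] = {}
        for sample, cond in meta.items():
            if (assay, sample) in qty:
                by_cond.setdefault(cond, []).append(sample)
        for (tissue, cultivar), samples in sorted(by_cond.items()):
            bio_cts = []
            aus = []
            for sample in sorted(samples):
                g = unk[(unk.assay_id == assay) & (unk.sample_id == sample)]
                bio_cts.append(g["ct"].to_numpy(dtype=float).tolist())
                q_t = qty[(assay, sample)]
                q_r = qty.get((reference_assay, sample), float("nan"))
                if np.isnan(q_t) or np.isnan(q_r) or q_r <= 0:
                    aus.append(float("nan"))
                else:
                    aus.append(normalize(q_t, q_r))
            expressed = call_expressed(bio_cts, table.max_cycle, ntc,
                                       ntc_guard_cycles)
            if expressed:
                clean = [a for a in aus if not np.isnan(a)]
                mean, sem = summarize(clean)
            else:
                mean, sem = 0.0, 0.0
            results.append(ExpressionResult(
                gene=assay, tissue=tissue, cultivar=cultivar,
                au_mean=mean, au_sem=sem, n_biological=len(samples),
                expressed=expressed))
    return results, curves
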