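"""Differential HDX-MS: state-vs-state comparison per peptide and timepoint.

A change is called significant when it clears three criteria at once: the
uptake difference exceeds both 5% of the correctable maximum and 0.4 Da in
absolute magnitude, and an unpaired two-tailed Welch t-test on the replicate
values gives p < 0.01.  All three inequalities are strict.  No
multiple-testing correction is applied: the three-criterion filter is
evaluated per peptide-timepoint, mirroring common HDX-MS practice — treat
borderline calls accordingly.

Summed #D-difference ("butterfly") profiles add the per-timepoint
differences over the whole time course per peptide and propagate the error
in quadrature, keyed by the peptide's central residue.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import (
    CorrectionConfig,
    Peptide,
    UptakeDataset,
    exchangeable_positions,
)

__all__ = [
    "Thresholds",
    "DifferenceRecord",
    "SummedDifference",
    "ComparisonResult",
    "two_sample_test",
    "compare_states",
    "peptide_significance",
    "summed_difference",
    "summed_differences",
    "coverage_stats",
    "differences_to_frame",
    "summed_to_frame",
]

#: Variance floor (Da^2) keeping the t statistic finite for zero-variance
#: replicate sets (identical centroids after rounding).
VAR_FLOOR = 1e-12

@dataclass(frozen=True)
class Thresholds:
    """Three-criterion significance filter: |Δ%D| > min_pct, |Δ#D| > min_mass
    (Da) and p < alpha, all strict."""

    min_pct: float = 5.0
    min_mass: float = 0.4
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.min_pct <= 0 or self.min_mass <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be strictly positive")

@dataclass(frozen=True)
class DifferenceRecord:
    """Per-timepoint state difference for one peptide (state B - state A)."""

    peptide: Peptide
    timepoint: float
    delta_d: float
    sd_delta: float
    delta_pct: float
    p_value: float
    passes: bool
    direction: Literal["increase", "decrease", "none"]

@dataclass(frozen=True)
class SummedDifference:
    """Time-course sum of per-timepoint differences with quadrature error."""

    peptide: Peptide
    central_residue: float
    sum_delta_d: float
    sd_sum: float

@dataclass
class ComparisonResult:
    records: list[DifferenceRecord]
    unmatched_a: list[Peptide] = field(default_factory=list)
    unmatched_b: list[Peptide] = field(default_factory=list)
    dropped_timepoints: list[float] = field(default_factory=list)

    def for_peptide(self, peptide: Peptide) -> list[DifferenceRecord]:
        return [r for r in self.records if r.peptide.key() == peptide.key()]

    def peptides(self) -> list[Peptide]:
        seen, out = set(), []
        for r in self.records:
            if r.peptide.key() not in seen:
                seen.add(r.peptide.key())
                out.append(r.peptide)
        return out

def two_sample_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
) -> float:
    """Two-tailed p-value comparing replicate uptake values of two states.

    Default is the Welch unequal-variance unpaired t-test; a paired variant
    is available behind ``paired=True`` for designs with genuine pairing.
    Sample variances are floored at 1e-12 Da^2 so that identical replicate
    values give a finite statistic.  With fewer than 2 replicates in either
    state the p-value is undefined (NaN) and the comparison can never pass.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return math.nan
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal replicate counts")
        d = b - a
        var = max(d.var(ddof=1), VAR_FLOOR)
        t = d.mean() / math.sqrt(var / len(d))
        df = len(d) - 1
        return 2.0 * stats.t.sf(abs(t), df)
    va = max(a.var(ddof=1), VAR_FLOOR)
    vb = max(b.var(ddof=1), VAR_FLOOR)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (b.mean() - a.mean()) / math.sqrt(se2)
    if a.mean() == b.mean():
        return 1.0
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * stats.t.sf(abs(t), df)

def _evaluate(delta_d: float, delta_pct: float, p: float, thr: Thresholds) -> tuple[bool, str]:
    passes = (
        math.isfinite(p)
        and not math.isnan(delta_pct)
        and abs(delta_pct) > thr.min_pct
        and abs(delta_d) > thr.min_mass
        and p < thr.alpha
    )
    if not passes:
        return False, "none"
    return True, ("increase" if delta_d > 0 else "decrease")

def compare_states(
    dataset_a: UptakeDataset,
    dataset_b: UptakeDataset,
    thresholds: Thresholds = Thresholds(),
    correction: CorrectionConfig | None = None,
    paired: bool = False,
) -> ComparisonResult:
    """Per (peptide, timepoint) differences between two states.

    delta_D = mean_B - mean_A on the raw deuteron scale; delta_pct is the
    same difference expressed as % of the D2O-corrected maximum
    (100 * delta_D / (maxD * f)); sd_delta combines the replicate SDs in
    quadrature.  Only peptides present in both datasets are compared
    (others are reported in the unmatched lists) and only shared labeling
    timepoints are used (t = 0 reference rows are excluded; dropped
    timepoints are reported with a warning).
    """
    if correction is None:
        fa, fb = dataset_a.d2o_fraction, dataset_b.d2o_fraction
        if not math.isclose(fa, fb, rel_tol=1e-9):
            raise ValueError(f"states have different D2O fractions ({fa} vs {fb}); "
                             "pass an explicit CorrectionConfig")
        correction = CorrectionConfig(d2o_fraction=fa)
    f = correction.d2o_fraction

    keys_a = {p.key(): p for p in dataset_a.peptides}
    keys_b = {p.key(): p for p in dataset_b.peptides}
    shared = sorted(set(keys_a) & set(keys_b))
    unmatched_a = [keys_a[k] for k in sorted(set(keys_a) - set(keys_b))]
    unmatched_b = [keys_b[k] for k in sorted(set(keys_b) - set(keys_a))]

    tps_a = {t for t in dataset_a.timepoints() if t > 0}
    tps_b = {t for t in dataset_b.timepoints() if t > 0}
    shared_tps = sorted(tps_a & tps_b)
    dropped = sorted((tps_a | tps_b) - set(shared_tps))
    if dropped:
        warnings.warn(f"timepoints present in only one state were dropped: {dropped}")

    state_a = dataset_a.states()
    state_b = dataset_b.states()
    if len(state_a) != 1 or len(state_b) != 1:
        raise ValueError("each dataset must contain exactly one state for comparison")

    records: list[DifferenceRecord] = []
    for key in shared:
        pep = keys_a[key]
        for t in shared_tps:
            va = dataset_a.replicate_values(pep, state_a[0], t)
            vb = dataset_b.replicate_values(pep, state_b[0], t)
            if len(va) == 0 or len(vb) == 0:
                continue
            delta = float(vb.mean() - va.mean())
            sd_a = float(va.std(ddof=1)) if len(va) > 1 else 0.0
            sd_b = float(vb.std(ddof=1)) if len(vb) > 1 else 0.0
            sd_delta = math.sqrt(sd_a**2 + sd_b**2)
            if pep.max_d > 0:
                delta_pct = 100.0 * delta / (pep.max_d * f)
            else:
                delta_pct = math.nan
            p = two_sample_test(va, vb, paired=paired)
            passes, direction = _evaluate(delta, delta_pct, p, thresholds)
            records.append(
                DifferenceRecord(pep, t, delta, sd_delta, delta_pct, p, passes, direction)
            )
    return ComparisonResult(records, unmatched_a, unmatched_b, dropped)

def peptide_significance(
    records: Sequence[DifferenceRecord],
) -> Literal["increase", "decrease", "mixed", "none"]:
    """Classify one peptide over its time course: significant if ANY
    timepoint passes; increase/decrease when all passing timepoints agree in
    sign, mixed when both signs pass."""
    if not records:
        raise ValueError("no records for peptide")
    dirs = {r.direction for r in records if r.passes}
    if not dirs:
        return "none"
    if dirs == {"increase"}:
        return "increase"
    if dirs == {"decrease"}:
        return "decrease"
    return "mixed"

def summed_difference(records: Sequence[DifferenceRecord]) -> SummedDifference:
    """Sum of per-timepoint differences for one peptide with the error
    propagated in quadrature: sd_sum = sqrt(sum_t sd_delta(t)^2)."""
    if not records:
        raise ValueError("cannot sum an empty record set")
    pep = records[0].peptide
    if any(r.peptide.key() != pep.key() for r in records):
        raise ValueError("records belong to different peptides")
    total = sum(r.delta_d for r in records)
    sd = math.sqrt(sum(r.sd_delta**2 for r in records))
    return SummedDifference(pep, pep.central_residue, total, sd)

def summed_differences(
    comparison: ComparisonResult,
    expected_timepoints: Sequence[float] | None = None,
) -> list[SummedDifference]:
    """Summed-difference profile over all peptides with complete time
    courses; peptides missing a timepoint are excluded with a warning."""
    if expected_timepoints is None:
        expected = {r.timepoint for r in comparison.records}
    else:
        expected = set(expected_timepoints)
    out = []
    for pep in comparison.peptides():
        recs = comparison.for_peptide(pep)
        have = {r.timepoint for r in recs}
        if have != expected:
            warnings.warn(
                f"peptide {pep.start}-{pep.end} missing timepoints "
                f"{sorted(expected - have)}; excluded from summed profile"
            )
            continue
        out.append(summed_difference(recs))
    return out

def coverage_stats(peptides: Sequence[Peptide], sequence: str) -> dict:
    """Peptide count and percent of the protein's exchangeable amides
    covered by the union of the peptides' exchangeable residues."""
    total = set(exchangeable_positions(sequence))
    if not peptides:
        return {"n_peptides": 0, "pct_exchangeable_covered": 0.0}
    covered: set[int] = set()
    for p in peptides:
        covered |= set(p.exchangeable_residues()) & total
    pct = 100.0 * len(covered) / len(total) if total else 0.0
    return {"n_peptides": len({p.key() for p in peptides}), "pct_exchangeable_covered": pct}

def differences_to_frame(comparison: ComparisonResult) -> pd.DataFrame:
    """Per-peptide-per-timepoint difference table for CSV export."""
    rows = [
        dict(
            start=r.peptide.start, end=r.peptide.end, sequence=r.peptide.sequence,
            charge=r.peptide.charge, timepoint=r.timepoint, delta_d=r.delta_d,
            sd_delta=r.sd_delta, delta_pct=r.delta_pct, p_value=r.p_value,
            passes=r.passes, direction=r.direction,
        )
        for r in comparison.records
    ]
    return pd.DataFrame(rows)

def summed_to_frame(summed: Sequence[SummedDifference]) -> pd.DataFrame:
    """Summed #D-difference table keyed by central residue (butterfly plot)."""
    rows = [
        dict(
            central_residue=s.central_residue, start=s.peptide.start, end=s.peptide.end,
            sum_delta_d=s.sum_delta_d, sd_sum=s.sd_sum,
        )
        for s in summed
    ]
    return pd.DataFrame(rows).sort_values("central_residue").reset_index(drop=True)
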