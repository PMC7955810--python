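"""Lipid-kinase assay arithmetic.

ADP-production fluorescence assays (Transcreener-style) are normalized
against a 0–100% ADP window, converted to % ATP turnover through a standard
curve, corrected for basal ATPase activity, and — for inhibitor series —
fitted with a four-parameter logistic (4PL) dose-response model

    y(x) = bottom + (top - bottom) / (1 + (x / IC50)^hill)

on log-spaced doses, Prism-style: unweighted least squares on the log10-dose
axis with an unconstrained Hill slope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ADPWindow",
    "StandardCurve",
    "DoseResponse",
    "FourPLFit",
    "normalize_to_window",
    "interpolate_turnover",
    "specific_activity",
    "fit_4pl",
]


@dataclass(frozen=True)
class ADPWindow:
    """Fluorescence at 0% and 100% ADP conversion (same plate, same mix)."""

    f_0: float
    f_100: float

    def __post_init__(self) -> None:
        if self.f_0 == self.f_100:
            raise ValueError("degenerate ADP window: F_0 == F_100")


def normalize_to_window(f: float | np.ndarray, window: ADPWindow) -> float | np.ndarray:
    """Percent-ADP-scale signal: 100 * (F - F_0) / (F_100 - F_0), unclipped."""
    return 100.0 * (np.asarray(f, dtype=float) - window.f_0) / (window.f_100 - window.f_0)


@dataclass(frozen=True)
class StandardCurve:
    """Ordered (ADP fraction, normalized signal) calibration pairs; the
    signal must be monotone in ADP fraction."""

    adp_fraction: tuple[float, ...]
    signal: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.adp_fraction) != len(self.signal) or len(self.adp_fraction) < 3:
            raise ValueError("standard curve needs >= 3 (fraction, signal) pairs")
        frac = np.asarray(self.adp_fraction)
        if np.any(np.diff(frac) <= 0):
            raise ValueError("ADP fractions must be strictly increasing")
        diffs = np.diff(np.asarray(self.signal))
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("standard-curve signal is not monotone")


def interpolate_turnover(norm_signal: float, curve: StandardCurve) -> float:
    """% ATP turnover by monotone piecewise-linear interpolation of the
    standard curve.  Signals outside the calibrated range are flagged with a
    warning and clamped to the nearest knot."""
    sig = np.asarray(curve.signal, dtype=float)
    frac = np.asarray(curve.adp_fraction, dtype=float)
    if sig[0] > sig[-1]:  # make the signal axis increasing for np.interp
        sig, frac = sig[::-1], frac[::-1]
    if not (sig[0] <= norm_signal <= sig[-1]):
        warnings.warn(
            f"signal {norm_signal} outside standard-curve range "
            f"[{sig[0]}, {sig[-1]}]: extrapolation clamped to range edge"
        )
    return float(np.interp(norm_signal, sig, frac))


def specific_activity(
    turnover_pct: float,
    atp_conc: float,
    time: float,
    enzyme_conc: float,
    basal: float = 0.0,
) -> float:
    """Specific activity (ADP produced per enzyme per unit time) after basal
    ATPase subtraction:

        (turnover_pct/100 * [ATP]) / (time * [enzyme]) - basal

    Units follow the inputs (e.g. µM ATP, minutes, nM enzyme).  Negative
    results (activity below basal) are preserved and flagged with a warning.
    """
    if time <= 0 or enzyme_conc <= 0:
        raise ValueError("time and enzyme concentration must be > 0")
    total = (turnover_pct / 100.0 * atp_conc) / (time * enzyme_conc)
    result = total - basal
    if result < 0:
        warnings.warn(f"specific activity {result:.4g} below basal; preserved unclipped")
    return result


@dataclass(frozen=True)
class DoseResponse:
    """Inhibitor dose series: concentrations (nM, > 0) and the fraction of
    uninhibited activity remaining at each dose (replicates flattened into
    repeated concentration entries are fine)."""

    concentrations: tuple[float, ...]
    fraction_activity: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.fraction_activity):
            raise ValueError("length mismatch")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be > 0 (log-dose model)")


@dataclass(frozen=True)
class FourPLFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    stderr: dict[str, float]

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        return _fourpl(np.log10(x), self.top, self.bottom, math.log10(self.ic50), self.hill)


def _fourpl(logx: np.ndarray, top: float, bottom: float, log_ic50: float, hill: float):
    # overflow in the power term is benign: 1/(1+inf) -> 0
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((logx - log_ic50) * hill))


def fit_4pl(dose_response: DoseResponse) -> FourPLFit:
    """Least-squares 4PL fit on the log10-dose axis.

    Initialization is a deterministic multi-start: log-IC50 candidates on a
    grid spanning the dose range crossed with Hill slopes {0.5, 1, 2}; the
    start with the lowest residual sum of squares wins.  Requires at least 5
    doses.  Parameter uncertainties are the square roots of the covariance
    diagonal.  At x = IC50 the fitted curve passes through
    (top + bottom) / 2 by construction.
    """
    x = np.asarray(dose_response.concentrations, dtype=float)
    y = np.asarray(dose_response.fraction_activity, dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("need >= 5 distinct concentrations spanning the transition")
    logx = np.log10(x)
    top0, bottom0 = float(y.max()), float(y.min())
    grid = np.linspace(logx.min(), logx.max(), 5)
    tried, best = [], None
    for lg in grid:
        for hill0 in (0.5, 1.0, 2.0):
            p0 = (top0, bottom0, float(lg), hill0)
            tried.append(p0)
            try:
                with warnings.catch_warnings():
                    # noiseless data can make the covariance singular; the
                    # parameter point estimates are still well defined
                    warnings.simplefilter("ignore")
                    popt, pcov = curve_fit(_fourpl, logx, y, p0=p0, maxfev=20000)
            except RuntimeError:
                continue
            ssr = float(((y - _fourpl(logx, *popt)) ** 2).sum())
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
    if best is None:
        raise RuntimeError(f"4PL fit failed to converge from initializations: {tried}")
    _, popt, pcov = best
    top, bottom, log_ic50, hill = popt
    with np.errstate(invalid="ignore"):
        err = np.sqrt(np.diag(pcov))
    ic50 = 10.0**log_ic50
    stderr = {
        "top": float(err[0]),
        "bottom": float(err[1]),
        # delta method: sd(IC50) = ln(10) * IC50 * sd(log10 IC50)
        "ic50": float(math.log(10.0) * ic50 * err[2]),
        "hill": float(err[3]),
    }
    return FourPLFit(float(top), float(bottom), float(ic50), float(hill), stderr)
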