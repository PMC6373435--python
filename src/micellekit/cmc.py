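"""Critical micelle concentration (CMC) estimation.

Two routes are implemented:

* **free-fraction route** — fit f(C) = a * C^b to the fraction of free
  molecules versus concentration and solve f(CMC) = 0.5: the CMC is the
  concentration at which half the molecules are free and half aggregated.
* **surface-tension route** — fit two least-squares lines to surface
  tension versus log10(concentration in M), choosing the contiguous split
  that minimises the total squared error; the CMC is the concentration at
  the intersection of the two lines (the plate-tensiometry break point).

Published reference CMC values for the four fatty acids under the
standard conditions are collected in :data:`REFERENCE_CMC_MM` so the
protonation/ionic-strength comparisons (percent decreases, experimental
versus simulated fold ratios) can be recomputed from the table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .aggregates import FreeFractionPoint
from .errors import (
    FitFailureError,
    InvalidInputError,
    NoCrossingError,
    NoIntersectionError,
)

#: Published CMC values in mM by (chain, condition).
#: Simulated conditions: fully deprotonated ("deprot"), deprotonated with
#: 140 mM NaCl ("deprot_nacl"), 1:1 deprotonated:neutral with NaCl
#: ("mixed_nacl"), fully neutral with NaCl ("neutral_nacl");
#: "deprot_nacl_50C" is the 50 degC run.  Experimental plate-tensiometry
#: values: "exp_ph12" (fully deprotonated) and "exp_ph7" (near-pKa, 1:1).
REFERENCE_CMC_MM: dict[tuple[str, str], float] = {
    ("C8", "deprot"): 38.69,
    ("C8", "deprot_nacl"): 31.68,
    ("C8", "mixed_nacl"): 13.88,
    ("C8", "neutral_nacl"): 9.26,
    ("C8", "exp_ph12"): 75.0,
    ("C8", "exp_ph7"): 42.1,
    ("C10", "deprot"): 18.68,
    ("C10", "deprot_nacl"): 14.89,
    ("C10", "mixed_nacl"): 8.27,
    ("C10", "neutral_nacl"): 5.08,
    ("C10", "exp_ph12"): 45.7,
    ("C10", "exp_ph7"): 15.5,
    ("C12", "deprot"): 1.64,
    ("C12", "deprot_nacl"): 1.33,
    ("C12", "deprot_nacl_50C"): 1.71,
    ("C12", "mixed_nacl"): 1.15,
    ("C12", "neutral_nacl"): 1.09,
    ("C12", "exp_ph12"): 5.97,
    ("C14", "deprot"): 0.99,
    ("C14", "deprot_nacl"): 0.86,
    ("C14", "mixed_nacl"): 0.77,
    ("C14", "neutral_nacl"): 0.83,
}

#: (chain, experimental condition, matched simulated condition) pairs used
#: for the experimental/simulated fold-ratio comparison.
FOLD_PAIRS: list[tuple[str, str, str]] = [
    ("C8", "exp_ph12", "deprot_nacl"),
    ("C8", "exp_ph7", "mixed_nacl"),
    ("C10", "exp_ph12", "deprot_nacl"),
    ("C10", "exp_ph7", "mixed_nacl"),
    ("C12", "exp_ph12", "deprot_nacl_50C"),
]


@dataclass
class PowerLawFit:
    """f(C) = amplitude * C^exponent, concentrations in mM."""

    amplitude: float
    exponent: float
    r_squared: float
    concentration_range: tuple[float, float]

    def __call__(self, concentration_mM):
        return self.amplitude * np.asarray(concentration_mM, dtype=float) ** self.exponent


@dataclass
class CMCEstimate:
    """A CMC in mM with provenance and fit diagnostics."""

    value_mM: float
    method: str  # "free-fraction" | "surface-tension"
    extrapolated: bool
    diagnostics: object

    def __post_init__(self):
        if not self.value_mM > 0:
            raise InvalidInputError("CMC must be positive")

    def to_dict(self) -> dict:
        diag: dict = {}
        if isinstance(self.diagnostics, PowerLawFit):
            diag = {
                "amplitude": self.diagnostics.amplitude,
                "exponent": self.diagnostics.exponent,
                "r_squared": self.diagnostics.r_squared,
                "concentration_range_mM": list(self.diagnostics.concentration_range),
            }
        elif isinstance(self.diagnostics, TwoLineFit):
            diag = {
                "slope1": self.diagnostics.slope1,
                "intercept1": self.diagnostics.intercept1,
                "slope2": self.diagnostics.slope2,
                "intercept2": self.diagnostics.intercept2,
                "breakpoint_log10C_M": self.diagnostics.breakpoint_log10C,
                "total_sse": self.diagnostics.total_sse,
            }
        return {
            "method": self.method,
            "cmc_mM": self.value_mM,
            "extrapolated": self.extrapolated,
            "diagnostics": diag,
        }


def fit_power_law(concentrations_mM: np.ndarray, fractions: np.ndarray) -> PowerLawFit:
    """Unweighted nonlinear least-squares fit of f = a * C^b.

    Initialised from the log-log linear regression; R^2 is computed on the
    untransformed fractions.
    """
    c = np.asarray(concentrations_mM, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if len(c) < 3:
        raise InvalidInputError("power-law fit needs at least 3 points")
    if np.any(c <= 0):
        raise InvalidInputError("concentrations must be positive")
    if np.any(f <= 0) or np.any(f > 1):
        raise InvalidInputError("free fractions must lie in (0, 1]")

    loglog = linregress(np.log(c), np.log(f))
    a0, b0 = math.exp(loglog.intercept), loglog.slope
    try:
        popt, _ = curve_fit(
            lambda x, a, b: a * x**b, c, f, p0=(a0, b0), maxfev=10000
        )
        a, b = float(popt[0]), float(popt[1])
    except RuntimeError as err:  # pragma: no cover - hard to trigger
        raise FitFailureError(
            f"power-law fit did not converge ({err}); log-log estimate was "
            f"a={a0:.6g}, b={b0:.6g}"
        ) from None
    resid = f - a * c**b
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res < 1e-12 else 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return PowerLawFit(a, b, r2, (float(c.min()), float(c.max())))


def fit_free_fraction(points: Sequence[FreeFractionPoint]) -> PowerLawFit:
    """Power-law fit through a free-fraction-vs-concentration series."""
    pts = list(points)
    c = np.array([p.concentration_mM for p in pts])
    f = np.array([p.mean_free_fraction for p in pts])
    return fit_power_law(c, f)


def cmc_from_free_fraction(fit: PowerLawFit, threshold: float = 0.5) -> CMCEstimate:
    """Solve a * C^b = threshold for C (the 50%-free CMC rule).

    Requires a decreasing fit (b < 0); flags the estimate as extrapolated
    when the crossing lies outside the fitted concentration range.
    """
    if fit.exponent >= 0:
        raise NoCrossingError(
            f"fitted exponent b={fit.exponent:.4g} is non-negative; the free "
            f"fraction never falls to {threshold}"
        )
    value = (threshold / fit.amplitude) ** (1.0 / fit.exponent)
    lo, hi = fit.concentration_range
    return CMCEstimate(
        value_mM=float(value),
        method="free-fraction",
        extrapolated=not (lo <= value <= hi),
        diagnostics=fit,
    )


@dataclass
class TensionCurve:
    """Surface tension (mN/m) versus concentration (mM), sorted ascending."""

    points: list[tuple[float, float]]

    def __post_init__(self):
        if any(c <= 0 for c, _ in self.points):
            raise InvalidInputError("concentrations must be positive")
        self.points = sorted(self.points)
        concs = [c for c, _ in self.points]
        if any(c1 <= c0 for c0, c1 in zip(concs, concs[1:])):
            raise InvalidInputError("concentrations must be distinct")

    @property
    def log10_molar(self) -> np.ndarray:
        return np.log10(np.array([c for c, _ in self.points]) * 1e-3)

    @property
    def tensions(self) -> np.ndarray:
        return np.array([t for _, t in self.points])


@dataclass
class TwoLineFit:
    """Two least-squares lines of tension vs log10(concentration in M)."""

    slope1: float
    intercept1: float
    slope2: float
    intercept2: float
    breakpoint_log10C: float
    total_sse: float
    split_index: int  # first point index belonging to segment 2


def _line_sse(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line through >= 2 points; returns slope, intercept, SSE."""
    if len(x) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return slope, y[0] - slope * x[0], 0.0
    res = linregress(x, y)
    sse = float(np.sum((y - (res.slope * x + res.intercept)) ** 2))
    return float(res.slope), float(res.intercept), sse


def cmc_from_surface_tension(
    curve: TensionCurve, slope_tol: float = 1e-9
) -> tuple[TwoLineFit, CMCEstimate]:
    """Break-point CMC from a surface-tension curve.

    Every contiguous split leaving at least two points per side is tried;
    the split with the smallest total SSE wins (ties go to the split with
    more points in the first segment).  The CMC is 10^(intersection) of the
    two fitted lines, converted back to mM.
    """
    x = curve.log10_molar
    y = curve.tensions
    n = len(x)
    if n < 4:
        raise InvalidInputError("two-line fit needs at least 4 points")
    best = None
    tol = 1e-12 * max(1.0, float(np.sum(y**2)))
    for k in range(2, n - 1):  # segment 1 = [:k], segment 2 = [k:]
        s1, i1, e1 = _line_sse(x[:k], y[:k])
        s2, i2, e2 = _line_sse(x[k:], y[k:])
        sse = e1 + e2
        if best is None or sse < best[0] - tol or abs(sse - best[0]) <= tol:
            best = (sse, s1, i1, s2, i2, k)  # later k wins ties
    sse, s1, i1, s2, i2, k = best
    if abs(s1 - s2) < slope_tol:
        raise NoIntersectionError(
            f"fitted segments are parallel (slopes {s1:.4g}, {s2:.4g})"
        )
    xstar = (i2 - i1) / (s1 - s2)
    fit = TwoLineFit(s1, i1, s2, i2, float(xstar), float(sse), k)
    cmc_mM = 10.0**xstar * 1e3
    lo, hi = float(x.min()), float(x.max())
    estimate = CMCEstimate(
        value_mM=float(cmc_mM),
        method="surface-tension",
        extrapolated=not (lo < xstar < hi),
        diagnostics=fit,
    )
    return fit, estimate


def percent_decrease(reference_mM: float, alternative_mM: float) -> int:
    """Percent CMC decrease from a reference condition, nearest integer."""
    return round(100.0 * (reference_mM - alternative_mM) / reference_mM)


def fold_ratio(experimental_mM: float, simulated_mM: float) -> float:
    """Experimental/simulated CMC ratio, rounded to 1 decimal."""
    return round(experimental_mM / simulated_mM, 1)


def compare_conditions(
    table: Mapping[tuple[str, str], float],
    decrease_pairs: Sequence[tuple[str, str, str]] = (
        ("C8", "deprot_nacl", "mixed_nacl"),
        ("C10", "deprot_nacl", "mixed_nacl"),
        ("C12", "deprot_nacl", "mixed_nacl"),
        ("C14", "deprot_nacl", "mixed_nacl"),
    ),
    fold_pairs: Sequence[tuple[str, str, str]] = tuple(FOLD_PAIRS),
) -> dict:
    """Condition-comparison report from a (chain, condition) -> CMC table.

    Computes per-chain percent decreases between condition pairs and
    experimental/simulated fold ratios; missing entries are listed as
    absent rather than raising.
    """
    report: dict = {"percent_decrease": {}, "fold_ratio": {}, "missing": []}
    for chain, ref, alt in decrease_pairs:
        if (chain, ref) not in table or (chain, alt) not in table:
            report["missing"].append([chain, ref, alt])
            continue
        report["percent_decrease"][chain] = percent_decrease(
            table[(chain, ref)], table[(chain, alt)]
        )
    folds = {}
    for chain, exp, sim in fold_pairs:
        if (chain, exp) not in table or (chain, sim) not in table:
            report["missing"].append([chain, exp, sim])
            continue
        folds[f"{chain}:{exp}/{sim}"] = fold_ratio(table[(chain, exp)], table[(chain, sim)])
    report["fold_ratio"] = folds
    if folds:
        report["min_fold"] = min(folds.values())
        report["max_fold"] = max(folds.values())
    return report
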