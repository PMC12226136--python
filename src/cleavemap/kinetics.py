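"""Quantitative enzyme-activity layer.

Michaelis–Menten fitting of initial rates (with fluorescence calibration
and an inner-filter correction hook), active-site titration against a
tight-binding inhibitor (x-intercept of the linear portion of the residual
activity curve), single-exponential progress-curve fitting for the
specificity constant kcat/Km under sub-saturating substrate, and fold
comparisons between enzymes.

Units are SI throughout: concentrations molar, rates molar per second,
kcat 1/s, kcat/Km 1/(M*s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .model import CleavemapError


class FitError(CleavemapError):
    """A nonlinear fit failed to converge or produced invalid parameters."""


# ---------------------------------------------------------------------------
# Calibration


def calibrate_rfu(
    rfu_rate: float, calibration: float, ife_factor: float = 1.0
) -> float:
    """Convert a fluorescence rate (RFU/s) to a product formation rate.

    ``calibration`` is RFU per molar product, typically derived from the
    total signal released by complete digestion of a known substrate
    amount; ``ife_factor`` is a per-well multiplicative inner-filter
    correction (1 = none).
    """
    if calibration <= 0:
        raise CleavemapError("calibration must be positive")
    return rfu_rate * ife_factor / calibration


def calibration_from_standard(
    total_rfu: float, substrate_conc: float
) -> float:
    """RFU per molar product from a fully digested standard."""
    if substrate_conc <= 0 or total_rfu <= 0:
        raise CleavemapError("standard signal and concentration must be > 0")
    return total_rfu / substrate_conc


# ---------------------------------------------------------------------------
# Michaelis-Menten


@dataclass
class MMSeries:
    """Initial-rate measurements at a range of substrate concentrations."""

    substrate_conc: list[float]
    v0: list[float]
    enzyme_conc_active: float

    def __post_init__(self) -> None:
        if len(self.substrate_conc) != len(self.v0):
            raise CleavemapError("substrate_conc and v0 lengths differ")
        if any(s <= 0 for s in self.substrate_conc):
            raise CleavemapError("substrate concentrations must be positive")
        if any(v < 0 for v in self.v0):
            raise CleavemapError("initial rates must be nonnegative")
        if self.enzyme_conc_active <= 0:
            raise CleavemapError("active enzyme concentration must be > 0")


@dataclass(frozen=True)
class MMFit:
    """Michaelis–Menten parameters with standard errors."""

    Km: float
    Vmax: float
    kcat: float
    kcat_over_Km: float
    Km_se: float
    Vmax_se: float


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_mm(series: MMSeries) -> MMFit:
    """Nonlinear least-squares fit of v0 = Vmax*S/(Km+S)."""
    s = np.asarray(series.substrate_conc, dtype=float)
    v = np.asarray(series.v0, dtype=float)
    if len(np.unique(s)) < 4:
        raise CleavemapError(
            "need at least 4 distinct substrate concentrations"
        )
    vmax0 = float(v.max()) or 1.0
    km0 = float(np.median(s))
    try:
        popt, pcov = curve_fit(
            _mm, s, v, p0=(vmax0, km0), maxfev=10000
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}")
    vmax, km = float(popt[0]), float(popt[1])
    if vmax <= 0 or km <= 0:
        raise FitError(
            f"non-physical Michaelis-Menten estimates Vmax={vmax:g}, Km={km:g}"
        )
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    kcat = vmax / series.enzyme_conc_active
    return MMFit(
        Km=km,
        Vmax=vmax,
        kcat=kcat,
        kcat_over_Km=kcat / km,
        Km_se=float(se[1]),
        Vmax_se=float(se[0]),
    )


# ---------------------------------------------------------------------------
# Active-site titration


@dataclass
class TitrationSeries:
    """Residual activity (%) versus tight-binding inhibitor concentration.

    ``linear_region`` optionally restricts the fit to an index range
    (inclusive); by default all points with residual activity >= the
    ``linear_floor`` percentage are used, which captures the initial linear
    portion of a stoichiometric titration.
    """

    inhibitor_conc: list[float]
    residual_activity: list[float]
    linear_region: tuple[int, int] | None = None
    linear_floor: float = 20.0

    def __post_init__(self) -> None:
        if len(self.inhibitor_conc) != len(self.residual_activity):
            raise CleavemapError("titration series lengths differ")
        if not self.inhibitor_conc or self.inhibitor_conc[0] != 0:
            raise CleavemapError(
                "titration must start at zero inhibitor (the 100% point)"
            )
        if abs(self.residual_activity[0] - 100.0) > 1e-6:
            raise CleavemapError(
                "residual activity at zero inhibitor must be normalised to 100"
            )

    def region_indices(self) -> list[int]:
        if self.linear_region is not None:
            lo, hi = self.linear_region
            return list(range(lo, hi + 1))
        return [
            i
            for i, act in enumerate(self.residual_activity)
            if act >= self.linear_floor
        ]


def fit_titration(series: TitrationSeries) -> float:
    """Active enzyme concentration from the titration x-intercept.

    Fits a least-squares line to the linear portion and returns the
    inhibitor concentration at which extrapolated activity reaches zero
    (1:1 binding stoichiometry).
    """
    idx = series.region_indices()
    if len(idx) < 3:
        raise CleavemapError("need at least 3 points in the linear region")
    x = np.asarray([series.inhibitor_conc[i] for i in idx], dtype=float)
    y = np.asarray([series.residual_activity[i] for i in idx], dtype=float)
    fit = linregress(x, y)
    if fit.slope >= 0:
        raise FitError(
            "titration slope is not negative; no titration endpoint"
        )
    return float(-fit.intercept / fit.slope)


# ---------------------------------------------------------------------------
# Progress curves


@dataclass
class ProgressSeries:
    """Product formation over time at sub-saturating substrate."""

    time: list[float]
    product_conc: list[float]
    S0: float
    enzyme_conc_active: float
    tolerance: float = 0.05  # assay noise allowance on product <= S0

    def __post_init__(self) -> None:
        if len(self.time) != len(self.product_conc):
            raise CleavemapError("time and product lengths differ")
        if self.S0 <= 0 or self.enzyme_conc_active <= 0:
            raise CleavemapError("S0 and enzyme concentration must be > 0")
        ceiling = self.S0 * (1.0 + self.tolerance)
        if any(p > ceiling for p in self.product_conc):
            raise CleavemapError(
                "product concentration exceeds available substrate"
            )


def progress_model(t, k2, S0, E):
    """P(t) = S0 (1 - exp(-(kcat/Km) E t)); valid for S0 << Km."""
    return S0 * (1.0 - np.exp(-k2 * E * t))


def fit_progress(series: ProgressSeries) -> float:
    """Specificity constant kcat/Km from a single-exponential progress fit."""
    t = np.asarray(series.time, dtype=float)
    p = np.asarray(series.product_conc, dtype=float)
    if len(t) < 4:
        raise CleavemapError("need at least 4 time points")
    # Initial guess from the fractional conversion at the last time point.
    frac = min(max(p[-1] / series.S0, 1e-6), 0.999999)
    k0 = -np.log(1.0 - frac) / (
        series.enzyme_conc_active * max(t[-1], 1e-12)
    )
    try:
        popt, _ = curve_fit(
            lambda tt, k2: progress_model(
                tt, k2, series.S0, series.enzyme_conc_active
            ),
            t,
            p,
            p0=(max(k0, 1e-6),),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"progress-curve fit did not converge: {exc}")
    k2 = float(popt[0])
    if k2 <= 0:
        raise FitError(f"non-physical specificity constant {k2:g}")
    return k2


# ---------------------------------------------------------------------------
# Fold comparison


@dataclass(frozen=True)
class FoldComparison:
    label: str
    fold: float
    direction: str  # "higher" | "lower" | "equal"

    def __str__(self) -> str:
        if self.direction == "equal":
            return f"{self.label}: 1-fold"
        return f"{self.label}: {self.fold:.3g}-fold {self.direction}"


def fold_compare(
    values: dict[str, float], reference: str
) -> dict[str, FoldComparison]:
    """Fold differences of each value against the reference entry.

    A value twice the reference reports "2-fold higher"; half the
    reference, "2-fold lower" (folds are always >= 1).
    """
    if reference not in values:
        raise CleavemapError(f"reference {reference!r} not among values")
    if any(v <= 0 for v in values.values()):
        raise CleavemapError("fold comparison requires positive values")
    ref = values[reference]
    out = {}
    for label, value in values.items():
        ratio = value / ref
        if ratio == 1.0:
            out[label] = FoldComparison(label, 1.0, "equal")
        elif ratio > 1.0:
            out[label] = FoldComparison(label, ratio, "higher")
        else:
            out[label] = FoldComparison(label, 1.0 / ratio, "lower")
    return out
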