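"""Antioxidant endpoint computation: scavenging %, IC50, FRAP conversion.

Radical-scavenging activity of a DPPH or ABTS assay point is
100 * (1 - A_sample / A_0). IC50 (the concentration removing 50% of the
radicals; lower means stronger antioxidant activity) is estimated either by
linear interpolation between the two measured points bracketing 50%, or by
a four-parameter-logistic (4PL) least-squares fit. Ferric-reducing power
(FRAP) converts an absorbance through a linear Fe(II) calibration line into
mmol Fe2+ per gram dry weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import InvalidArgumentError, InvalidInputError, NotEstimableError

HALF_MAX = 50.0  # percent scavenging defining the IC50


def scavenging_activity(a_sample: float, a_0: float) -> float:
    """Percent radical scavenging, 100 * (1 - A_sample/A_0).

    May exceed [0, 100] for pathological readings (pro-oxidant or
    over-bleached); such values are passed through with a warning so assay
    problems stay visible.
    """
    if a_0 <= 0:
        raise InvalidInputError(f"control absorbance must be positive, got {a_0}")
    if a_sample < 0:
        raise InvalidInputError(f"sample absorbance must be non-negative, got {a_sample}")
    value = 100.0 * (1.0 - a_sample / a_0)
    if not 0.0 <= value <= 100.0:
        warnings.warn(f"scavenging {value:.1f}% outside [0, 100]", stacklevel=2)
    return value


@dataclass
class AssayCurve:
    """Concentration series of one scavenging assay (DPPH or ABTS)."""

    assay: str
    concentrations: np.ndarray   # mg/mL, strictly increasing
    a_sample: np.ndarray
    a_0: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.a_sample = np.asarray(self.a_sample, dtype=float)
        self.a_0 = np.asarray(self.a_0, dtype=float)
        if (np.diff(self.concentrations) <= 0).any():
            raise InvalidInputError("concentrations must be strictly increasing")
        if (self.a_0 <= 0).any():
            raise InvalidInputError("control absorbances must be positive")

    @property
    def scavenging(self) -> np.ndarray:
        """Percent scavenging per point (not clipped)."""
        return 100.0 * (1.0 - self.a_sample / self.a_0)


@dataclass
class Ic50Result:
    ic50: float                  # mg/mL
    method: str                  # "interpolation" | "4PL"
    bracket: tuple[float, float]
    params: dict = field(default_factory=dict)


def _four_pl(c, bottom, top, ic50, slope):
    return bottom + (top - bottom) / (1.0 + (ic50 / c) ** slope)


def estimate_ic50(curve: AssayCurve, method: str = "interpolation") -> Ic50Result:
    """Concentration at 50% scavenging.

    "interpolation" (default) draws a straight line between the two
    measured points bracketing 50% on the concentration axis; "4PL" fits a
    four-parameter logistic by least squares and reports the concentration
    where the fitted curve crosses 50%.
    """
    conc = curve.concentrations
    scav = curve.scavenging

    exact = np.flatnonzero(scav == HALF_MAX)
    if exact.size:
        c = float(conc[exact[0]])
        return Ic50Result(ic50=c, method=method, bracket=(c, c))

    if method == "interpolation":
        crossing = np.flatnonzero((scav[:-1] - HALF_MAX) * (scav[1:] - HALF_MAX) < 0)
        if crossing.size == 0:
            raise NotEstimableError(
                f"50% not bracketed; scavenging spans [{scav.min():.1f}, {scav.max():.1f}]%"
            )
        i = int(crossing[0])
        frac = (HALF_MAX - scav[i]) / (scav[i + 1] - scav[i])
        ic50 = float(conc[i] + frac * (conc[i + 1] - conc[i]))
        return Ic50Result(ic50=ic50, method="interpolation",
                          bracket=(float(conc[i]), float(conc[i + 1])))

    if method in ("4PL", "fourPL"):
        if len(conc) < 4:
            raise InvalidArgumentError("4PL fit needs >= 4 points")
        if not scav.min() < HALF_MAX < scav.max():
            raise NotEstimableError(
                f"50% outside the measured range [{scav.min():.1f}, {scav.max():.1f}]%"
            )
        p0 = [max(scav.min(), 0.0), min(scav.max(), 100.0), float(np.median(conc)), 1.0]
        bounds = ([-20.0, 50.0, conc[0] / 10, 0.1], [50.0, 150.0, conc[-1] * 10, 10.0])
        params, _ = optimize.curve_fit(_four_pl, conc, scav, p0=p0, bounds=bounds, maxfev=10000)
        bottom, top, c50, slope = params
        # concentration where the fitted curve crosses 50%
        if not min(bottom, top) < HALF_MAX < max(bottom, top):
            raise NotEstimableError("fitted curve never reaches 50%")
        ic50 = float(c50 * ((top - HALF_MAX) / (HALF_MAX - bottom)) ** (-1.0 / slope))
        lower = float(conc[conc <= ic50].max()) if (conc <= ic50).any() else float(conc[0])
        upper = float(conc[conc >= ic50].min()) if (conc >= ic50).any() else float(conc[-1])
        return Ic50Result(
            ic50=ic50, method="4PL", bracket=(lower, upper),
            params={"bottom": float(bottom), "top": float(top),
                    "inflection": float(c50), "slope": float(slope)},
        )

    raise InvalidArgumentError(f"unknown method {method!r}")


@dataclass
class CalibrationLine:
    slope: float       # absorbance per mmol/L
    intercept: float   # absorbance
    r_squared: float
    valid_range: tuple[float, float]  # mmol/L


def fit_calibration(concentrations, absorbances) -> CalibrationLine:
    """Ordinary least-squares calibration line absorbance vs concentration."""
    conc = np.asarray(concentrations, dtype=float)
    ab = np.asarray(absorbances, dtype=float)
    if len(conc) < 3:
        raise InvalidArgumentError("calibration needs >= 3 points")
    if len(np.unique(conc)) != len(conc):
        raise InvalidArgumentError("calibration concentrations must be distinct")
    fit = stats.linregress(conc, ab)
    return CalibrationLine(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        valid_range=(float(conc.min()), float(conc.max())),
    )


def frap_value(absorbance: float, line: CalibrationLine,
               sample_mass: float = 1.0, volume: float = 1.0) -> float:
    """Ferric-reducing power in mmol Fe2+ per gram dry weight.

    Inverts the calibration line to a concentration (mmol/L) and scales by
    extract volume (L) over sample mass (g). Warns when the absorbance
    falls outside the calibrated span.
    """
    if line.slope == 0:
        raise InvalidArgumentError("calibration slope must be non-zero")
    if sample_mass <= 0 or volume <= 0:
        raise InvalidArgumentError("sample_mass and volume must be positive")
    lo = line.slope * line.valid_range[0] + line.intercept
    hi = line.slope * line.valid_range[1] + line.intercept
    if not min(lo, hi) <= absorbance <= max(lo, hi):
        warnings.warn(
            f"absorbance {absorbance} outside the calibrated span [{lo:.3f}, {hi:.3f}]",
            stacklevel=2,
        )
    concentration = (absorbance - line.intercept) / line.slope  # mmol/L
    return concentration * volume / sample_mass
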