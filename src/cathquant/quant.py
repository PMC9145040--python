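"""Peak-area ratios, weighted calibration and back-calculation.

The calibration response is the peak-area ratio PAR = analyte area / IS
area.  Curves are straight lines fitted by weighted least squares with
weights 1/x (1/x^2 and unweighted also available), the standard choice for
bioanalytical assays spanning three orders of magnitude, where the response
variance grows with concentration.  R^2 is computed on the weighted
regression (about the weighted mean); the unweighted R^2 is kept alongside
for transparency.

Back-calculated concentrations below the lowest calibrator or above the
highest are censored rather than reported numerically; a sample that still
exceeds the upper limit after dilution is reported as
"> dilution_factor x ULOQ".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

FLAG_BELOW_LOQ = "below_loq"
FLAG_ABOVE_ULOQ = "above_uloq"
FLAG_ABOVE_DILUTED_ULOQ = "above_diluted_uloq"
FLAG_IS_MISSING = "is_missing"

WEIGHTINGS = ("1/x", "1/x2", "none")


class QuantError(ValueError):
    pass


def compute_par(analyte_area: float, is_area: float) -> float:
    """Peak-area ratio of analyte over internal standard."""
    if is_area <= 0:
        raise QuantError("internal-standard area must be positive")
    return analyte_area / is_area


@dataclass(frozen=True)
class CalibrationFit:
    analyte: str
    slope: float
    intercept: float
    r2: float
    r2_unweighted: float
    weighting: str
    loq: float
    uloq: float
    level_back_calc: dict[float, float]
    passed: bool
    r2_min: float = 0.990


def fit_calibration(
    points: list[tuple[float, float]],
    weighting: str = "1/x",
    *,
    analyte: str = "",
    r2_min: float = 0.990,
) -> CalibrationFit:
    """Fit a straight calibration line to (level, PAR) points.

    Requires at least five distinct non-zero levels.  ``passed`` is set when
    the weighted R^2 meets ``r2_min`` and the slope is positive.
    """
    if weighting not in WEIGHTINGS:
        raise QuantError(f"weighting must be one of {WEIGHTINGS}")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if len(set(x)) < 5:
        raise QuantError("need at least 5 distinct calibration levels")
    if np.any(x <= 0):
        raise QuantError("calibration levels must be positive")
    if np.ptp(x) == 0:
        raise QuantError("calibration levels have zero variance")
    if weighting == "1/x":
        w = 1.0 / x
    elif weighting == "1/x2":
        w = 1.0 / x**2
    else:
        w = np.ones_like(x)
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = float(model.params[0]), float(model.params[1])
    r2 = float(model.rsquared)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_unweighted = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    back = {}
    if slope != 0:
        for level in sorted(set(x)):
            pars = y[x == level]
            back[float(level)] = float((pars.mean() - intercept) / slope)
    return CalibrationFit(
        analyte=analyte,
        slope=slope,
        intercept=intercept,
        r2=r2,
        r2_unweighted=r2_unweighted,
        weighting=weighting,
        loq=float(x.min()),
        uloq=float(x.max()),
        level_back_calc=back,
        passed=(r2 >= r2_min and slope > 0),
        r2_min=r2_min,
    )


@dataclass(frozen=True)
class QuantResult:
    """A quantified (possibly censored) concentration for one analyte."""

    sample_id: str
    analyte: str
    par: float | None
    concentration: float
    dilution_factor: float = 1.0
    flags: frozenset[str] = frozenset()
    uloq: float = 1000.0  # curve upper bound, carried for censored reporting

    @property
    def censored(self) -> bool:
        return bool(
            self.flags & {FLAG_BELOW_LOQ, FLAG_ABOVE_ULOQ, FLAG_ABOVE_DILUTED_ULOQ, FLAG_IS_MISSING}
        )

    @property
    def quantifiable(self) -> bool:
        """True when the analyte is present at or above the LOQ (numeric or censored-high)."""
        return not self.censored or bool(
            self.flags & {FLAG_ABOVE_ULOQ, FLAG_ABOVE_DILUTED_ULOQ}
        )


def back_calculate(
    par: float,
    fit: CalibrationFit,
    dilution_factor: float = 1.0,
    *,
    sample_id: str = "",
) -> QuantResult:
    """Back-calculate a concentration from a PAR against a fitted curve.

    The undiluted concentration is ``dilution_factor x (par - intercept) /
    slope``.  Censoring precedence: above the diluted upper limit > above
    the upper limit > below the lower limit; negative estimates clamp to 0.
    """
    if dilution_factor < 1:
        raise QuantError("dilution_factor must be >= 1")
    if fit.slope <= 0:
        raise QuantError("calibration slope must be positive")
    measured = (par - fit.intercept) / fit.slope  # on-instrument concentration
    conc = dilution_factor * measured
    flags: set[str] = set()
    if measured > fit.uloq:
        flags.add(FLAG_ABOVE_DILUTED_ULOQ if dilution_factor > 1 else FLAG_ABOVE_ULOQ)
    elif conc < fit.loq:
        flags.add(FLAG_BELOW_LOQ)
        conc = max(conc, 0.0)
    return QuantResult(
        sample_id=sample_id,
        analyte=fit.analyte,
        par=par,
        concentration=conc,
        dilution_factor=dilution_factor,
        flags=frozenset(flags),
        uloq=fit.uloq,
    )


def missing_is_result(sample_id: str, analyte: str, dilution_factor: float = 1.0) -> QuantResult:
    """Result for an injection whose internal-standard peak is unusable."""
    return QuantResult(
        sample_id=sample_id,
        analyte=analyte,
        par=None,
        concentration=math.nan,
        dilution_factor=dilution_factor,
        flags=frozenset({FLAG_IS_MISSING}),
    )


def format_concentration(value: float) -> str:
    """Report-style rounding: integers from 100 ng/mL up, one decimal below."""
    if value >= 100:
        return str(int(math.floor(value + 0.5)))
    return f"{value:.1f}"


def reported_text(result: QuantResult) -> str:
    """Human-readable reported value, including censoring text."""
    if FLAG_IS_MISSING in result.flags:
        return "IS missing"
    if FLAG_ABOVE_DILUTED_ULOQ in result.flags:
        # the diluted measurement still exceeds the curve ULOQ, e.g. ">5000"
        return f">{format_concentration(result.dilution_factor * result.uloq)}"
    if FLAG_ABOVE_ULOQ in result.flags:
        return f">{format_concentration(result.uloq)}"
    if FLAG_BELOW_LOQ in result.flags:
        return "<LOQ"
    return format_concentration(result.concentration)
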