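"""Absolute quantitation of TCA metabolites from internal-standard
response ratios via calibration curves, with a cross-platform
concordance check (GC-MS vs LC-MS).

Each analyte's response ratio (analyte peak area / isotope-labeled
internal standard area) is regressed on known calibrator concentrations;
sample concentrations are read off the inverted line. Ratioing to the
internal standard cancels global intensity scaling, so the calibration
transfers across injections. Curves are unweighted by default with an
optional 1/x weighting for heteroscedastic responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import CorrelationResult, correlate

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "quantify",
    "platform_concordance",
]

MIN_CALIBRATORS = 5
R2_WARN_THRESHOLD = 0.98
EXTRAPOLATION_FACTOR = 1.5


@dataclass
class CalibrationCurve:
    """Fitted response-ratio vs concentration line for one analyte."""

    analyte: str
    concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    weighting: str = "none"  # "none" | "1/x"

    @property
    def max_response(self) -> float:
        return float(np.max(self.responses))


def fit_calibration(
    points,
    analyte: str = "",
    weighting: str = "none",
) -> CalibrationCurve:
    """Fit a calibration line from (known concentration, response ratio)
    pairs.

    Requires at least 5 calibrators with strictly increasing
    concentrations (the GC-MS assay here uses 12, the LC-MS assay 10).
    Warns when r^2 < 0.98, the usual acceptance threshold for a
    bioanalytical calibration.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (concentration, response) pairs")
    if len(pts) < MIN_CALIBRATORS:
        raise ValueError(
            f"calibration needs >= {MIN_CALIBRATORS} points, got {len(pts)}"
        )
    conc, resp = pts[:, 0], pts[:, 1]
    if np.any(np.diff(conc) <= 0):
        raise ValueError("calibrator concentrations must be strictly increasing")
    if weighting == "none":
        w = np.ones_like(conc)
    elif weighting == "1/x":
        if np.any(conc <= 0):
            raise ValueError("1/x weighting requires positive concentrations")
        w = 1.0 / conc
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    # weighted least squares via statsmodels keeps the r^2 definition standard
    import statsmodels.api as sm

    X = sm.add_constant(conc)
    fit = sm.WLS(resp, X, weights=w).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    r2 = float(fit.rsquared)
    if r2 < R2_WARN_THRESHOLD:
        warnings.warn(
            f"{analyte or 'calibration'}: r^2 = {r2:.4f} below "
            f"{R2_WARN_THRESHOLD}", stacklevel=2,
        )
    return CalibrationCurve(
        analyte=analyte,
        concentrations=conc,
        responses=resp,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        weighting=weighting,
    )


def quantify(curve: CalibrationCurve, response_ratio: float) -> float:
    """Invert the calibration line: concentration = (ratio - b) / m.

    Responses above 1.5x the top calibrator are flagged as extrapolation
    (clinical samples can exceed the calibrated range); negative
    estimates are floored at 0 with a warning.
    """
    if abs(curve.slope) < 1e-12:
        raise ValueError(f"{curve.analyte}: calibration slope is ~0")
    if response_ratio > EXTRAPOLATION_FACTOR * curve.max_response:
        warnings.warn(
            f"{curve.analyte}: response {response_ratio:.4g} beyond "
            f"{EXTRAPOLATION_FACTOR}x the top calibrator; extrapolating",
            stacklevel=2,
        )
    conc = (response_ratio - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"{curve.analyte}: negative concentration estimate "
            f"{conc:.4g}, floored at 0", stacklevel=2,
        )
        return 0.0
    return float(conc)


def platform_concordance(
    gc: pd.DataFrame, lc: pd.DataFrame, analyte: str | None = None
) -> CorrelationResult:
    """Concordance of GC-MS vs LC-MS concentrations on matched samples.

    Both frames need columns sample_id, analyte, concentration; rows are
    matched on (sample_id, analyte), optionally restricted to one
    analyte. Delegates to :func:`tcatrace.enrichment.correlate`.
    """
    if analyte is not None:
        gc = gc[gc["analyte"] == analyte]
        lc = lc[lc["analyte"] == analyte]
    merged = gc.merge(
        lc, on=["sample_id", "analyte"], suffixes=("_gc", "_lc")
    )
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} matched samples; need >= 3 for concordance"
        )
    return correlate(merged["concentration_gc"], merged["concentration_lc"])
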