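"""Microplate symbiont-density assay.

Total bacterial density on a washed plate is measured as OD600 and is the sum
of two components: GFP-expressing food bacteria (*K. pneumoniae*) and
non-fluorescent *Paraburkholderia* symbionts.  A standard curve relating GFP
fluorescence (excitation 485 nm / emission 515 nm) to the food bacterium's own
OD600 lets the food component be predicted from fluorescence and subtracted
from total OD, leaving the symbiont density.  A quadratic term is fitted as a
curvature diagnostic (nonlinearity at high density corrupts the subtraction),
and predicted OD is validated against colony-forming-unit counts by ordinary
least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import CalibrationSet

QUADRATIC_ALPHA = 0.05  # significance level for the curvature diagnostic


@dataclass(frozen=True)
class StandardCurve:
    """Fitted fluorescence -> OD600 line with curvature diagnostics."""

    intercept: float
    slope: float
    r_squared: float
    intercept_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    quadratic_coefficient: float
    quadratic_p_value: float
    fit_fluorescence_range: tuple[float, float]

    @property
    def quadratic_significant(self) -> bool:
        """True when the curvature diagnostic fails (p < 0.05)."""
        return (
            np.isfinite(self.quadratic_p_value)
            and self.quadratic_p_value < QUADRATIC_ALPHA
        )

    def predict(self, fluorescence: float | np.ndarray) -> float | np.ndarray:
        """Predicted food-bacterium OD600 at the given fluorescence."""
        return self.intercept + self.slope * np.asarray(fluorescence, dtype=float)


@dataclass(frozen=True)
class DensityEstimate:
    """Deconvolved symbiont OD600 for one plate measurement."""

    symbiont_od: float
    clamped: bool  # raw difference was negative and clipped to 0
    extrapolated: bool  # fluorescence outside the curve's fitted range


@dataclass(frozen=True)
class CfuValidation:
    """OLS of CFU counts on predicted OD600 (assay validation)."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def _as_xy(calibration) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(calibration, CalibrationSet):
        return calibration.gfp_fluorescence, calibration.od600
    if isinstance(calibration, pd.DataFrame):
        return (
            calibration["gfp_fluorescence"].to_numpy(dtype=float),
            calibration["od600"].to_numpy(dtype=float),
        )
    x, y = calibration
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def fit_standard_curve(calibration) -> StandardCurve:
    """Fit the OD600-on-fluorescence standard curve by OLS.

    Accepts a :class:`~dictypatch.synthetic.CalibrationSet`, a DataFrame with
    ``gfp_fluorescence``/``od600`` columns, or an ``(x, y)`` pair.  Also fits
    the quadratic model and reports the quadratic coefficient with its p-value
    as a curvature diagnostic; with a perfect (zero-residual) fit the p-value
    is undefined and reported as NaN.
    """
    fluor, od = _as_xy(calibration)
    if fluor.size < 3:
        raise ValueError(f"need at least 3 calibration points, got {fluor.size}")
    if np.unique(fluor).size < 2:
        raise ValueError(
            "all fluorescence values identical: standard curve is unidentifiable"
        )
    linear = sm.OLS(od, sm.add_constant(fluor)).fit()
    ci = linear.conf_int(alpha=0.05)

    quad_coef = 0.0
    quad_p = float("nan")
    if np.unique(fluor).size >= 3:
        design = np.column_stack([np.ones_like(fluor), fluor, fluor**2])
        quad = sm.OLS(od, design).fit()
        quad_coef = float(quad.params[2])
        quad_p = float(quad.pvalues[2])

    return StandardCurve(
        intercept=float(linear.params[0]),
        slope=float(linear.params[1]),
        r_squared=float(linear.rsquared),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        quadratic_coefficient=quad_coef,
        quadratic_p_value=quad_p,
        fit_fluorescence_range=(float(fluor.min()), float(fluor.max())),
    )


def estimate_symbiont_density(
    total_od: float, gfp_fluorescence: float, curve: StandardCurve
) -> DensityEstimate:
    """Subtract the predicted food-bacterium OD from the total OD.

    Returns ``max(0, total_od - curve.predict(fluorescence))``; a negative raw
    difference is clamped to 0 and flagged (OD is a physical density).
    Fluorescence outside the curve's fitted range sets the ``extrapolated``
    flag but still yields an estimate.
    """
    if total_od < 0:
        raise ValueError(f"total_od must be >= 0, got {total_od}")
    if gfp_fluorescence < 0:
        raise ValueError(f"gfp_fluorescence must be >= 0, got {gfp_fluorescence}")
    lo, hi = curve.fit_fluorescence_range
    extrapolated = not (lo <= gfp_fluorescence <= hi)
    raw = total_od - float(curve.predict(gfp_fluorescence))
    return DensityEstimate(
        symbiont_od=max(0.0, raw),
        clamped=raw < 0,
        extrapolated=extrapolated,
    )


def estimate_symbiont_density_table(
    plates: pd.DataFrame, curve: StandardCurve
) -> pd.DataFrame:
    """Apply :func:`estimate_symbiont_density` to a plate table.

    ``plates`` needs ``total_od`` and ``gfp_fluorescence`` columns; metadata
    columns pass through.  Adds ``symbiont_od``, ``clamped``, ``extrapolated``.
    """
    out = plates.copy()
    estimates = [
        estimate_symbiont_density(row.total_od, row.gfp_fluorescence, curve)
        for row in plates.itertuples()
    ]
    out["symbiont_od"] = [e.symbiont_od for e in estimates]
    out["clamped"] = [e.clamped for e in estimates]
    out["extrapolated"] = [e.extrapolated for e in estimates]
    return out


def validate_against_cfu(predicted_od, cfu_count) -> CfuValidation:
    """Regress CFU counts on predicted OD600 and report the fit.

    High r-squared indicates the OD-based density assay tracks viable counts.
    """
    od = np.asarray(predicted_od, dtype=float)
    cfu = np.asarray(cfu_count, dtype=float)
    if od.size != cfu.size:
        raise ValueError("predicted_od and cfu_count must have equal length")
    if od.size < 3:
        raise ValueError(f"need at least 3 (OD, CFU) pairs, got {od.size}")
    if np.any(cfu < 0):
        raise ValueError("cfu_count values must be >= 0")
    if np.unique(od).size < 2:
        raise ValueError(
            "all predicted_od values identical: validation regression is unidentifiable"
        )
    fit = sm.OLS(cfu, sm.add_constant(od)).fit()
    return CfuValidation(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        n=int(od.size),
    )
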