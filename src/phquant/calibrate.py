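"""Ratio-vs-pH calibration: fit a monotone logistic and invert it.

The probe's 405/488 excitation ratio is a sigmoidal, strictly monotone
function of pH.  We model it with the standard four-parameter logistic

    R(pH) = R_min + (R_max - R_min) / (1 + 10**(s * (pH_half - pH)))

where ``s`` is a signed Hill-type steepness: positive when the ratio
increases with pH, negative otherwise (the direction is inferred from the
data, never assumed).  The logistic is closed-form invertible, which is what
turns measured ratios from treatment experiments into pH values.

Each experiment/batch gets its own curve: sensor response drifts between
sessions, so a calibration is only valid for the acquisition it came from.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = ["RatiometricCalibration", "fit_calibration", "invert_calibration"]


def _logistic(pH, r_min, r_max, ph_half, s):
    return r_min + (r_max - r_min) / (1.0 + 10.0 ** (s * (ph_half - pH)))


class RatiometricCalibration(BaseEstimator):
    """Four-parameter monotone logistic calibration of ratio vs pH.

    Parameters
    ----------
    per_cell : bool, default True
        Fit on individual (pH, ratio) points.  If False, fit on per-pH mean
        ratios, mimicking calibrations drawn through condition means.

    Attributes (after ``fit``)
    --------------------------
    r_min_, r_max_ : float
        Lower/upper ratio asymptotes (r_max_ > r_min_).
    ph_half_ : float
        Midpoint pH of the response.
    slope_ : float
        Positive steepness; ``direction_`` carries the sign.
    direction_ : int
        +1 if the ratio increases with pH, -1 if it decreases.
    valid_range_ : tuple of float
        (min, max) buffer pH used in the fit; inversion outside it is
        flagged as extrapolation.
    rss_ : float
        Residual sum of squares of the fit.
    n_points_ : int
        Number of points fitted.
    monotone_warning_ : bool
        True when the slope's ~95% confidence interval spans zero, i.e. the
        data do not establish a monotone response.
    """

    def __init__(self, per_cell: bool = True):
        self.per_cell = per_cell

    # -- fitting -----------------------------------------------------------

    def fit(self, pH, ratio):
        pH = np.asarray(pH, dtype=float).ravel()
        ratio = np.asarray(ratio, dtype=float).ravel()
        if pH.shape != ratio.shape:
            raise ValueError("pH and ratio must have the same length")
        ok = np.isfinite(pH) & np.isfinite(ratio)
        pH, ratio = pH[ok], ratio[ok]
        levels = np.unique(pH)
        if levels.size < 4:
            raise ValueError(
                f"calibration needs >= 4 distinct buffer pH levels for 4 free "
                f"parameters; got {levels.size}"
            )

        level_means = np.array([ratio[pH == lv].mean() for lv in levels])
        if not self.per_cell:
            x, y = levels, level_means
        else:
            x, y = pH, ratio

        # deterministic, scale-free initialization
        r_lo, r_hi = np.percentile(ratio, [5, 95])
        if r_hi <= r_lo:
            r_hi = r_lo + max(1e-6, abs(r_lo) * 1e-3)
        direction = 1.0 if np.corrcoef(levels, level_means)[0, 1] >= 0 else -1.0
        mid = 0.5 * (r_lo + r_hi)
        ph_half0 = levels[np.argmin(np.abs(level_means - mid))]
        p0 = [r_lo, r_hi, ph_half0, direction * 1.0]

        popt, pcov = curve_fit(_logistic, x, y, p0=p0, maxfev=20000)
        r_min, r_max, ph_half, s = popt
        if r_max < r_min:  # equivalent reparametrization: swap asymptotes, flip sign
            r_min, r_max, s = r_max, r_min, -s

        self.r_min_ = float(r_min)
        self.r_max_ = float(r_max)
        self.ph_half_ = float(ph_half)
        self.slope_ = float(abs(s))
        self.direction_ = 1 if s >= 0 else -1
        self.valid_range_ = (float(levels.min()), float(levels.max()))
        resid = ratio - self.predict(pH)
        self.rss_ = float(resid @ resid)
        self.n_points_ = int(pH.size)
        s_sd = float(np.sqrt(pcov[3, 3])) if np.all(np.isfinite(pcov)) else np.inf
        self.monotone_warning_ = bool(abs(s) < 1.96 * s_sd)
        return self

    # -- forward and inverse ----------------------------------------------

    def predict(self, pH):
        """Ratio predicted by the fitted curve at the given pH value(s)."""
        check_is_fitted(self, "r_min_")
        pH = np.asarray(pH, dtype=float)
        s = self.direction_ * self.slope_
        return _logistic(pH, self.r_min_, self.r_max_, self.ph_half_, s)

    def inverse_predict(self, ratio):
        """Invert the curve: ratio(s) -> (pH, extrapolated flag).

        Closed form inside the open interval (r_min_, r_max_); ratios at or
        beyond an asymptote, and ratios mapping outside the buffer range
        used in the fit, are clamped to the nearest ``valid_range_`` endpoint
        and flagged as extrapolated.
        """
        check_is_fitted(self, "r_min_")
        ratio = np.asarray(ratio, dtype=float)
        scalar = ratio.ndim == 0
        ratio = np.atleast_1d(ratio)
        if np.any(~np.isfinite(ratio)) or np.any(ratio <= 0):
            raise ValueError("ratios must be finite and positive")

        s = self.direction_ * self.slope_
        lo, hi = self.valid_range_
        # endpoint reached when the ratio runs past the corresponding asymptote
        ph_at_rmin = lo if s > 0 else hi
        ph_at_rmax = hi if s > 0 else lo

        pH = np.empty_like(ratio)
        extrapolated = np.zeros(ratio.shape, dtype=bool)
        inside = (ratio > self.r_min_) & (ratio < self.r_max_)
        f = (ratio[inside] - self.r_min_) / (self.r_max_ - self.r_min_)
        pH[inside] = self.ph_half_ - np.log10(1.0 / f - 1.0) / s
        pH[~inside & (ratio <= self.r_min_)] = ph_at_rmin
        pH[~inside & (ratio >= self.r_max_)] = ph_at_rmax
        extrapolated[~inside] = True

        # 1e-9 grace band so endpoint round-trips do not flag on float rounding
        below, above = pH < lo - 1e-9, pH > hi + 1e-9
        np.clip(pH, lo, hi, out=pH)
        extrapolated |= below | above
        if scalar:
            return float(pH[0]), bool(extrapolated[0])
        return pH, extrapolated

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "r_min_")
        return {
            "model": "logistic4",
            "r_min": self.r_min_,
            "r_max": self.r_max_,
            "ph_half": self.ph_half_,
            "slope": self.slope_,
            "direction": self.direction_,
            "valid_range": list(self.valid_range_),
            "rss": self.rss_,
            "n_points": self.n_points_,
            "monotone_warning": self.monotone_warning_,
            "per_cell": self.per_cell,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RatiometricCalibration":
        obj = cls(per_cell=d.get("per_cell", True))
        obj.r_min_ = float(d["r_min"])
        obj.r_max_ = float(d["r_max"])
        obj.ph_half_ = float(d["ph_half"])
        obj.slope_ = float(d["slope"])
        obj.direction_ = int(d["direction"])
        obj.valid_range_ = tuple(d["valid_range"])
        obj.rss_ = float(d.get("rss", float("nan")))
        obj.n_points_ = int(d.get("n_points", 0))
        obj.monotone_warning_ = bool(d.get("monotone_warning", False))
        return obj

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RatiometricCalibration":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_calibration(
    measurements: pd.DataFrame,
    pH_col: str = "pH_E",
    ratio_col: str = "ratio",
    per_cell: bool = True,
) -> RatiometricCalibration:
    """Fit a calibration curve from a QC-passed measurement table.

    The table must carry the known buffer pH per cell (column ``pH_col``) and
    the measured 405/488 ratio (column ``ratio_col``).
    """
    df = measurements
    if "qc_pass" in df.columns:
        df = df[df["qc_pass"]]
    return RatiometricCalibration(per_cell=per_cell).fit(df[pH_col], df[ratio_col])


def invert_calibration(curve: RatiometricCalibration, ratio):
    """Convert ratio(s) to pH with an extrapolation flag (thin wrapper)."""
    return curve.inverse_predict(ratio)


def calibration_report(
    measurements: pd.DataFrame, pH_col: str = "pH_E", ratio_col: str = "ratio"
) -> pd.DataFrame:
    """Per-pH mean +/- SEM ratio table (the numbers behind a calibration plot)."""
    df = measurements
    if "qc_pass" in df.columns:
        df = df[df["qc_pass"]]
    g = df.groupby(pH_col)[ratio_col]
    out = pd.DataFrame({"mean_ratio": g.mean(), "sem_ratio": g.sem(), "n_cells": g.size()})
    return out.reset_index()
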