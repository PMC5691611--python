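"""Growth-curve analytics for serial-passage evolution experiments.

Exponential growth rates are estimated by ordinary least squares on the
semi-log plot (ln OD600 versus time) restricted to an OD window that
represents exponential phase.  The module also handles the two OD600 scales
that coexist on automated platforms -- microplate-reader readings and
1-cm-path benchtop readings, related by a fixed ratio -- plus green-pixel
calibration curves from plate-imaging screens, and cumulative cell divisions
(CCD), the standard clock for adaptive laboratory evolution experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "PLATE_TO_BENCHTOP",
    "ODSeries",
    "GrowthMetrics",
    "CCDResult",
    "CalibrationCurve",
    "InsufficientDataError",
    "fit_rate",
    "plate_to_benchtop",
    "benchtop_to_plate",
    "pixels_to_od",
    "compute_ccd",
    "read_od_csv",
]

#: Default ratio between a 1-cm-path benchtop OD600 and the plate-reader OD600.
PLATE_TO_BENCHTOP = 4.2


class InsufficientDataError(ValueError):
    """Raised when too few usable readings remain for a regression."""


@dataclass(frozen=True)
class ODSeries:
    """Optical-density readings for one flask or well.

    Parameters
    ----------
    times : array-like of float
        Sampling times in hours, strictly increasing.
    ods : array-like of float
        OD600 readings, non-negative, same length as ``times``.
    unit : {"plate", "benchtop"}
        Which instrument scale the readings are on.
    """

    times: np.ndarray
    ods: np.ndarray
    unit: str = "plate"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.ods, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("times and ods must be 1-D and of equal length")
        if t.size == 0:
            raise ValueError("empty OD series")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("OD readings must be non-negative")
        if self.unit not in ("plate", "benchtop"):
            raise ValueError(f"unknown OD unit {self.unit!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ods", y)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class GrowthMetrics:
    """Summary of one growth curve: rate, lag, final density."""

    rate: float
    rate_se: float
    lag: float
    final_od: float
    window: tuple[float, float]


@dataclass(frozen=True)
class CCDResult:
    """Cumulative cell divisions over a flask series."""

    ccd: float
    per_flask: tuple[float, ...]


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone piecewise-linear map from green-pixel values to OD600."""

    pixel_values: np.ndarray
    od_values: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.pixel_values, dtype=float)
        od = np.asarray(self.od_values, dtype=float)
        if g.ndim != 1 or g.size != od.size:
            raise ValueError("pixel and OD axes must be 1-D and equally long")
        if g.size < 2:
            raise ValueError("calibration curve needs at least 2 knots")
        if not (np.all(np.diff(g) > 0) and np.all(np.diff(od) > 0)):
            raise ValueError("calibration knots must be strictly increasing on both axes")
        object.__setattr__(self, "pixel_values", g)
        object.__setattr__(self, "od_values", od)

    @classmethod
    def from_csv(cls, path) -> "CalibrationCurve":
        """Load a two-column (g, od) calibration CSV."""
        import pandas as pd

        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("calibration CSV needs two columns (g, od)")
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def _median3(y: np.ndarray) -> np.ndarray:
    """3-point running median with edge replication."""
    if y.size < 3:
        return y
    padded = np.concatenate([y[:1], y, y[-1:]])
    stacked = np.stack([padded[:-2], padded[1:-1], padded[2:]])
    return np.median(stacked, axis=0)


def fit_rate(series: ODSeries, od_min: float = 0.01, od_max: float = 0.3) -> GrowthMetrics:
    """Fit the exponential growth rate by semi-log linear regression.

    Readings with ``od_min <= OD <= od_max`` enter an OLS fit of
    ln(OD) on time; the slope is the growth rate in h^-1.  The slope
    standard error is heteroscedasticity-robust (HC3): instrument noise is
    roughly constant on the OD scale, hence strongly heteroscedastic after
    the log transform, and HC3 keeps the error estimate honest in the small
    samples typical of a single batch curve.  Non-positive
    readings inside the window are excluded with a warning.  The lag time is
    the time at which the fitted exponential intersects the first observed
    density, and the final OD is the maximum of a 3-point median-smoothed
    series (robust against single-read spikes).

    Raises
    ------
    InsufficientDataError
        If fewer than 3 usable points fall inside the window.
    """
    t = series.times
    y = series.ods
    in_window = (y >= od_min) & (y <= od_max)
    nonpos = in_window & (y <= 0)
    if np.any(nonpos):
        warnings.warn(
            f"excluding {int(nonpos.sum())} non-positive OD reading(s) from the fit window",
            stacklevel=2,
        )
        in_window &= y > 0
    if int(in_window.sum()) < 3:
        raise InsufficientDataError(
            f"only {int(in_window.sum())} usable points in OD window [{od_min}, {od_max}]"
        )
    tw = t[in_window]
    yw = np.log(y[in_window])
    fit = sm.OLS(yw, sm.add_constant(tw)).fit(cov_type="HC3")
    intercept, rate = (float(p) for p in fit.params)
    rate_se = float(fit.bse[1])
    if not np.isfinite(rate_se):
        rate_se = 0.0

    # Lag: where the fitted exponential crosses the inoculation density.
    first_pos = y[y > 0]
    lag = float("nan")
    if rate > 0 and first_pos.size:
        od0 = float(first_pos[0])
        lag = max(0.0, (np.log(od0) - intercept) / rate)

    final_od = float(np.max(_median3(y)))
    return GrowthMetrics(
        rate=rate,
        rate_se=rate_se,
        lag=lag,
        final_od=final_od,
        window=(float(tw[0]), float(tw[-1])),
    )


def plate_to_benchtop(od_plate: float, ratio: float = PLATE_TO_BENCHTOP) -> float:
    """Convert a plate-reader OD600 to the 1-cm benchtop scale."""
    od = np.asarray(od_plate, dtype=float)
    if np.any(od < 0):
        raise ValueError("OD must be non-negative")
    out = od * ratio
    return float(out) if out.ndim == 0 else out


def benchtop_to_plate(od_benchtop: float, ratio: float = PLATE_TO_BENCHTOP) -> float:
    """Convert a benchtop OD600 to plate-reader units."""
    od = np.asarray(od_benchtop, dtype=float)
    if np.any(od < 0):
        raise ValueError("OD must be non-negative")
    out = od / ratio
    return float(out) if out.ndim == 0 else out


def pixels_to_od(g, curve: CalibrationCurve):
    """Convert green-pixel values to OD600 by monotone linear interpolation.

    Values outside the calibrated range are clamped to the end knots and a
    warning is emitted.
    """
    garr = np.asarray(g, dtype=float)
    lo, hi = curve.pixel_values[0], curve.pixel_values[-1]
    if np.any(garr < lo) or np.any(garr > hi):
        warnings.warn("pixel value outside calibration range; clamping", stacklevel=2)
    out = np.interp(garr, curve.pixel_values, curve.od_values)
    return float(out) if out.ndim == 0 else out


def compute_ccd(
    flask_log: Sequence[tuple[float, float]],
    cells_per_od: float,
    volume_ml: float,
    ratio: float = PLATE_TO_BENCHTOP,
) -> CCDResult:
    """Cumulative cell divisions from per-flask start/end plate ODs.

    Each net new cell corresponds to one division, so per-flask divisions are
    ``(od_end - od_start) * ratio * cells_per_od * volume_ml`` with ODs on the
    plate scale, and the CCD is the running sum across flasks.
    """
    per_flask = []
    for i, (od_start, od_end) in enumerate(flask_log):
        if od_start < 0 or od_end < od_start:
            raise ValueError(f"flask {i}: require 0 <= od_start <= od_end")
        per_flask.append((od_end - od_start) * ratio * cells_per_od * volume_ml)
    return CCDResult(ccd=float(sum(per_flask)), per_flask=tuple(per_flask))


def read_od_csv(path) -> dict[int, tuple[ODSeries, float]]:
    """Read the OD CSV written by the simulator.

    Returns a mapping ``flask_index -> (ODSeries, concentration_pct)``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"flask_index", "time_h", "od_plate", "concentration_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"OD CSV missing columns: {sorted(missing)}")
    out: dict[int, tuple[ODSeries, float]] = {}
    for idx, grp in df.groupby("flask_index"):
        grp = grp.sort_values("time_h")
        series = ODSeries(grp["time_h"].to_numpy(), grp["od_plate"].to_numpy())
        out[int(idx)] = (series, float(grp["concentration_pct"].iloc[0]))
    return out
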