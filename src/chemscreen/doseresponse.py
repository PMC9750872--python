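"""Four-parameter logistic (4PL) dose-response fitting.

Viability is expressed as percent of vehicle (vehicle mean set to 100%) and
fitted with

    y(x) = bottom + (top - bottom) / (1 + (x / ic50)^hill)

on log-concentration, by bounded least squares with multi-start
initialization (bottom in [0, 100], top in [50, 150], hill in (0, 10]).
The IC50 is flagged as extrapolated when it falls outside the tested
concentration range; data admitting no acceptable fit yield a missing IC50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

BOTTOM_BOUNDS = (0.0, 100.0)
TOP_BOUNDS = (50.0, 150.0)
HILL_BOUNDS = (1e-3, 10.0)


def four_param_logistic(x, bottom, top, hill, ic50):
    """Descending 4PL curve: y -> top as x -> 0, y -> bottom as x -> inf."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def percent_viability(readings, vehicle_readings) -> np.ndarray:
    """Readings as percent of the vehicle-control mean (vehicle mean == 100%)."""
    vehicle = np.asarray(vehicle_readings, dtype=float)
    if vehicle.size == 0:
        raise ValueError("vehicle readings are required for normalization")
    return 100.0 * np.asarray(readings, dtype=float) / vehicle.mean()


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4PL parameters for one compound x cell line.

    ``ic50`` is NaN when no admissible fit exists; ``extrapolated`` flags an
    IC50 outside the tested concentration range.
    """

    bottom: float
    top: float
    hill: float
    ic50: float
    rmse: float
    extrapolated: bool
    compound: str = ""
    cell_line: str = ""

    @property
    def ok(self) -> bool:
        return np.isfinite(self.ic50)


def fit_ic50(
    concentrations,
    viability,
    compound: str = "",
    cell_line: str = "",
    max_rmse: float | None = None,
) -> DoseResponseFit:
    """Fit a 4PL curve to percent-viability data.

    Parameters
    ----------
    concentrations, viability
        Paired arrays (replicates as repeated concentrations); at least 4
        distinct positive concentrations are required.
    max_rmse
        Optional admissibility ceiling; a best fit with larger residual RMSE
        is reported with a missing IC50 (non-monotone / unfittable data).
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(viability, dtype=float)
    if x.shape != y.shape:
        raise ValueError("concentrations and viability must be paired")
    if (x <= 0).any():
        raise ValueError("concentrations must be strictly positive")
    distinct = np.unique(x)
    if distinct.size < 4:
        raise ValueError("at least 4 distinct concentrations are required")

    lx = np.log10(x)
    lo, hi = lx.min(), lx.max()

    def resid(theta):
        bottom, top, hill, lic50 = theta
        return four_param_logistic(x, bottom, top, hill, 10.0 ** lic50) - y

    bounds = (
        [BOTTOM_BOUNDS[0], TOP_BOUNDS[0], HILL_BOUNDS[0], lo - 3.0],
        [BOTTOM_BOUNDS[1], TOP_BOUNDS[1], HILL_BOUNDS[1], hi + 3.0],
    )
    b0 = float(np.clip(y.min(), *BOTTOM_BOUNDS))
    t0 = float(np.clip(y.max(), *TOP_BOUNDS))
    best = None
    for lic0 in np.linspace(lo, hi, 5):
        for hill0 in (0.5, 1.0, 2.0):
            theta0 = np.clip([b0, t0, hill0, lic0],
                             bounds[0], bounds[1])
            try:
                sol = least_squares(resid, theta0, bounds=bounds,
                                    xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:  # pragma: no cover - numerical edge
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                               compound, cell_line)
    bottom, top, hill, lic50 = best.x
    ic50 = 10.0 ** lic50
    rmse = float(np.sqrt(2.0 * best.cost / y.size))
    extrapolated = not (distinct.min() <= ic50 <= distinct.max())
    if max_rmse is not None and rmse > max_rmse:
        logger.warning("%s/%s: best 4PL fit RMSE %.2f exceeds %.2f; IC50 withheld",
                       compound, cell_line, rmse, max_rmse)
        ic50 = np.nan
    return DoseResponseFit(float(bottom), float(top), float(hill), ic50,
                           rmse, bool(extrapolated), compound, cell_line)


def fit_plate(plate: pd.DataFrame, max_rmse: float | None = None) -> pd.DataFrame:
    """Fit every (compound, cell_line) group of a long-format plate table.

    Columns: ``cell_line, concentration, replicate, reading, is_vehicle``
    (``compound`` optional). Vehicle wells are used for the 100%
    normalization of their group; returns one row per group with the fitted
    parameters.
    """
    required = {"cell_line", "concentration", "reading", "is_vehicle"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    tab = plate.copy()
    if "compound" not in tab.columns:
        tab["compound"] = ""
    rows = []
    for (compound, line), grp in tab.groupby(["compound", "cell_line"], sort=True):
        vehicle = grp.loc[grp["is_vehicle"].astype(bool), "reading"]
        dosed = grp.loc[~grp["is_vehicle"].astype(bool)]
        pct = percent_viability(dosed["reading"], vehicle)
        fit = fit_ic50(dosed["concentration"].to_numpy(), pct,
                       compound=compound, cell_line=line, max_rmse=max_rmse)
        rows.append(fit.__dict__)
    return pd.DataFrame(rows)
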