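"""Inverse-distance-weighted interpolation with cross-validated power choice.

IDW predicts at s0 a weighted mean of the observations, with weights
d_i^(-p) for haversine distance d_i. It is an exact interpolator (a target
coinciding with an observation returns that observation's value) and every
prediction is a convex combination of the data, hence bounded by the
observed range. The power p is chosen by leave-one-out cross-validation
over a candidate ladder, minimising RMSE; ties go to the smallest power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .geo import haversine, make_grid  # noqa: F401  (make_grid re-exported here)

DEFAULT_POWERS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass
class IDWSurface:
    """A fitted IDW surface: grid coordinates, predictions, the chosen power
    and the LOO-CV table behind the choice.

    ``scale_factor`` is presentation metadata only (map legends sometimes
    rescale trace concentrations for readability); it never enters any
    statistic.
    """

    grid: np.ndarray  # (m, 2) lon/lat
    predictions: np.ndarray  # (m,)
    power: float
    cv_table: pd.DataFrame  # columns: power, rmse
    analyte: str = ""
    scale_factor: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lon": self.grid[:, 0],
                "lat": self.grid[:, 1],
                "value": self.predictions,
                "display_value": self.predictions * self.scale_factor,
            }
        )


def idw_predict(obs_coords, obs_values, target_coords, power: float) -> np.ndarray:
    """IDW predictions at ``target_coords``.

    z(s0) = sum_i z_i d_i^(-p) / sum_i d_i^(-p); a zero distance returns
    that observation's value exactly (first such observation on exact
    duplicates).
    """
    if power <= 0:
        raise ConfigurationError(f"IDW power must be > 0, got {power}")
    obs_coords = np.atleast_2d(np.asarray(obs_coords, dtype=float))
    obs_values = np.asarray(obs_values, dtype=float)
    target_coords = np.atleast_2d(np.asarray(target_coords, dtype=float))
    if obs_coords.shape[0] == 0:
        raise DataError("no observations")
    if obs_coords.shape[0] != obs_values.size:
        raise DataError("obs_coords and obs_values disagree in length")

    # (m, n) distances target x observation
    D = haversine(target_coords[:, None, :], obs_coords[None, :, :])
    out = np.empty(target_coords.shape[0])
    exact = D == 0.0
    has_exact = exact.any(axis=1)
    for i in np.flatnonzero(has_exact):
        out[i] = obs_values[np.argmax(exact[i])]
    rest = ~has_exact
    if rest.any():
        w = D[rest] ** (-power)
        out[rest] = (w @ obs_values) / w.sum(axis=1)
    return out


def loo_cv_power(
    obs_coords,
    obs_values,
    candidate_powers=DEFAULT_POWERS,
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out cross-validated choice of the IDW power.

    For each candidate p, every observation is predicted from the other
    n - 1 and the RMSE recorded; returns ``(best_power, cv_table)`` where
    ties resolve to the smallest candidate.
    """
    obs_coords = np.atleast_2d(np.asarray(obs_coords, dtype=float))
    obs_values = np.asarray(obs_values, dtype=float)
    n = obs_coords.shape[0]
    if n < 3:
        raise DataError("LOO-CV needs at least 3 observations")
    powers = sorted(float(p) for p in candidate_powers)
    if not powers:
        raise ConfigurationError("empty candidate power set")

    D = haversine(obs_coords[:, None, :], obs_coords[None, :, :])
    np.fill_diagonal(D, np.inf)  # exclude self in the held-out prediction
    rows = []
    for p in powers:
        with np.errstate(over="ignore", divide="ignore"):
            w = D ** (-p)
        # duplicated coordinates: d=0 off-diagonal -> inf weight; the held-out
        # prediction then equals that duplicate's value, matching exactness
        dup = np.isinf(w)
        pred = np.empty(n)
        plain = ~dup.any(axis=1)
        if plain.any():
            pred[plain] = (w[plain] @ obs_values) / w[plain].sum(axis=1)
        for i in np.flatnonzero(~plain):
            pred[i] = obs_values[np.argmax(dup[i])]
        rmse = float(np.sqrt(np.mean((pred - obs_values) ** 2)))
        rows.append({"power": p, "rmse": rmse})
    cv = pd.DataFrame(rows)
    best = float(cv.loc[cv["rmse"].idxmin(), "power"])  # idxmin -> first = smallest p on ties
    return best, cv


def fit_surface(
    obs_coords,
    obs_values,
    bbox,
    n_cells_per_axis: int = 50,
    candidate_powers=DEFAULT_POWERS,
    analyte: str = "",
    scale_factor: float = 1.0,
) -> IDWSurface:
    """Cross-validate the power, then predict on a regular grid over bbox."""
    power, cv = loo_cv_power(obs_coords, obs_values, candidate_powers)
    grid = make_grid(bbox, n_cells_per_axis)
    preds = idw_predict(obs_coords, obs_values, grid, power)
    return IDWSurface(grid, preds, power, cv, analyte=analyte, scale_factor=scale_factor)
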