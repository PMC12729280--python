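"""Aeration-temperature surface analysis.

Per reactor: the initial linear phase (default first 100 h) is fitted with
a straight line whose slope serves as the growth rate, and the mean
temperature over the same window is computed. The resulting
(temperature, aeration, slope) triples are fitted with a Monod saturation
term in aeration times a Gaussian temperature term.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    MissingTemperatureError,
    UnidentifiableError,
)
from .fitting import goodness_of_fit
from .models import MonodGaussParams, monod_gauss
from .preprocessing import GrowthSeries


@dataclass(frozen=True)
class ReactorConfig:
    """Static reactor metadata: airflow setting and working volume."""

    reactor_id: str
    airflow_L_min: float
    working_volume_L: float = 4.0

    def __post_init__(self) -> None:
        if self.airflow_L_min <= 0:
            raise InvalidInputError("airflow_L_min must be > 0")
        if self.working_volume_L <= 0:
            raise InvalidInputError("working_volume_L must be > 0")

    @property
    def vvm(self) -> float:
        return to_vvm(self.airflow_L_min, self.working_volume_L)


@dataclass(frozen=True)
class SurfacePoint:
    """One reactor's (aeration vvm, mean temperature, initial slope) triple."""

    reactor_id: str
    B: float
    T_mean: float
    slope: float

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise InvalidInputError("B must be > 0")
        if not math.isfinite(self.slope):
            raise InvalidInputError("slope must be finite")


@dataclass
class SurfaceFit:
    """Fitted surface parameters with goodness-of-fit and diagnostics."""

    params: MonodGaussParams
    r2: float
    rmse: float
    n_points: int
    converged: bool
    stderr: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "params": {
                "mumax": self.params.mumax,
                "KB": self.params.KB,
                "Topt": self.params.Topt,
                "sigma": self.params.sigma,
            },
            "r2": self.r2,
            "rmse": self.rmse,
            "n_points": self.n_points,
            "converged": self.converged,
            "stderr": self.stderr,
        }


def to_vvm(airflow_L_min: float, working_volume_L: float) -> float:
    """Aeration intensity in vessel volumes per minute: airflow / volume."""
    if airflow_L_min <= 0 or working_volume_L <= 0:
        raise InvalidInputError("airflow and working volume must be > 0")
    return airflow_L_min / working_volume_L


def initial_slope(series: GrowthSeries, t_max_h: float = 100.0) -> float:
    """OLS slope (g/(L*h)) of biomass over samples with t <= t_max_h."""
    t = series.time_h
    x = series.biomass_for_fitting
    mask = t <= t_max_h
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 samples in [0, {t_max_h:g}] h, got {int(mask.sum())}"
        )
    slope, _ = np.polyfit(t[mask], x[mask], 1)
    return float(slope)


def mean_temperature(series: GrowthSeries, t_max_h: float = 100.0) -> float:
    """Arithmetic mean of temperature records with t <= t_max_h."""
    if series.temperature_C is None:
        raise MissingTemperatureError("series carries no temperature records")
    mask = (series.time_h <= t_max_h) & np.isfinite(series.temperature_C)
    if not mask.any():
        raise MissingTemperatureError(
            f"no temperature records in [0, {t_max_h:g}] h"
        )
    return float(series.temperature_C[mask].mean())


def surface_points(
    series_list: Sequence[GrowthSeries],
    configs: dict[str, ReactorConfig],
    t_max_h: float = 100.0,
) -> list[SurfacePoint]:
    """Compute per-reactor surface points from series plus reactor configs."""
    points = []
    for series in series_list:
        cfg = configs[series.reactor_id]
        points.append(
            SurfacePoint(
                reactor_id=series.reactor_id,
                B=cfg.vvm,
                T_mean=mean_temperature(series, t_max_h),
                slope=initial_slope(series, t_max_h),
            )
        )
    return points


def fit_surface(
    points: Sequence[SurfacePoint],
    init: dict | None = None,
    bounds: dict | None = None,
    seed: int = 0,
) -> SurfaceFit:
    """Least-squares fit of the Monod x Gauss surface to slope points.

    Requires >= 4 points spanning at least two distinct aeration and two
    distinct temperature values; otherwise the temperature parameters are
    unidentifiable and an error is raised. A warning is emitted when the
    fitted sigma exceeds the observed temperature span (the temperature
    term is then effectively unconstrained by the data).
    """
    if len(points) < 4:
        raise InsufficientDataError("need >= 4 surface points")
    B = np.array([p.B for p in points])
    T = np.array([p.T_mean for p in points])
    y = np.array([p.slope for p in points])
    if len(np.unique(B)) < 2 or len(np.unique(T)) < 2:
        raise UnidentifiableError(
            "surface fit needs >= 2 distinct aeration and temperature values"
        )

    t_span = float(T.max() - T.min())
    full_init = {
        "mumax": max(float(y.max()), 1e-6),
        "KB": float(np.median(B)),
        "Topt": float(T.mean()),
        "sigma": max(t_span / 2.0, 0.5),
    }
    if init:
        full_init.update(init)
    full_bounds = {
        "mumax": (1e-12, 10.0),
        "KB": (1e-9, 10.0),
        "Topt": (15.0, 40.0),
        "sigma": (1e-6, 15.0),
    }
    if bounds:
        full_bounds.update(bounds)

    names = ("mumax", "KB", "Topt", "sigma")
    lo = np.array([full_bounds[k][0] for k in names])
    hi = np.array([full_bounds[k][1] for k in names])
    theta0 = np.clip(np.array([full_init[k] for k in names]), lo, hi)

    def residuals(theta):
        p = MonodGaussParams(*theta)
        return monod_gauss(T, B, p) - y

    sol = least_squares(residuals, theta0, bounds=(lo, hi), method="trf",
                        x_scale="jac")
    params = MonodGaussParams(*map(float, sol.x))
    predicted = monod_gauss(T, B, params)
    r2, rmse = goodness_of_fit(y, predicted)

    # residual-based approximate standard errors from the Jacobian
    stderr = None
    dof = len(y) - 4
    if dof > 0:
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * (2.0 * sol.cost / dof)
            stderr = {k: float(math.sqrt(max(cov[i, i], 0.0)))
                      for i, k in enumerate(names)}
        except np.linalg.LinAlgError:
            stderr = None

    if params.sigma > t_span > 0:
        warnings.warn(
            f"fitted sigma ({params.sigma:.2f} degC) exceeds the observed "
            f"temperature span ({t_span:.2f} degC); the temperature optimum "
            "is weakly identified",
            UserWarning,
            stacklevel=2,
        )

    return SurfaceFit(
        params=params,
        r2=r2,
        rmse=rmse,
        n_points=len(points),
        converged=bool(sol.success),
        stderr=stderr,
    )


def surface_grid(
    params: MonodGaussParams,
    T_values: np.ndarray,
    B_values: np.ndarray,
) -> "np.ndarray":
    """Rate over a T x B lattice (rows: T, cols: B) for plotting/export."""
    TT, BB = np.meshgrid(T_values, B_values, indexing="ij")
    return monod_gauss(TT, BB, params)
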