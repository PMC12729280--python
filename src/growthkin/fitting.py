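"""Nonlinear least-squares estimation of registered growth models.

Fits minimize the sum of squared concentration residuals with
trust-region-reflective bounded least squares. Goodness of fit is reported
as R^2 and RMSE (denominator n). Initial guesses come from data heuristics
so runs are reproducible without hand-tuning; an optional seeded
multi-start explores perturbed starting points and keeps the best SSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
)
from .models import MODEL_REGISTRY, ModelSpec, get_model
from .preprocessing import GrowthSeries


@dataclass
class FitResult:
    """Estimated parameters plus goodness-of-fit and convergence metadata."""

    model_name: str
    params: dict[str, float]
    r2: float
    rmse: float
    residuals: np.ndarray
    n_obs: int
    converged: bool
    init_used: dict[str, float]
    bounds_used: dict[str, tuple[float, float]]
    sse: float = math.nan
    message: str = ""

    @property
    def xmax(self) -> float:
        """Model-reported maximum biomass on a common scale across families."""
        return float(get_model(self.model_name).xmax_of(self.params))

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "params": self.params,
            "r2": self.r2,
            "rmse": self.rmse,
            "xmax": self.xmax if self.converged else math.nan,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "sse": self.sse,
            "init_used": self.init_used,
            "bounds_used": {k: list(v) for k, v in self.bounds_used.items()},
            "message": self.message,
        }


def goodness_of_fit(observed, predicted) -> tuple[float, float]:
    """(R^2, RMSE) for a prediction.

    R^2 = 1 - SS_res/SS_tot with SS_tot about the observed mean; RMSE uses
    denominator n. A zero total sum of squares (constant observations)
    yields R^2 = NaN as a flagged "undefined" value.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    if y.size < 2:
        raise InsufficientDataError("need at least 2 observations")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rmse = math.sqrt(ss_res / y.size)
    if ss_tot == 0.0:
        return (math.nan, rmse)
    return (1.0 - ss_res / ss_tot, rmse)


# ---------------------------------------------------------------------------
# heuristics


def _log_slope(t: np.ndarray, x: np.ndarray) -> float:
    """Two-point log slope over the first third of the series (1/h)."""
    n = max(2, len(t) // 3)
    t0, t1 = t[0], t[n - 1]
    x0, x1 = max(x[0], 1e-9), max(x[n - 1], 1e-9)
    if t1 <= t0 or x1 <= x0:
        return 0.01
    return float(np.log(x1 / x0) / (t1 - t0))


def _max_finite_slope(t: np.ndarray, x: np.ndarray) -> float:
    d = np.diff(x) / np.diff(t)
    return float(max(d.max(), 1e-6))


def _lag_heuristic(t: np.ndarray, x: np.ndarray) -> float:
    """Time at which biomass first exceeds 110% of its initial value."""
    above = np.nonzero(x > 1.1 * max(x[0], 1e-9))[0]
    return float(t[above[0]]) if len(above) else 0.0


def _transition_heuristic(t: np.ndarray, x: np.ndarray) -> float:
    # lazy import: transition_detection also imports nothing from here
    from .transition import detect_transition_arrays

    try:
        est = detect_transition_arrays(t, x, window_end_h=min(92.0, t[-1] / 3))
        if est.t_s is not None:
            return float(est.t_s)
    except Exception:
        pass
    return float(0.5 * t[-1])


def default_initial_guess(spec: ModelSpec, t: np.ndarray, x: np.ndarray) -> dict:
    """Data-driven starting point for each model family."""
    x0 = max(float(x[0]), 1e-6)
    xmax = float(x.max())
    mu = max(_log_slope(t, x), 1e-4)
    slope = _max_finite_slope(t, x)
    lag = _lag_heuristic(t, x)
    if spec.name == "logistic":
        return {"X0": x0, "K": xmax, "mu": mu}
    if spec.name == "logistic_lag":
        return {"X0": x0, "K": xmax, "mu": mu, "t_lag": lag}
    if spec.name == "gompertz":
        return {"Xmax": xmax, "mumax": slope, "lam": lag}
    if spec.name == "baranyi_roberts":
        c = max(float(np.log(max(xmax / x0, 1.0 + 1e-6))), 1e-3)
        return {"mumax": mu, "lam": lag, "C": c, "X0": x0}
    if spec.name == "hybrid_two_phase":
        return _hybrid_guess(t, x, _transition_heuristic(t, x))
    raise ConfigurationError(f"no heuristic for model {spec.name!r}")


def _hybrid_guess(t: np.ndarray, x: np.ndarray, t_s: float) -> dict:
    x0 = max(float(x[0]), 1e-6)
    n_lin = max(2, int(np.sum(t <= t_s)))
    a = max(float(np.polyfit(t[:n_lin], x[:n_lin], 1)[0]), 1e-6)
    x_ts = min(x0 + a * t_s, 0.95 * float(x.max()))
    k = max(float(x.max()), x_ts * 1.1)
    r = max(a / max(0.24 * k, 1e-9), 1e-4)
    return {"X0": x0, "a": a, "t_s": t_s, "K": k, "r": r}


def candidate_inits(spec: ModelSpec, t: np.ndarray, x: np.ndarray) -> list[dict]:
    """Deterministic starting points; several for the change-point model,
    whose SSE surface is multimodal in t_s."""
    base = default_initial_guess(spec, t, x)
    if spec.name != "hybrid_two_phase":
        return [base]
    tmax = float(t[-1])
    starts = [base]
    for frac in (0.25, 0.45, 0.65):
        starts.append(_hybrid_guess(t, x, frac * tmax))
    return starts


def default_bounds(spec: ModelSpec, t: np.ndarray, x: np.ndarray) -> dict:
    """Default box constraints: rates in [0, 10], capacities in
    (0, 10*max(obs)], lag/transition times in [0, max(t)]."""
    xmax = float(x.max())
    tmax = float(t[-1])
    cap = (1e-9, 10.0 * max(xmax, 1e-6))
    rate = (0.0, 10.0)
    lag = (0.0, tmax)
    per_param = {
        "X0": cap,
        "K": cap,
        "Xmax": cap,
        "mu": rate,
        "mumax": rate,
        "r": rate,
        "a": rate,
        "t_lag": lag,
        "lam": lag,
        "t_s": lag,
        "C": (0.0, 20.0),
    }
    return {name: per_param[name] for name in spec.param_names}


def _predict_clamped(spec: ModelSpec, t: np.ndarray, values: dict) -> np.ndarray:
    # solver excursions may push the hybrid stitch value to/above K; clamp K
    # just above the stitch so the curve degrades to a flat plateau instead
    # of raising inside the residual function
    if spec.name == "hybrid_two_phase":
        x_ts = values["X0"] + values["a"] * values["t_s"]
        if x_ts >= values["K"]:
            values = dict(values, K=x_ts * (1.0 + 1e-9) + 1e-12)
    return np.asarray(spec.predict_named(t, values), dtype=float)


# ---------------------------------------------------------------------------
# fitting


def _series_arrays(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, GrowthSeries):
        t = np.asarray(series.time_h, dtype=float)
        x = np.asarray(series.biomass_for_fitting, dtype=float)
    else:
        t, x = series
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
    order = np.argsort(t, kind="stable")
    return t[order], x[order]


def fit_model(
    series,
    model_name: str,
    init: dict | None = None,
    bounds: dict | None = None,
    seed: int = 0,
    n_starts: int = 1,
) -> FitResult:
    """Fit one registered model to a series by bounded least squares.

    ``series`` is a :class:`GrowthSeries` or a ``(t, x)`` pair. Rows are
    sorted by time internally, so fitting is invariant to input order.
    Non-convergence is reported on the result, not raised.
    """
    spec = get_model(model_name)
    t, x = _series_arrays(series)
    p = len(spec.param_names)
    if len(t) < p + 1:
        raise InsufficientDataError(
            f"{model_name} needs >= {p + 1} observations, got {len(t)}"
        )
    if np.ptp(x) == 0.0:
        raise DegenerateDataError(
            f"all biomass values identical ({x[0]:g} g/L); no signal to fit"
        )

    inits = candidate_inits(spec, t, x)
    if init:
        inits = [dict(g, **init) for g in inits]
    full_bounds = default_bounds(spec, t, x)
    if bounds:
        full_bounds.update(bounds)
    lo = np.array([full_bounds[k][0] for k in spec.param_names])
    hi = np.array([full_bounds[k][1] for k in spec.param_names])
    theta0 = np.clip(
        np.array([inits[0][k] for k in spec.param_names]), lo, hi
    )

    def residuals(theta: np.ndarray) -> np.ndarray:
        values = dict(zip(spec.param_names, theta))
        return _predict_clamped(spec, t, values) - x

    starts = [
        np.clip(np.array([g[k] for k in spec.param_names]), lo, hi) for g in inits
    ]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        span = np.where(np.isfinite(hi - lo), hi - lo, 1.0)
        for _ in range(n_starts - 1):
            jitter = theta0 * rng.uniform(0.5, 1.5, size=p)
            jitter += 0.05 * span * rng.standard_normal(p)
            starts.append(np.clip(jitter, lo, hi))

    best = None
    for start in starts:
        try:
            sol = least_squares(
                residuals, start, bounds=(lo, hi), method="trf", x_scale="jac"
            )
        except Exception as exc:  # pragma: no cover - defensive
            sol = None
            fail_msg = str(exc)
        if sol is None:
            candidate = (math.inf, None, fail_msg)
        else:
            sse = float(2.0 * sol.cost)
            candidate = (sse, sol, sol.message)
        if best is None or candidate[0] < best[0] or (
            candidate[0] == best[0]
            and candidate[1] is not None
            and best[1] is not None
            and tuple(candidate[1].x) < tuple(best[1].x)
        ):
            best = candidate

    sse, sol, message = best
    if sol is None:
        return FitResult(
            model_name=model_name,
            params=dict(zip(spec.param_names, theta0)),
            r2=math.nan,
            rmse=math.nan,
            residuals=np.full_like(x, math.nan),
            n_obs=len(x),
            converged=False,
            init_used={k: float(v) for k, v in zip(spec.param_names, theta0)},
            bounds_used=full_bounds,
            message=message,
        )

    params = {k: float(v) for k, v in zip(spec.param_names, sol.x)}
    predicted = _predict_clamped(spec, t, dict(params))
    r2, rmse = goodness_of_fit(x, predicted)
    return FitResult(
        model_name=model_name,
        params=params,
        r2=r2,
        rmse=rmse,
        residuals=predicted - x,
        n_obs=len(x),
        converged=bool(sol.success),
        init_used={k: float(v) for k, v in zip(spec.param_names, theta0)},
        bounds_used=full_bounds,
        sse=sse,
        message=message,
    )


# ---------------------------------------------------------------------------
# multi-model comparison


@dataclass
class ComparisonTable:
    """Per (reactor, model) goodness-of-fit rows with failure flags."""

    rows: list[dict] = field(default_factory=list)
    fits: dict[tuple[str, str], FitResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_wide_frame(self) -> pd.DataFrame:
        """One row per reactor, {model}_r2/{model}_rmse/{model}_xmax columns."""
        df = self.to_frame()
        meta_cols = [c for c in ("aeration_L_min", "aeration_vvm") if c in df.columns]
        wide = df.pivot(index="reactor_id", columns="model_name")
        out = pd.DataFrame(index=wide.index)
        if meta_cols:
            meta = df.groupby("reactor_id")[meta_cols].first()
            out = out.join(meta)
        for model in sorted(df["model_name"].unique()):
            for metric in ("r2", "rmse", "xmax"):
                out[f"{model}_{metric}"] = wide[(metric, model)]
        return out.reset_index()

    def ranked(self, reactor_id: str) -> list[str]:
        """Model names for one reactor, best first (R^2 desc, RMSE asc)."""
        sub = [r for r in self.rows if r["reactor_id"] == reactor_id and r["ok"]]
        sub.sort(key=lambda r: (-(r["r2"] if r["r2"] == r["r2"] else -math.inf), r["rmse"]))
        return [r["model_name"] for r in sub]


def compare_models(
    series_list: Sequence[GrowthSeries],
    model_names: Sequence[str],
    seed: int = 0,
    n_starts: int = 1,
    metadata: dict[str, dict] | None = None,
) -> ComparisonTable:
    """Fit every model to every series and tabulate R^2 / RMSE / Xmax.

    A model failing on one series flags that cell as failed; the table is
    still produced. ``metadata`` maps reactor_id to extra columns (e.g.
    aeration_L_min, aeration_vvm).
    """
    if not len(series_list):
        raise ConfigurationError("no series supplied")
    if not len(model_names):
        raise ConfigurationError("empty model set")
    unknown = [m for m in model_names if m not in MODEL_REGISTRY]
    if unknown:
        raise ConfigurationError(f"unknown models: {unknown}")

    table = ComparisonTable()
    for series in series_list:
        extra = (metadata or {}).get(series.reactor_id, {})
        for model in model_names:
            row = {"reactor_id": series.reactor_id, "model_name": model, **extra}
            try:
                fit = fit_model(series, model, seed=seed, n_starts=n_starts)
                table.fits[(series.reactor_id, model)] = fit
                row.update(
                    r2=fit.r2,
                    rmse=fit.rmse,
                    xmax=fit.xmax,
                    ok=fit.converged,
                    error="" if fit.converged else fit.message,
                )
            except Exception as exc:
                row.update(r2=math.nan, rmse=math.nan, xmax=math.nan, ok=False,
                           error=f"{type(exc).__name__}: {exc}")
            table.rows.append(row)
    return table
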