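"""Forward evaluation of the six growth formulations.

All time-course models map (t hours, params) -> biomass concentration in
g/L; the aeration-temperature model maps (temperature degC, aeration vvm)
-> initial growth rate in g/(L*h). Everything is vectorized over the first
argument and numerically stable for rate*time products up to at least 700.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import DegenerateStitchError, DomainError

_EULER = float(np.e)

#: below this, rate parameters are treated as exactly zero (analytic limits)
_RATE_EPS = 1e-12


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class LogisticParams:
    """X0 initial g/L, K carrying capacity g/L, mu specific rate 1/h."""

    X0: float
    K: float
    mu: float

    def __post_init__(self) -> None:
        if self.X0 <= 0:
            raise DomainError(f"X0 must be > 0, got {self.X0}")
        if self.K <= 0:
            raise DomainError(f"K must be > 0, got {self.K}")


@dataclass(frozen=True)
class LogisticLagParams:
    X0: float
    K: float
    mu: float
    t_lag: float

    def __post_init__(self) -> None:
        LogisticParams(self.X0, self.K, self.mu)
        if self.t_lag < 0:
            raise DomainError(f"t_lag must be >= 0, got {self.t_lag}")


@dataclass(frozen=True)
class GompertzParams:
    """Zwietering modified-Gompertz: Xmax asymptote g/L, mumax maximum
    slope g/(L*h), lam lag duration h."""

    Xmax: float
    mumax: float
    lam: float

    def __post_init__(self) -> None:
        if self.Xmax <= 0:
            raise DomainError(f"Xmax must be > 0, got {self.Xmax}")
        if self.mumax < 0:
            raise DomainError(f"mumax must be >= 0, got {self.mumax}")
        if self.lam < 0:
            raise DomainError(f"lam must be >= 0, got {self.lam}")


@dataclass(frozen=True)
class BaranyiParams:
    """mumax 1/h, lam lag h, C asymptotic ln(X/X0), X0 g/L for
    back-conversion to concentration."""

    mumax: float
    lam: float
    C: float
    X0: float

    def __post_init__(self) -> None:
        if self.mumax < 0:
            raise DomainError(f"mumax must be >= 0, got {self.mumax}")
        if self.lam < 0:
            raise DomainError(f"lam must be >= 0, got {self.lam}")
        if self.C < 0:
            raise DomainError(f"C must be >= 0, got {self.C}")
        if self.X0 <= 0:
            raise DomainError(f"X0 must be > 0, got {self.X0}")


@dataclass(frozen=True)
class HybridParams:
    """Linear phase X0 + a*t stitched to a logistic at t_s.

    The stitch value X(t_s) = X0 + a*t_s must stay strictly below K so
    the logistic branch is well-defined and increasing.
    """

    X0: float
    a: float
    t_s: float
    K: float
    r: float

    def __post_init__(self) -> None:
        if self.X0 <= 0:
            raise DomainError(f"X0 must be > 0, got {self.X0}")
        if self.a < 0:
            raise DomainError(f"a must be >= 0, got {self.a}")
        if self.t_s < 0:
            raise DomainError(f"t_s must be >= 0, got {self.t_s}")
        if self.r < 0:
            raise DomainError(f"r must be >= 0, got {self.r}")
        if self.stitch_value >= self.K:
            raise DegenerateStitchError(
                f"X(t_s) = {self.stitch_value:g} >= K = {self.K:g}"
            )

    @property
    def stitch_value(self) -> float:
        return self.X0 + self.a * self.t_s


@dataclass(frozen=True)
class MonodGaussParams:
    """mumax rate scale g/(L*h), KB half-saturation vvm, Topt degC,
    sigma thermal window width degC."""

    mumax: float
    KB: float
    Topt: float
    sigma: float

    def __post_init__(self) -> None:
        for name in ("mumax", "KB", "sigma"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")


# ---------------------------------------------------------------------------
# forward models


def logistic(t, p: LogisticParams):
    """Closed-form logistic curve K / (1 + ((K-X0)/X0) e^{-mu t})."""
    t = np.asarray(t, dtype=float)
    if abs(p.mu) < _RATE_EPS:
        return np.full_like(t, p.X0)
    ratio = (p.K - p.X0) / p.X0
    with np.errstate(over="ignore"):
        out = p.K / (1.0 + ratio * np.exp(-p.mu * t))
    return out


def logistic_lag(t, p: LogisticLagParams):
    """X0 up to t_lag, then a logistic restarted at t - t_lag."""
    t = np.asarray(t, dtype=float)
    base = LogisticParams(p.X0, p.K, p.mu)
    shifted = logistic(np.maximum(t - p.t_lag, 0.0), base)
    return np.where(t < p.t_lag, p.X0, shifted)


def gompertz(t, p: GompertzParams):
    """Modified Gompertz: Xmax exp(-exp((mumax e / Xmax)(lam - t) + 1))."""
    t = np.asarray(t, dtype=float)
    inner = (p.mumax * _EULER / p.Xmax) * (p.lam - t) + 1.0
    # exp(inner) may overflow for t << lam; the outer exp(-inf) -> 0 is the
    # correct limit, so just silence the overflow.
    with np.errstate(over="ignore"):
        out = p.Xmax * np.exp(-np.exp(inner))
    return out


def _baranyi_A(t: np.ndarray, mumax: float, lam: float) -> np.ndarray:
    # e^{-mt} + e^{-ml} - e^{-m(t+l)} = e^{-mt} + e^{-ml}(1 - e^{-mt});
    # every term lies in (0, 1], so the log never overflows.
    emt = np.exp(-mumax * t)
    eml = np.exp(-mumax * lam)
    return t + np.log(emt + eml * (1.0 - emt)) / mumax


def baranyi_roberts(t, p: BaranyiParams):
    """Baranyi-Roberts curve, returned as concentration X0 * e^{y(t)}."""
    t = np.asarray(t, dtype=float)
    if p.mumax < _RATE_EPS:
        return np.full_like(t, p.X0)
    u = p.mumax * _baranyi_A(t, p.mumax, p.lam)
    # y = u - ln(1 + (e^u - 1)/e^C) = u + C - ln(e^C + e^u - 1); evaluate the
    # log via a shifted log-sum-exp so u up to ~700 stays finite.
    m = np.maximum(u, p.C)
    log_term = m + np.log(np.exp(p.C - m) + np.exp(u - m) - np.exp(-m))
    y = u + p.C - log_term
    return p.X0 * np.exp(y)


def hybrid_two_phase(t, p: HybridParams):
    """Linear ramp to t_s, then a logistic continuous at the stitch."""
    t = np.asarray(t, dtype=float)
    x_ts = p.stitch_value
    linear = p.X0 + p.a * t
    ratio = (p.K - x_ts) / x_ts
    with np.errstate(over="ignore"):
        log_branch = p.K / (1.0 + ratio * np.exp(-p.r * (t - p.t_s)))
    return np.where(t < p.t_s, linear, log_branch)


def monod_gauss(T, B, p: MonodGaussParams):
    """Rate = mumax * B/(KB + B) * exp(-(T - Topt)^2 / (2 sigma^2))."""
    T = np.asarray(T, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise DomainError("aeration B must be >= 0")
    return p.mumax * B / (p.KB + B) * np.exp(-((T - p.Topt) ** 2) / (2.0 * p.sigma**2))


def logistic_ode_rhs(X, p: LogisticParams):
    """dX/dt = mu X (1 - X/K); right-hand side of the logistic ODE."""
    X = np.asarray(X, dtype=float)
    return p.mu * X * (1.0 - X / p.K)


# ---------------------------------------------------------------------------
# registry


@dataclass(frozen=True)
class ModelSpec:
    """Registry entry: parameter names/units, evaluator, and Xmax extractor.

    ``predict`` takes (t, params) where params is an instance of
    ``params_cls``; ``predict_named`` accepts a plain dict instead.
    ``xmax_of`` maps a parameter dict to the model's reported maximum
    biomass (K for logistic/hybrid, Xmax for Gompertz, X0*e^C for
    Baranyi-Roberts).
    """

    name: str
    param_names: tuple[str, ...]
    units: tuple[str, ...]
    params_cls: type
    predict: Callable
    xmax_of: Callable[[dict], float]

    def make_params(self, values: dict):
        return self.params_cls(**{k: values[k] for k in self.param_names})

    def predict_named(self, t, values: dict):
        return self.predict(t, self.make_params(values))


def _xmax_baranyi(v: dict) -> float:
    return v["X0"] * float(np.exp(v["C"]))


MODEL_REGISTRY: dict[str, ModelSpec] = {
    "logistic": ModelSpec(
        "logistic",
        ("X0", "K", "mu"),
        ("g/L", "g/L", "1/h"),
        LogisticParams,
        logistic,
        lambda v: v["K"],
    ),
    "logistic_lag": ModelSpec(
        "logistic_lag",
        ("X0", "K", "mu", "t_lag"),
        ("g/L", "g/L", "1/h", "h"),
        LogisticLagParams,
        logistic_lag,
        lambda v: v["K"],
    ),
    "gompertz": ModelSpec(
        "gompertz",
        ("Xmax", "mumax", "lam"),
        ("g/L", "g/(L*h)", "h"),
        GompertzParams,
        gompertz,
        lambda v: v["Xmax"],
    ),
    "baranyi_roberts": ModelSpec(
        "baranyi_roberts",
        ("mumax", "lam", "C", "X0"),
        ("1/h", "h", "ln(X/X0)", "g/L"),
        BaranyiParams,
        baranyi_roberts,
        _xmax_baranyi,
    ),
    "hybrid_two_phase": ModelSpec(
        "hybrid_two_phase",
        ("X0", "a", "t_s", "K", "r"),
        ("g/L", "g/(L*h)", "h", "g/L", "1/h"),
        HybridParams,
        hybrid_two_phase,
        lambda v: v["K"],
    ),
}

#: canonical surface model name (fit over (T, B), not over time)
SURFACE_MODEL = "monod_gauss"


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None
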