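"""Change-point detection for the linear-to-logistic growth transition.

The early growth phase is fitted with an ordinary least-squares line over
a fixed window, the line is extrapolated across the whole series, and the
transition time t_s is the first post-window sample whose absolute
deviation from the line exceeds the mean plus k standard deviations of the
within-window absolute deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .preprocessing import GrowthSeries


@dataclass
class TransitionEstimate:
    """Detected stitch time with the linear fit and threshold diagnostics.

    ``t_s`` is None when no post-window sample exceeds the threshold.
    """

    t_s: float | None
    linear_intercept: float
    linear_slope: float
    threshold: float
    window_end_h: float
    deviations: np.ndarray
    k_sd: float = 2.0

    @property
    def found(self) -> bool:
        return self.t_s is not None

    def to_dict(self) -> dict:
        return {
            "t_s": self.t_s,
            "found": self.found,
            "linear_intercept": self.linear_intercept,
            "linear_slope": self.linear_slope,
            "threshold": self.threshold,
            "window_end_h": self.window_end_h,
            "k_sd": self.k_sd,
            "deviations": self.deviations.tolist(),
        }


def detect_transition_arrays(
    time_h: np.ndarray,
    biomass_gL: np.ndarray,
    window_end_h: float = 92.0,
    k_sd: float = 2.0,
    persist: int = 1,
) -> TransitionEstimate:
    """Array-level implementation of :func:`detect_transition`.

    ``persist`` requires that many consecutive exceedances before firing
    (default 1: first exceedance wins).
    """
    t = np.asarray(time_h, dtype=float)
    x = np.asarray(biomass_gL, dtype=float)
    in_window = t <= window_end_h
    n_in = int(in_window.sum())
    if n_in < 3:
        raise InsufficientDataError(
            f"need >= 3 samples in [0, {window_end_h:g}] h, got {n_in}"
        )
    if n_in == len(t):
        raise InsufficientDataError("no samples beyond the fit window")

    slope, intercept = np.polyfit(t[in_window], x[in_window], 1)
    predicted = intercept + slope * t
    deviations = np.abs(x - predicted)

    window_dev = deviations[in_window]
    mean, sd = float(window_dev.mean()), float(window_dev.std(ddof=0))
    # sd may be 0 for an exact line; the floor keeps float dust from firing
    threshold = max(mean + k_sd * sd, 1e-9 * float(np.abs(x).max()))

    exceed = (~in_window) & (deviations > threshold)
    t_s: float | None = None
    if persist <= 1:
        idx = np.nonzero(exceed)[0]
        if len(idx):
            t_s = float(t[idx[0]])
    else:
        run = 0
        for i in range(len(t)):
            run = run + 1 if exceed[i] else 0
            if run >= persist:
                t_s = float(t[i - persist + 1])
                break

    return TransitionEstimate(
        t_s=t_s,
        linear_intercept=float(intercept),
        linear_slope=float(slope),
        threshold=float(threshold),
        window_end_h=float(window_end_h),
        deviations=deviations,
        k_sd=float(k_sd),
    )


def detect_transition(
    series: GrowthSeries,
    window_end_h: float = 92.0,
    k_sd: float = 2.0,
    persist: int = 1,
) -> TransitionEstimate:
    """Locate the linear-to-logistic transition time for one series."""
    return detect_transition_arrays(
        series.time_h,
        series.biomass_for_fitting,
        window_end_h=window_end_h,
        k_sd=k_sd,
        persist=persist,
    )
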