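"""End-to-end orchestration: simulate/load -> preprocess -> detect ->
fit -> compare -> surface, with JSON/CSV artifacts and a run log.

All randomness flows from one root seed through per-stage derived seeds,
so a rerun with the same config is byte-identical and each stage can be
reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
import platform
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError
from .fitting import compare_models
from .models import MODEL_REGISTRY
from .preprocessing import (
    CalibrationSpec,
    GrowthSeries,
    apply_volume_correction,
    extract_events,
    load_series,
)
from .simulate import CampaignScenario, generate_campaign
from .surface import ReactorConfig, fit_surface, surface_points
from .transition import detect_transition

logger = logging.getLogger("growthkin")

DEFAULT_MODELS = (
    "logistic",
    "logistic_lag",
    "gompertz",
    "baranyi_roberts",
    "hybrid_two_phase",
)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; see ``from_yaml`` for the file form."""

    reactors: tuple[ReactorConfig, ...]
    input_dir: str | None = None  # None -> simulate a campaign
    models: tuple[str, ...] = DEFAULT_MODELS
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    evaporation_mL_per_h: float = 1.5
    noise_cv: float = 0.02
    duration_h: float = 700.0
    detection_window_h: float = 92.0
    detection_k_sd: float = 2.0
    surface_t_max_h: float = 100.0
    n_starts: int = 1
    out_dir: str = "growthkin_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [m for m in self.models if m not in MODEL_REGISTRY]
        if unknown:
            raise ConfigurationError(f"unknown models in config: {unknown}")
        if not self.models:
            raise ConfigurationError("model list is empty")
        if not self.reactors:
            raise ConfigurationError("no reactors configured")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        reactors = tuple(
            ReactorConfig(
                reactor_id=str(r["reactor_id"]),
                airflow_L_min=float(r["airflow_L_min"]),
                working_volume_L=float(r.get("working_volume_L", 4.0)),
            )
            for r in raw.pop("reactors")
        )
        cal_raw = raw.pop("calibration", {})
        cal = CalibrationSpec(
            k_cal=float(cal_raw.get("k_cal", 0.4)),
            od_linear_range=tuple(cal_raw.get("od_range", (0.3, 0.6))),
        )
        models = tuple(raw.pop("models", DEFAULT_MODELS))
        return cls(reactors=reactors, calibration=cal, models=models, **raw)


def _stage_seed(root_seed: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode())  # stable across processes, unlike hash()
    ss = np.random.SeedSequence([root_seed, tag])
    return int(ss.generate_state(1)[0])


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the report bundle as a dict and
    writes artifacts (comparison CSV, per-fit JSON, surface JSON, run log)
    under ``cfg.out_dir``. Per-reactor stage failures are recorded and the
    pipeline continues."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    failures: list[dict] = []

    # --- acquire series -----------------------------------------------------
    configs = {r.reactor_id: r for r in cfg.reactors}
    if cfg.input_dir is None:
        scenario = CampaignScenario(
            reactors=cfg.reactors,
            duration_h=cfg.duration_h,
            noise_cv=cfg.noise_cv,
            evaporation_mL_per_h=cfg.evaporation_mL_per_h,
            seed=cfg.seed,
        )
        series_list, events_map, truth = generate_campaign(scenario, cfg.calibration)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    else:
        series_list, events_map = [], {}
        for reactor in cfg.reactors:
            path = Path(cfg.input_dir) / f"{reactor.reactor_id}.csv"
            try:
                series_list.append(load_series(path, cfg.calibration))
                events_map[reactor.reactor_id] = extract_events(path)
            except Exception as exc:
                failures.append({"stage": "load", "reactor": reactor.reactor_id,
                                 "error": str(exc)})
        if not series_list:
            raise ConfigurationError(f"no loadable series in {cfg.input_dir}")

    # --- preprocess ---------------------------------------------------------
    corrected: list[GrowthSeries] = []
    for series in series_list:
        reactor = configs[series.reactor_id]
        try:
            corrected.append(
                apply_volume_correction(
                    series,
                    events_map.get(series.reactor_id, []),
                    reactor.working_volume_L,
                    cfg.evaporation_mL_per_h,
                )
            )
        except Exception as exc:
            failures.append({"stage": "preprocess", "reactor": series.reactor_id,
                             "error": str(exc)})
            corrected.append(series)

    # --- transition detection ----------------------------------------------
    transitions = {}
    for series in corrected:
        try:
            est = detect_transition(series, cfg.detection_window_h, cfg.detection_k_sd)
            transitions[series.reactor_id] = est.to_dict()
        except Exception as exc:
            failures.append({"stage": "detect", "reactor": series.reactor_id,
                             "error": str(exc)})
    with open(out / "transitions.json", "w") as fh:
        json.dump(transitions, fh, indent=2)

    # --- model fitting & comparison ----------------------------------------
    metadata = {
        r.reactor_id: {"aeration_L_min": r.airflow_L_min, "aeration_vvm": r.vvm}
        for r in cfg.reactors
    }
    table = compare_models(
        corrected, cfg.models, seed=_stage_seed(cfg.seed, "fit"),
        n_starts=cfg.n_starts, metadata=metadata,
    )
    wide = table.to_wide_frame()
    wide.to_csv(out / "comparison.csv", index=False, float_format="%.6g")
    fits_payload = {
        f"{rid}/{model}": fit.to_dict() for (rid, model), fit in table.fits.items()
    }
    with open(out / "fits.json", "w") as fh:
        json.dump(fits_payload, fh, indent=2)

    # --- surface analysis ---------------------------------------------------
    surface_payload: dict[str, Any] = {}
    try:
        points = surface_points(corrected, configs, cfg.surface_t_max_h)
        sfit = fit_surface(points, seed=_stage_seed(cfg.seed, "surface"))
        surface_payload = {
            "points": [
                {"reactor_id": p.reactor_id, "B": p.B, "T_mean": p.T_mean,
                 "slope": p.slope}
                for p in points
            ],
            "fit": sfit.to_dict(),
        }
    except Exception as exc:
        failures.append({"stage": "surface", "reactor": "*", "error": str(exc)})
    with open(out / "surface.json", "w") as fh:
        json.dump(surface_payload, fh, indent=2)

    # --- run log ------------------------------------------------------------
    run_log = {
        "growthkin_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "models": list(cfg.models),
        "n_series": len(corrected),
        "failures": failures,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)

    return {
        "comparison": wide,
        "table": table,
        "transitions": transitions,
        "surface": surface_payload,
        "failures": failures,
        "out_dir": str(out),
    }
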