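import numpy as np
import pytest

from growthkin.preprocessing import CalibrationSpec, GrowthSeries
from growthkin.surface import ReactorConfig

#: airflow settings (L/min) of the eight-reactor campaign layout
CAMPAIGN_AIRFLOWS = [1.0, 2.0, 3.6, 3.7, 5.5, 7.6, 8.0, 13.0]


@pytest.fixture
def cal() -> CalibrationSpec:
    return CalibrationSpec()


@pytest.fixture
def eight_reactors() -> tuple[ReactorConfig, ...]:
    return tuple(
        ReactorConfig(reactor_id=f"PBR{i + 1}", airflow_L_min=a, working_volume_L=4.0)
        for i, a in enumerate(CAMPAIGN_AIRFLOWS)
    )


def make_series(time_h, biomass_gL, reactor_id="R1", temperature_C=None,
                cal=CalibrationSpec()) -> GrowthSeries:
    """Build a GrowthSeries directly from biomass values (od back-computed)."""
    time_h = np.asarray(time_h, dtype=float)
    biomass = np.asarray(biomass_gL, dtype=float)
    n = np.maximum(1, np.ceil(biomass / (cal.k_cal * cal.od_linear_range[1])))
    od = np.where(biomass > 0, biomass / (cal.k_cal * n), 0.0)
    return GrowthSeries(
        reactor_id=reactor_id,
        time_h=time_h,
        od750=od,
        dilution_factor=n,
        biomass_gL=biomass,
        temperature_C=temperature_C,
    )
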