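import numpy as np
import pytest

from vocscreen.cuvette import ConcentrationSeries, CuvetteConfig, CuvetteRole
from vocscreen.synth import ExperimentSpec, default_cuvettes, generate_experiment


def constant_series(value, t_end=1000.0, n=11, cuvette_id="c01",
                    compound_id="voc1"):
    t = np.linspace(0.0, t_end, n)
    return ConcentrationSeries(cuvette_id, compound_id, t,
                               np.full(n, float(value)))


@pytest.fixture
def plant_config():
    return CuvetteConfig("c01", volume_l=40.0, inlet_flow_lpm=10.0,
                         role=CuvetteRole.PLANT, leaf_area_m2=0.1)


@pytest.fixture(scope="session")
def small_noiseless_experiment():
    """2 plants + 1 background + 1 soil, one light phase, constant rates."""
    spec = ExperimentSpec(
        cuvettes=default_cuvettes(2, 1, 1),
        dwell_s=120.0, lag_s=10.0,
        duration_s=4 * 3600.0, sample_period_s=10.0,
        profile_shape="constant",
        seed=7,
    )
    return generate_experiment(spec)


@pytest.fixture(scope="session")
def platform_day_experiment():
    """Full 24-cuvette layout, 12/12 photoperiod, 6 L/min, 300 s dwell."""
    spec = ExperimentSpec(
        cuvettes=default_cuvettes(18, 3, 3),
        dwell_s=300.0, lag_s=30.0,
        duration_s=86400.0, sample_period_s=60.0,
        profile_shape="diurnal",
        seed=11,
    )
    return generate_experiment(spec)
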