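import numpy as np
import pytest

from reefcast import climatology as cl
from reefcast import downscaling as dn
from reefcast import synthetic_data as sd
from reefcast.co2_effects import build_aragonite_table


@pytest.fixture(scope="session")
def ffs_historic():
    """55-year observation-style record at the mid-archipelago site."""
    params = sd.site_preset(
        "FFS", start_year=1945, n_years=55, trend_per_century=0.6, seed=11
    )
    return sd.gen_historic_sst(params)


@pytest.fixture(scope="session")
def ffs_clim(ffs_historic):
    return cl.monthly_climatology(ffs_historic)


@pytest.fixture(scope="session")
def co2_a1b():
    return sd.gen_co2_pathway(sd.A1B_LIKE_CO2)


@pytest.fixture(scope="session")
def aragonite_table():
    return build_aragonite_table()


@pytest.fixture(scope="session")
def warming_ensemble_inputs(ffs_historic):
    """Multi-model trend + anomaly distributions for a warming century.

    Three synthetic model runs with distinct injected biases and seasonal
    amplitude defects, bias-corrected and averaged, emulate a screened
    multi-model ensemble warming ~2.5 °C over 2000–2099.
    """
    models_20c, models_scen = [], []
    for i, (bias, amp) in enumerate([(1.5, 1.3), (-0.8, 0.8), (0.4, 1.1)]):
        p20 = sd.site_preset(
            "FFS", start_year=1900, n_years=100, trend_per_century=0.5,
            bias=bias, seasonal_amp_factor=amp, seed=100 + i,
        )
        ps = sd.site_preset(
            "FFS", start_year=2000, n_years=100, trend_per_century=2.5,
            bias=bias, seasonal_amp_factor=amp, seed=200 + i,
        )
        models_20c.append(sd.gen_model_sst(p20))
        models_scen.append(sd.gen_model_sst(ps))
    bias_corrected = [
        scen.with_sst(scen.sst - dn.fit_transform(m20, ffs_historic).bias)
        for m20, scen in zip(models_20c, models_scen)
    ]
    trend = dn.multi_model_trend(bias_corrected)
    dist = dn.monthly_anomaly_distributions(ffs_historic)
    return {
        "models_20c": models_20c,
        "models_scen": models_scen,
        "trend": trend,
        "distributions": dist,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
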