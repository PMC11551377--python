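import pytest

import sedgeflux as sf


@pytest.fixture
def noiseless_obs():
    """16 exact points on E(T) = 2 * 8**((T-30)/10), T in [20, 35]."""
    cfg = sf.ChamberSimConfig(true_q10=8.0, e_ref=2.0, t_min=20.0, t_max=35.0,
                              n_points=16, noise_cv=0.0, seed=0)
    return sf.gen_chamber_series(cfg)


@pytest.fixture
def met_with_heatwave():
    """10 baseline + 5 heat-wave days (boost 8 K), 30-min step, acclimated."""
    met = sf.gen_met_series(sf.MetSimConfig(seed=0))
    return sf.rolling_acclimation(met)


@pytest.fixture
def sedge():
    return sf.SpeciesParams("sedge", emission_factor=2.0, lai=1.5,
                            response="exponential", q10=7.2)


@pytest.fixture
def tree():
    return sf.SpeciesParams("tree", emission_factor=2.0, lai=1.5,
                            response="exponential", q10=3.7)
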