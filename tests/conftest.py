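import pytest
from hypothesis import settings

from cardiopbpk import default_config, build_model, run

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def default_params(default_cfg):
    return build_model(default_cfg)


@pytest.fixture(scope="session")
def reference_sim(default_cfg, default_params):
    """The reference scenario: 22 mg oral dose, 0-48 h on a 0.01 h grid."""
    return run(default_params, default_cfg.dose_mg,
               t_end=default_cfg.run.t_end, dt=default_cfg.run.dt,
               rtol=default_cfg.run.rtol, atol=default_cfg.run.atol)
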