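import pytest

from gazedyn import bias_report, synthdata


@pytest.fixture(scope="session")
def small_session():
    """A modest synthetic session shared across read-only tests."""
    cfg = synthdata.GeneratorConfig(n_trials=300, seed=7)
    return synthdata.generate_session(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_session):
    s = small_session
    return bias_report.run_pipeline(s.pose, s.eye, s.events,
                                    s.config.monitor_xy)
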