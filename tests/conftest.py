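import pytest

from saltpolicy import baseline_config


@pytest.fixture()
def cfg():
    return baseline_config()


@pytest.fixture()
def epi(cfg):
    return cfg.epidemiology


@pytest.fixture()
def rr(cfg):
    return cfg.relative_risks
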