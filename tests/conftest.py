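import math

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def bargh_summary():
    """The reported statistics of the original walking-speed experiment."""
    from bayes_audit import Direction, StudySummary

    return StudySummary(
        t_value=2.0,
        df=28,
        n1=15,
        n2=15,
        p_value=0.05,
        effect_d=0.75,
        direction=Direction.PREDICTED_POSITIVE,
        label="original elderly-priming study",
    )


@pytest.fixture
def jzs_spec():
    from bayes_audit import BfMethodSpec

    return BfMethodSpec()


@pytest.fixture
def case_config():
    from bayes_audit import load_config, packaged_config_path

    return load_config(packaged_config_path("bargh1996"))
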