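import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_deployment():
    """A 30-minute default-noise synthetic deployment with ground truth."""
    import turtlehr as t

    record, truth = t.generate_deployment(
        t.BehaviorModel(duration_min=30, resting_dwell_min=6, moving_dwell_min=4),
        seed=123,
    )
    return record, truth
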