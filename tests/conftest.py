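import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fake_clock():
    from rwdsandbox._clock import FakeClock

    return FakeClock()


@pytest.fixture
def deployment(tmp_path, fake_clock):
    """A full single-processor platform with one enrolled user."""
    from rwdsandbox.harness import build_deployment

    dep = build_deployment(str(tmp_path / "dep"), clock=fake_clock,
                           n_processors=1, max_parallel=2, n_rows=50, seed=7)
    yield dep
    dep.shutdown()


@pytest.fixture
def client(deployment):
    from rwdsandbox.harness import ReferenceClient

    return ReferenceClient(deployment, "alice", "wonderland")
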