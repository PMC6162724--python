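import pytest
from hypothesis import HealthCheck, settings

from nfsearch.neuro_signal import BlockProtocol, VirtualSubject
from nfsearch.task_domains import generate_grid, generate_puzzle_instances

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    """Default NF block: 30 s rest, 30 s NF, 20 s count; 10 Hz."""
    return BlockProtocol()


@pytest.fixture(scope="session")
def null_subject():
    """Trait asymmetry only — no volitional NF response."""
    return VirtualSubject(trait_asymmetry=0.5, responder=False, noise_sd=1.0, seed=0)


@pytest.fixture(scope="session")
def responder_subject():
    return VirtualSubject(
        trait_asymmetry=0.5, state_gain=1.0, responder=True,
        fatigue_decay=0.9, noise_sd=1.0, seed=0,
    )


@pytest.fixture(scope="session")
def quiet_responder():
    """Noise-free responder: closed-form signal checks."""
    return VirtualSubject(
        trait_asymmetry=0.4, state_gain=1.0, responder=True,
        fatigue_decay=0.8, noise_sd=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def easy_instances():
    return generate_puzzle_instances(12, difficulty=12, seed=7)


@pytest.fixture(scope="session")
def medium_instance():
    [inst] = generate_puzzle_instances(1, difficulty=24, seed=42)
    return inst


@pytest.fixture(scope="session")
def small_grids():
    return [
        generate_grid(12, 12, 0.25, seed=s, connectivity=con)
        for s, con in [(1, 4), (2, 4), (3, 8), (4, 4), (5, 8)]
    ]
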