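import pytest
from hypothesis import HealthCheck, settings

from scatreims import SimulationConfig, matrix_from_simulation

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def five_class_matrix():
    """Study-condition dataset: 5 classes, 20 individuals each, 3 pellets,
    default peak profile (40 shared + 20 class-affected peaks, effect x4)."""
    cfg = SimulationConfig(
        classes=["BV", "FV", "HM", "WM", "R"],
        seed=42,
        n_individuals_per_class=20,
        pellets_per_individual=3,
    )
    return matrix_from_simulation(cfg)


@pytest.fixture(scope="session")
def small_two_class_matrix():
    """Compact strongly separable dataset for fast classifier tests."""
    cfg = SimulationConfig(
        classes=["A", "B"],
        seed=9,
        n_individuals_per_class=10,
        pellets_per_individual=2,
    )
    return matrix_from_simulation(cfg)
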