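import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from mamut.simulate import SimConfig, default_class_rates, simulate_ma_experiment


@pytest.fixture(scope="session")
def small_truth():
    """A small but non-trivial experiment: ~200 expected mutations."""
    config = SimConfig(
        genome_length=200_000,
        gc_content=0.25,
        n_lines=6,
        transfers_per_line=156,
        divisions_per_cycle=5.1,
        class_rates=default_class_rates(total_rate=2.5e-7),
        callable_fraction=0.8,
        rng_seed=42,
    )
    return simulate_ma_experiment(config)


@pytest.fixture(scope="session")
def written_truth(small_truth, tmp_path_factory):
    from mamut.simulate import write_truth_set

    out = tmp_path_factory.mktemp("truth")
    paths = write_truth_set(small_truth, out)
    return out, paths
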