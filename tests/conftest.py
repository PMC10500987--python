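import pytest

from evbkit import LambdaSchedule, SamplerConfig
from evbkit.toy import default_model, run_fep_schedule


@pytest.fixture(scope="session")
def toy_model():
    return default_model()


@pytest.fixture(scope="session")
def schedule51():
    return LambdaSchedule.uniform(51)


@pytest.fixture(scope="session")
def replica_windows(toy_model, schedule51):
    """Five independent replicas of the default 51-window FEP run,
    100k Metropolis steps per window, at 300 K."""
    return [
        run_fep_schedule(toy_model, schedule51, 0.0,
                         SamplerConfig(n_steps=100_000, seed=seed,
                                       temperature=300.0))
        for seed in range(1, 6)
    ]


@pytest.fixture(scope="session")
def windows_one_replica(replica_windows):
    return replica_windows[0]
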