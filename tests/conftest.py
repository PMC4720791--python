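import numpy as np
import pytest

import brainswitch as bs


def small_config(task_kind: str = "ballistic", seed: int = 11,
                 **overrides) -> bs.SimulationConfig:
    """Desk-scale session: 200 Hz, 3 runs x 6 trials, shortened idle phase."""
    defaults = dict(
        sampling_rate=200.0,
        n_runs=3,
        trials_per_run=6,
        task_kind=task_kind,
        phase_durations=bs.PhaseDurations(idle=4.0, focus=2.0,
                                          preparation=3.0, task=4.0),
        seed=seed,
    )
    defaults.update(overrides)
    return bs.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_session() -> bs.Recording:
    return bs.generate_session(small_config())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
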