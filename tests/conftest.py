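import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid():
    from visuomotor.synth import DelayGrid

    return DelayGrid(iti_min=1.0, iti_max=1.1, quiescence_min=0.5, quiescence_max=0.6)


@pytest.fixture(scope="session")
def hand_session(small_grid):
    """Two-trial session built by hand for exact enumeration checks.

    Wheel: rectangular ccw velocity pulses (-500 units/s) at [2.0, 2.2) s
    (displacement -100, a reward) and [4.05, 4.15) s (displacement -50).
    Trial 1: iti=1.0, q=0.5 from t0=0 -> V=1.5, M=2.0, RT=0.5.
    Trial 2: iti=1.0, q=0.5 from t0=2.5 -> V=4.0, M=4.05, RT=0.05 (masked).
    """
    from visuomotor.synth.session import SessionRecord, TrialRecord
    from visuomotor.wheel import WheelTrace

    dt = 0.001
    velocity = np.zeros(6000)
    velocity[2000:2200] = -500.0
    velocity[4050:4150] = -500.0
    wheel = WheelTrace.from_velocity(velocity, dt=dt)
    trials = [
        TrialRecord(0, 0.0, 1.0, 0.5, 1.5, 2.0, "reward"),
        TrialRecord(1, 2.5, 1.0, 0.5, 4.0, 4.05, "none"),
    ]
    return SessionRecord(
        trials=trials,
        wheel=wheel,
        delay_grid=small_grid,
        movement_threshold=10.0,
    )


@pytest.fixture(scope="session")
def null_session():
    from visuomotor.synth import BehaviorRegime, DelayGrid, simulate_session

    return simulate_session(
        BehaviorRegime(mode="null"), DelayGrid(), n_trials=40, seed=101
    )


@pytest.fixture(scope="session")
def associated_session():
    from visuomotor.synth import BehaviorRegime, DelayGrid, simulate_session

    return simulate_session(
        BehaviorRegime(mode="associated"), DelayGrid(), n_trials=40, seed=202
    )
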