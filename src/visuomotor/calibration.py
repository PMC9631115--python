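"""Type-I-error calibration sweeps for the two randomization tests.

Both procedures here measure empirical false-positive rates under their
respective null hypotheses, at the significance thresholds used in
practice (p < 0.05 for the reaction-time test, p < 0.01 for the unit
responsiveness test).  With the add-one correction in both tests, the
expected rejection rate is bounded by the nominal level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .behavior import test_association
from .ephys import shuffle_responsiveness
from .synth.session import BehaviorRegime, DelayGrid, simulate_session

__all__ = [
    "CalibrationResult",
    "null_session_false_positive_rate",
    "shuffle_false_positive_rate",
]


@dataclass
class CalibrationResult:
    n_tested: int
    n_flagged: int
    alpha: float

    @property
    def rate(self) -> float:
        return self.n_flagged / self.n_tested

    @property
    def binomial_upper_edge(self) -> float:
        """Upper edge of the normal-approximation 95% interval at nominal alpha."""
        return self.alpha + 1.96 * np.sqrt(self.alpha * (1 - self.alpha) / self.n_tested)


def null_session_false_positive_rate(
    n_sessions: int = 500,
    n_trials: int = 60,
    n_resamples: int = 2000,
    alpha: float = 0.05,
    rt_floor: float = 0.1,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    regime: Optional[BehaviorRegime] = None,
    grid: Optional[DelayGrid] = None,
) -> CalibrationResult:
    """Rejection rate of the conditional-randomization test on null sessions.

    Sessions are simulated with wheel movements statistically independent of
    stimulus onsets (Poisson bout process) on the full task delay grid; each
    session's p-value uses the enumeration-backed conditional null.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    regime = regime or BehaviorRegime(mode="null")
    grid = grid or DelayGrid()
    n_flagged = n_valid = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_sessions):
            session = simulate_session(regime, grid, n_trials=n_trials, rng=rng)
            result = test_association(
                session, n_resamples=n_resamples, rng=rng, alpha=alpha, rt_floor=rt_floor
            )
            if result.p_value is None:
                continue
            n_valid += 1
            if result.p_value < alpha:
                n_flagged += 1
    return CalibrationResult(n_tested=n_valid, n_flagged=n_flagged, alpha=alpha)


def shuffle_false_positive_rate(
    n_units: int = 2000,
    n_trials: int = 50,
    rate_hz: float = 5.0,
    window_s: float = 0.2,
    n_shuffles: int = 1000,
    alpha: float = 0.01,
    seed=None,
    rng: Optional[np.random.Generator] = None,
) -> CalibrationResult:
    """Flag rate of the within-trial shuffle test on stationary Poisson units.

    Each simulated unit fires at the same expected rate in the baseline
    window (-500:-300 ms) and the response window (0:200 ms); spike counts
    per 200 ms window are Poisson draws converted to rates.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    n_flagged = 0
    mean_count = rate_hz * window_s
    for _ in range(n_units):
        baseline = rng.poisson(mean_count, n_trials) / window_s
        response = rng.poisson(mean_count, n_trials) / window_s
        result = shuffle_responsiveness(
            baseline, response, n_shuffles=n_shuffles, alpha=alpha, rng=rng
        )
        if result.significant:
            n_flagged += 1
    return CalibrationResult(n_tested=n_units, n_flagged=n_flagged, alpha=alpha)
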