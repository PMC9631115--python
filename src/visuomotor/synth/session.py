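"""Simulated wheel-task sessions with replayable trial logic.

The simulated task mirrors the head-fixed steering-wheel operant design: a
grating appears on the right screen after a random inter-trial interval
(ITI) plus an enforced quiescence period whose timer restarts with any wheel
movement.  Once the stimulus is on, it is positionally yoked to the wheel;
a counterclockwise displacement past the reward threshold ends the trial
with a reward, a clockwise displacement past the punish threshold with a
white-noise punishment.

Wheel behavior comes in two regimes:

* ``null`` — movement bouts form a Poisson process independent of the
  stimuli (the chance behavior of an untrained animal that has learned to
  turn the wheel but not the association).
* ``associated`` — in addition to the background process, each stimulus is
  answered with probability ``response_probability`` by a bout at a latency
  drawn from a shifted log-normal whose mode defaults to 150 ms, matching
  the 100-200 ms stimulus-locked turns of a trained animal.

Sessions are generated so that the recorded stimulus onsets are *exactly*
reproducible by replaying each trial's delay parameters against the final
wheel trace — the property the conditional-randomization test depends on.
The generator renders the background bout process into the 1 kHz wheel
trace up front and then walks the trials against the *rendered* trace,
splicing each stimulus-triggered response bout into the trace as it is
produced; every recorded quantity is therefore computed from the very
trace the record ships with.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..wheel import MovementIntervals, WheelTrace

__all__ = [
    "DelayGrid",
    "ShiftedLogNormal",
    "BehaviorRegime",
    "TrialRecord",
    "SessionRecord",
    "simulate_wheel",
    "simulate_session",
]

#: Counterclockwise (rewarded) wheel displacement is negative by convention.
CCW_SIGN = -1.0


@dataclass(frozen=True)
class DelayGrid:
    """Discrete grid of per-trial delay parameters.

    ITIs and quiescence periods are drawn uniformly from ``[min, max]`` in
    steps of ``increment`` (100 ms in the task program).
    """

    iti_min: float = 4.0
    iti_max: float = 7.0
    quiescence_min: float = 0.5
    quiescence_max: float = 2.0
    increment: float = 0.1

    def __post_init__(self) -> None:
        if self.increment <= 0:
            raise ValueError("increment must be positive")
        for lo, hi, name in (
            (self.iti_min, self.iti_max, "iti"),
            (self.quiescence_min, self.quiescence_max, "quiescence"),
        ):
            if lo > hi:
                raise ValueError(f"{name}_min must not exceed {name}_max")
            steps = (hi - lo) / self.increment
            if abs(steps - round(steps)) > 1e-6:
                raise ValueError(f"{name} range must be an integer multiple of the increment")

    @property
    def iti_values(self) -> np.ndarray:
        n = round((self.iti_max - self.iti_min) / self.increment) + 1
        return np.round(self.iti_min + self.increment * np.arange(n), 9)

    @property
    def quiescence_values(self) -> np.ndarray:
        n = round((self.quiescence_max - self.quiescence_min) / self.increment) + 1
        return np.round(self.quiescence_min + self.increment * np.arange(n), 9)

    @property
    def n_combinations(self) -> int:
        return self.iti_values.size * self.quiescence_values.size

    def sample(self, rng: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
        itis = rng.choice(self.iti_values, size=size)
        quiescences = rng.choice(self.quiescence_values, size=size)
        return itis, quiescences

    def contains(self, iti: float, quiescence: float) -> bool:
        def on(v, lo, hi):
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                return False
            steps = (v - lo) / self.increment
            return abs(steps - round(steps)) < 1e-6

        return on(iti, self.iti_min, self.iti_max) and on(
            quiescence, self.quiescence_min, self.quiescence_max
        )


@dataclass(frozen=True)
class ShiftedLogNormal:
    """Reaction-latency distribution: ``shift + LogNormal(mu, sigma)``.

    Positive support with a controllable mode; the default mode of 150 ms
    places the bulk of latencies in the 100-200 ms band.
    """

    shift: float = 0.05
    sigma: float = 0.35
    mode: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.shift <= 2.0:
            raise ValueError("latency location must lie in [0, 2] s")
        if self.mode <= self.shift:
            raise ValueError("mode must exceed the shift")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def mu(self) -> float:
        # mode of LogNormal(mu, sigma) is exp(mu - sigma^2)
        return math.log(self.mode - self.shift) + self.sigma**2

    def draw(self, rng: np.random.Generator, size=None):
        return self.shift + rng.lognormal(self.mu, self.sigma, size=size)


@dataclass
class BehaviorRegime:
    """Generator knobs for the simulated wheel behavior."""

    mode: str = "null"
    bout_rate: float = 0.25
    bout_duration: float = 0.3
    latency: ShiftedLogNormal = field(default_factory=ShiftedLogNormal)
    response_probability: float = 0.9
    bout_amplitude: float = 120.0
    p_ccw: float = 0.85

    def __post_init__(self) -> None:
        if self.mode not in ("null", "associated"):
            raise ValueError("mode must be 'null' or 'associated'")
        if self.bout_rate < 0:
            raise ValueError("bout_rate must be non-negative")
        if self.bout_duration <= 0:
            raise ValueError("bout_duration must be positive")
        if not 0.0 <= self.response_probability <= 1.0:
            raise ValueError("response_probability must lie in [0, 1]")
        if self.bout_amplitude <= 0:
            raise ValueError("bout_amplitude must be positive")


@dataclass
class TrialRecord:
    """One trial: delay parameters, stimulus onset, first movement, outcome."""

    index: int
    prev_outcome_time: float
    iti: float
    quiescence: float
    stim_onset: float
    first_move: float  # nan if no movement followed the stimulus
    outcome: str  # 'reward' | 'punish' | 'none'

    @property
    def reaction_time(self) -> float:
        return self.first_move - self.stim_onset


@dataclass
class SessionRecord:
    """A full session: trial table plus the wheel trace it was played on."""

    trials: list[TrialRecord]
    wheel: WheelTrace
    delay_grid: DelayGrid
    movement_threshold: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        onsets = np.array([t.stim_onset for t in self.trials])
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("stimulus onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def intervals(self) -> MovementIntervals:
        return MovementIntervals.from_trace(self.wheel, self.movement_threshold)

    def trials_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "prev_outcome_time": [t.prev_outcome_time for t in self.trials],
                "iti": [t.iti for t in self.trials],
                "quiescence": [t.quiescence for t in self.trials],
                "stim_onset": [t.stim_onset for t in self.trials],
                "first_move": [t.first_move for t in self.trials],
                "outcome": [t.outcome for t in self.trials],
            }
        )

    def verify_replay(self, atol: float = 1e-9) -> None:
        """Check that replaying each trial's delays reproduces its onset.

        Raises ``ValueError`` on the first inconsistent trial; a session that
        passes is a valid input to the conditional-randomization test.
        """
        intervals = self.intervals()
        for t in self.trials:
            v = intervals.earliest_quiet(t.prev_outcome_time + t.iti, t.quiescence)
            if abs(v - t.stim_onset) > atol:
                raise ValueError(
                    f"trial {t.index}: replayed onset {v:.6f} != recorded {t.stim_onset:.6f}"
                )
            m = intervals.first_move_after(t.stim_onset)
            recorded = t.first_move
            if np.isnan(recorded):
                if np.isfinite(m) and m < self.wheel.end_time:
                    raise ValueError(f"trial {t.index}: movement {m:.3f} missing from record")
            elif abs(m - recorded) > atol:
                raise ValueError(
                    f"trial {t.index}: replayed first move {m:.6f} != recorded {recorded:.6f}"
                )


# ---------------------------------------------------------------------------
# bout bookkeeping


def _render_velocity(
    starts: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    n_samples: int,
    dt: float,
) -> np.ndarray:
    """Superpose half-sine velocity profiles; each bout displaces by its amplitude."""
    velocity = np.zeros(n_samples)
    t = np.arange(n_samples) * dt
    for s, d, a in zip(starts, durations, amplitudes):
        i0 = max(int(np.ceil(s / dt)), 0)
        i1 = min(int(np.floor((s + d) / dt)) + 1, n_samples)
        if i1 <= i0:
            continue
        tau = t[i0:i1] - s
        velocity[i0:i1] += a * (np.pi / (2 * d)) * np.sin(np.pi * tau / d)
    return velocity


def _draw_background_bouts(
    regime: BehaviorRegime, duration: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Poisson background bouts: (starts, durations, signed amplitudes)."""
    n = rng.poisson(regime.bout_rate * duration)
    starts = np.sort(rng.uniform(0.0, duration, size=n))
    signs = np.where(rng.random(n) < regime.p_ccw, CCW_SIGN, -CCW_SIGN)
    amplitudes = signs * regime.bout_amplitude
    durations = np.full(n, regime.bout_duration)
    return starts, durations, amplitudes


def _splice_bout(
    velocity: np.ndarray,
    position: np.ndarray,
    dt: float,
    start: float,
    duration: float,
    amplitude: float,
) -> None:
    """Add one half-sine bout into a rendered trace, updating position in place."""
    n_samples = velocity.size
    i0 = max(int(np.ceil(start / dt)), 0)
    i1 = min(int(np.floor((start + duration) / dt)) + 1, n_samples)
    if i1 <= i0:
        return
    tau = np.arange(i0, i1) * dt - start
    w = amplitude * (np.pi / (2 * duration)) * np.sin(np.pi * tau / duration)
    velocity[i0:i1] += w
    position[i0:i1] += np.cumsum(w) * dt
    position[i1:] += np.sum(w) * dt


# ---------------------------------------------------------------------------
# public generators


def simulate_wheel(
    regime: BehaviorRegime,
    duration: float,
    stim_times: Sequence[float] = (),
    seed=None,
    rng: Optional[np.random.Generator] = None,
    sample_rate: float = 1000.0,
) -> WheelTrace:
    """Generate a wheel trace for a fixed duration and (optionally) fixed stimuli.

    In the ``associated`` regime each stimulus in ``stim_times`` is answered
    with probability ``response_probability`` by an extra bout at a drawn
    latency; the background Poisson bout process is present in both regimes.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    dt = 1.0 / sample_rate
    starts, durations, amplitudes = _draw_background_bouts(regime, duration, rng)
    starts, durations, amplitudes = list(starts), list(durations), list(amplitudes)
    if regime.mode == "associated":
        for v in np.asarray(stim_times, float):
            if rng.random() < regime.response_probability:
                start = v + regime.latency.draw(rng)
                if start < duration:
                    starts.append(start)
                    durations.append(regime.bout_duration)
                    amplitudes.append(CCW_SIGN * regime.bout_amplitude)
    n_samples = int(round(duration * sample_rate))
    velocity = _render_velocity(
        np.array(starts), np.array(durations), np.array(amplitudes), n_samples, dt
    )
    return WheelTrace.from_velocity(velocity, dt=dt)


def simulate_session(
    regime: BehaviorRegime,
    grid: DelayGrid,
    n_trials: int,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    sample_rate: float = 1000.0,
    movement_threshold: float = 10.0,
    reward_threshold: float = 90.0,
    punish_threshold: float = 90.0,
    response_timeout: float = 60.0,
    max_duration: Optional[float] = None,
    metadata: Optional[dict] = None,
) -> SessionRecord:
    """Simulate a full session honoring the ITI + resetting-quiescence trial logic.

    The returned record is self-consistent: replaying each trial's delay
    parameters against the returned wheel trace reproduces the recorded
    stimulus onset exactly (``SessionRecord.verify_replay``).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    dt = 1.0 / sample_rate

    itis, quiescences = grid.sample(rng, n_trials)

    if max_duration is None:
        wait = response_timeout
        if regime.bout_rate > 0:
            wait = min(response_timeout, 3.0 / regime.bout_rate + regime.bout_duration + 2.0)
        if regime.mode == "associated":
            wait = min(wait, 3.0 + regime.bout_duration)
        max_duration = n_trials * (grid.iti_max + 3.0 * grid.quiescence_max + wait) + 60.0

    # --- render the background process ------------------------------------
    n_samples = int(round(max_duration * sample_rate))
    bg_starts, bg_durations, bg_amplitudes = _draw_background_bouts(regime, max_duration, rng)
    velocity = _render_velocity(bg_starts, bg_durations, bg_amplitudes, n_samples, dt)
    position = np.cumsum(velocity) * dt

    def detect() -> MovementIntervals:
        return MovementIntervals.from_trace(
            WheelTrace(t0=0.0, dt=dt, position=position, velocity=velocity), movement_threshold
        )

    # --- walk the trials against the rendered trace ------------------------
    # Response bouts are spliced into the trace the moment a stimulus is
    # answered, so every recorded quantity (onset, first movement, outcome)
    # is computed from the trace the record ships with.
    intervals = detect()
    trials: list[TrialRecord] = []
    t0 = 0.0
    truncated = False
    timeout_samples = int(round(response_timeout * sample_rate))
    tail_margin = 2.0 * regime.bout_duration + 1.0
    for i in range(n_trials):
        v = float(intervals.earliest_quiet(t0 + itis[i], quiescences[i]))
        if v >= max_duration - tail_margin:
            truncated = True
            break
        if regime.mode == "associated" and rng.random() < regime.response_probability:
            start = v + regime.latency.draw(rng)
            if start < max_duration - tail_margin:
                _splice_bout(
                    velocity,
                    position,
                    dt,
                    start,
                    regime.bout_duration,
                    CCW_SIGN * regime.bout_amplitude,
                )
                intervals = detect()
        outcome, outcome_time = _outcome_from_arrays(
            position, dt, v, reward_threshold, punish_threshold, timeout_samples
        )
        trials.append(
            TrialRecord(
                index=i,
                prev_outcome_time=t0,
                iti=float(itis[i]),
                quiescence=float(quiescences[i]),
                stim_onset=v,
                first_move=np.nan,  # filled from the final trace below
                outcome=outcome,
            )
        )
        t0 = outcome_time

    trace = WheelTrace(t0=0.0, dt=dt, position=position, velocity=velocity)
    intervals = detect()
    for trial in trials:
        m = float(intervals.first_move_after(trial.stim_onset))
        trial.first_move = m if (np.isfinite(m) and m < trace.end_time) else np.nan

    if truncated or len(trials) < n_trials:
        warnings.warn(
            f"session truncated at {len(trials)}/{n_trials} trials "
            "(continuous movement or duration limit)",
            stacklevel=2,
        )

    meta = {"regime": regime.mode, "sample_rate": sample_rate}
    if metadata:
        meta.update(metadata)
    return SessionRecord(
        trials=trials,
        wheel=trace,
        delay_grid=grid,
        movement_threshold=movement_threshold,
        metadata=meta,
    )


def _outcome_from_arrays(
    position: np.ndarray,
    dt: float,
    stim_time: float,
    reward_threshold: float,
    punish_threshold: float,
    timeout_samples: int,
) -> tuple[str, float]:
    """First reward/punish threshold crossing of the stimulus-yoked displacement."""
    j0 = int(np.clip(round(stim_time / dt), 0, position.size - 1))
    j1 = min(position.size, j0 + timeout_samples)
    disp = position[j0:j1] - position[j0]
    rew = disp * CCW_SIGN >= reward_threshold
    pun = disp * (-CCW_SIGN) >= punish_threshold
    i_rew = int(np.argmax(rew)) if rew.any() else -1
    i_pun = int(np.argmax(pun)) if pun.any() else -1
    if i_rew < 0 and i_pun < 0:
        return "none", stim_time + timeout_samples * dt
    if i_pun < 0 or (0 <= i_rew < i_pun):
        return "reward", (j0 + i_rew) * dt
    return "punish", (j0 + i_pun) * dt
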