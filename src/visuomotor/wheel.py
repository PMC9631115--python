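"""Wheel-trace primitives shared by the task simulator and the behavioral statistics.

The task logic and the conditional-randomization test both need the same two
queries against a wheel movement record:

* ``earliest_quiet`` — given a quiescence-timer start and a required quiet
  duration, when does the stimulus appear?  The timer restarts whenever the
  wheel moves, so the answer is the end of the first movement-free window of
  the required length.
* ``first_move_after`` — the onset of the next wheel movement after a given
  time (the movement that defines the reaction time).

Movement is defined as the wheel speed exceeding a velocity floor for at
least one sample; contiguous runs of such samples form movement *bouts*,
represented as half-open intervals ``[start, end)`` in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WheelTrace", "MovementIntervals", "movement_bouts"]


@dataclass
class WheelTrace:
    """Uniformly sampled wheel displacement record.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    dt : float
        Sample spacing, seconds (1 ms by default at the 1 kHz logging rate).
    position : ndarray
        Cumulative wheel displacement, arbitrary angular units (degrees by
        convention in this package; counterclockwise is negative).
    velocity : ndarray
        Discrete derivative of ``position`` (units / s).
    """

    t0: float
    dt: float
    position: np.ndarray
    velocity: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.position.shape != self.velocity.shape:
            raise ValueError("position and velocity must have equal length")

    @classmethod
    def from_velocity(cls, velocity: np.ndarray, dt: float, t0: float = 0.0) -> "WheelTrace":
        velocity = np.asarray(velocity, dtype=float)
        position = np.cumsum(velocity) * dt
        return cls(t0=t0, dt=dt, position=position, velocity=velocity)

    @property
    def n_samples(self) -> int:
        return self.position.size

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def end_time(self) -> float:
        return self.t0 + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) * self.dt

    def moving(self, threshold: float) -> np.ndarray:
        """Boolean mask of samples where speed exceeds ``threshold``."""
        return np.abs(self.velocity) > threshold

    def index_at(self, t: float) -> int:
        return int(np.clip(round((t - self.t0) / self.dt), 0, self.n_samples - 1))


def movement_bouts(trace: WheelTrace, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Detect movement bouts as contiguous runs of supra-threshold speed.

    Returns ``(starts, ends)`` in seconds: the time of the first moving
    sample of each run and the time one sample past the last moving sample.
    """
    moving = trace.moving(threshold)
    if not moving.any():
        return np.empty(0), np.empty(0)
    edges = np.diff(moving.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if moving[0]:
        starts = np.concatenate(([0], starts))
    if moving[-1]:
        ends = np.concatenate((ends, [moving.size]))
    return trace.t0 + starts * trace.dt, trace.t0 + ends * trace.dt


class MovementIntervals:
    """Sorted, disjoint movement intervals with fast quiescence queries.

    The quiescence replay used throughout the behavioral statistics reduces
    to: starting a timer at ``a``, the stimulus appears at the first time
    ``V >= a + q`` such that no movement intersects ``(V - q, V)``.  With
    bout gaps precomputed per quiescence duration ``q`` this is answered in
    O(log n) per query, vectorized over many timer starts.
    """

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        if starts.shape != ends.shape:
            raise ValueError("starts and ends must have equal length")
        if starts.size and (np.any(np.diff(starts) <= 0) or np.any(ends <= starts)):
            raise ValueError("intervals must be sorted and non-degenerate")
        self.starts = starts
        self.ends = ends
        # gap after bout j: quiet time until the next bout begins
        self._gaps = (
            np.concatenate((starts[1:] - ends[:-1], [np.inf])) if starts.size else np.empty(0)
        )
        self._resolvers: dict[float, np.ndarray] = {}

    @classmethod
    def from_trace(cls, trace: WheelTrace, threshold: float) -> "MovementIntervals":
        return cls(*movement_bouts(trace, threshold))

    @property
    def n_bouts(self) -> int:
        return self.starts.size

    def _resolver(self, q: float) -> np.ndarray:
        """For each bout j, the first bout k >= j followed by a gap >= q."""
        key = round(float(q), 9)
        res = self._resolvers.get(key)
        if res is None:
            open_idx = np.flatnonzero(self._gaps >= q)  # non-empty: last gap is inf
            res = open_idx[np.searchsorted(open_idx, np.arange(self.n_bouts))]
            self._resolvers[key] = res
        return res

    def earliest_quiet(self, timer_start, q: float):
        """Stimulus time for a resetting quiescence timer started at ``timer_start``.

        Vectorized over ``timer_start``; returns the same shape.
        """
        a = np.asarray(timer_start, dtype=float)
        scalar = a.ndim == 0
        a = np.atleast_1d(a)
        v = a + q
        if self.n_bouts:
            j0 = np.searchsorted(self.ends, a, side="right")
            inb = j0 < self.n_bouts
            blocked = np.zeros(a.shape, dtype=bool)
            blocked[inb] = self.starts[j0[inb]] < a[inb] + q
            if blocked.any():
                k = self._resolver(q)[j0[blocked]]
                v[blocked] = self.ends[k] + q
        return v[0] if scalar else v

    def first_move_after(self, t):
        """Onset time of the first bout strictly after ``t`` (inf if none)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.starts, t_arr, side="right")
        out = np.full(t_arr.shape, np.inf)
        ok = idx < self.n_bouts
        out[ok] = self.starts[idx[ok]]
        return out[0] if np.ndim(t) == 0 else out
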