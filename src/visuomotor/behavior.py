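"""Conditional-randomization statistics for wheel-task reaction times.

The scientific question: are wheel turns time-locked to the visual stimulus,
or does a short median reaction time merely reflect frequent spontaneous
turning?  The test conditions on everything except the per-trial delay
parameters: the full wheel trace and the observed first-movement times
``M_i`` are held fixed, and the ITI / quiescence durations are redrawn
uniformly on their grid, *subject to* the constraint that replaying the
trial logic with the new delays still registers the same movement time
``M_i``.  Each accepted redraw yields a new stimulus onset ``V_i'`` and
hence a new reaction time ``M_i - V_i'``; the test statistic is the median
reaction time across trials (reaction times under a 100 ms floor excluded),
compared one-sided against the resampled null medians.

Because each trial's delays affect only that trial's stimulus onset once the
wheel trace and outcome times are fixed, the conditional distribution
factorizes over trials, and each trial's acceptance set can be enumerated
exactly on the finite delay grid.  Both a rejection-sampling null
(``conditional_null``, faithful to the resampling description) and an
enumeration-backed null (``exact_conditional_null``) are provided; they
target the same distribution and are cross-checked in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .synth.session import CCW_SIGN, SessionRecord, TrialRecord
from .wheel import MovementIntervals, WheelTrace

__all__ = [
    "ReactionTimeSet",
    "NullDistribution",
    "AssociationTest",
    "AssociationResult",
    "ConsistencyError",
    "compute_reaction_times",
    "replay_stimulus_time",
    "conditional_null",
    "exact_conditional_null",
    "test_association",
    "association_day",
    "performance_index",
    "split_thirds",
    "delay_movement_onsets",
]


class ConsistencyError(RuntimeError):
    """A trial's observed data is not in its own conditional support."""


@dataclass
class ReactionTimeSet:
    """Per-trial reaction times with the fast-reaction exclusion mask."""

    reaction_times: np.ndarray  # seconds, one per trial with a movement
    masked: np.ndarray  # True where RT < rt_floor (excluded from the statistic)
    trial_indices: np.ndarray
    n_dropped: int  # trials with no movement after the stimulus
    rt_floor: float = 0.1

    @property
    def included(self) -> np.ndarray:
        return self.reaction_times[~self.masked]

    @property
    def observed_median(self) -> float:
        vals = self.included
        return float(np.median(vals)) if vals.size else float("nan")


@dataclass
class NullDistribution:
    """Resampled null medians of the reaction time."""

    medians: np.ndarray
    n_resamples: int
    method: str  # 'rejection_sampling' | 'exact_enumeration'
    rt_floor: float
    acceptance_rates: Optional[np.ndarray] = None
    trial_indices: Optional[np.ndarray] = None
    #: per-trial conditional reaction-time supports (enumeration only)
    supports: Optional[list] = None
    #: resampled stimulus onsets, shape (n_resamples, n_trials), if requested
    stim_times: Optional[np.ndarray] = None

    @property
    def chance_median(self) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.nanmedian(self.medians))


@dataclass
class AssociationTest:
    """Result of the conditional-randomization test on one session."""

    p_value: Optional[float]
    observed_median: float
    chance_median: float
    n_trials_used: int
    alpha: float
    null: NullDistribution
    performance: Optional[float] = None

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < self.alpha


@dataclass
class AssociationResult:
    """Per-day p-values and the derived association day."""

    p_values: Sequence[Optional[float]]
    alpha: float = 0.05
    performance_indices: Optional[Sequence[float]] = None
    days: Optional[Sequence] = None

    @property
    def association_day(self):
        return association_day(self.p_values, alpha=self.alpha, days=self.days)


# ---------------------------------------------------------------------------
# reaction times and replay


def compute_reaction_times(
    session: SessionRecord, rt_floor: float = 0.1
) -> ReactionTimeSet:
    """Reaction times ``M_i - V_i`` from the wheel trace, with the floor mask.

    Trials whose stimulus was never followed by a movement are dropped and
    counted in ``n_dropped``.
    """
    intervals = session.intervals()
    rts, idx = [], []
    n_dropped = 0
    for trial in session.trials:
        m = float(intervals.first_move_after(trial.stim_onset))
        if not np.isfinite(m) or m >= session.wheel.end_time:
            n_dropped += 1
            continue
        rts.append(m - trial.stim_onset)
        idx.append(trial.index)
    rts = np.asarray(rts)
    return ReactionTimeSet(
        reaction_times=rts,
        masked=rts < rt_floor,
        trial_indices=np.asarray(idx, dtype=int),
        n_dropped=n_dropped,
        rt_floor=rt_floor,
    )


def replay_stimulus_time(
    wheel: WheelTrace,
    prev_outcome_time: float,
    iti: float,
    quiescence: float,
    movement_threshold: float = 10.0,
    boundary: Optional[float] = None,
) -> Optional[float]:
    """Replay the ITI + resetting-quiescence logic against a fixed wheel trace.

    Returns the stimulus onset the task program would have produced, or
    ``None`` if the quiescence timer never completes before ``boundary``
    (the end of the trace by default).
    """
    intervals = MovementIntervals.from_trace(wheel, movement_threshold)
    v = float(intervals.earliest_quiet(prev_outcome_time + iti, quiescence))
    limit = wheel.end_time if boundary is None else boundary
    return v if v <= limit else None


# ---------------------------------------------------------------------------
# conditional null


@dataclass
class TrialSupport:
    """Exact conditional support of one trial's reaction time on the delay grid."""

    trial_index: int
    observed_rt: float
    reaction_times: np.ndarray  # accepted-combination RTs (with multiplicity)
    stim_times: np.ndarray
    n_accepted: int
    n_combinations: int

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_combinations


def _usable_trials(session: SessionRecord) -> list[TrialRecord]:
    """Trials whose stimulus was followed by a movement (the RT is defined)."""
    return [t for t in session.trials if np.isfinite(t.first_move)]


def _enumerate_trial(
    intervals: MovementIntervals,
    trial: TrialRecord,
    iti_values: np.ndarray,
    q_values: np.ndarray,
) -> TrialSupport:
    m = trial.first_move
    v_acc, n_comb = [], iti_values.size * q_values.size
    for q in q_values:
        v = intervals.earliest_quiet(trial.prev_outcome_time + iti_values, q)
        ok = np.abs(intervals.first_move_after(v) - m) < 1e-9
        v_acc.append(v[ok])
    stim_times = np.concatenate(v_acc)
    if stim_times.size == 0:
        raise ConsistencyError(
            f"trial {trial.index}: no delay combination reproduces the observed "
            "movement time; the session record is inconsistent with its wheel trace"
        )
    return TrialSupport(
        trial_index=trial.index,
        observed_rt=m - trial.stim_onset,
        reaction_times=m - stim_times,
        stim_times=stim_times,
        n_accepted=stim_times.size,
        n_combinations=n_comb,
    )


def enumerate_trial_supports(session: SessionRecord) -> list[TrialSupport]:
    """Exact per-trial conditional reaction-time distributions.

    For each trial, every (ITI, quiescence) grid combination is replayed
    against the fixed wheel trace; combinations whose replayed stimulus is
    still followed first by the observed movement are accepted.  The
    conditional distribution of the trial's reaction time is uniform over
    the accepted combinations.
    """
    intervals = session.intervals()
    grid = session.delay_grid
    return [
        _enumerate_trial(intervals, t, grid.iti_values, grid.quiescence_values)
        for t in _usable_trials(session)
    ]


def _masked_medians(rt_matrix: np.ndarray, rt_floor: float) -> np.ndarray:
    vals = np.where(rt_matrix >= rt_floor, rt_matrix, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(vals, axis=1)


def exact_conditional_null(
    session: SessionRecord,
    n_resamples: int = 10_000,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    rt_floor: float = 0.1,
    max_combinations: int = 10_000,
) -> NullDistribution:
    """Enumeration-backed conditional null distribution of the median RT.

    Each null median is formed by drawing, independently per trial, one
    reaction time from that trial's exact conditional support.
    """
    grid = session.delay_grid
    if grid.n_combinations > max_combinations:
        raise ValueError(
            f"delay grid has {grid.n_combinations} combinations "
            f"(> {max_combinations}); use conditional_null instead"
        )
    if n_resamples < 1:
        raise ValueError("n_resamples must be at least 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    supports = enumerate_trial_supports(session)
    rt_matrix = np.empty((n_resamples, len(supports)))
    for j, sup in enumerate(supports):
        rt_matrix[:, j] = sup.reaction_times[
            rng.integers(0, sup.n_accepted, size=n_resamples)
        ]
    return NullDistribution(
        medians=_masked_medians(rt_matrix, rt_floor),
        n_resamples=n_resamples,
        method="exact_enumeration",
        rt_floor=rt_floor,
        acceptance_rates=np.array([s.acceptance_rate for s in supports]),
        trial_indices=np.array([s.trial_index for s in supports]),
        supports=supports,
    )


def conditional_null(
    session: SessionRecord,
    n_resamples: int = 10_000,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    rt_floor: float = 0.1,
    proposal_cap: int = 1_000,
    keep_stim_times: bool = False,
) -> NullDistribution:
    """Rejection-sampled conditional null distribution of the median RT.

    Per trial and resample, (ITI, quiescence) pairs are proposed uniformly
    on the grid and replayed; a proposal is accepted when the first movement
    after the replayed stimulus equals the observed movement time.  After
    ``proposal_cap`` rounds, any still-unresolved resamples for a trial fall
    back to that trial's enumerated acceptance set, preserving exactness for
    low-acceptance trials at bounded runtime.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be at least 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    intervals = session.intervals()
    grid = session.delay_grid
    iti_values, q_values = grid.iti_values, grid.quiescence_values
    trials = _usable_trials(session)

    rt_matrix = np.empty((n_resamples, len(trials)))
    stim_matrix = np.empty((n_resamples, len(trials))) if keep_stim_times else None
    rates = np.empty(len(trials))
    for j, trial in enumerate(trials):
        m, t0 = trial.first_move, trial.prev_outcome_time
        v_out = np.empty(n_resamples)
        pending = np.arange(n_resamples)
        n_proposed = n_accepted = 0
        for _ in range(proposal_cap):
            if pending.size == 0:
                break
            itis = rng.choice(iti_values, size=pending.size)
            qs = rng.choice(q_values, size=pending.size)
            v = np.empty(pending.size)
            for q in np.unique(qs):
                sel = qs == q
                v[sel] = intervals.earliest_quiet(t0 + itis[sel], q)
            ok = np.abs(intervals.first_move_after(v) - m) < 1e-9
            v_out[pending[ok]] = v[ok]
            n_proposed += pending.size
            n_accepted += int(ok.sum())
            pending = pending[~ok]
        if pending.size:
            sup = _enumerate_trial(intervals, trial, iti_values, q_values)
            v_out[pending] = sup.stim_times[
                rng.integers(0, sup.n_accepted, size=pending.size)
            ]
        rt_matrix[:, j] = m - v_out
        if stim_matrix is not None:
            stim_matrix[:, j] = v_out
        rates[j] = n_accepted / n_proposed if n_proposed else 1.0

    return NullDistribution(
        medians=_masked_medians(rt_matrix, rt_floor),
        n_resamples=n_resamples,
        method="rejection_sampling",
        rt_floor=rt_floor,
        acceptance_rates=rates,
        trial_indices=np.array([t.index for t in trials]),
        stim_times=stim_matrix,
    )


# ---------------------------------------------------------------------------
# the test


def test_association(
    session: SessionRecord,
    n_resamples: int = 10_000,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    alpha: float = 0.05,
    rt_floor: float = 0.1,
    method: str = "auto",
    min_trials: int = 10,
    two_sided: bool = False,
) -> AssociationTest:
    """One-sided (lower-tail) conditional-randomization test on one session.

    ``p = (1 + #{null medians <= observed median}) / (1 + n_resamples)``;
    the add-one correction makes the test conservative at finite resamples,
    and ties (including the observed parameters themselves, which are always
    in the conditional support) count toward the null tail.  Sessions with
    fewer than ``min_trials`` floor-surviving reaction times report
    ``p_value=None``.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if method == "auto":
        method = (
            "exact_enumeration"
            if session.delay_grid.n_combinations <= 10_000
            else "rejection_sampling"
        )
    if method == "exact_enumeration":
        null = exact_conditional_null(
            session, n_resamples=n_resamples, rng=rng, rt_floor=rt_floor
        )
    elif method == "rejection_sampling":
        null = conditional_null(
            session, n_resamples=n_resamples, rng=rng, rt_floor=rt_floor
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    rt_set = compute_reaction_times(session, rt_floor=rt_floor)
    observed = rt_set.observed_median
    chance = null.chance_median
    n_used = int(rt_set.included.size)

    if n_used < min_trials:
        p = None
    else:
        null_vals = null.medians
        lower = int(np.sum((null_vals <= observed) | np.isnan(null_vals)))
        if two_sided:
            upper = int(np.sum((null_vals >= observed) | np.isnan(null_vals)))
            tail = min(lower, upper)
            p = min(1.0, 2.0 * (1 + tail) / (1 + null.n_resamples))
        else:
            p = (1 + lower) / (1 + null.n_resamples)

    perf = None
    if np.isfinite(observed) and np.isfinite(chance) and observed > 0 and chance > 0:
        perf = performance_index(observed, chance)
    return AssociationTest(
        p_value=p,
        observed_median=observed,
        chance_median=chance,
        n_trials_used=n_used,
        alpha=alpha,
        null=null,
        performance=perf,
    )


def association_day(p_values: Sequence[Optional[float]], alpha: float = 0.05, days=None):
    """First day whose p-value falls below ``alpha``; None if none does.

    Days are labelled 1-based in training order unless ``days`` provides
    explicit labels; days with an undefined p-value count as not significant.
    """
    for i, p in enumerate(p_values):
        if p is not None and p < alpha:
            return days[i] if days is not None else i + 1
    return None


def performance_index(observed_median: float, chance_median: float) -> float:
    """Task performance index in [-1, 1].

    ``(chance - observed) / (observed + chance)``: positive when reaction
    times are shorter than chance, zero at chance, approaching +1 as
    reaction times vanish relative to chance.
    """
    if observed_median <= 0 or chance_median <= 0:
        raise ValueError("medians must be positive")
    return (chance_median - observed_median) / (observed_median + chance_median)


def split_thirds(items: Sequence):
    """Contiguous, order-preserving thirds; earlier groups take the remainder."""
    n = len(items)
    if n < 3:
        raise ValueError("need at least 3 items to split into thirds")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if g < rem else 0) for g in range(3)]
    out, start = [], 0
    for s in sizes:
        out.append(items[start : start + s])
        start += s
    return out


# ---------------------------------------------------------------------------
# delay-period movement epochs (for the hemisphere-weighted subtraction)


def delay_movement_onsets(
    session: SessionRecord,
    reward_threshold: float = 90.0,
    punish_threshold: float = 90.0,
) -> np.ndarray:
    """Onsets of delay-period movements that would have been rewarded.

    Qualifying movements occur between a trial's previous outcome and its
    stimulus onset (no stimulus on screen) and reach the counterclockwise
    reward threshold without first reaching the clockwise punish threshold.
    These are the epochs used to fit the between-hemisphere movement gain.
    """
    intervals = session.intervals()
    trace = session.wheel
    onsets = []
    for trial in session.trials:
        lo, hi = trial.prev_outcome_time, trial.stim_onset
        sel = (intervals.starts >= lo) & (intervals.ends <= hi)
        for s, e in zip(intervals.starts[sel], intervals.ends[sel]):
            i0, i1 = trace.index_at(s), trace.index_at(e)
            disp = trace.position[i0 : i1 + 1] - trace.position[i0]
            hit_reward = np.any(disp * CCW_SIGN >= reward_threshold)
            hit_punish = np.any(disp * (-CCW_SIGN) >= punish_threshold)
            if hit_reward and not hit_punish:
                onsets.append(s)
    return np.asarray(onsets)
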