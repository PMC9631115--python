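"""Spike-sorted unit quality control and responsiveness classification.

Quality control follows seven criteria commonly applied to Neuropixels
recordings after spike sorting: (1) somatic waveform shape (one trough, at
most two peaks, trough first and larger), (2) spatial decay of the template
amplitude across channels shallower than a floor, (3) trough-to-peak
duration between 100 and 800 µs, (4) quiet waveform baseline (< 30% of the
maximum amplitude), (5) < 20% of spikes missing below the detection floor
(estimated by a truncated-Gaussian fit of the spike-amplitude
distribution), (6) at least 300 spikes, and (7) refractory-period
contamination F_p < 10%, obtained by counting inter-spike intervals in the
censored-to-refractory window and solving

    r = 2 (tau_R - tau_C) N^2 (1 - F_p) F_p / T

for F_p (smaller root; F_p = 1 when the count exceeds the formula's
maximum).

Responsiveness of a unit to stimuli or movements is assessed with a
within-trial shuffle test: the statistic is the mean over trials of
(response-window rate - baseline-window rate), and the null swaps the two
windows independently within each trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, signal, stats

__all__ = [
    "QCParams",
    "QCResult",
    "WaveformShape",
    "UnitRecord",
    "ResponsivenessResult",
    "qc_waveform_shape",
    "qc_spatial_decay",
    "estimate_missing_fraction",
    "count_refractory_violations",
    "refractory_contamination",
    "classify_unit_quality",
    "classify_cell_type",
    "normalize_multiunit",
    "shuffle_responsiveness",
    "detect_surface_channel",
]


@dataclass
class QCParams:
    """Thresholds of the seven unit-quality criteria."""

    refractory_period: float = 0.002  # tau_R, s
    censored_period: float = 0.0001  # tau_C, s
    min_spikes: int = 300
    min_duration_us: float = 100.0
    max_duration_us: float = 800.0
    baseline_amp_frac: float = 0.30
    max_missing: float = 0.20
    max_contamination: float = 0.10
    spatial_decay_slope_floor: float = -20.0  # amplitude units per channel spacing
    peak_prominence_frac: float = 0.10  # fraction of trough amplitude
    baseline_frac_of_samples: float = 0.2  # leading samples treated as baseline
    pair_counting: str = "all"  # 'all' ordered pairs or 'consecutive' ISIs

    def __post_init__(self) -> None:
        if not self.refractory_period > self.censored_period >= 0:
            raise ValueError("need refractory_period > censored_period >= 0")
        for name in ("baseline_amp_frac", "max_missing", "max_contamination"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class UnitRecord:
    """One spike-sorted unit as stored in a Phy-style directory."""

    spike_times: np.ndarray  # s, sorted
    amplitudes: np.ndarray  # per-spike amplitudes, a.u.
    template: np.ndarray  # (n_channels, n_samples) waveform, µV
    sample_rate: float  # waveform sampling rate, Hz
    peak_channel: int
    channel_positions: np.ndarray  # (n_channels, 2) µm
    unit_id: int = 0

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike times must be sorted")
        if self.sample_rate <= 0:
            raise ValueError("waveform sample rate must be positive")


@dataclass
class WaveformShape:
    passed: bool
    shape_ok: bool
    duration_ok: bool
    baseline_ok: bool
    trough_to_peak_us: float
    baseline_frac: float
    n_troughs: int
    n_peaks: int
    reason: Optional[str] = None


@dataclass
class QCResult:
    """Per-criterion verdicts and the derived quality quantities."""

    shape_ok: bool
    decay_ok: bool
    duration_ok: bool
    baseline_ok: bool
    missing_ok: bool
    count_ok: bool
    contamination_ok: bool
    trough_to_peak_us: float
    decay_slope: float
    missing_fraction: float
    contamination: float
    n_violations: int
    n_spikes: int

    @property
    def overall(self) -> bool:
        return (
            self.shape_ok
            and self.decay_ok
            and self.duration_ok
            and self.baseline_ok
            and self.missing_ok
            and self.count_ok
            and self.contamination_ok
        )


@dataclass
class ResponsivenessResult:
    """Within-trial shuffle test of event responsiveness."""

    p_value: Optional[float]
    statistic: float  # mean (response - baseline) rate difference, Hz
    sign: str  # 'positive' | 'negative' | 'none'
    n_shuffles: int
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < self.alpha


# ---------------------------------------------------------------------------
# waveform criteria


def qc_waveform_shape(
    waveform: np.ndarray, sample_rate: float, params: Optional[QCParams] = None
) -> WaveformShape:
    """Evaluate the somatic-shape, duration, and baseline criteria.

    Trough/peak detection uses a prominence threshold at a fraction of the
    trough amplitude so that sub-threshold ripples do not count as extrema.
    """
    params = params or QCParams()
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1:
        raise ValueError("waveform must be one-dimensional (peak channel)")
    amp = np.abs(w).max()
    if amp == 0:
        return WaveformShape(False, False, False, False, float("nan"), float("nan"), 0, 0, "flat waveform")

    trough_amp = -w.min()
    prominence = params.peak_prominence_frac * max(trough_amp, amp)
    troughs, _ = signal.find_peaks(-w, prominence=prominence)
    peaks, _ = signal.find_peaks(w, prominence=prominence)

    shape_ok = False
    t2p_us = float("nan")
    if troughs.size == 1 and 1 <= peaks.size <= 2:
        trough_idx = troughs[0]
        after = peaks[peaks > trough_idx]
        if after.size:
            main_peak = after[np.argmax(w[after])]
            shape_ok = trough_amp > w[main_peak]
            t2p_us = (main_peak - trough_idx) / sample_rate * 1e6
    duration_ok = (
        np.isfinite(t2p_us)
        and params.min_duration_us < t2p_us < params.max_duration_us
    )

    n_base = max(int(params.baseline_frac_of_samples * w.size), 1)
    baseline_frac = float(np.abs(w[:n_base]).max() / amp)
    baseline_ok = baseline_frac < params.baseline_amp_frac

    passed = bool(shape_ok and duration_ok and baseline_ok)
    return WaveformShape(
        passed=passed,
        shape_ok=bool(shape_ok),
        duration_ok=bool(duration_ok),
        baseline_ok=bool(baseline_ok),
        trough_to_peak_us=float(t2p_us),
        baseline_frac=baseline_frac,
        n_troughs=int(troughs.size),
        n_peaks=int(peaks.size),
    )


def qc_spatial_decay(
    channel_amplitudes: np.ndarray,
    channel_distances: np.ndarray,
    params: Optional[QCParams] = None,
    indeterminate_passes: bool = True,
) -> tuple[bool, float]:
    """Slope of per-channel maximum amplitude versus distance from the peak.

    A well-localized somatic unit decays with distance (negative slope, but
    shallower than the floor); a slope steeper than the floor marks a
    non-localized (noise) unit.  Distances are expressed in channel
    spacings, keeping the conventional floor of -20 meaningful.
    """
    params = params or QCParams()
    amps = np.asarray(channel_amplitudes, dtype=float)
    dists = np.asarray(channel_distances, dtype=float)
    if amps.shape != dists.shape:
        raise ValueError("amplitudes and distances must match")
    if amps.size < 3:
        warnings.warn("fewer than 3 channels; spatial-decay criterion indeterminate")
        return indeterminate_passes, float("nan")
    slope = float(np.polyfit(dists, amps, 1)[0])
    return slope > params.spatial_decay_slope_floor, slope


# ---------------------------------------------------------------------------
# missing spikes


def estimate_missing_fraction(amplitudes: np.ndarray, detection_floor: float) -> float:
    """Fraction of spikes lost below the detection floor.

    A Gaussian truncated at ``detection_floor`` is fitted to the observed
    amplitudes by maximum likelihood; the missing fraction is the fitted
    mass below the floor.
    """
    amps = np.asarray(amplitudes, dtype=float)
    amps = amps[amps >= detection_floor]
    if amps.size < 10:
        raise ValueError("too few amplitudes above the floor to fit")
    sd = amps.std()
    if sd == 0:
        warnings.warn("zero-variance amplitudes; missing fraction reported as 0")
        return 0.0

    def nll(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        z = (amps - mu) / sigma
        a = (detection_floor - mu) / sigma
        log_tail = stats.norm.logsf(a)
        return amps.size * (log_sigma + log_tail) + 0.5 * np.sum(z**2)

    x0 = np.array([amps.mean(), np.log(sd)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8})
    mu, sigma = res.x[0], float(np.exp(res.x[1]))
    return float(np.clip(stats.norm.cdf((detection_floor - mu) / sigma), 0.0, 1.0))


# ---------------------------------------------------------------------------
# refractory contamination


def count_refractory_violations(
    spike_times: np.ndarray, params: Optional[QCParams] = None
) -> int:
    """Count spike pairs with inter-spike interval in (tau_C, tau_R].

    By default all ordered pairs are counted (the quantity the contamination
    formula models); ``params.pair_counting='consecutive'`` restricts to
    adjacent spikes.
    """
    params = params or QCParams()
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        return 0
    if params.pair_counting == "consecutive":
        isi = np.diff(t)
        return int(np.sum((isi > params.censored_period) & (isi <= params.refractory_period)))
    hi = np.searchsorted(t, t + params.refractory_period, side="right") - np.arange(t.size) - 1
    lo = np.searchsorted(t, t + params.censored_period, side="right") - np.arange(t.size) - 1
    return int(np.sum(hi - lo))


def refractory_contamination(
    spike_times: np.ndarray,
    duration: float,
    params: Optional[QCParams] = None,
    n_violations: Optional[int] = None,
) -> tuple[float, int]:
    """Contamination fraction F_p from refractory-period violations.

    Solves ``r = 2 (tau_R - tau_C) N^2 (1 - F_p) F_p / T`` for F_p, taking
    the smaller root; when the violation count exceeds the maximum the
    formula can produce (negative discriminant) F_p is reported as 1.
    Returns ``(F_p, r)``.
    """
    params = params or QCParams()
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.asarray(spike_times, dtype=float)
    n = t.size
    if n < 2:
        warnings.warn("fewer than 2 spikes; contamination reported as 0")
        return 0.0, 0
    r = count_refractory_violations(t, params) if n_violations is None else int(n_violations)
    c = r * duration / (2.0 * (params.refractory_period - params.censored_period) * n * n)
    disc = 1.0 - 4.0 * c
    if disc < 0:
        return 1.0, r
    return float((1.0 - np.sqrt(disc)) / 2.0), r


# ---------------------------------------------------------------------------
# full classification


def classify_unit_quality(
    unit: UnitRecord, duration: float, params: Optional[QCParams] = None,
    detection_floor: Optional[float] = None,
) -> QCResult:
    """Evaluate all seven quality criteria for one unit.

    ``detection_floor`` defaults to the smallest observed amplitude (the
    sorter detected nothing below it).
    """
    params = params or QCParams()
    shape = qc_waveform_shape(unit.template[unit.peak_channel], unit.sample_rate, params)

    chan_amp = np.abs(unit.template).max(axis=1)
    pos = np.asarray(unit.channel_positions, dtype=float)
    dist = np.linalg.norm(pos - pos[unit.peak_channel], axis=1)
    spacing = np.min(dist[dist > 0]) if np.any(dist > 0) else 1.0
    decay_ok, slope = qc_spatial_decay(chan_amp, dist / spacing, params)

    n_spikes = unit.spike_times.size
    count_ok = n_spikes >= params.min_spikes

    amps = np.asarray(unit.amplitudes, dtype=float)
    floor = float(amps.min()) if detection_floor is None else detection_floor
    try:
        missing = estimate_missing_fraction(amps, floor)
    except ValueError:
        missing = float("nan")
    missing_ok = bool(np.isfinite(missing) and missing < params.max_missing)

    f_p, r = refractory_contamination(unit.spike_times, duration, params)
    contamination_ok = f_p < params.max_contamination

    return QCResult(
        shape_ok=shape.shape_ok,
        decay_ok=bool(decay_ok),
        duration_ok=shape.duration_ok,
        baseline_ok=shape.baseline_ok,
        missing_ok=missing_ok,
        count_ok=bool(count_ok),
        contamination_ok=bool(contamination_ok),
        trough_to_peak_us=shape.trough_to_peak_us,
        decay_slope=slope,
        missing_fraction=missing,
        contamination=f_p,
        n_violations=r,
        n_spikes=int(n_spikes),
    )


def classify_cell_type(trough_to_peak_us: float, threshold_us: float = 400.0) -> str:
    """Split units into narrow (putative fast-spiking interneurons) vs wide.

    Narrow strictly below the threshold; a unit exactly at the boundary is
    classified wide.
    """
    return "narrow" if trough_to_peak_us < threshold_us else "wide"


# ---------------------------------------------------------------------------
# multiunit normalization


def normalize_multiunit(
    rate_traces: np.ndarray,
    baseline_rates: np.ndarray,
    pooled_baseline_rates: Optional[np.ndarray] = None,
    softening_percentile: float = 10.0,
) -> tuple[np.ndarray, float]:
    """ΔFR/FR₀ normalization of multiunit rate traces.

    ``(FR - FR0) / (FR0 + s)`` per area, where ``s`` is the given percentile
    of baseline rates pooled across all areas and recordings (defaults to
    the supplied baselines when no pool is given).  Returns the normalized
    traces and the softening used.
    """
    traces = np.atleast_2d(np.asarray(rate_traces, dtype=float))
    fr0 = np.atleast_1d(np.asarray(baseline_rates, dtype=float))
    if fr0.size != traces.shape[0]:
        raise ValueError("one baseline rate per trace is required")
    if fr0.size == 0:
        raise ValueError("empty baseline")
    pool = fr0 if pooled_baseline_rates is None else np.asarray(pooled_baseline_rates, float)
    softening = float(np.percentile(pool, softening_percentile))
    return (traces - fr0[:, None]) / (fr0 + softening)[:, None], softening


# ---------------------------------------------------------------------------
# shuffle test


def shuffle_responsiveness(
    baseline_rates: np.ndarray,
    response_rates: np.ndarray,
    n_shuffles: int = 1000,
    alpha: float = 0.01,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    min_trials: int = 5,
) -> ResponsivenessResult:
    """Within-trial baseline/response shuffle test.

    The observed statistic is the mean over trials of (response - baseline)
    firing rate.  The null swaps the two window values independently within
    each trial with probability one half per shuffle; the two-sided p-value
    carries the add-one correction, so the false-positive rate is bounded
    by alpha in expectation.
    """
    base = np.asarray(baseline_rates, dtype=float)
    resp = np.asarray(response_rates, dtype=float)
    if base.shape != resp.shape or base.ndim != 1:
        raise ValueError("need equal-length per-trial baseline and response rates")
    n_trials = base.size
    diffs = resp - base
    statistic = float(diffs.mean()) if n_trials else float("nan")
    if n_trials < min_trials:
        return ResponsivenessResult(None, statistic, "none", n_shuffles, alpha)

    rng = np.random.default_rng(seed) if rng is None else rng
    signs = rng.integers(0, 2, size=(n_shuffles, n_trials)) * 2 - 1
    null = (signs * diffs).mean(axis=1)
    p = float((1 + np.sum(np.abs(null) >= abs(statistic))) / (1 + n_shuffles))
    sign = "none"
    if p < alpha:
        sign = "positive" if statistic > 0 else "negative"
    return ResponsivenessResult(p, statistic, sign, n_shuffles, alpha)


# ---------------------------------------------------------------------------
# surface-channel detection


def detect_surface_channel(
    lfp_correlation: np.ndarray, min_contrast: float = 0.1
) -> Optional[int]:
    """Locate the cortical surface from the LFP channel-correlation matrix.

    Channels above the brain share ambient signal and correlate strongly
    with each other but not with in-brain channels, producing a block
    structure with a sharp drop at the surface.  The boundary maximizing the
    within-block minus cross-block mean correlation (searched from the top
    of the probe) is returned as the index of the first in-brain channel;
    ``None`` when no boundary reaches ``min_contrast``.
    """
    c = np.asarray(lfp_correlation, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    n = c.shape[0]
    off = ~np.eye(n, dtype=bool)
    best_b, best_contrast = None, -np.inf
    for b in range(1, n):
        top, bottom = slice(0, b), slice(b, n)
        within_vals = []
        for blk in (top, bottom):
            sub = c[blk, blk]
            m = off[blk, blk]
            if m.any():
                within_vals.append(sub[m].mean())
        within = float(np.mean(within_vals))
        cross = float(c[top, bottom].mean())
        contrast = within - cross
        if contrast > best_contrast + 1e-12:
            best_contrast, best_b = contrast, b
    if best_b is None or best_contrast < min_contrast:
        warnings.warn("no detectable surface boundary in the LFP correlation matrix")
        return None
    return best_b
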