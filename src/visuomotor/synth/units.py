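"""Synthetic spike-sorted units with controlled contamination and truncation.

A unit's spike train is the superposition of two independent
refractory-respecting Poisson processes: the unit itself and a contaminating
source (another neuron whose spikes were mis-assigned), whose share of the
total rate is the planted contamination fraction.  Because the two sources
are independent, cross-source spike pairs fall inside the refractory window
at exactly the rate the contamination formula models, giving the estimator
an exact target.  Per-spike amplitudes are Gaussian, truncated at a
detection floor to emulate drift-induced missed spikes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..ephys import UnitRecord

__all__ = [
    "SyntheticUnitTruth",
    "make_template",
    "simulate_unit",
    "simulate_units",
    "simulate_lfp_correlation",
]


@dataclass
class SyntheticUnitTruth:
    """Ground-truth parameters of one simulated unit."""

    base_rate: float = 5.0  # total firing rate before truncation, Hz
    contamination: float = 0.0  # planted F_p
    amplitude_mean: float = 50.0
    amplitude_sd: float = 10.0
    detection_floor: float = -np.inf  # amplitudes below are dropped
    refractory_period: float = 0.002  # s
    trough_to_peak_us: float = 400.0
    trough_amplitude: float = 80.0
    peak_amplitude: float = 40.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination < 1.0:
            raise ValueError("contamination must lie in [0, 1)")
        if self.refractory_period <= 0:
            raise ValueError("refractory period must be positive")
        if self.base_rate < 0:
            raise ValueError("base_rate must be non-negative")


def _refractory_poisson(
    rate: float, duration: float, refractory: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson process with a dead time, at the requested *total* rate."""
    if rate <= 0:
        return np.empty(0)
    mean_isi = 1.0 / rate
    if mean_isi <= refractory:
        raise ValueError("rate too high for the refractory period")
    lam = 1.0 / (mean_isi - refractory)
    n_guess = int(rate * duration * 1.5) + 20
    times: list[np.ndarray] = []
    t = 0.0
    while t < duration:
        isi = refractory + rng.exponential(1.0 / lam, size=n_guess)
        chunk = t + np.cumsum(isi)
        times.append(chunk)
        t = chunk[-1]
    all_t = np.concatenate(times)
    return all_t[all_t < duration]


def make_template(
    n_channels: int = 8,
    n_samples: int = 82,
    sample_rate: float = 30000.0,
    trough_amplitude: float = 80.0,
    peak_amplitude: float = 40.0,
    trough_to_peak_us: float = 400.0,
    trough_width_us: float = 60.0,
    peak_width_us: float = 120.0,
    decay_per_channel: float = 0.6,
    peak_channel: Optional[int] = None,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Parametric somatic template: Gaussian trough then a later Gaussian peak.

    Returns ``(template (channels, samples), peak_channel, channel_positions)``
    with amplitudes decaying geometrically with channel distance; channel
    spacing is 20 µm along the probe.  Widths must be well under the
    trough-to-peak separation for the planted duration to be realized.
    """
    if peak_channel is None:
        peak_channel = n_channels // 2
    t = np.arange(n_samples) / sample_rate
    t_trough = 0.35 * n_samples / sample_rate
    t_peak = t_trough + trough_to_peak_us * 1e-6
    width_t = trough_width_us * 1e-6
    width_p = peak_width_us * 1e-6
    shape = -trough_amplitude * np.exp(-((t - t_trough) ** 2) / (2 * width_t**2))
    shape += peak_amplitude * np.exp(-((t - t_peak) ** 2) / (2 * width_p**2))
    channel_gain = decay_per_channel ** np.abs(np.arange(n_channels) - peak_channel)
    template = channel_gain[:, None] * shape[None, :]
    positions = np.column_stack([np.zeros(n_channels), 20.0 * np.arange(n_channels)])
    return template, peak_channel, positions


def simulate_unit(
    truth: SyntheticUnitTruth,
    duration: float,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    unit_id: int = 0,
) -> UnitRecord:
    """Simulate one unit's spike train, amplitudes, and template."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    own = _refractory_poisson(
        truth.base_rate * (1.0 - truth.contamination), duration, truth.refractory_period, rng
    )
    contaminant = _refractory_poisson(
        truth.base_rate * truth.contamination, duration, truth.refractory_period, rng
    )
    times = np.sort(np.concatenate([own, contaminant]))
    amplitudes = rng.normal(truth.amplitude_mean, truth.amplitude_sd, size=times.size)
    keep = amplitudes >= truth.detection_floor
    times, amplitudes = times[keep], amplitudes[keep]

    template, peak_channel, positions = make_template(
        trough_amplitude=truth.trough_amplitude,
        peak_amplitude=truth.peak_amplitude,
        trough_to_peak_us=truth.trough_to_peak_us,
    )
    return UnitRecord(
        spike_times=times,
        amplitudes=amplitudes,
        template=template,
        sample_rate=30000.0,
        peak_channel=peak_channel,
        channel_positions=positions,
        unit_id=unit_id,
    )


def simulate_units(
    truths: list[SyntheticUnitTruth],
    duration: float,
    seed=None,
    rng: Optional[np.random.Generator] = None,
) -> list[UnitRecord]:
    rng = np.random.default_rng(seed) if rng is None else rng
    return [simulate_unit(t, duration, rng=rng, unit_id=i) for i, t in enumerate(truths)]


def simulate_lfp_correlation(
    n_channels: int = 40,
    surface_channel: int = 20,
    n_samples: int = 4000,
    shared_out_strength: float = 0.9,
    seed=None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """LFP channel-correlation matrix with out-of-brain channels on top.

    Channels above ``surface_channel`` share a common ambient signal;
    in-brain channels carry smooth depth-dependent mixtures of independent
    sources, so neighbors correlate but the two groups do not.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    lfp = np.empty((n_channels, n_samples))
    ambient = rng.normal(size=n_samples)
    for ch in range(surface_channel):
        lfp[ch] = shared_out_strength * ambient + (1 - shared_out_strength) * rng.normal(
            size=n_samples
        )
    n_in = n_channels - surface_channel
    n_modes = max(n_in // 4, 2)
    modes = rng.normal(size=(n_modes, n_samples))
    depths = np.linspace(0, 1, n_in)
    centers = np.linspace(0, 1, n_modes)
    weights = np.exp(-((depths[:, None] - centers[None, :]) ** 2) / (2 * 0.15**2))
    lfp[surface_channel:] = weights @ modes + 0.3 * rng.normal(size=(n_in, n_samples))
    return np.corrcoef(lfp)
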