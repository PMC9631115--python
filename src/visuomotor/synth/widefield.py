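"""Synthetic two-wavelength widefield stacks with planted ground truth.

The generator emulates the acquisition geometry the processing chain
expects: frames at 70 Hz with strictly alternating blue/violet
illumination (35 Hz per channel).  The blue (calcium) channel carries

* a unilateral visual component: a left-hemisphere spatial map driven by a
  stimulus-locked temporal transient,
* a bilateral movement component driven by smoothed wheel speed,
* a shared heartbeat-band artifact (a ~10 Hz sinusoid with slow amplitude
  modulation, well inside the 5-15 Hz correction band) with a per-pixel
  gain map, and
* white noise.

The violet (hemodynamic) channel carries only the heartbeat artifact (with
a channel-specific gain) plus noise, so the per-pixel violet-to-blue
regression of the hemodynamic correction has an exact target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..wheel import WheelTrace
from ..widefield import FrameStack
from .session import SessionRecord

__all__ = ["SyntheticWidefieldTruth", "default_widefield_truth", "simulate_widefield"]


def _gaussian_blob(shape: tuple[int, int], center: tuple[float, float], sigma: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2))


@dataclass
class SyntheticWidefieldTruth:
    """Planted components of a synthetic widefield session."""

    shape: tuple[int, int]
    visual_map: np.ndarray  # unilateral (left-hemisphere) spatial weights
    motor_map: np.ndarray  # bilateral spatial weights
    heartbeat_gain_map: np.ndarray  # per-pixel artifact gain
    heartbeat_freq: float = 10.0
    heartbeat_gain_blue: float = 1.0
    heartbeat_gain_violet: float = 1.4
    noise_scale: float = 0.05
    baseline: float = 100.0
    visual_amplitude: float = 2.0
    motor_amplitude: float = 2.0
    visual_tau: float = 0.08  # alpha-function time constant; peak at ~tau
    # filled in by the generator
    visual_trace: Optional[np.ndarray] = None
    motor_trace: Optional[np.ndarray] = None
    frame_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("visual_map", "motor_map", "heartbeat_gain_map"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != tuple(self.shape):
                raise ValueError(f"{name} does not match the configured frame geometry")
            setattr(self, name, arr)


def default_widefield_truth(
    shape: tuple[int, int] = (24, 32), noise_scale: float = 0.05
) -> SyntheticWidefieldTruth:
    """A small-geometry truth: left-lateral visual blob, bilateral motor blobs.

    Columns left of ``cols // 2`` are the left hemisphere.  The visual blob
    sits in the left anterior quadrant (a stand-in mPFC/visual locus); the
    motor component is mirrored across the midline.
    """
    rows, cols = shape
    visual = _gaussian_blob(shape, (rows * 0.3, cols * 0.25), min(rows, cols) * 0.12)
    motor_left = _gaussian_blob(shape, (rows * 0.6, cols * 0.25), min(rows, cols) * 0.15)
    motor = motor_left + motor_left[:, ::-1]
    heartbeat = 0.5 + _gaussian_blob(shape, (rows * 0.5, cols * 0.5), min(rows, cols) * 0.4)
    return SyntheticWidefieldTruth(
        shape=shape,
        visual_map=visual,
        motor_map=motor,
        heartbeat_gain_map=heartbeat,
        noise_scale=noise_scale,
    )


def _alpha_response(frame_times: np.ndarray, onsets: np.ndarray, tau: float) -> np.ndarray:
    """Sum of alpha-function transients (t/tau) exp(1 - t/tau) at each onset."""
    out = np.zeros_like(frame_times)
    for v in onsets:
        dt = frame_times - v
        sel = (dt >= 0) & (dt < 10 * tau)
        x = dt[sel] / tau
        out[sel] += x * np.exp(1.0 - x)
    return out


def _movement_drive(wheel: WheelTrace, frame_times: np.ndarray, smooth_s: float = 0.1) -> np.ndarray:
    speed = np.abs(wheel.velocity)
    n = max(int(round(smooth_s / wheel.dt)), 1)
    kernel = np.ones(n) / n
    smoothed = np.convolve(speed, kernel, mode="same")
    drive = np.interp(frame_times, wheel.times, smoothed)
    peak = drive.max()
    return drive / peak if peak > 0 else drive


def simulate_widefield(
    session: SessionRecord,
    truth: Optional[SyntheticWidefieldTruth] = None,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    frame_rate: float = 70.0,
    duration: Optional[float] = None,
) -> tuple[FrameStack, SyntheticWidefieldTruth]:
    """Render an interleaved blue/violet stack for a simulated session.

    Returns the stack and the truth object with the realized visual and
    movement temporal traces filled in (on the blue frame grid) for
    recovery tests.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if truth is None:
        truth = default_widefield_truth()
    if duration is None:
        duration = session.wheel.duration
    n_frames = int(round(duration * frame_rate))
    frame_times = np.arange(n_frames) / frame_rate
    illumination = np.where(np.arange(n_frames) % 2 == 0, "blue", "violet")

    stim_onsets = np.array([t.stim_onset for t in session.trials])
    visual = truth.visual_amplitude * _alpha_response(frame_times, stim_onsets, truth.visual_tau)
    motor = truth.motor_amplitude * _movement_drive(session.wheel, frame_times)
    heartbeat = np.sin(2 * np.pi * truth.heartbeat_freq * frame_times) * (
        1.0 + 0.3 * np.sin(2 * np.pi * 0.1 * frame_times)
    )

    rows, cols = truth.shape
    vis_map = truth.visual_map.ravel()
    mot_map = truth.motor_map.ravel()
    hb_map = truth.heartbeat_gain_map.ravel()

    blue_sel = illumination == "blue"
    pix = np.empty((n_frames, rows * cols), dtype=np.float32)
    pix[:] = truth.baseline
    pix[blue_sel] += np.outer(visual[blue_sel], vis_map) + np.outer(motor[blue_sel], mot_map)
    gains = np.where(blue_sel, truth.heartbeat_gain_blue, truth.heartbeat_gain_violet)
    pix += np.outer(gains * heartbeat, hb_map)
    if truth.noise_scale > 0:
        pix += rng.normal(0.0, truth.noise_scale, size=pix.shape).astype(np.float32)

    stack = FrameStack(
        frames=pix.reshape(n_frames, rows, cols),
        frame_times=frame_times,
        illumination=illumination,
    )
    truth.visual_trace = visual[blue_sel]
    truth.motor_trace = motor[blue_sel]
    truth.frame_times = frame_times[blue_sel]
    return stack, truth
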