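"""Widefield fluorescence processing chain.

Mesoscale calcium imaging of the dorsal cortex is acquired with alternating
blue (calcium-dependent) and violet (calcium-invariant, hemodynamic)
illumination at 35 Hz per channel.  The stages implemented here follow the
standard chain for such data:

1. SVD compression (``svd_compress``) — movies are factored as
   ``F = U S Vt`` and all temporal (orthogonally invariant) operations act
   on the small ``S*V`` matrix instead of the pixel movie.
2. Hemodynamic correction (``hemodynamic_correct``) — a per-pixel scaling
   of the violet channel, regressed on 5-15 Hz band-passed signals where
   the heartbeat artifact dominates, is subtracted from the blue channel.
3. ΔF/F₀ normalization (``normalize_dff``) with linear detrend and a
   0.01 Hz high-pass; F₀ is softened by the median F₀ across pixels.
4. Linear deconvolution (``deconvolve``) of the calcium indicator with a
   supplied kernel (frequency-domain division, Tikhonov-regularized).
5. Cross-recording recasting (``recast_to_master``) into a shared spatial
   basis, within-animal rigid alignment on vasculature edges
   (``align_days``), the movement-weighted hemisphere subtraction
   (``fit_hemisphere_ratio`` / ``hemisphere_subtract``), and retinotopic
   visual-field-sign mapping (``field_sign_map``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "FrameStack",
    "SVDComponents",
    "HemoModel",
    "DffTrace",
    "DeconvKernel",
    "HemisphereModel",
    "FieldSignMap",
    "RigidTransform",
    "svd_compress",
    "hemodynamic_correct",
    "normalize_dff",
    "deconvolve",
    "recast_to_master",
    "align_days",
    "fit_hemisphere_ratio",
    "hemisphere_subtract",
    "field_sign_map",
    "roi_trace",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class FrameStack:
    """Interleaved two-wavelength image stack.

    ``frames`` has shape ``(n_frames, rows, cols)``; ``illumination`` holds
    the per-frame label (``'blue'`` / ``'violet'``) and must strictly
    alternate; ``frame_times`` must strictly increase.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    illumination: np.ndarray
    um_per_pixel: float = 20.6

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.illumination = np.asarray(self.illumination)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, rows, cols)")
        n = self.frames.shape[0]
        if self.frame_times.shape != (n,) or self.illumination.shape != (n,):
            raise ValueError("frame_times and illumination must match frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if n > 1 and np.any(self.illumination[1:] == self.illumination[:-1]):
            raise ValueError("illumination labels must strictly alternate")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def channel(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(pixels x time matrix, frame times)`` for one channel."""
        sel = self.illumination == label
        if not sel.any():
            raise ValueError(f"no frames with illumination {label!r}")
        sub = self.frames[sel]
        return sub.reshape(sub.shape[0], -1).T.astype(float), self.frame_times[sel]


@dataclass
class SVDComponents:
    """Truncated SVD of a pixels x time fluorescence matrix."""

    U: np.ndarray  # pixels x k
    sv: np.ndarray  # k x time  (S * Vt)
    singular_values: np.ndarray
    shape: Optional[tuple[int, int]] = None  # (rows, cols) of the pixel space
    frame_times: Optional[np.ndarray] = None

    @property
    def k(self) -> int:
        return self.U.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.U @ self.sv

    def with_sv(self, sv: np.ndarray) -> "SVDComponents":
        return SVDComponents(
            U=self.U,
            sv=sv,
            singular_values=self.singular_values,
            shape=self.shape,
            frame_times=self.frame_times,
        )


@dataclass
class HemoModel:
    """Per-pixel violet-to-blue scaling used for hemodynamic correction."""

    scale: np.ndarray  # (rows, cols)
    band: tuple[float, float] = (5.0, 15.0)
    downsample: int = 3


@dataclass
class DffTrace:
    """ΔF/F₀-normalized traces with the baseline and softening used."""

    dff: np.ndarray  # pixels x time
    f0: np.ndarray  # per-pixel session-mean fluorescence
    softening: float  # median of f0 across pixels


@dataclass
class DeconvKernel:
    """Calcium-indicator impulse response consumed by ``deconvolve``."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("kernel must be finite")

    def resampled(self, rate: float) -> "DeconvKernel":
        if np.isclose(rate, self.sample_rate):
            return self
        t_old = np.arange(self.samples.size) / self.sample_rate
        t_new = np.arange(int(np.floor(t_old[-1] * rate)) + 1) / rate
        return DeconvKernel(np.interp(t_new, t_old, self.samples), rate)


@dataclass
class HemisphereModel:
    """Fitted left/right movement-gain ratio for hemisphere subtraction."""

    ratio: float  # m_L / m_R: scale applied to the right-hemisphere trace
    residual: float  # relative LSQ residual of the epoch-average fit
    n_epochs: int

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("fitted ratio must be positive")


@dataclass
class FieldSignMap:
    """Retinotopic maps and the visual field sign derived from them."""

    sign_map: np.ndarray  # in [-1, 1] (nan where unresponsive)
    azimuth_map: np.ndarray  # deg, response-weighted center of mass
    elevation_map: np.ndarray  # deg
    n_boot: int = 10
    smoothing_sigma: float = 2.0
    #: time window (s after square onset) the input responses were averaged in
    response_window: tuple[float, float] = (0.3, 0.5)


@dataclass
class RigidTransform:
    """Rotation (deg, about the image center) then translation (rows, cols)."""

    angle: float
    shift: tuple[float, float]

    def apply(self, image: np.ndarray) -> np.ndarray:
        from skimage.transform import rotate

        out = rotate(image, self.angle, preserve_range=True, order=1)
        return ndimage.shift(out, self.shift, order=1, mode="constant")


# ---------------------------------------------------------------------------
# compression


def svd_compress(
    matrix: np.ndarray,
    k: int = 2000,
    shape: Optional[tuple[int, int]] = None,
    frame_times: Optional[np.ndarray] = None,
) -> SVDComponents:
    """Truncated SVD of a ``pixels x time`` matrix, keeping ``k`` components.

    The default of 2000 retained components matches typical full-session
    recordings; tests and simulations use far fewer.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("input must be a pixels x time matrix")
    if not 1 <= k <= min(matrix.shape):
        if k > min(matrix.shape):
            k = min(matrix.shape)
        else:
            raise ValueError("k must be at least 1")
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    return SVDComponents(
        U=u[:, :k],
        sv=s[:k, None] * vt[:k],
        singular_values=s[:k],
        shape=shape,
        frame_times=frame_times,
    )


# ---------------------------------------------------------------------------
# hemodynamic correction


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float, order: int = 3) -> np.ndarray:
    nyq = fs / 2.0
    if not 0 < band[0] < band[1] < nyq:
        raise ValueError(f"band {band} must lie within (0, Nyquist={nyq:.2f})")
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def _interp_onto(times_src: np.ndarray, values: np.ndarray, times_dst: np.ndarray) -> np.ndarray:
    """Linear sub-sample interpolation of (pixels x t_src) onto a new time grid."""
    idx = np.clip(np.searchsorted(times_src, times_dst) - 1, 0, times_src.size - 2)
    t0, t1 = times_src[idx], times_src[idx + 1]
    w = np.clip((times_dst - t0) / (t1 - t0), 0.0, 1.0)
    return values[:, idx] * (1 - w) + values[:, idx + 1] * w


def _block_mean(image_stack: np.ndarray, factor: int) -> np.ndarray:
    """Spatial block-mean of (rows, cols, t), cropping to a multiple of factor."""
    r, c = image_stack.shape[:2]
    r2, c2 = (r // factor) * factor, (c // factor) * factor
    x = image_stack[:r2, :c2]
    x = x.reshape(r2 // factor, factor, c2 // factor, factor, -1)
    return x.mean(axis=(1, 3))


def hemodynamic_correct(
    blue: np.ndarray,
    violet: np.ndarray,
    blue_times: np.ndarray,
    violet_times: np.ndarray,
    shape: tuple[int, int],
    band: tuple[float, float] = (5.0, 15.0),
    downsample: int = 3,
) -> tuple[np.ndarray, HemoModel]:
    """Remove blood-volume artifacts from the blue channel.

    The violet channel is sub-sample shifted onto the blue time grid, both
    channels are spatially downsampled and band-passed 5-15 Hz (the
    heartbeat band) for fitting, and a per-pixel scaling from violet to blue
    is regressed (ordinary least squares, no intercept).  The *unfiltered*,
    mean-removed, scaled violet signal is then subtracted from the blue
    signal, so the blue baseline (needed downstream for F₀) is preserved.
    """
    blue = np.asarray(blue, dtype=float)
    violet = np.asarray(violet, dtype=float)
    if blue.shape[0] != violet.shape[0]:
        raise ValueError("blue and violet must share the pixel dimension")
    if blue.shape[1] != blue_times.size or violet.shape[1] != violet_times.size:
        raise ValueError("trace lengths must match their time vectors")
    n_pix = blue.shape[0]
    if n_pix != shape[0] * shape[1]:
        raise ValueError("shape does not match the pixel dimension")

    fs = 1.0 / float(np.median(np.diff(blue_times)))
    violet_shifted = _interp_onto(violet_times, violet, blue_times)

    b_img = blue.reshape(*shape, -1)
    v_img = violet_shifted.reshape(*shape, -1)
    b_ds = _block_mean(b_img, downsample).reshape(-1, blue.shape[1])
    v_ds = _block_mean(v_img, downsample).reshape(-1, blue.shape[1])

    b_f = _bandpass(b_ds, band, fs)
    v_f = _bandpass(v_ds, band, fs)
    v_power = np.sum(v_f * v_f, axis=1)
    silent = v_power < 1e-12 * max(np.max(v_power), 1.0)
    if silent.all():
        warnings.warn("violet channel carries no band-limited signal; no correction applied")
    with np.errstate(divide="ignore", invalid="ignore"):
        slope_ds = np.where(silent, 0.0, np.sum(b_f * v_f, axis=1) / np.maximum(v_power, 1e-30))

    r_ds, c_ds = shape[0] // downsample, shape[1] // downsample
    slope_img = slope_ds.reshape(r_ds, c_ds)
    slope_full = np.repeat(np.repeat(slope_img, downsample, axis=0), downsample, axis=1)
    pad_r, pad_c = shape[0] - slope_full.shape[0], shape[1] - slope_full.shape[1]
    slope_full = np.pad(slope_full, ((0, pad_r), (0, pad_c)), mode="edge")

    scale = slope_full.reshape(-1, 1)
    violet_centered = violet_shifted - violet_shifted.mean(axis=1, keepdims=True)
    corrected = blue - scale * violet_centered
    return corrected, HemoModel(scale=slope_full, band=band, downsample=downsample)


# ---------------------------------------------------------------------------
# normalization and deconvolution


def normalize_dff(
    traces: np.ndarray,
    fs: float,
    highpass_hz: float = 0.01,
    detrend: bool = True,
) -> DffTrace:
    """Linear detrend, 0.01 Hz high-pass, and softened ΔF/F₀ normalization.

    F₀ is the per-pixel session mean of the raw input; the denominator is
    softened additively by the median of F₀ across pixels, which keeps dark
    pixels from exploding and maps an all-zero input to zero output.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    f0 = traces.mean(axis=1)
    softening = float(np.median(f0))

    x = signal.detrend(traces, axis=1, type="linear") if detrend else traces - f0[:, None]
    if highpass_hz and highpass_hz > 0:
        sos = signal.butter(2, highpass_hz, btype="highpass", fs=fs, output="sos")
        padlen = min(x.shape[1] - 1, 3 * (2 * 2 + 1))
        x = signal.sosfiltfilt(sos, x, axis=1, padlen=padlen)
    x = x - x.mean(axis=1, keepdims=True)

    denom = f0 + softening
    bad = denom <= 0
    if bad.any():
        warnings.warn("non-positive baseline fluorescence; affected pixels set to zero")
        denom = np.where(bad, 1.0, denom)
        x = np.where(bad[:, None], 0.0, x)
    return DffTrace(dff=x / denom[:, None], f0=f0, softening=softening)


def deconvolve(
    traces: np.ndarray,
    kernel: DeconvKernel,
    fs: float,
    lam: float = 1e-3,
) -> np.ndarray:
    """Regularized inverse filtering of the calcium-indicator dynamics.

    Frequency-domain division ``X = Y K* / (|K|^2 + lam * max|K|^2)``
    applied along time; because the operation is linear it can act on the
    ``S*V`` temporal components with results identical to pixel space.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    k = kernel.resampled(fs).samples
    if k.size == 0:
        raise ValueError("empty kernel")
    n = traces.shape[1] + k.size
    kf = np.fft.rfft(k, n)
    power = np.abs(kf) ** 2
    reg = lam * power.max() if lam > 0 else 0.0
    yf = np.fft.rfft(traces, n, axis=1)
    xf = yf * np.conj(kf) / (power + reg)
    x = np.fft.irfft(xf, n, axis=1)[:, : traces.shape[1]]
    return x


# ---------------------------------------------------------------------------
# cross-recording recasting and alignment


def recast_to_master(
    u_master: np.ndarray, u_experiment: np.ndarray, sv_experiment: np.ndarray
) -> np.ndarray:
    """Recast experiment temporal components into a master spatial basis.

    ``SV_recast = U_masterᵀ · U_experiment · SV_experiment``; after
    recasting, recordings from different sessions share the master basis
    and their temporal components can be averaged directly.
    """
    u_master = np.asarray(u_master, dtype=float)
    u_experiment = np.asarray(u_experiment, dtype=float)
    sv_experiment = np.asarray(sv_experiment, dtype=float)
    if u_master.shape[0] != u_experiment.shape[0]:
        raise ValueError("master and experiment bases must share the pixel space")
    if u_experiment.shape[1] != sv_experiment.shape[0]:
        raise ValueError("U_experiment and SV_experiment are incompatible")
    return u_master.T @ (u_experiment @ sv_experiment)


def _edge_map(image: np.ndarray, blur_sigma: float) -> np.ndarray:
    """Vasculature edge image: raw minus its gaussian blur (unsharp mask)."""
    return image - ndimage.gaussian_filter(image, blur_sigma)


def align_days(
    mean_images: Sequence[np.ndarray],
    blur_sigma: float = 4.0,
    angle_range: float = 5.0,
    angle_step: float = 0.5,
    upsample_factor: int = 20,
) -> list[RigidTransform]:
    """Rigid within-animal alignment of daily mean images on vasculature edges.

    The first image is the reference.  For each other day, rotation is
    searched on a coarse grid then refined, with the translation at each
    angle found by phase cross-correlation of the edge maps; the transform
    maximizing edge-map correlation wins, ties broken by the smallest
    displacement.
    """
    from skimage.registration import phase_cross_correlation
    from skimage.transform import rotate

    images = [np.asarray(im, dtype=float) for im in mean_images]
    ref = images[0]
    if np.ptp(ref) == 0:
        raise ValueError("reference image is flat; cannot align")
    ref_edge = _edge_map(ref, blur_sigma)

    def evaluate(mov_edge: np.ndarray, angle: float):
        rot = rotate(mov_edge, angle, preserve_range=True, order=1)
        shift, _, _ = phase_cross_correlation(
            ref_edge, rot, upsample_factor=upsample_factor, normalization=None
        )
        reg = ndimage.shift(rot, shift, order=1, mode="constant")
        denom = ref_edge.std() * reg.std()
        score = float(np.mean((ref_edge - ref_edge.mean()) * (reg - reg.mean())) / denom) if denom else -1.0
        return score, (float(shift[0]), float(shift[1]))

    transforms = [RigidTransform(0.0, (0.0, 0.0))]
    for im in images[1:]:
        if np.ptp(im) == 0:
            raise ValueError("degenerate (flat) image cannot be aligned")
        mov_edge = _edge_map(im, blur_sigma)
        candidates = []
        for angle in np.arange(-angle_range, angle_range + angle_step / 2, angle_step):
            score, shift = evaluate(mov_edge, angle)
            candidates.append((score, angle, shift))
        best = max(candidates, key=lambda c: (c[0], -abs(c[1]), -np.hypot(*c[2])))
        fine = np.arange(best[1] - angle_step, best[1] + angle_step + 1e-9, angle_step / 5)
        for angle in fine:
            score, shift = evaluate(mov_edge, angle)
            candidates.append((score, angle, shift))
        score, angle, shift = max(candidates, key=lambda c: (c[0], -np.hypot(*c[2]), -abs(c[1])))
        transforms.append(RigidTransform(float(angle), shift))
    return transforms


# ---------------------------------------------------------------------------
# hemisphere-weighted subtraction


def fit_hemisphere_ratio(
    left_trace: np.ndarray,
    right_trace: np.ndarray,
    movement_onsets: Sequence[int],
    window: tuple[int, int] = (0, 30),
    days: Optional[Sequence] = None,
    min_epochs: int = 3,
) -> HemisphereModel:
    """Fit the left/right movement-gain ratio from stimulus-free movements.

    Epoch windows (sample indices ``onset+window[0] .. onset+window[1]``)
    around qualifying delay-period movements are averaged within day, then
    across days, and a least-squares scale from the right- to the
    left-hemisphere average is fitted.  Because movement-evoked activity is
    bilateral while visual activity is unilateral, this ratio lets the
    movement component be cancelled by a weighted hemisphere difference.
    """
    left_trace = np.asarray(left_trace, dtype=float)
    right_trace = np.asarray(right_trace, dtype=float)
    onsets = np.asarray(movement_onsets, dtype=int)
    w0, w1 = window
    valid = (onsets + w0 >= 0) & (onsets + w1 <= left_trace.size)
    onsets = onsets[valid]
    if onsets.size < min_epochs:
        raise ValueError(
            f"only {onsets.size} qualifying movement epochs (< {min_epochs}); cannot fit ratio"
        )
    day_labels = np.zeros(onsets.size, dtype=int) if days is None else np.asarray(days)[valid]

    def epoch_avg(trace):
        segs = np.stack([trace[o + w0 : o + w1] for o in onsets])
        day_means = [segs[day_labels == d].mean(axis=0) for d in np.unique(day_labels)]
        return np.mean(day_means, axis=0)

    l_avg, r_avg = epoch_avg(left_trace), epoch_avg(right_trace)
    denom = float(r_avg @ r_avg)
    if denom <= 0:
        raise ValueError("right-hemisphere epoch average is identically zero")
    ratio = float(l_avg @ r_avg) / denom
    resid = float(np.linalg.norm(l_avg - ratio * r_avg) / max(np.linalg.norm(l_avg), 1e-30))
    return HemisphereModel(ratio=ratio, residual=resid, n_epochs=int(onsets.size))


def hemisphere_subtract(
    left_trace: np.ndarray, right_trace: np.ndarray, model: HemisphereModel
) -> np.ndarray:
    """Movement-weighted hemisphere difference ``F_L - (m_L/m_R) F_R``.

    With the fitted ratio exact, the bilateral movement component cancels
    and the output is proportional to the unilateral visual signal; positive
    values mean more left-hemisphere activity.
    """
    return np.asarray(left_trace, dtype=float) - model.ratio * np.asarray(right_trace, dtype=float)


# ---------------------------------------------------------------------------
# retinotopy: visual field sign


def _com_maps(
    responses: np.ndarray,
    positions: np.ndarray,
    smoothing_sigma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Response-weighted center-of-mass azimuth/elevation maps.

    ``responses``: (n_squares, rows, cols) mean response to each square;
    negative responses are clipped to zero before weighting.
    """
    smoothed = np.stack(
        [ndimage.gaussian_filter(r, smoothing_sigma) for r in responses]
    )
    w = np.clip(smoothed, 0.0, None)
    total = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        az = np.tensordot(positions[:, 0], w, axes=1) / total
        el = np.tensordot(positions[:, 1], w, axes=1) / total
    return az, el


def _sign_from_com(az_map: np.ndarray, el_map: np.ndarray) -> np.ndarray:
    gaz_r, gaz_c = np.gradient(az_map)
    gel_r, gel_c = np.gradient(el_map)
    angle_az = np.arctan2(gaz_r, gaz_c)
    angle_el = np.arctan2(gel_r, gel_c)
    return np.sin(angle_el - angle_az)


def field_sign_map(
    square_responses: np.ndarray,
    square_positions: np.ndarray,
    n_boot: int = 10,
    smoothing_sigma: float = 2.0,
    seed=None,
    rng: Optional[np.random.Generator] = None,
) -> FieldSignMap:
    """Visual field sign from sparse-noise square responses.

    ``square_responses``: (n_presentations, rows, cols) response of every
    cortical pixel to each square presentation (already averaged in the
    response window); ``square_positions``: (n_presentations, 2) azimuth and
    elevation of each presented square, degrees.  Per bootstrap (presenta-
    tions resampled with replacement), per-square mean responses are
    gaussian-smoothed, a response-weighted center of mass gives per-pixel
    azimuth/elevation maps, and the sign is the sine of the angle between
    the elevation and azimuth gradients; bootstraps are averaged.

    Orientation convention: with azimuth represented along increasing image
    columns and elevation along increasing image rows (a non-mirror
    representation), the sign is +1; a mirror image of that map gives -1.
    """
    responses = np.asarray(square_responses, dtype=float)
    positions = np.asarray(square_positions, dtype=float)
    if responses.ndim != 3 or positions.shape != (responses.shape[0], 2):
        raise ValueError("need (n_pres, rows, cols) responses and (n_pres, 2) positions")
    uniq = np.unique(positions, axis=0)
    if uniq.shape[0] < 4:
        raise ValueError("too few distinct square positions for gradient mapping")
    rng = np.random.default_rng(seed) if rng is None else rng

    keys = {tuple(p): i for i, p in enumerate(uniq)}
    labels = np.array([keys[tuple(p)] for p in positions])

    def per_square_means(idx):
        sums = np.zeros((uniq.shape[0], *responses.shape[1:]))
        counts = np.zeros(uniq.shape[0])
        np.add.at(sums, labels[idx], responses[idx])
        np.add.at(counts, labels[idx], 1.0)
        counts = np.maximum(counts, 1.0)
        return sums / counts[:, None, None]

    signs = []
    for _ in range(n_boot):
        idx = rng.integers(0, responses.shape[0], size=responses.shape[0])
        az, el = _com_maps(per_square_means(idx), uniq, smoothing_sigma)
        signs.append(_sign_from_com(az, el))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sign = np.nanmean(np.stack(signs), axis=0)

    az_full, el_full = _com_maps(per_square_means(np.arange(responses.shape[0])), uniq, smoothing_sigma)
    return FieldSignMap(
        sign_map=sign,
        azimuth_map=az_full,
        elevation_map=el_full,
        n_boot=n_boot,
        smoothing_sigma=smoothing_sigma,
    )


# ---------------------------------------------------------------------------
# ROI extraction


def roi_trace(u: np.ndarray, sv: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean trace over an ROI, computed in component space.

    ``mean_roi(U rows) @ SV`` equals the pixel-space reconstruction averaged
    over the mask, by linearity.
    """
    u = np.asarray(u, dtype=float)
    mask = np.asarray(mask, dtype=bool).ravel()
    if mask.size != u.shape[0]:
        raise ValueError("mask does not match the pixel dimension of U")
    if not mask.any():
        raise ValueError("empty ROI mask")
    return u[mask].mean(axis=0) @ sv
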