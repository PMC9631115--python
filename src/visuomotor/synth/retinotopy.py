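"""Retinotopy phantoms: sparse-noise square responses with known field sign.

Each cortical pixel is assigned a preferred visual-field location through a
smooth (linear) retinotopic map; its response to a presented square is a
Gaussian receptive field evaluated at the square's position, plus optional
noise.  Mirrored areas reverse the azimuth progression, flipping the
visual field sign, so the field-sign pipeline has an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["RetinotopyPhantom", "simulate_retinotopy"]


@dataclass
class RetinotopyPhantom:
    """Ground-truth retinotopic mapping for a set of cortical areas.

    ``areas`` is a list of ``(col_slice, mirrored)`` pairs splitting the
    image into vertical bands; within each band azimuth varies linearly
    with the column (reversed when mirrored) and elevation with the row.
    """

    shape: tuple[int, int] = (24, 36)
    azimuth_range: tuple[float, float] = (0.0, 90.0)
    elevation_range: tuple[float, float] = (0.0, 60.0)
    areas: Sequence[tuple[slice, bool]] = field(default_factory=lambda: [(slice(None), False)])

    def maps(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-pixel (azimuth, elevation, area_id) ground-truth maps."""
        rows, cols = self.shape
        az = np.empty(self.shape)
        area_id = np.empty(self.shape, dtype=int)
        el_col = np.linspace(*self.elevation_range, rows)
        el = np.tile(el_col[:, None], (1, cols))
        for i, (col_slice, mirrored) in enumerate(self.areas):
            idx = np.arange(cols)[col_slice]
            ramp = np.linspace(*self.azimuth_range, idx.size)
            if mirrored:
                ramp = ramp[::-1]
            az[:, idx] = ramp[None, :]
            area_id[:, idx] = i
        return az, el, area_id

    @property
    def expected_signs(self) -> list[float]:
        """Field-sign oracle per area: +1 non-mirror, -1 mirrored."""
        return [-1.0 if mirrored else 1.0 for _, mirrored in self.areas]


def two_area_phantom(shape: tuple[int, int] = (24, 48), border_col: Optional[int] = None) -> RetinotopyPhantom:
    """A non-mirror area abutting its mirror image at ``border_col``."""
    border = shape[1] // 2 if border_col is None else border_col
    return RetinotopyPhantom(
        shape=shape,
        areas=[(slice(0, border), False), (slice(border, shape[1]), True)],
    )


def simulate_retinotopy(
    phantom: Optional[RetinotopyPhantom] = None,
    n_azimuth: int = 10,
    n_elevation: int = 7,
    n_repeats: int = 3,
    rf_sigma: float = 12.0,
    noise: float = 0.0,
    seed=None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray, RetinotopyPhantom]:
    """Per-presentation mean responses to a grid of sparse-noise squares.

    Returns ``(responses, positions, phantom)`` where ``responses`` has
    shape ``(n_presentations, rows, cols)`` and ``positions`` gives the
    (azimuth, elevation) of each presentation in degrees.  Presentations
    cycle the full square grid ``n_repeats`` times in random order.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if phantom is None:
        phantom = RetinotopyPhantom()
    az_map, el_map, _ = phantom.maps()

    az_grid = np.linspace(*phantom.azimuth_range, n_azimuth)
    el_grid = np.linspace(*phantom.elevation_range, n_elevation)
    grid = np.array([(a, e) for a in az_grid for e in el_grid])
    order = np.concatenate([rng.permutation(grid.shape[0]) for _ in range(n_repeats)])
    positions = grid[order]

    d2 = (az_map[None] - positions[:, 0, None, None]) ** 2 + (
        el_map[None] - positions[:, 1, None, None]
    ) ** 2
    responses = np.exp(-d2 / (2 * rf_sigma**2))
    if noise > 0:
        responses = responses + rng.normal(0.0, noise, size=responses.shape)
    return responses, positions, phantom
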