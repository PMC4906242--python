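"""Render per-bouton fluorescence time courses into noisy 16-bit image stacks.

Boutons are Gaussian spots with unit-sum kernels, so the noiseless integrated
intensity of a spot at frame t is exactly ``amplitude * f(t)``.  Noise is
Poisson (gain-scaled photon counting) plus additive Gaussian read noise;
optional whole-frame integer stage drift and per-bouton linear baseline drift
emulate the artifacts the analysis stages must correct or reject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, model_validator

__all__ = ["RenderParams", "RenderedField", "place_boutons", "render_movie"]


class RenderParams(BaseModel):
    image_size: tuple[int, int] = (256, 256)
    psf_sigma: float = 1.5  # px
    expression_median: float = 20000.0  # integrated counts at f = 1
    expression_lognorm_sigma: float = 0.5
    background_level: float = 20.0  # counts
    gain: float = 1.0  # counts per photon; 0 disables Poisson noise
    read_noise_sd: float = 3.0  # counts; 0 disables read noise
    min_distance: float = 8.0  # px, center-to-center
    stage_drift: list[tuple[int, int, int]] = []  # (frame, dx, dy) applied from frame on
    baseline_drift_slope: float = 0.0  # counts/s added to drifting boutons
    drift_bouton_fraction: float = 0.0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "RenderParams":
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if min(self.image_size) < int(np.ceil(6 * self.psf_sigma)) + 2:
            raise ValueError("image too small for psf_sigma margin")
        if self.gain < 0 or self.read_noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0 <= self.drift_bouton_fraction <= 1:
            raise ValueError("drift_bouton_fraction must be in [0, 1]")
        return self


@dataclass
class RenderedField:
    """One rendered movie with its per-bouton ground truth."""

    stack: np.ndarray  # (T, H, W) uint16
    positions: np.ndarray  # (B, 2) float, (row, col)
    amplitudes: np.ndarray  # (B,) integrated counts at f = 1
    traces: np.ndarray  # (B, T) noiseless fluorescent fractions used
    drift_boutons: np.ndarray  # bool mask of boutons given baseline drift
    shifts: np.ndarray  # (T, 2) applied integer (drow, dcol) per frame


def place_boutons(
    n: int,
    render: RenderParams,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> np.ndarray:
    """Sample (row, col) centers >= 3*psf_sigma from edges with a minimum spacing."""
    h, w = render.image_size
    margin = 3.0 * render.psf_sigma
    pos: list[np.ndarray] = []
    tries = 0
    while len(pos) < n:
        if tries > max_tries * max(n, 1):
            raise RuntimeError(
                f"could not place {n} boutons at min_distance={render.min_distance} "
                f"in a {h}x{w} field"
            )
        tries += 1
        p = np.array(
            [rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin)]
        )
        if all(np.hypot(*(p - q)) >= render.min_distance for q in pos):
            pos.append(p)
    return np.asarray(pos).reshape(n, 2)


def _spot_kernel(pos: np.ndarray, sigma: float, shape: tuple[int, int]):
    """Unit-sum Gaussian patch around pos; returns (rows, cols, weights)."""
    r0, c0 = pos
    half = int(np.ceil(4 * sigma))
    rows = np.arange(max(0, int(round(r0)) - half), min(shape[0], int(round(r0)) + half + 1))
    cols = np.arange(max(0, int(round(c0)) - half), min(shape[1], int(round(c0)) + half + 1))
    g = np.exp(-((rows[:, None] - r0) ** 2 + (cols[None, :] - c0) ** 2) / (2 * sigma**2))
    g /= g.sum()
    return rows, cols, g


def _integer_shift(frame: np.ndarray, drow: int, dcol: int, fill: float) -> np.ndarray:
    """Translate a frame by whole pixels, filling exposed edges."""
    out = np.full_like(frame, fill)
    h, w = frame.shape
    rs, re = max(0, drow), min(h, h + drow)
    cs, ce = max(0, dcol), min(w, w + dcol)
    out[rs:re, cs:ce] = frame[rs - drow : re - drow, cs - dcol : ce - dcol]
    return out


def render_movie(
    traces: np.ndarray,
    render: RenderParams,
    rng: np.random.Generator,
    positions: np.ndarray | None = None,
    amplitudes: np.ndarray | None = None,
    frame_interval: float = 2.0,
    quantize: bool = True,
) -> RenderedField:
    """Render bouton traces (B, T array of fluorescent fractions) to a stack.

    Deterministic for a fixed ``rng`` state.  ``stage_drift`` entries
    (frame, dx, dy) are cumulative whole-frame shifts applied from the given
    frame onward (x = column, y = row).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_boutons, n_frames = traces.shape
    h, w = render.image_size

    if positions is None:
        positions = place_boutons(n_boutons, render, rng)
    else:
        positions = np.asarray(positions, dtype=float).reshape(n_boutons, 2)
    if amplitudes is None:
        amplitudes = render.expression_median * np.exp(
            rng.normal(0.0, render.expression_lognorm_sigma, size=n_boutons)
        )
    amplitudes = np.asarray(amplitudes, dtype=float)

    drift_mask = np.zeros(n_boutons, dtype=bool)
    if render.drift_bouton_fraction > 0 and render.baseline_drift_slope != 0:
        k = int(round(render.drift_bouton_fraction * n_boutons))
        drift_mask[rng.choice(n_boutons, size=k, replace=False)] = True

    kernels = [_spot_kernel(p, render.psf_sigma, (h, w)) for p in positions]

    # cumulative per-frame shifts
    shifts = np.zeros((n_frames, 2), dtype=int)
    for frame, dx, dy in render.stage_drift:
        shifts[frame:] += (dy, dx)  # stored as (drow, dcol)

    stack = np.empty((n_frames, h, w), dtype=np.uint16 if quantize else np.float64)
    for t in range(n_frames):
        img = np.full((h, w), float(render.background_level))
        for b, (rows, cols, g) in enumerate(kernels):
            amp = amplitudes[b] * traces[b, t]
            if drift_mask[b]:
                amp += render.baseline_drift_slope * t * frame_interval
            img[np.ix_(rows, cols)] += amp * g
        if render.gain > 0:
            img = rng.poisson(np.maximum(img, 0.0) / render.gain) * render.gain
        if render.read_noise_sd > 0:
            img = img + rng.normal(0.0, render.read_noise_sd, size=img.shape)
        drow, dcol = shifts[t]
        if drow or dcol:
            img = _integer_shift(img, drow, dcol, float(render.background_level))
        stack[t] = np.clip(np.round(img), 0, 65535).astype(np.uint16) if quantize else img

    return RenderedField(
        stack=stack,
        positions=positions,
        amplitudes=amplitudes,
        traces=traces,
        drift_boutons=drift_mask,
        shifts=shifts,
    )
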