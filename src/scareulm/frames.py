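"""Image-domain synthesis of ULM-like frame sequences.

Bubbles are rendered as Gaussian point-spread blobs (FWHM ~ one wavelength)
at their ground-truth in-plane positions, on top of a low-rank tissue/skull
clutter background (a configurable number of static spatial patterns, each
slowly modulated below 5 Hz to mimic injected skull motion) plus white
noise.  This replaces RF-level simulation and beamforming with a surrogate
that exercises the same SVD -> localization -> tracking -> HMM chain.

The in-plane coordinates are (x, z): x maps to columns, z to rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .flow import BubbleTransit

WAVELENGTH_UM_DEFAULT = 150.0        # ~10 MHz in soft tissue


@dataclass
class FrameStack:
    """Frame sequence (rows x cols x time) with acquisition metadata."""

    frames: np.ndarray
    pixel_pitch_um: float
    frame_rate_hz: float
    wavelength_um: float = WAVELENGTH_UM_DEFAULT
    origin_um: tuple[float, float] = (0.0, 0.0)   # (x0, z0) of pixel (0, 0)
    t0_s: float = 0.0
    n_clipped: int = 0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    def frame_times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) / self.frame_rate_hz

    def pixel_to_um(self, row, col):
        x0, z0 = self.origin_um
        return (x0 + np.asarray(col) * self.pixel_pitch_um,
                z0 + np.asarray(row) * self.pixel_pitch_um)

    def um_to_pixel(self, x_um, z_um):
        x0, z0 = self.origin_um
        return ((np.asarray(z_um) - z0) / self.pixel_pitch_um,
                (np.asarray(x_um) - x0) / self.pixel_pitch_um)


@dataclass
class CasoratiMatrix:
    """Space x time view: column t is frame t flattened in raster order."""

    matrix: np.ndarray               # (n_pixels, n_frames)
    frame_shape: tuple[int, int]

    @property
    def ensemble_size(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]


def slow_time_courses(rank: int, n_frames: int, frame_rate_hz: float,
                      rng: np.random.Generator, min_freq_hz: float = 1.0,
                      max_freq_hz: float = 4.8,
                      modulation: float = 0.1) -> np.ndarray:
    """(rank, n_frames) clutter time courses: 1 + slow oscillation.

    Each course is an independent sum of three sub-5 Hz sinusoids scaled to
    unit peak, so the clutter matrix keeps numerical rank == ``rank``
    (one time course per spatial pattern).  The lower frequency bound keeps
    the courses linearly well-separated over sub-second ensembles.
    """
    t = np.arange(n_frames) / frame_rate_hz
    courses = np.empty((rank, n_frames))
    for i in range(rank):
        f = rng.uniform(min_freq_hz, max_freq_hz, 3)
        ph = rng.uniform(0, 2 * np.pi, 3)
        a = rng.uniform(0.7, 1.0, 3)
        s = (a[:, None] * np.sin(2 * np.pi * f[:, None] * t + ph[:, None])).sum(0)
        peak = np.abs(s).max()
        courses[i] = 1.0 + modulation * (s / peak if peak > 0 else s)
    return courses


def clutter_patterns(rank: int, shape: tuple[int, int],
                     rng: np.random.Generator,
                     smooth_px: float = 4.0) -> np.ndarray:
    """(rank, rows, cols) smooth random static fields with unit RMS.

    Each field's local envelope is flattened so the clutter covers the
    whole aperture with comparable strength (as skull/tissue clutter does),
    rather than leaving quiet pockets.
    """
    from scipy.ndimage import gaussian_filter
    pats = np.empty((rank,) + tuple(shape))
    for i in range(rank):
        p = gaussian_filter(rng.standard_normal(shape), smooth_px)
        env = np.sqrt(gaussian_filter(p ** 2, 3 * smooth_px))
        p = p / np.clip(env, 0.2 * env.mean(), None)
        pats[i] = p / np.sqrt(np.mean(p ** 2))
    return pats


def render_frames(transits: Sequence[BubbleTransit],
                  fov_um: tuple[float, float] = (1800.0, 1200.0),
                  origin_um: tuple[float, float] = (0.0, 0.0),
                  frame_rate_hz: float = 1000.0,
                  n_frames: int = 1000,
                  t0_s: float = 0.0,
                  wavelength_um: float = WAVELENGTH_UM_DEFAULT,
                  pitch_fraction: float = 1 / 8,
                  clutter_rank: int = 20,
                  clutter_amplitude: float = 30.0,
                  clutter_modulation: float = 0.1,
                  noise_sigma: float = 0.05,
                  bubble_amplitude: float = 1.0,
                  seed: int = 0) -> FrameStack:
    """Render a frame stack from ground-truth transits.

    Each frame is the linear superposition of Gaussian bubble blobs, the
    rank-``clutter_rank`` slowly modulated clutter background, and white
    Gaussian noise; deterministic under ``seed``.  Bubbles outside the field
    of view are clipped silently and counted in ``n_clipped``.
    """
    rng = np.random.default_rng(seed)
    pitch = wavelength_um * pitch_fraction
    cols = int(round(fov_um[0] / pitch))
    rows = int(round(fov_um[1] / pitch))
    stack = np.zeros((rows, cols, n_frames), dtype=np.float32)

    # --- clutter ------------------------------------------------------
    if clutter_rank > 0 and clutter_amplitude != 0.0:
        pats = clutter_patterns(clutter_rank, (rows, cols), rng)
        courses = slow_time_courses(clutter_rank, n_frames, frame_rate_hz, rng,
                                    modulation=clutter_modulation)
        stack += np.einsum("prc,pt->rct", pats, courses,
                           optimize=True).astype(np.float32) * clutter_amplitude

    # --- bubbles ------------------------------------------------------
    sigma_px = (wavelength_um / 2.355) / pitch     # FWHM == one wavelength
    rad = int(np.ceil(3 * sigma_px))
    yy, xx = np.mgrid[-rad:rad + 1, -rad:rad + 1]
    x0, z0 = origin_um
    t_frames = t0_s + np.arange(n_frames) / frame_rate_hz
    n_clipped = 0
    for tr in transits:
        if len(tr.t_s) < 2:
            continue
        k0 = int(np.searchsorted(t_frames, tr.t_s[0], side="left"))
        k1 = int(np.searchsorted(t_frames, tr.t_s[-1], side="right"))
        if k1 <= k0:
            continue
        tk = t_frames[k0:k1]
        xk = np.interp(tk, tr.t_s, tr.position_um[:, 0])
        zk = np.interp(tk, tr.t_s, tr.position_um[:, 2])
        ck = (xk - x0) / pitch
        rk = (zk - z0) / pitch
        for k, (r, c) in enumerate(zip(rk, ck)):
            ri, ci = int(round(r)), int(round(c))
            if ri < -rad or ri >= rows + rad or ci < -rad or ci >= cols + rad:
                n_clipped += 1
                continue
            blob = bubble_amplitude * np.exp(
                -((yy + ri - r) ** 2 + (xx + ci - c) ** 2) / (2 * sigma_px ** 2))
            r_lo, r_hi = max(ri - rad, 0), min(ri + rad + 1, rows)
            c_lo, c_hi = max(ci - rad, 0), min(ci + rad + 1, cols)
            stack[r_lo:r_hi, c_lo:c_hi, k0 + k] += blob[
                r_lo - (ri - rad):blob.shape[0] - ((ri + rad + 1) - r_hi),
                c_lo - (ci - rad):blob.shape[1] - ((ci + rad + 1) - c_hi)]

    # --- noise --------------------------------------------------------
    if noise_sigma > 0:
        stack += rng.normal(0.0, noise_sigma, stack.shape).astype(np.float32)

    return FrameStack(frames=stack, pixel_pitch_um=pitch,
                      frame_rate_hz=frame_rate_hz, wavelength_um=wavelength_um,
                      origin_um=origin_um, t0_s=t0_s, n_clipped=n_clipped)


# ---------------------------------------------------------------------------
# casorati view
# ---------------------------------------------------------------------------

def to_casorati(fs: FrameStack, start: int = 0,
                ensemble_size: int | None = None) -> CasoratiMatrix:
    """Exact reshape of an ensemble into an (n_pixels x n_frames) matrix."""
    if ensemble_size is None:
        ensemble_size = fs.n_frames - start
    if start < 0 or start + ensemble_size > fs.n_frames:
        raise IndexError(
            f"ensemble [{start}, {start + ensemble_size}) exceeds "
            f"stack of {fs.n_frames} frames")
    rows, cols, _ = fs.frames.shape
    sub = fs.frames[:, :, start:start + ensemble_size]
    return CasoratiMatrix(matrix=sub.reshape(rows * cols, ensemble_size),
                          frame_shape=(rows, cols))


def from_casorati(c: CasoratiMatrix) -> np.ndarray:
    """Inverse of :func:`to_casorati` (rows x cols x n_frames array)."""
    rows, cols = c.frame_shape
    return c.matrix.reshape(rows, cols, c.ensemble_size)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_h5(fs: FrameStack, path: str) -> None:
    import h5py
    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=fs.frames, compression="gzip")
        d.attrs.update(pixel_pitch_um=fs.pixel_pitch_um,
                       frame_rate_hz=fs.frame_rate_hz,
                       wavelength_um=fs.wavelength_um,
                       origin_x_um=fs.origin_um[0], origin_z_um=fs.origin_um[1],
                       t0_s=fs.t0_s, n_clipped=fs.n_clipped)


def load_h5(path: str) -> FrameStack:
    import h5py
    with h5py.File(path, "r") as f:
        d = f["frames"]
        a = d.attrs
        return FrameStack(frames=d[...], pixel_pitch_um=float(a["pixel_pitch_um"]),
                          frame_rate_hz=float(a["frame_rate_hz"]),
                          wavelength_um=float(a["wavelength_um"]),
                          origin_um=(float(a["origin_x_um"]), float(a["origin_z_um"])),
                          t0_s=float(a["t0_s"]), n_clipped=int(a["n_clipped"]))
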