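"""SCaRe dwell-time maps, ULM renderings and transit-time statistics.

The SCaRe map accumulates, on a super-resolved grid (default one
thirty-second of a wavelength), the time accepted capillary transits spend
in the decoded low-velocity state: each low-state sample deposits one
frame interval at its nearest pixel, so total dwell is conserved.  CHT
statistics cover a Cauchy maximum-likelihood fit (capillary transit times
are heavy-tailed), QQ quantile comparison between conditions, and the
percent change of the per-scan maximum CHT across time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .hmm import CapillaryCall
from .tracking import Track

SCARE_PITCH_WL = 1 / 32            # super-resolved grid spacing
DENSITY_WINDOW_WL = 8.0            # Gaussian smoothing window for density


@dataclass
class GridSpec:
    """Super-resolved accumulation grid in (x, z), micrometres."""

    origin_um: tuple[float, float]
    fov_um: tuple[float, float]
    pitch_um: float

    @property
    def shape(self) -> tuple[int, int]:
        return (int(np.ceil(self.fov_um[1] / self.pitch_um)),
                int(np.ceil(self.fov_um[0] / self.pitch_um)))

    def index(self, x_um, z_um):
        col = np.rint((np.asarray(x_um) - self.origin_um[0]) / self.pitch_um)
        row = np.rint((np.asarray(z_um) - self.origin_um[1]) / self.pitch_um)
        return row.astype(int), col.astype(int)

    @classmethod
    def from_wavelength(cls, origin_um, fov_um, wavelength_um,
                        pitch_fraction: float = SCARE_PITCH_WL):
        return cls(tuple(origin_um), tuple(fov_um),
                   wavelength_um * pitch_fraction)


@dataclass
class SCaReMap:
    grid: np.ndarray                 # dwell seconds per pixel
    spec: GridSpec
    n_clipped: int = 0

    @property
    def total_dwell_s(self) -> float:
        return float(self.grid.sum())


@dataclass
class CHTStats:
    cht_samples_s: np.ndarray
    cauchy_location_s: float
    cauchy_scale_s: float
    cauchy_loglik: float
    normal_loglik: float
    max_cht_s: float


def accumulate_scare_map(calls: Sequence[CapillaryCall],
                         tracks: Sequence[Track],
                         spec: GridSpec) -> SCaReMap:
    """Accumulate accepted low-state dwell onto the super-resolved grid.

    Each low-state sample of an accepted call adds its sample interval
    (1 / frame rate) of dwell at the nearest pixel; samples outside the
    grid are clipped and counted.  Total accumulated dwell equals the sum
    of accepted CHTs up to clipping.
    """
    by_id = {t.track_id: t for t in tracks}
    rows, cols = spec.shape
    grid = np.zeros((rows, cols))
    clipped = 0
    for call in calls:
        if not call.accepted:
            continue
        t = by_id[call.track_id]
        low = call.state_sequence
        # low-state samples were identified at categorization time via the
        # single low run; recover them from the stored interval
        t0, t1 = call.low_interval_s
        mask = (t.t_s >= t0 - 1e-12) & (t.t_s <= t1 + 1e-12)
        r, c = spec.index(t.x_um[mask], t.z_um[mask])
        inside = (r >= 0) & (r < rows) & (c >= 0) & (c < cols)
        clipped += int((~inside).sum())
        np.add.at(grid, (r[inside], c[inside]), t.dt_s)
    return SCaReMap(grid=grid, spec=spec, n_clipped=clipped)


def density_map(m: SCaReMap, window_um: float | None = None,
                wavelength_um: float | None = None) -> np.ndarray:
    """Gaussian-smoothed SCaRe density (sum-preserving in the interior).

    The default window is eight wavelengths; the Gaussian sigma is a
    quarter of the window so the kernel support is about one window wide.
    """
    from scipy.ndimage import gaussian_filter
    if window_um is None:
        if wavelength_um is None:
            raise ValueError("give window_um or wavelength_um")
        window_um = DENSITY_WINDOW_WL * wavelength_um
    sigma_px = (window_um / 4.0) / m.spec.pitch_um
    return gaussian_filter(m.grid, sigma_px, mode="constant")


def render_ulm(tracks: Sequence[Track], spec: GridSpec,
               mode: str = "density") -> np.ndarray:
    """Per-pixel track accumulation: density, velocity, direction, amplitude.

    density: interpolated sample counts; velocity: mean speed (mm/s);
    direction: mean sign of vz (positive = downward in z); amplitude: mean
    backscatter amplitude.
    """
    if mode not in ("density", "velocity", "direction", "amplitude"):
        raise ValueError(f"unknown mode {mode!r}")
    rows, cols = spec.shape
    acc = np.zeros((rows, cols))
    cnt = np.zeros((rows, cols))
    for t in tracks:
        r, c = spec.index(t.x_um, t.z_um)
        inside = (r >= 0) & (r < rows) & (c >= 0) & (c < cols)
        r, c = r[inside], c[inside]
        if mode == "density":
            w = np.ones(r.shape)
        elif mode == "velocity":
            w = t.speed_mm_s[inside]
        elif mode == "direction":
            w = np.sign(t.vz_mm_s[inside])
        else:
            w = t.amplitude[inside]
        np.add.at(acc, (r, c), w)
        np.add.at(cnt, (r, c), 1.0)
    if mode == "density":
        return acc
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.clip(cnt, 1, None), 0.0)
    return out


# ---------------------------------------------------------------------------
# CHT statistics
# ---------------------------------------------------------------------------

def fit_cauchy(cht_s: Sequence[float], min_samples: int = 20) -> CHTStats:
    """Maximum-likelihood Cauchy fit with a Normal-fit comparison.

    Degenerate (all-identical) samples get a floored scale of 1e-9.
    """
    x = np.asarray(cht_s, float)
    if len(x) < min_samples:
        raise ValueError(f"need >= {min_samples} samples")
    if np.ptp(x) == 0:
        loc, scale = float(x[0]), 1e-9
    else:
        loc, scale = stats.cauchy.fit(x)
    c_ll = float(stats.cauchy.logpdf(x, loc, scale).sum())
    mu, sd = float(x.mean()), float(x.std(ddof=0))
    n_ll = float(stats.norm.logpdf(x, mu, max(sd, 1e-12)).sum())
    return CHTStats(cht_samples_s=x, cauchy_location_s=float(loc),
                    cauchy_scale_s=float(scale), cauchy_loglik=c_ll,
                    normal_loglik=n_ll, max_cht_s=float(x.max()))


def qq_compare(baseline_s: Sequence[float], comparison_s: Sequence[float],
               n_quantiles: int = 100) -> np.ndarray:
    """Matched empirical quantiles at ``n_quantiles`` probability levels.

    Returns an (n_quantiles, 2) array of (baseline, comparison) pairs;
    identical samples lie on the identity line, and a heavier-tailed
    comparison pulls the upper pairs above it.
    """
    b = np.asarray(baseline_s, float)
    c = np.asarray(comparison_s, float)
    if len(b) < n_quantiles or len(c) < n_quantiles:
        raise ValueError("both samples must have >= n_quantiles points")
    p = (np.arange(n_quantiles) + 0.5) / n_quantiles
    return np.column_stack([np.quantile(b, p), np.quantile(c, p)])


def max_cht_change(per_timepoint_max_s: Sequence[float]):
    """Percent change of per-scan max CHT vs baseline, plus monotonicity.

    Returns (percent changes for time points after baseline, strictly
    monotone increasing flag).  A zero baseline is flagged as undefined.
    """
    m = np.asarray(per_timepoint_max_s, float)
    if len(m) < 2:
        raise ValueError("need at least two time points")
    if m[0] == 0:
        raise ValueError("undefined percent change: zero baseline max CHT")
    pct = 100.0 * (m[1:] - m[0]) / m[0]
    monotone = bool(np.all(np.diff(m) > 0))
    return pct, monotone


def export_max_cht(records, path: str) -> None:
    """Tidy per-scan endpoint table for external mixed-model analysis.

    ``records``: iterables of (animal, group, timepoint, max_cht_s).
    """
    import pandas as pd
    df = pd.DataFrame(records, columns=["animal", "group", "timepoint",
                                        "max_cht_s"])
    df.to_csv(path, index=False)


def polygon_mask(spec: GridSpec, polygon_um: np.ndarray) -> np.ndarray:
    """Boolean ROI mask on the grid from an (n, 2) polygon in (x, z) um."""
    from matplotlib.path import Path
    rows, cols = spec.shape
    r, c = np.mgrid[0:rows, 0:cols]
    x = spec.origin_um[0] + c * spec.pitch_um
    z = spec.origin_um[1] + r * spec.pitch_um
    pts = np.column_stack([x.ravel(), z.ravel()])
    return Path(polygon_um).contains_points(pts).reshape(rows, cols)
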