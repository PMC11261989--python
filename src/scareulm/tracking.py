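"""Bubble localization, track linking, Kalman/RTS smoothing and pairing.

Localization finds local maxima on filtered frames and refines them to
subpixel precision by intensity-weighted centroiding (a radial-symmetry
style refinement).  Linking is greedy nearest-neighbour frame-to-frame
assignment under a maximum step.  Each linked track is then passed through
a constant-velocity Kalman filter with a grid-snapped innovation and a
Rauch-Tung-Striebel backward smoother, and finally fragments are merged by
two-stage track pairing (exact endpoint coincidence, then chronological
pairing within one wavelength and a 100 ms gap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .frames import FrameStack

log = logging.getLogger(__name__)

PAIRING_MAX_GAP_S = 0.100          # chronological pairing temporal gap
PAIRING_MAX_DIST_WL = 1.0          # ... and spatial gap, in wavelengths


class Detection(NamedTuple):
    frame: int
    x_um: float
    z_um: float
    amplitude: float


@dataclass
class KalmanConfig:
    dt: float
    sigma_process: float = 1.0     # Q = sigma * I
    epsilon: float = 25.0          # R = epsilon * I (~(5 um localization)^2)
    grid_um: float = 1e-3          # innovation snapping grid g

    def __post_init__(self):
        if min(self.dt, self.sigma_process, self.epsilon, self.grid_um) <= 0:
            raise ValueError("all Kalman parameters must be positive")


@dataclass
class Track:
    """Smoothed 2D trajectory with spline-derived velocities."""

    track_id: int
    t_s: np.ndarray
    x_um: np.ndarray
    z_um: np.ndarray
    vx_mm_s: np.ndarray
    vz_mm_s: np.ndarray
    amplitude: np.ndarray
    paired_from: tuple = ()
    smoothed: bool = False

    def __len__(self):
        return len(self.t_s)

    @property
    def speed_mm_s(self) -> np.ndarray:
        return np.hypot(self.vx_mm_s, self.vz_mm_s)

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.t_s))) if len(self.t_s) > 1 else np.nan


# ---------------------------------------------------------------------------
# localization
# ---------------------------------------------------------------------------

def localize(frame: np.ndarray, threshold: float, wavelength_um: float,
             pixel_pitch_um: float, origin_um=(0.0, 0.0),
             frame_index: int = 0) -> list[Detection]:
    """Local maxima above ``threshold`` refined to subpixel centres.

    No two detections are closer than half a wavelength.
    """
    from skimage.feature import peak_local_max
    min_dist = max(1, int(round(0.5 * wavelength_um / pixel_pitch_um)))
    peaks = peak_local_max(frame, min_distance=min_dist,
                           threshold_abs=threshold, exclude_border=False)
    out = []
    rows, cols = frame.shape
    x0, z0 = origin_um

    def _axis_offset(vm, v0, vp):
        # log-parabolic 3-point refinement; exact for a Gaussian profile
        if min(vm, v0, vp) > 0:
            lm, l0, lp = np.log(vm), np.log(v0), np.log(vp)
            den = lm - 2 * l0 + lp
            if den < 0:
                return float(np.clip(0.5 * (lm - lp) / den, -1.0, 1.0))
        den = vm - 2 * v0 + vp
        if den < 0:
            return float(np.clip(0.5 * (vm - vp) / den, -1.0, 1.0))
        return 0.0

    for r, c in peaks:
        rc, cc = float(r), float(c)
        if 0 < r < rows - 1:
            rc += _axis_offset(frame[r - 1, c], frame[r, c], frame[r + 1, c])
        if 0 < c < cols - 1:
            cc += _axis_offset(frame[r, c - 1], frame[r, c], frame[r, c + 1])
        out.append(Detection(frame=frame_index,
                             x_um=x0 + cc * pixel_pitch_um,
                             z_um=z0 + rc * pixel_pitch_um,
                             amplitude=float(frame[r, c])))
    out.sort(key=lambda d: (d.x_um, d.z_um))
    return out


def localize_stack(fs: FrameStack, threshold: float | None = None,
                   threshold_nsigma: float = 5.0) -> list[list[Detection]]:
    """Per-frame localization over a (filtered) stack.

    With ``threshold=None`` an absolute threshold is derived from the
    robust noise scale of the stack: ``threshold_nsigma`` times the
    median-absolute-deviation-based sigma.
    """
    if threshold is None:
        sample = fs.frames[:, :, :: max(1, fs.n_frames // 200)]
        sigma = 1.4826 * np.median(np.abs(sample - np.median(sample)))
        threshold = threshold_nsigma * float(sigma)
    return [localize(fs.frames[:, :, k], threshold, fs.wavelength_um,
                     fs.pixel_pitch_um, fs.origin_um, frame_index=k)
            for k in range(fs.n_frames)]


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

@dataclass
class _RawTrack:
    frames: list
    xs: list
    zs: list
    amps: list


def link(detections_per_frame: Sequence[Sequence[Detection]],
         max_step_um: float, min_length: int = 3) -> list[_RawTrack]:
    """Greedy nearest-neighbour frame-to-frame linking.

    Active tracks claim the closest detection in the next frame (globally
    greedy over candidate pairs, distances under ``max_step_um``); ties are
    broken toward the earlier-started track and the smaller-x detection, so
    the result is deterministic for a given input order.  Unmatched
    detections seed new tracks; a track that misses a frame is closed.
    """
    active: list[_RawTrack] = []
    done: list[_RawTrack] = []
    for k, dets in enumerate(detections_per_frame):
        dets = list(dets)
        if active:
            cand = []
            for ti, tr in enumerate(active):
                for di, d in enumerate(dets):
                    dist = np.hypot(tr.xs[-1] - d.x_um, tr.zs[-1] - d.z_um)
                    if dist <= max_step_um:
                        cand.append((dist, tr.frames[0], d.x_um, ti, di))
            cand.sort()
            used_t, used_d = set(), set()
            assigned = {}
            for dist, _, _, ti, di in cand:
                if ti in used_t or di in used_d:
                    continue
                used_t.add(ti)
                used_d.add(di)
                assigned[ti] = di
            still = []
            for ti, tr in enumerate(active):
                if ti in assigned:
                    d = dets[assigned[ti]]
                    tr.frames.append(k)
                    tr.xs.append(d.x_um)
                    tr.zs.append(d.z_um)
                    tr.amps.append(d.amplitude)
                    still.append(tr)
                else:
                    done.append(tr)
            active = still
            dets = [d for di, d in enumerate(dets) if di not in used_d]
        for d in dets:
            active.append(_RawTrack([k], [d.x_um], [d.z_um], [d.amplitude]))
    done.extend(active)
    return [t for t in done if len(t.frames) >= min_length]


# ---------------------------------------------------------------------------
# Kalman filter + RTS smoother
# ---------------------------------------------------------------------------

def kalman_rts_positions(x_meas: np.ndarray, z_meas: np.ndarray,
                         cfg: KalmanConfig):
    """Forward KF with grid-snapped innovation, then RTS backward pass.

    State [x, z, vx, vz]; F has dt coupling position to velocity; P starts
    at the identity; Q = sigma*I, R = epsilon*I.  The innovation is snapped
    to the localization grid: y = nint((z_meas - H x_pred)/g) * g.  Returns
    (smoothed positions (n, 2), smoothed velocities (n, 2), covariances).
    """
    n = len(x_meas)
    dt, sig, eps, g = cfg.dt, cfg.sigma_process, cfg.epsilon, cfg.grid_um
    F = np.eye(4)
    F[0, 2] = F[1, 3] = dt
    Q = sig * np.eye(4)
    H = np.zeros((2, 4))
    H[0, 0] = H[1, 1] = 1.0
    R = eps * np.eye(2)
    I4 = np.eye(4)

    xf = np.zeros((n, 4))
    Pf = np.zeros((n, 4, 4))
    v0 = ((x_meas[1] - x_meas[0]) / dt, (z_meas[1] - z_meas[0]) / dt) \
        if n > 1 else (0.0, 0.0)
    xf[0] = [x_meas[0], z_meas[0], v0[0], v0[1]]
    Pf[0] = np.eye(4)
    for t in range(1, n):
        x_pred = F @ xf[t - 1]
        P_pred = F @ Pf[t - 1] @ F.T + Q
        meas = np.array([x_meas[t], z_meas[t]])
        y = np.rint((meas - H @ x_pred) / g) * g
        S = H @ P_pred @ H.T + R
        try:
            Sinv = np.linalg.inv(S)
        except np.linalg.LinAlgError:
            log.warning("singular innovation covariance; regularizing")
            Sinv = np.linalg.inv(S + eps * np.eye(2))
        K = P_pred @ H.T @ Sinv
        xf[t] = x_pred + K @ y
        Pf[t] = (I4 - K @ H) @ P_pred

    xs = np.zeros_like(xf)
    Ps = np.zeros_like(Pf)
    xs[-1] = xf[-1]
    Ps[-1] = Pf[-1]
    for t in range(n - 2, -1, -1):
        P_pred_next = F @ Pf[t] @ F.T + Q
        C = Pf[t] @ F.T @ np.linalg.inv(P_pred_next)
        xs[t] = xf[t] + C @ (xs[t + 1] - F @ xf[t])
        Ps[t] = Pf[t] + C @ (Ps[t + 1] - P_pred_next) @ C.T
        Ps[t] = 0.5 * (Ps[t] + Ps[t].T)
    return xs[:, :2], xs[:, 2:], Ps


def _spline_velocity(t: np.ndarray, x: np.ndarray, z: np.ndarray):
    """Cubic-spline position interpolation, derivative at sample times (mm/s)."""
    if len(t) >= 4:
        sx, sz = CubicSpline(t, x), CubicSpline(t, z)
        return sx(t, 1) / 1e3, sz(t, 1) / 1e3
    vx = np.gradient(x, t) / 1e3
    vz = np.gradient(z, t) / 1e3
    return vx, vz


def smooth_track(raw: _RawTrack, frame_rate_hz: float, cfg: KalmanConfig,
                 track_id: int = 0, t0_s: float = 0.0) -> Track:
    """Kalman+RTS smooth a linked raw track and derive spline velocities."""
    t = t0_s + np.asarray(raw.frames, float) / frame_rate_hz
    pos, _, _ = kalman_rts_positions(np.asarray(raw.xs, float),
                                     np.asarray(raw.zs, float), cfg)
    vx, vz = _spline_velocity(t, pos[:, 0], pos[:, 1])
    return Track(track_id=track_id, t_s=t, x_um=pos[:, 0], z_um=pos[:, 1],
                 vx_mm_s=vx, vz_mm_s=vz,
                 amplitude=np.asarray(raw.amps, float), smoothed=True)


def build_tracks(detections_per_frame, frame_rate_hz: float,
                 max_step_um: float, cfg: KalmanConfig | None = None,
                 t0_s: float = 0.0, min_length: int = 3) -> list[Track]:
    cfg = cfg or KalmanConfig(dt=1.0 / frame_rate_hz)
    raws = link(detections_per_frame, max_step_um, min_length=min_length)
    return [smooth_track(r, frame_rate_hz, cfg, track_id=i, t0_s=t0_s)
            for i, r in enumerate(raws)]


# ---------------------------------------------------------------------------
# track pairing
# ---------------------------------------------------------------------------

def _merge(a: Track, b: Track, new_id: int) -> Track:
    """Concatenate two chronologically ordered tracks."""
    tr = Track(track_id=new_id,
               t_s=np.concatenate([a.t_s, b.t_s]),
               x_um=np.concatenate([a.x_um, b.x_um]),
               z_um=np.concatenate([a.z_um, b.z_um]),
               vx_mm_s=np.concatenate([a.vx_mm_s, b.vx_mm_s]),
               vz_mm_s=np.concatenate([a.vz_mm_s, b.vz_mm_s]),
               amplitude=np.concatenate([a.amplitude, b.amplitude]),
               paired_from=tuple(a.paired_from or (a.track_id,)) +
               tuple(b.paired_from or (b.track_id,)),
               smoothed=a.smoothed and b.smoothed)
    vx, vz = _spline_velocity(tr.t_s, tr.x_um, tr.z_um)
    tr.vx_mm_s, tr.vz_mm_s = vx, vz
    return tr


def pair_tracks(tracks: Sequence[Track], wavelength_um: float,
                max_gap_s: float = PAIRING_MAX_GAP_S,
                max_dist_wl: float = PAIRING_MAX_DIST_WL,
                coincidence_tol_um: float = 1e-6) -> list[Track]:
    """Two-stage merging of track fragments.

    Stage 1 merges tracks whose end/start are the same point in space and
    time (within a tight tolerance).  Stage 2 chronologically merges a
    track ending at t_e with the nearest-in-time track starting at
    t_s in (t_e, t_e + max_gap_s) whose endpoint distance is below
    ``max_dist_wl`` wavelengths in both x and z.  Conflicting candidates
    are resolved nearest-in-time first; merging is applied transitively by
    processing tracks in start-time order.
    """
    from bisect import bisect_left, bisect_right

    max_d = max_dist_wl * wavelength_um
    pool = sorted(tracks, key=lambda t: (t.t_s[0], t.x_um[0]))

    def sweep(stage1: bool, pool):
        """One pass: walk tracks by start time, greedily extending each
        with its nearest-in-time mergeable successor (transitive chains
        merge in a single pass)."""
        pool = sorted(pool, key=lambda t: (t.t_s[0], t.x_um[0]))
        starts = [t.t_s[0] for t in pool]
        used = [False] * len(pool)
        out = []
        tol = 1e-9
        for i in range(len(pool)):
            if used[i]:
                continue
            used[i] = True
            cur = pool[i]
            while True:
                te = cur.t_s[-1]
                if stage1:
                    lo = bisect_left(starts, te - coincidence_tol_um)
                    hi = bisect_right(starts, te + coincidence_tol_um)
                else:
                    lo = bisect_right(starts, te + tol)
                    hi = bisect_left(starts, te + max_gap_s)
                best = None
                for j in range(lo, hi):
                    if used[j]:
                        continue
                    b = pool[j]
                    gap = b.t_s[0] - te
                    dx = abs(b.x_um[0] - cur.x_um[-1])
                    dz = abs(b.z_um[0] - cur.z_um[-1])
                    if stage1:
                        ok = dx <= coincidence_tol_um and dz <= coincidence_tol_um
                    else:
                        ok = 0.0 < gap < max_gap_s and dx < max_d and dz < max_d
                    if ok and (best is None or gap < best[0]):
                        best = (gap, j)
                if best is None:
                    break
                used[best[1]] = True
                cur = _merge(cur, pool[best[1]], new_id=cur.track_id)
            out.append(cur)
        return out

    pool = sweep(True, pool)
    pool = sweep(False, pool)
    pool.sort(key=lambda t: (t.t_s[0], t.x_um[0]))
    for new_id, t in enumerate(pool):
        t.track_id = new_id
    return pool


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def tracks_to_frame(tracks: Sequence[Track]):
    import pandas as pd
    rows = [pd.DataFrame({"track_id": t.track_id, "t_s": t.t_s,
                          "x_um": t.x_um, "z_um": t.z_um,
                          "vx_mm_s": t.vx_mm_s, "vz_mm_s": t.vz_mm_s,
                          "amplitude": t.amplitude})
            for t in tracks]
    if not rows:
        import pandas as pd
        return pd.DataFrame(columns=["track_id", "t_s", "x_um", "z_um",
                                     "vx_mm_s", "vz_mm_s", "amplitude"])
    return pd.concat(rows, ignore_index=True)


def tracks_from_frame(df) -> list[Track]:
    out = []
    for tid, g in df.groupby("track_id"):
        g = g.sort_values("t_s")
        out.append(Track(track_id=int(tid), t_s=g["t_s"].to_numpy(),
                         x_um=g["x_um"].to_numpy(), z_um=g["z_um"].to_numpy(),
                         vx_mm_s=g["vx_mm_s"].to_numpy(),
                         vz_mm_s=g["vz_mm_s"].to_numpy(),
                         amplitude=g["amplitude"].to_numpy()))
    return out
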