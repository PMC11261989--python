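"""Localization, linking, Kalman/RTS smoothing and track pairing."""

import numpy as np
import pytest

from scareulm import tracking as T
from scareulm.frames import FrameStack


def gaussian_frame(shape, centers, sigma=3.0, amp=1.0):
    frame = np.zeros(shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for r, c in centers:
        frame += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma ** 2))
    return frame


WL, PITCH = 150.0, 18.75     # wavelength and pixel pitch (um)


class TestLocalize:
    def test_single_blob_subpixel(self):
        frame = gaussian_frame((40, 40), [(20.3, 17.6)])
        dets = T.localize(frame, 0.1, WL, PITCH)
        assert len(dets) == 1
        assert abs(dets[0].x_um - 17.6 * PITCH) < 0.05 * WL
        assert abs(dets[0].z_um - 20.3 * PITCH) < 0.05 * WL

    def test_two_blobs_three_wavelengths_apart(self):
        sep_px = 3 * WL / PITCH
        frame = gaussian_frame((80, 80), [(20, 20), (20, 20 + sep_px)])
        dets = T.localize(frame, 0.1, WL, PITCH)
        assert len(dets) == 2

    def test_noise_below_threshold_empty(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(0, 0.01, (40, 40))
        assert T.localize(frame, 0.5, WL, PITCH) == []


class TestLink:
    @staticmethod
    def dets_from_tracks(paths):
        """paths: list of (n_frames, 2) arrays of (x, z) um; None = absent."""
        n = max(len(p) for p in paths)
        per_frame = []
        for k in range(n):
            frame = []
            for p in paths:
                if k < len(p) and p[k] is not None:
                    frame.append(T.Detection(k, p[k][0], p[k][1], 1.0))
            per_frame.append(frame)
        return per_frame

    def test_single_moving_bubble_full_track(self):
        path = [(10.0 * k, 5.0 * k) for k in range(20)]
        tracks = T.link(self.dets_from_tracks([path]), max_step_um=50.0)
        assert len(tracks) == 1
        assert len(tracks[0].frames) == 20

    def test_distant_parallel_bubbles_no_swap(self):
        a = [(10.0 * k, 0.0) for k in range(15)]
        b = [(10.0 * k, 5000.0) for k in range(15)]
        tracks = T.link(self.dets_from_tracks([a, b]), max_step_um=50.0)
        assert len(tracks) == 2
        zs = sorted({round(z) for t in tracks for z in t.zs})
        assert all(len({round(z) for z in t.zs}) == 1 for t in tracks)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_hungarian_oracle_per_step(self, seed):
        """Greedy frame-to-frame cost never mislinks well-separated
        constant-velocity bubbles; verify against the optimal assignment."""
        from scipy.optimize import linear_sum_assignment
        rng = np.random.default_rng(seed)
        n_b, n_f = 4, 12
        starts = rng.uniform(0, 2000, (n_b, 2))
        vels = rng.uniform(-15, 15, (n_b, 2))
        paths = [[tuple(starts[i] + k * vels[i]) for k in range(n_f)]
                 for i in range(n_b)]
        tracks = T.link(self.dets_from_tracks(paths), max_step_um=60.0)
        assert len(tracks) == n_b
        # each recovered track follows one true bubble throughout: compare
        # with the Hungarian assignment between consecutive frames
        for t in tracks:
            pts = np.column_stack([t.xs, t.zs])
            truth = np.array([[starts[i] + k * vels[i] for k in t.frames]
                              for i in range(n_b)])
            d = np.linalg.norm(truth - pts[None], axis=2).sum(axis=1)
            best = np.argmin(d)
            cost = np.linalg.norm(truth[best] - pts, axis=1)
            assert np.all(cost < 1e-9)


class TestKalmanRTS:
    def test_small_epsilon_follows_measurements(self):
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.uniform(1, 3, 40))
        z = np.cumsum(rng.uniform(1, 3, 40))
        cfg = T.KalmanConfig(dt=1e-3, sigma_process=1.0, epsilon=1e-12,
                             grid_um=1e-9)
        pos, _, _ = T.kalman_rts_positions(x, z, cfg)
        assert np.allclose(pos[:, 0], x, atol=1e-4)
        assert np.allclose(pos[:, 1], z, atol=1e-4)

    def test_textbook_oracle_equivalence(self):
        """Noise-free constant-velocity input: match an independently
        written standard-form KF+RTS to 1e-6 um (snap grid negligible)."""

        def oracle(xm, zm, dt, sig, eps):
            F = np.eye(4); F[0, 2] = F[1, 3] = dt
            Q = sig * np.eye(4)
            H = np.zeros((2, 4)); H[0, 0] = H[1, 1] = 1.0
            R = eps * np.eye(2)
            n = len(xm)
            xf = np.zeros((n, 4)); Pf = np.zeros((n, 4, 4))
            xf[0] = [xm[0], zm[0], (xm[1] - xm[0]) / dt, (zm[1] - zm[0]) / dt]
            Pf[0] = np.eye(4)
            for t in range(1, n):
                xp = F @ xf[t - 1]
                Pp = F @ Pf[t - 1] @ F.T + Q
                y = np.array([xm[t], zm[t]]) - H @ xp
                S = H @ Pp @ H.T + R
                K = Pp @ H.T @ np.linalg.inv(S)
                xf[t] = xp + K @ y
                Pf[t] = (np.eye(4) - K @ H) @ Pp
            xs = xf.copy()
            for t in range(n - 2, -1, -1):
                Pp = F @ Pf[t] @ F.T + Q
                C = Pf[t] @ F.T @ np.linalg.inv(Pp)
                xs[t] = xf[t] + C @ (xs[t + 1] - F @ xf[t])
            return xs[:, :2]

        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(5, 40)
            v = rng.uniform(-5, 5, 2)
            x0 = rng.uniform(0, 100, 2)
            t = np.arange(n) * 1e-3
            xm = x0[0] + v[0] * t * 1e3
            zm = x0[1] + v[1] * t * 1e3
            cfg = T.KalmanConfig(dt=1e-3, sigma_process=0.5, epsilon=2.0,
                                 grid_um=1e-9)
            pos, _, _ = T.kalman_rts_positions(xm, zm, cfg)
            expect = oracle(xm, zm, 1e-3, 0.5, 2.0)
            assert np.allclose(pos, expect, atol=1e-6)

    def test_innovation_grid_snap(self):
        # residual 0.0037 um with grid 0.001 um snaps to 0.004 um
        g = 0.001
        assert np.rint(0.0037 / g) * g == pytest.approx(0.004)

    def test_smoothed_covariance_symmetric_psd(self):
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.normal(2, 1, 30))
        z = np.cumsum(rng.normal(1, 1, 30))
        cfg = T.KalmanConfig(dt=1e-3)
        _, _, Ps = T.kalman_rts_positions(x, z, cfg)
        for P in Ps:
            assert np.allclose(P, P.T, atol=1e-9)
            assert np.linalg.eigvalsh(P).min() > -1e-9


class TestPairing:
    @staticmethod
    def fragment(t0, x0, v, n, dt=1e-3, track_id=0):
        t = t0 + np.arange(n) * dt
        x = x0 + v * (t - t0) * 1e3
        z = 0.5 * x
        return T.Track(track_id=track_id, t_s=t, x_um=x, z_um=z,
                       vx_mm_s=np.full(n, v), vz_mm_s=np.full(n, 0.5 * v),
                       amplitude=np.ones(n))

    def make_pair(self, gap_s, dist_wl, v=5.0, n=50):
        a = self.fragment(0.0, 0.0, v, n, track_id=0)
        x_start = a.x_um[-1] + dist_wl * WL / np.sqrt(1.25)
        b = T.Track(track_id=1, t_s=a.t_s[-1] + gap_s + np.arange(n) * 1e-3,
                    x_um=x_start + v * np.arange(n),
                    z_um=0.5 * (x_start + v * np.arange(n)),
                    vx_mm_s=np.full(n, v), vz_mm_s=np.full(n, 0.5 * v),
                    amplitude=np.ones(n))
        return [a, b]

    def test_merge_within_limits(self):
        out = T.pair_tracks(self.make_pair(0.050, 0.5), WL)
        assert len(out) == 1
        assert np.all(np.diff(out[0].t_s) > 0)

    def test_no_merge_beyond_gap(self):
        assert len(T.pair_tracks(self.make_pair(0.150, 0.5), WL)) == 2

    def test_no_merge_beyond_distance(self):
        assert len(T.pair_tracks(self.make_pair(0.050, 1.5), WL)) == 2

    def test_sample_count_preserved(self):
        tracks = self.make_pair(0.050, 0.5)
        n_before = sum(len(t) for t in tracks)
        out = T.pair_tracks(tracks, WL)
        assert sum(len(t) for t in out) == n_before

    def test_transitive_chain_merge(self):
        a = self.fragment(0.0, 0.0, 5.0, 50, track_id=0)
        frags = [a]
        for i in range(1, 4):
            prev = frags[-1]
            nxt = T.Track(track_id=i, t_s=prev.t_s[-1] + 0.02 + np.arange(50) * 1e-3,
                          x_um=prev.x_um[-1] + 10 + 5.0 * np.arange(50),
                          z_um=prev.z_um[-1] + 5 + 2.5 * np.arange(50),
                          vx_mm_s=np.full(50, 5.0), vz_mm_s=np.full(50, 2.5),
                          amplitude=np.ones(50))
            frags.append(nxt)
        out = T.pair_tracks(frags, WL)
        assert len(out) == 1
        assert len(out[0]) == 200

    def test_stage1_exact_coincidence(self):
        a = self.fragment(0.0, 0.0, 5.0, 50, track_id=0)
        b = T.Track(track_id=1, t_s=a.t_s[-1] + np.arange(1, 51) * 1e-3,
                    x_um=a.x_um[-1] + 5.0 * np.arange(1, 51),
                    z_um=a.z_um[-1] + 2.5 * np.arange(1, 51),
                    vx_mm_s=np.full(50, 5.0), vz_mm_s=np.full(50, 2.5),
                    amplitude=np.ones(50))
        out = T.pair_tracks([a, b], WL)
        assert len(out) == 1


class TestEndToEnd:
    def test_u_profile_recovered_from_frames(self):
        """A rendered dwelling bubble yields one track whose speed profile
        is high -> low -> high (the classification signature)."""
        from scareulm import frames as FRmod
        from scareulm.flow import BubbleTransit, CLASS_CODES
        from scareulm import hmm as H
        dt = 1e-3
        speeds = np.concatenate([np.full(400, 8.0), np.full(800, 0.8),
                                 np.full(400, 8.0)])
        x = 150 + np.cumsum(speeds) * dt * 1e3
        n = len(x)
        tr = BubbleTransit(t_s=np.arange(n) * dt, arclength_um=x - x[0],
                           position_um=np.column_stack([x, np.zeros(n),
                                                        np.full(n, 800.0)]),
                           velocity_mm_s=speeds, edge_ids=np.zeros(n, int),
                           class_codes=np.full(n, CLASS_CODES["capillary"]),
                           record_dt_s=dt, complete=True)
        fs = FRmod.render_frames([tr], fov_um=(9000, 1600), n_frames=n,
                                 clutter_rank=0, noise_sigma=0.01, seed=0)
        dets = T.localize_stack(fs, threshold_nsigma=6.0)
        tracks = T.build_tracks(dets, 1000.0, max_step_um=150.0)
        tracks = T.pair_tracks(tracks, 150.0)
        main = max(tracks, key=len)
        assert len(main) > 0.9 * n
        sp = H.smoothed_speed(main)
        thirds = np.array_split(sp, 3)
        assert np.median(thirds[0]) > 2.0
        assert np.median(thirds[1]) < 2.0
        assert np.median(thirds[2]) > 2.0
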