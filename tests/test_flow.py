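"""Bubble sampling, pulsatile waveform and transit integration."""

import numpy as np
import pytest

from scareulm import flow as F
from scareulm import graph as G


@pytest.fixture(scope="module")
def network():
    vg = G.generate_graph(G.GraphConfig(seed=2))
    G.solve_hemodynamics(vg)
    return vg, G.enumerate_paths(vg, max_paths=5000).paths


class TestWaveform:
    def test_period_at_500_bpm(self):
        w = F.PulsatileWaveform(heart_rate_bpm=500.0)
        assert w.period_s == pytest.approx(0.12)

    def test_modulation_depth_definition(self):
        # 75% variation: (peak - trough) / peak = 0.75
        w = F.PulsatileWaveform(modulation_depth=0.75)
        t = np.linspace(0, w.period_s, 20000, endpoint=False)
        v = w.value(t)
        assert v.max() == pytest.approx(1.0, abs=1e-6)
        assert v.min() == pytest.approx(0.25, abs=1e-6)
        peak = 10.0 * v.max()
        trough = 10.0 * v.min()
        assert trough == pytest.approx(2.5, abs=1e-4)

    def test_periodicity(self):
        w = F.PulsatileWaveform()
        t = np.linspace(0, 1, 333)
        assert np.allclose(w.value(t), w.value(t + 7 * w.period_s), atol=1e-9)

    def test_zero_depth_constant(self):
        w = F.PulsatileWaveform(modulation_depth=0.0)
        assert np.allclose(w.value(np.linspace(0, 1, 100)), 1.0)

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            F.PulsatileWaveform(modulation_depth=1.5)

    def test_numba_matches_numpy_evaluation(self):
        w = F.PulsatileWaveform()
        t = np.linspace(0, 0.5, 64)
        expect = w.value(t)
        got = [F._wf_value(ti, w.period_s, w.modulation_depth, w._pmin,
                           w._pmax, w._amps, w._cen, w._wid) for ti in t]
        assert np.allclose(got, expect, atol=1e-12)


class TestSampling:
    def test_determinism(self, network):
        vg, paths = network
        b1 = F.sample_bubbles(paths, 50, seed=9)
        b2 = F.sample_bubbles(paths, 50, seed=9)
        assert [b.diameter_um for b in b1] == [b.diameter_um for b in b2]

    def test_positive_truncation(self, network):
        vg, paths = network
        bubbles = F.sample_bubbles(paths, 2000, seed=1)
        assert all(b.diameter_um > 0 for b in bubbles)

    def test_pass_through_constraint(self, network):
        vg, paths = network
        for b in F.sample_bubbles(paths, 500, seed=3):
            assert b.diameter_um <= b.path.min_diameter_um

    def test_oversized_bubble_spec_rejected(self, network):
        vg, paths = network
        narrow = min(paths, key=lambda p: p.min_diameter_um)
        with pytest.raises(ValueError):
            F.BubbleSpec(diameter_um=narrow.min_diameter_um + 1.0, path=narrow,
                         start_time_s=0.0, radial_offset_fraction=0.1)

    def test_unsatisfiable_raises(self, network):
        vg, paths = network
        with pytest.raises(F.SamplingError):
            F.sample_bubbles(paths, 5, seed=0, diameter_mean_um=500.0,
                             diameter_sd_um=1e-6, max_tries=50)


class TestPropagation:
    def test_constant_speed_segment_timing(self):
        # single capillary tube, no modulation: 100 um at 1 mm/s -> 0.1 s
        vg = G.build_graph({"a": (0, 0, 0), "b": (100, 0, 0)},
                           [dict(tail="a", head="b", radius_um=4.0,
                                 vessel_class="capillary")],
                           inlets=["a"], outlets=["b"])
        G.solve_hemodynamics(vg, 10.0, 0.0)
        v_mean = next(d["mean_velocity_mm_s"] for *_, d in vg.edges())
        path = G.enumerate_paths(vg).paths[0]
        b = F.BubbleSpec(diameter_um=1.0, path=path, start_time_s=0.0,
                         radial_offset_fraction=np.sqrt(0.5))  # factor 1.0
        w = F.PulsatileWaveform(modulation_depth=0.0)
        tr = F.propagate(b, vg, w, dt=1e-4)
        assert tr.complete
        expected = 100.0 / (2 * v_mean * (1 - 0.5) * 1e3)
        assert tr.t_s[-1] - tr.t_s[0] == pytest.approx(expected, rel=1e-3)

    def test_centerline_moves_at_twice_mean(self):
        vg = G.build_graph({"a": (0, 0, 0), "b": (1000, 0, 0)},
                           [dict(tail="a", head="b", radius_um=4.0,
                                 vessel_class="capillary")],
                           inlets=["a"], outlets=["b"])
        G.solve_hemodynamics(vg, 50.0, 0.0)
        v_mean = next(d["mean_velocity_mm_s"] for *_, d in vg.edges())
        path = G.enumerate_paths(vg).paths[0]
        b = F.BubbleSpec(1.0, path, 0.0, 0.0)
        tr = F.propagate(b, vg, F.PulsatileWaveform(modulation_depth=0.0))
        assert np.allclose(tr.velocity_mm_s, 2 * v_mean, rtol=1e-9)

    def test_pulse_wave_delay(self):
        # 3.5 mm at 350 cm/s -> 1 ms delay between waveform phases
        w = F.PulsatileWaveform()
        assert 3500.0 / w.pwv_um_s == pytest.approx(1e-3)

    def test_arclength_nondecreasing_and_positive_velocity(self, network):
        vg, paths = network
        trs = F.simulate_transits(vg, paths, 20, seed=4, acquisition_s=2.0)
        for tr in trs:
            assert np.all(np.diff(tr.arclength_um) >= 0)
            assert np.all(tr.velocity_mm_s >= 0)

    def test_integration_convergence_halving_dt(self, network):
        vg, paths = network
        b = F.sample_bubbles(paths, 1, seed=6)[0]
        w = F.PulsatileWaveform()
        t1 = F.propagate(b, vg, w, dt=2e-4).t_s[-1]
        t2 = F.propagate(b, vg, w, dt=1e-4).t_s[-1]
        assert abs(t1 - t2) / t2 < 0.01

    def test_dt_bound(self, network):
        vg, paths = network
        b = F.sample_bubbles(paths, 1, seed=6)[0]
        with pytest.raises(ValueError):
            F.propagate(b, vg, dt=5e-3)

    def test_u_shape_statistics(self, network):
        """Flank (arterial/venous) maxima exceed the capillary maximum for
        nearly all completed transits; strict for centred bubbles."""
        vg, paths = network
        trs = [t for t in F.simulate_transits(vg, paths, 60, seed=7,
                                              acquisition_s=3.0)
               if t.complete]
        ok = 0
        counted = 0
        for tr in trs:
            c = tr.class_codes
            art = tr.velocity_mm_s[(c == 0) | (c == 1)]
            cap = tr.velocity_mm_s[c == 2]
            ven = tr.velocity_mm_s[(c == 3) | (c == 4)]
            if len(art) and len(cap) and len(ven):
                counted += 1
                ok += art.max() > cap.max() and ven.max() > cap.max()
        assert counted >= 40
        assert ok / counted >= 0.9


class TestCHTTruth:
    def test_counting_convention(self):
        tr = F.BubbleTransit(
            t_s=np.arange(5) * 0.1, arclength_um=np.arange(5.0),
            position_um=np.zeros((5, 3)),
            velocity_mm_s=np.array([10.0, 1.0, 1.0, 1.0, 10.0]),
            edge_ids=np.zeros(5, int),
            class_codes=np.full(5, F.CLASS_CODES["capillary"]),
            record_dt_s=0.1, complete=True)
        assert F.cht_truth(tr, 2.0) == pytest.approx(0.3)

    def test_never_below_threshold_gives_zero(self):
        tr = F.BubbleTransit(
            t_s=np.arange(4) * 0.1, arclength_um=np.arange(4.0),
            position_um=np.zeros((4, 3)),
            velocity_mm_s=np.full(4, 5.0), edge_ids=np.zeros(4, int),
            class_codes=np.full(4, F.CLASS_CODES["capillary"]),
            record_dt_s=0.1, complete=True)
        assert F.cht_truth(tr, 2.0) == 0.0

    def test_windows_velocity_bound_exhaustive(self, network):
        """Every sample inside a returned window is sub-threshold capillary
        (exhaustive scan oracle over a large simulation)."""
        vg, paths = network
        trs = F.simulate_transits(vg, paths, 150, seed=8, acquisition_s=3.0)
        checked = 0
        for tr in trs:
            for i, j in F.capillary_windows(tr, 2.0):
                assert np.all(tr.velocity_mm_s[i:j] < 2.0)
                assert np.all(tr.class_codes[i:j] == F.CLASS_CODES["capillary"])
                checked += 1
        assert checked > 100

    def test_cht_heavy_tailed_cauchy_beats_normal(self, network):
        from scareulm import maps as M
        vg, paths = network
        trs = [t for t in F.simulate_transits(vg, paths, 150, seed=9,
                                              acquisition_s=5.0,
                                              max_time_s=60.0) if t.complete]
        cht = np.array([F.cht_truth(t) for t in trs])
        cht = cht[cht > 0]
        stats = M.fit_cauchy(cht)
        assert stats.cauchy_loglik > stats.normal_loglik
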