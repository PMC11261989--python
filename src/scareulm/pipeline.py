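"""End-to-end orchestration: graph -> transits -> frames -> filter ->
tracks -> capillary calls -> maps and statistics.

Each stage draws its randomness from a child seed spawned deterministically
from the pipeline seed, so identical configurations give byte-identical
tabular outputs.  The long-ensemble vs short-ensemble comparison used to
quantify capillary recovery is exposed as :func:`le_se_experiment`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import flow, frames, graph, hmm, maps, svdfilt, tracking
from .config import PipelineConfig

log = logging.getLogger(__name__)


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage child seeds (kept below 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


@dataclass
class SceneResult:
    vg: graph.VascularGraph
    paths: list
    transits: list
    cht_truth_s: np.ndarray


@dataclass
class PipelineResult:
    scene: SceneResult
    stack: frames.FrameStack | None
    tracks: list
    calls: list
    model: hmm.HMMModel | None
    scare_map: maps.SCaReMap | None
    counts: dict = field(default_factory=dict)


def simulate_scene(cfg: PipelineConfig) -> SceneResult:
    """Generate the network, solve hemodynamics and propagate bubbles."""
    seeds = stage_seeds(cfg.seed)
    gcfg = cfg.graph
    gcfg.seed = seeds[0]
    vg = graph.generate_graph(gcfg)
    graph.solve_hemodynamics(vg, cfg.sim.inlet_pressure_pa,
                             cfg.sim.outlet_pressure_pa, cfg.sim.viscosity_pa_s)
    enum = graph.enumerate_paths(vg, max_paths=cfg.sim.max_paths,
                                 rule=gcfg.single_capillary_rule)
    wf = flow.PulsatileWaveform(
        heart_rate_bpm=cfg.sim.heart_rate_bpm,
        modulation_depth=cfg.sim.modulation_depth,
        pulse_wave_velocity_cm_s=cfg.sim.pulse_wave_velocity_cm_s)
    transits = flow.simulate_transits(
        vg, enum.paths, cfg.sim.n_bubbles, seed=seeds[1],
        acquisition_s=cfg.sim.acquisition_s, waveform=wf, dt=cfg.sim.dt_s,
        record_dt=cfg.sim.record_dt_s, max_time_s=cfg.sim.max_time_s,
        diameter_mean_um=cfg.sim.diameter_mean_um,
        diameter_sd_um=cfg.sim.diameter_sd_um)
    cht = np.array([flow.cht_truth(t, cfg.hmm.v_thresh_mm_s)
                    for t in transits if t.complete])
    return SceneResult(vg=vg, paths=enum.paths, transits=transits,
                       cht_truth_s=cht)


def render_scene(scene: SceneResult, cfg: PipelineConfig) -> frames.FrameStack:
    seeds = stage_seeds(cfg.seed)
    Lx, _, Lz = cfg.graph.domain_um
    return frames.render_frames(
        scene.transits, fov_um=(Lx, Lz), origin_um=(0.0, 0.0),
        frame_rate_hz=cfg.frames.frame_rate_hz, n_frames=cfg.frames.n_frames,
        t0_s=cfg.frames.t0_s, wavelength_um=cfg.frames.wavelength_um,
        pitch_fraction=cfg.frames.pitch_fraction,
        clutter_rank=cfg.frames.clutter_rank,
        clutter_amplitude=cfg.frames.clutter_amplitude,
        clutter_modulation=cfg.frames.clutter_modulation,
        noise_sigma=cfg.frames.noise_sigma,
        bubble_amplitude=cfg.frames.bubble_amplitude, seed=seeds[2])


def process_stack(fs: frames.FrameStack, cfg: PipelineConfig,
                  ensemble_size: int | None = None) -> list:
    """Filter, localize, link, smooth and pair: stack -> tracks."""
    ens = ensemble_size or cfg.filter.ensemble_size
    filt = svdfilt.filter_stack(fs, ens, cfg.filter.cutoff,
                                standardize=cfg.filter.standardize)
    dets = tracking.localize_stack(filt, threshold_nsigma=cfg.track.threshold_nsigma)
    kcfg = tracking.KalmanConfig(dt=1.0 / fs.frame_rate_hz,
                                 sigma_process=cfg.track.kalman_sigma,
                                 epsilon=cfg.track.kalman_epsilon,
                                 grid_um=cfg.track.kalman_grid_um)
    tracks = tracking.build_tracks(
        dets, fs.frame_rate_hz,
        max_step_um=cfg.track.max_step_wl * fs.wavelength_um,
        cfg=kcfg, t0_s=fs.t0_s, min_length=cfg.track.min_length)
    return tracking.pair_tracks(tracks, fs.wavelength_um,
                                max_gap_s=cfg.track.pairing_max_gap_s,
                                max_dist_wl=cfg.track.pairing_max_dist_wl)


def classify(tracks: list, cfg: PipelineConfig,
             model: hmm.HMMModel | None = None):
    seeds = stage_seeds(cfg.seed)
    return hmm.classify_tracks(
        tracks, v_thresh_mm_s=cfg.hmm.v_thresh_mm_s,
        a_thresh_mm_s2=cfg.hmm.a_thresh_mm_s2, cht_min_s=cfg.hmm.cht_min_s,
        standardized_length=cfg.hmm.standardized_length, model=model,
        n_restarts=cfg.hmm.n_restarts, seed=seeds[3], min_run=cfg.hmm.min_run)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute all enabled stages, writing outputs + manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    counts = {}
    stage = "graph/simulate"
    try:
        scene = simulate_scene(cfg)
        counts["bubbles"] = len(scene.transits)
        counts["complete_transits"] = int(sum(t.complete for t in scene.transits))
        counts["paths"] = len(scene.paths)
        graph.to_graphml(scene.vg, str(outdir / "graph.graphml"))
        graph.to_edge_csv(scene.vg, str(outdir / "edges.csv"))
        flow.transits_to_frame(scene.transits).to_csv(
            outdir / "transits.csv", index=False)

        stage = "frames"
        fs = render_scene(scene, cfg)
        counts["frames"] = fs.n_frames
        counts["clipped_positions"] = fs.n_clipped
        if cfg.save_frames:
            frames.save_h5(fs, str(outdir / "frames.h5"))

        stage = "filter/track"
        tracks = process_stack(fs, cfg)
        counts["tracks"] = len(tracks)
        tracking.tracks_to_frame(tracks).to_csv(outdir / "tracks.csv", index=False)

        calls, model, smap = [], None, None
        if cfg.run_classify:
            stage = "classify"
            calls, model = classify(tracks, cfg)
            counts["accepted_calls"] = int(sum(c.accepted for c in calls))
            hmm.calls_to_frame(calls).to_csv(outdir / "calls.csv", index=False)
            if model is not None:
                model.to_json(str(outdir / "hmm_model.json"))
        if cfg.run_maps and cfg.run_classify:
            stage = "maps/stats"
            Lx, _, Lz = cfg.graph.domain_um
            spec = maps.GridSpec.from_wavelength(
                (0.0, 0.0), (Lx, Lz), cfg.frames.wavelength_um,
                cfg.maps.scare_pitch_fraction)
            smap = maps.accumulate_scare_map(calls, tracks, spec)
            _write_map(smap, outdir)
            chts = [c.cht_s for c in calls if c.accepted]
            stats = {"n_accepted": len(chts),
                     "max_cht_s": max(chts) if chts else 0.0}
            if len(chts) >= 20:
                cs = maps.fit_cauchy(chts)
                stats.update(cauchy_location_s=cs.cauchy_location_s,
                             cauchy_scale_s=cs.cauchy_scale_s,
                             cauchy_loglik=cs.cauchy_loglik,
                             normal_loglik=cs.normal_loglik)
            with open(outdir / "stats.json", "w") as f:
                json.dump(stats, f, indent=2)
    except Exception:
        log.exception("pipeline failed at stage %s (partial outputs kept)", stage)
        raise
    manifest = {"config": json.loads(cfg.to_json()),
                "param_hash": cfg.param_hash(),
                "stage_seeds": stage_seeds(cfg.seed),
                "counts": counts,
                "skipped": [s for s, on in
                            (("classify", cfg.run_classify),
                             ("maps", cfg.run_maps)) if not on],
                "elapsed_s": round(time.time() - t_start, 2)}
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return PipelineResult(scene=scene, stack=fs if cfg.save_frames else None,
                          tracks=tracks, calls=calls, model=model,
                          scare_map=smap, counts=counts)


def _write_map(smap: maps.SCaReMap, outdir: Path) -> None:
    import tifffile
    tifffile.imwrite(str(outdir / "scare_map.tif"),
                     smap.grid.astype(np.float32))
    with open(outdir / "scare_map.json", "w") as f:
        json.dump({"pitch_um": smap.spec.pitch_um,
                   "origin_um": list(smap.spec.origin_um),
                   "total_dwell_s": smap.total_dwell_s,
                   "n_clipped": smap.n_clipped}, f, indent=2)


# ---------------------------------------------------------------------------
# LE vs SE comparison
# ---------------------------------------------------------------------------

def process_stack_short_ensembles(fs: frames.FrameStack, cfg: PipelineConfig,
                                  ensemble_size: int) -> list:
    """Conventional short-ensemble processing: each ensemble is an
    independent short acquisition (filtered, localized and tracked on its
    own), so no track can outlive one ensemble."""
    tracks = []
    for start in range(0, fs.n_frames, ensemble_size):
        size = min(ensemble_size, fs.n_frames - start)
        if size <= cfg.filter.cutoff + 1:
            continue
        sub = frames.FrameStack(
            frames=fs.frames[:, :, start:start + size],
            pixel_pitch_um=fs.pixel_pitch_um, frame_rate_hz=fs.frame_rate_hz,
            wavelength_um=fs.wavelength_um, origin_um=fs.origin_um,
            t0_s=fs.t0_s + start / fs.frame_rate_hz)
        tracks.extend(process_stack(sub, cfg, ensemble_size=size))
    for i, t in enumerate(tracks):
        t.track_id = i
    return tracks


def le_se_experiment(cfg: PipelineConfig, se_ensemble_s: float = 0.5,
                     le_ensemble: int = 6000) -> dict:
    """Max recovered capillary transit time: long vs short SVD ensembles.

    The same scene and frame stack are processed twice.  The SE arm mimics
    conventional non-continuous ULM: independent ``se_ensemble_s``-second
    acquisitions, each SVD-filtered and tracked on its own (a track cannot
    outlive its ensemble).  The LE arm filters ``le_ensemble``-frame
    continuous ensembles and tracks across the whole record.  Tracking and
    HMM classification parameters are identical; the figure of merit is
    the percent increase of the maximum accepted transit time under LE.
    """
    scene = simulate_scene(cfg)
    fs = render_scene(scene, cfg)
    se_frames = int(round(se_ensemble_s * cfg.frames.frame_rate_hz))
    out = {}
    for name in ("se", "le"):
        if name == "se":
            tracks = process_stack_short_ensembles(fs, cfg, se_frames)
        else:
            tracks = process_stack(fs, cfg, ensemble_size=le_ensemble)
        calls, _ = classify(tracks, cfg)
        chts = [c.cht_s for c in calls if c.accepted]
        out[name] = {"n_tracks": len(tracks),
                     "n_accepted": len(chts),
                     "max_cht_s": max(chts) if chts else 0.0}
    se_max, le_max = out["se"]["max_cht_s"], out["le"]["max_cht_s"]
    out["max_cht_truth_s"] = float(scene.cht_truth_s.max()) if len(
        scene.cht_truth_s) else 0.0
    out["pct_increase"] = (100.0 * (le_max - se_max) / se_max
                           if se_max > 0 else float("inf"))
    return out


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("diamond_graph", "u_track", "clutter20", "hmm_sequences")


def make_fixtures(kind: str, seed: int = 0, outdir: str | Path = "."):
    """Emit one of the small canonical inputs used throughout the tests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "diamond_graph":
        vg = diamond_graph()
        path = outdir / "diamond.graphml"
        graph.to_graphml(vg, str(path))
        return path
    if kind == "u_track":
        tr = synthetic_u_track(dwell_s=0.3)
        path = outdir / "u_track.csv"
        tracking.tracks_to_frame([tr]).to_csv(path, index=False)
        return path
    if kind == "clutter20":
        fs = frames.render_frames([], fov_um=(600.0, 600.0), n_frames=256,
                                  clutter_rank=20, noise_sigma=0.0, seed=seed)
        path = outdir / "clutter20.h5"
        frames.save_h5(fs, str(path))
        return path
    if kind == "hmm_sequences":
        rng = np.random.default_rng(seed)
        model = hmm.HMMModel(np.array([[0.95, 0.05], [0.10, 0.90]]),
                             np.array([[0.05, 0.05, 0.45, 0.45],
                                       [0.45, 0.45, 0.05, 0.05]]),
                             np.array([0.5, 0.5]))
        seqs = [sample_hmm(model, 100, rng)[1] for _ in range(200)]
        path = outdir / "hmm_sequences.json"
        with open(path, "w") as f:
            json.dump([s.tolist() for s in seqs], f)
        return path
    raise ValueError(f"unknown fixture kind {kind!r}; valid: {FIXTURE_KINDS}")


def diamond_graph() -> graph.VascularGraph:
    """Smallest fully-connected closure: two parallel capillaries."""
    nodes = {"in": (0, 0, 50), "a": (100, 0, 50), "A": (200, 0, 50),
             "V": (400, 0, 50), "v": (500, 0, 50), "out": (600, 0, 50)}
    edges = [
        dict(tail="in", head="a", radius_um=6.0, vessel_class="artery"),
        dict(tail="a", head="A", radius_um=4.0, vessel_class="arteriole"),
        dict(tail="A", head="V", radius_um=2.0, vessel_class="capillary"),
        dict(tail="A", head="V", radius_um=2.5, vessel_class="capillary"),
        dict(tail="V", head="v", radius_um=4.5, vessel_class="venule"),
        dict(tail="v", head="out", radius_um=7.0, vessel_class="vein"),
    ]
    return graph.build_graph(nodes, edges, inlets=["in"], outlets=["out"])


def synthetic_u_track(dwell_s: float, high_s: float = 0.5,
                      frame_rate_hz: float = 1000.0,
                      v_high_mm_s: float = 10.0, v_low_mm_s: float = 1.0,
                      ramp_s: float = 0.05, track_id: int = 0) -> tracking.Track:
    """Constructed high -> low -> high velocity track at a given dwell."""
    dt = 1.0 / frame_rate_hz
    n_hi = int(round(high_s / dt))
    n_lo = int(round(dwell_s / dt))
    n_ramp = int(round(ramp_s / dt))
    speed = np.concatenate([
        np.full(n_hi, v_high_mm_s),
        np.linspace(v_high_mm_s, v_low_mm_s, n_ramp),
        np.full(n_lo, v_low_mm_s),
        np.linspace(v_low_mm_s, v_high_mm_s, n_ramp),
        np.full(n_hi, v_high_mm_s)])
    t = np.arange(len(speed)) * dt
    x = np.cumsum(speed) * dt * 1e3          # mm/s * s -> um
    z = 0.3 * x
    norm = np.hypot(1.0, 0.3)
    return tracking.Track(track_id=track_id, t_s=t, x_um=x / norm, z_um=z / norm,
                          vx_mm_s=speed / norm, vz_mm_s=0.3 * speed / norm,
                          amplitude=np.ones_like(t))


def sample_hmm(model: hmm.HMMModel, length: int,
               rng: np.random.Generator):
    """Draw (states, symbols) from a discrete HMM (test/fixture utility)."""
    states = np.zeros(length, dtype=int)
    obs = np.zeros(length, dtype=int)
    states[0] = rng.choice(model.n_states, p=model.initial)
    for t in range(length):
        if t > 0:
            states[t] = rng.choice(model.n_states,
                                   p=model.transition[states[t - 1]])
        obs[t] = rng.choice(model.emission.shape[1],
                            p=model.emission[states[t]])
    return states, obs
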