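"""Pipeline configuration: every stage's parameters in one JSON-round-trip
object.

Defaults follow the method's printed operating point wherever one exists:
2 mm/s capillary velocity definition, 0.120 s minimum accepted transit
time, track pairing within one wavelength and 100 ms, 20-eigenvalue SVD
cutoff, 6000-frame long ensembles, 1 kHz compounded frame rate, 75%
systole-to-diastole velocity modulation travelling at 350 cm/s at 500 BPM.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .graph import GraphConfig


@dataclass
class SimConfig:
    n_bubbles: int = 200
    acquisition_s: float = 120.0       # bubble arrival window (s)
    inlet_pressure_pa: float = 36000.0
    outlet_pressure_pa: float = 0.0
    viscosity_pa_s: float = 3.5e-3
    heart_rate_bpm: float = 500.0
    modulation_depth: float = 0.75
    pulse_wave_velocity_cm_s: float = 350.0
    dt_s: float = 1e-4
    record_dt_s: float = 1e-3
    max_time_s: float = 40.0
    diameter_mean_um: float = 2.0
    diameter_sd_um: float = 3.0
    max_paths: int = 20000


@dataclass
class FrameConfig:
    frame_rate_hz: float = 1000.0
    n_frames: int = 12000
    t0_s: float = 30.0                 # rendered window start within the run
    wavelength_um: float = 150.0
    pitch_fraction: float = 1 / 8
    clutter_rank: int = 20
    clutter_amplitude: float = 30.0
    clutter_modulation: float = 0.05
    noise_sigma: float = 0.05
    bubble_amplitude: float = 1.0


@dataclass
class FilterConfig:
    ensemble_size: int = 6000          # LE default; SE uses ~0.5 s of frames
    cutoff: int = 20
    standardize: bool = True


@dataclass
class TrackConfig:
    threshold_nsigma: float = 4.0
    max_step_wl: float = 1.0           # linking step bound, wavelengths
    kalman_sigma: float = 1.0
    kalman_epsilon: float = 25.0
    kalman_grid_um: float = 1e-3
    pairing_max_gap_s: float = 0.100
    pairing_max_dist_wl: float = 1.0
    min_length: int = 3


@dataclass
class HMMConfig:
    v_thresh_mm_s: float = 2.0
    a_thresh_mm_s2: float | None = None    # None -> batch median |accel|
    cht_min_s: float = 0.120
    standardized_length: int = 100
    n_restarts: int = 5
    min_run: int = 3                       # run-length denoise, standardized scale


@dataclass
class MapConfig:
    scare_pitch_fraction: float = 1 / 32
    density_window_wl: float = 8.0


@dataclass
class PipelineConfig:
    seed: int = 0
    graph: GraphConfig = field(default_factory=GraphConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    frames: FrameConfig = field(default_factory=FrameConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    track: TrackConfig = field(default_factory=TrackConfig)
    hmm: HMMConfig = field(default_factory=HMMConfig)
    maps: MapConfig = field(default_factory=MapConfig)
    run_classify: bool = True
    run_maps: bool = True
    save_frames: bool = False

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=_jsonable)
        if path:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "PipelineConfig":
        """Load from a JSON string or a path to a JSON file."""
        if source.strip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as f:
                d = json.load(f)
        return cls(
            seed=d.get("seed", 0),
            graph=_build(GraphConfig, d.get("graph", {})),
            sim=_build(SimConfig, d.get("sim", {})),
            frames=_build(FrameConfig, d.get("frames", {})),
            filter=_build(FilterConfig, d.get("filter", {})),
            track=_build(TrackConfig, d.get("track", {})),
            hmm=_build(HMMConfig, d.get("hmm", {})),
            maps=_build(MapConfig, d.get("maps", {})),
            run_classify=d.get("run_classify", True),
            run_maps=d.get("run_maps", True),
            save_frames=d.get("save_frames", False),
        )

    def param_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _jsonable(o):
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON-serializable: {o!r}")


def _build(cls, d):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kw = {}
    for k, v in d.items():
        if k not in fields:
            raise ValueError(f"unknown {cls.__name__} field {k!r}")
        if isinstance(v, list):
            v = tuple(v)
        kw[k] = v
    return cls(**kw)
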