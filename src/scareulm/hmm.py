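"""2-state discrete HMM classification of capillary transits.

Track velocity profiles are encoded into a 4-symbol alphabet from speed and
acceleration thresholds, standardized in length for unsupervised
Baum-Welch training of a 2-state model (high-velocity vs low-velocity
state), decoded with Viterbi, and categorized: a track is accepted as a
single-capillary transit when its decoded state runs collapse to
high -> low -> high (the U-shape) and the low-velocity dwell lasts at least
a minimum capillary heterogeneous transit time (default 0.120 s).

Baum-Welch, the forward pass and Viterbi are implemented here in scaled /
log domain; they are generic in the number of states and symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tracking import Track

log = logging.getLogger(__name__)

CHT_MIN_S = 0.120                  # minimum accepted capillary transit time
V_THRESH_MM_S = 2.0                # capillary velocity definition
N_SYMBOLS = 4
EMISSION_FLOOR = 1e-6
ACCEL_QUANTILE = 0.9               # batch quantile setting the accel threshold


@dataclass
class HMMModel:
    """Row-stochastic transition/emission/initial parameters."""

    transition: np.ndarray          # (n_states, n_states)
    emission: np.ndarray            # (n_states, n_symbols)
    initial: np.ndarray             # (n_states,)

    def __post_init__(self):
        self.transition = np.asarray(self.transition, float)
        self.emission = np.asarray(self.emission, float)
        self.initial = np.asarray(self.initial, float)
        self.validate()

    def validate(self, tol: float = 1e-9) -> None:
        for name, m in (("transition", self.transition),
                        ("emission", self.emission)):
            if np.any(m < -tol):
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(m.sum(axis=1), 1.0, atol=tol):
                raise ValueError(f"{name} rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=tol):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    def low_state(self, low_symbols=(0, 1)) -> int:
        """Index of the low-velocity state: the one whose emissions put the
        most mass on the sub-threshold symbols."""
        mass = self.emission[:, list(low_symbols)].sum(axis=1)
        return int(np.argmax(mass))

    def to_json(self, path: str, **extra) -> None:
        import json
        with open(path, "w") as f:
            json.dump(dict(transition=self.transition.tolist(),
                           emission=self.emission.tolist(),
                           initial=self.initial.tolist(), **extra), f, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "HMMModel":
        import json
        with open(path) as f:
            d = json.load(f)
        return cls(np.array(d["transition"]), np.array(d["emission"]),
                   np.array(d["initial"]))


@dataclass
class CapillaryCall:
    """Classification outcome for one track."""

    track_id: int
    accepted: bool
    reason: str                     # "ok" | no_low | no_flank | multi_low | too_short
    state_sequence: np.ndarray = field(repr=False)
    low_interval_s: tuple | None = None      # (t_start, t_end)
    cht_s: float = 0.0


# ---------------------------------------------------------------------------
# observation encoding
# ---------------------------------------------------------------------------

SPEED_SMOOTH_S = 0.12        # one cardiac period at 500 BPM


def smoothed_speed(track: Track, smooth_s: float = SPEED_SMOOTH_S) -> np.ndarray:
    """Cycle-averaged speed: moving mean over one cardiac period.

    Pulsatile flow modulates the instantaneous speed by up to the full
    systole-diastole swing within every cycle; a boxcar average whose
    length equals the period cancels that periodic component exactly while
    preserving the slower envelope that distinguishes capillary dwell from
    arteriolar/venular flank flow.
    """
    speed = track.speed_mm_s
    if smooth_s <= 0 or len(track) < 5:
        return speed
    dt = track.dt_s
    win = int(round(smooth_s / dt))
    if win < 3:
        return speed
    from scipy.ndimage import uniform_filter1d
    return uniform_filter1d(speed, size=min(win, len(speed)), mode="nearest")


def track_acceleration(track: Track,
                       smooth_s: float = SPEED_SMOOTH_S) -> np.ndarray:
    """|d speed / dt| of the cycle-averaged speed, mm/s^2."""
    return np.abs(np.gradient(smoothed_speed(track, smooth_s), track.t_s))


def encode_observations(track: Track, v_thresh_mm_s: float = V_THRESH_MM_S,
                        a_thresh_mm_s2: float = 10.0,
                        smooth_s: float = SPEED_SMOOTH_S) -> np.ndarray:
    """4-symbol encoding: symbol = 2*[speed >= v_th] + [|accel| >= a_th].

    0: slow/steady, 1: slow/changing, 2: fast/steady, 3: fast/changing.
    Speed and acceleration are taken from the cycle-averaged speed trace.
    """
    if len(track) < 3:
        raise ValueError("track too short to encode (need >= 3 samples)")
    speed = smoothed_speed(track, smooth_s)
    accel = np.abs(np.gradient(speed, track.t_s))
    return (2 * (speed >= v_thresh_mm_s) + (accel >= a_thresh_mm_s2)).astype(int)


def standardize_length(sequences: Sequence[np.ndarray], length: int = 100):
    """Nearest-index resampling of symbol sequences to a common length.

    Run order is preserved and run proportions are approximately kept.
    Sequences shorter than 3 symbols are dropped (logged); the indices of
    the surviving sequences are returned alongside.
    """
    if length < 10:
        raise ValueError("standardized length must be >= 10")
    out, kept = [], []
    for i, s in enumerate(sequences):
        s = np.asarray(s)
        if len(s) < 3:
            log.info("dropping sequence %d (length %d < 3)", i, len(s))
            continue
        idx = np.rint(np.linspace(0, len(s) - 1, length)).astype(int)
        out.append(s[idx])
        kept.append(i)
    return out, kept


def map_states_to_native(states_std: np.ndarray, n_native: int) -> np.ndarray:
    """Inverse of :func:`standardize_length` for decoded state sequences.

    Native sample j takes the state of the standardized sample whose source
    index is nearest to j (piecewise-constant expansion).
    """
    L = len(states_std)
    idx = np.rint(np.linspace(0, n_native - 1, L)).astype(int)
    # boundaries at midpoints between consecutive source indices
    mid = (idx[:-1] + idx[1:]) / 2.0
    pos = np.searchsorted(mid, np.arange(n_native), side="right")
    return states_std[pos]


# ---------------------------------------------------------------------------
# forward / Baum-Welch / Viterbi
# ---------------------------------------------------------------------------

def forward_loglik(seq: np.ndarray, model: HMMModel) -> float:
    """Scaled forward pass; log P(sequence | model)."""
    A, B, pi = model.transition, model.emission, model.initial
    alpha = pi * B[:, seq[0]]
    ll = 0.0
    for t in range(len(seq)):
        if t > 0:
            alpha = (alpha @ A) * B[:, seq[t]]
        c = alpha.sum()
        if c <= 0:
            return -np.inf
        ll += np.log(c)
        alpha = alpha / c
    return float(ll)


def _forward_backward(seq, A, B, pi):
    T, n = len(seq), A.shape[0]
    alpha = np.zeros((T, n))
    beta = np.zeros((T, n))
    c = np.zeros(T)
    alpha[0] = pi * B[:, seq[0]]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * B[:, seq[t]]
        c[t] = alpha[t].sum()
        if c[t] <= 0:
            c[t] = np.finfo(float).tiny
        alpha[t] /= c[t]
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = A @ (B[:, seq[t + 1]] * beta[t + 1])
        beta[t] /= c[t + 1]
    return alpha, beta, c


def baum_welch(sequences: Sequence[np.ndarray], init: HMMModel,
               max_iter: int = 100, tol: float = 1e-6) -> tuple[HMMModel, list]:
    """EM estimation of a discrete HMM from multiple sequences.

    Returns the fitted model and the per-iteration total log-likelihood
    trace (nondecreasing up to round-off).  Emission columns for symbols
    never observed are floored at 1e-6 and renormalized.
    """
    if len(sequences) < 1:
        raise ValueError("need at least one sequence")
    A = init.transition.copy()
    B = init.emission.copy()
    pi = init.initial.copy()
    n = A.shape[0]
    n_sym = B.shape[1]
    ll_trace = []
    for it in range(max_iter):
        A_num = np.zeros_like(A)
        B_num = np.zeros_like(B)
        pi_num = np.zeros(n)
        gamma_sum = np.zeros(n)
        total_ll = 0.0
        for seq in sequences:
            seq = np.asarray(seq)
            alpha, beta, c = _forward_backward(seq, A, B, pi)
            total_ll += float(np.log(c).sum())
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            pi_num += gamma[0]
            for t in range(len(seq) - 1):
                xi = (alpha[t][:, None] * A * B[:, seq[t + 1]][None, :]
                      * beta[t + 1][None, :]) / c[t + 1]
                A_num += xi
            for s in range(n_sym):
                B_num[:, s] += gamma[seq == s].sum(axis=0)
            gamma_sum += gamma.sum(axis=0)
        ll_trace.append(total_ll)
        A = A_num / np.clip(A_num.sum(axis=1, keepdims=True), 1e-300, None)
        B = B_num / np.clip(gamma_sum[:, None], 1e-300, None)
        if np.any(B.sum(axis=1) == 0) or np.any(B < EMISSION_FLOOR):
            degenerate = B < EMISSION_FLOOR
            if degenerate.any():
                log.debug("flooring %d degenerate emission entries",
                          int(degenerate.sum()))
            B = np.clip(B, EMISSION_FLOOR, None)
        B /= B.sum(axis=1, keepdims=True)
        A = np.clip(A, EMISSION_FLOOR, None)
        A /= A.sum(axis=1, keepdims=True)
        pi = pi_num / pi_num.sum()
        pi = np.clip(pi, EMISSION_FLOOR, None)
        pi /= pi.sum()
        if it > 0 and abs(ll_trace[-1] - ll_trace[-2]) < tol * abs(ll_trace[-2] + 1e-12):
            break
    return HMMModel(A, B, pi), ll_trace


def random_model(n_states: int = 2, n_symbols: int = N_SYMBOLS,
                 rng: np.random.Generator | None = None,
                 stickiness: float = 8.0) -> HMMModel:
    """Random row-stochastic initialization, biased toward sticky states."""
    rng = rng or np.random.default_rng()
    A = rng.dirichlet(np.ones(n_states), size=n_states)
    A = (A + stickiness * np.eye(n_states))
    A /= A.sum(axis=1, keepdims=True)
    B = rng.dirichlet(np.ones(n_symbols), size=n_states)
    pi = rng.dirichlet(np.ones(n_states))
    return HMMModel(A, B, pi)


def structured_model(n_symbols: int = N_SYMBOLS) -> HMMModel:
    """Velocity-informed initialization: state 0 prefers sub-threshold
    symbols {0, 1}, state 1 the supra-threshold ones {2, 3}."""
    B = np.full((2, n_symbols), 0.1 / (n_symbols - 2))
    B[0, :2] = [0.55, 0.35]
    B[1, 2:4] = [0.55, 0.35]
    B /= B.sum(axis=1, keepdims=True)
    A = np.array([[0.95, 0.05], [0.05, 0.95]])
    return HMMModel(A, B, np.array([0.5, 0.5]))


def fit_hmm(sequences: Sequence[np.ndarray], n_restarts: int = 5,
            seed: int = 0, max_iter: int = 100, tol: float = 1e-6) -> HMMModel:
    """Baum-Welch from a velocity-informed start plus random restarts.

    The best likelihood wins among candidates whose two states actually
    separate sub- from supra-threshold symbols (emission mass difference on
    symbols {0, 1} above 0.5); if no candidate separates, the overall best
    likelihood is returned.
    """
    rng = np.random.default_rng(seed)
    inits = [structured_model()] + [random_model(rng=rng)
                                    for _ in range(max(n_restarts - 1, 0))]
    cands = []
    for init in inits:
        model, trace = baum_welch(sequences, init, max_iter=max_iter, tol=tol)
        if trace:
            cands.append((trace[-1], model))
    if not cands:
        return None
    separated = [c for c in cands if np.abs(
        np.diff(c[1].emission[:, :2].sum(axis=1)))[0] > 0.5]
    pool = separated or cands
    return max(pool, key=lambda c: c[0])[1]


def viterbi(seq: np.ndarray, model: HMMModel) -> np.ndarray:
    """Most probable state path, log domain, ties toward lower state index."""
    seq = np.asarray(seq)
    with np.errstate(divide="ignore"):
        logA = np.log(model.transition)
        logB = np.log(model.emission)
        logpi = np.log(model.initial)
    if np.all(np.isinf(logB[:, seq].max(axis=0))):
        log.warning("zero-probability sequence; using uniform emission floor")
        logB = np.log(np.clip(model.emission, EMISSION_FLOOR, None))
    T, n = len(seq), model.n_states
    delta = logpi + logB[:, seq[0]]
    back = np.zeros((T, n), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA
        back[t] = np.argmax(scores, axis=0)      # argmax -> lowest index on ties
        delta = scores[back[t], np.arange(n)] + logB[:, seq[t]]
    states = np.zeros(T, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        states[t] = back[t + 1][states[t + 1]]
    return states


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------

def _runs(states: np.ndarray):
    """Collapse a state sequence into (state, start, stop) runs."""
    runs = []
    i = 0
    while i < len(states):
        j = i
        while j < len(states) and states[j] == states[i]:
            j += 1
        runs.append((int(states[i]), i, j))
        i = j
    return runs


def denoise_states(states: np.ndarray, min_run: int = 3) -> np.ndarray:
    """Absorb runs shorter than ``min_run`` into the preceding run."""
    states = states.copy()
    runs = _runs(states)
    for s, i, j in runs:
        if j - i < min_run and i > 0:
            states[i:j] = states[i - 1]
    return states


EDGE_TRIM_S = 0.2          # ignore sub-0.2 s runs at the ends of a track


def categorize(track: Track, states: np.ndarray, low_state: int,
               cht_min_s: float = CHT_MIN_S,
               min_run: int = 0,
               edge_trim_s: float = EDGE_TRIM_S) -> CapillaryCall:
    """Accept a track as a single-capillary transit if its decoded states
    collapse to exactly high -> low -> high with a low dwell >= cht_min_s.

    Velocity estimates in the first and last fraction of a second of a
    track are unreliable (filter warm-up, one-sided smoothing at the
    boundary), so state runs shorter than ``edge_trim_s`` at either end are
    discarded before pattern matching.  The CHT is measured on the track's
    own time axis as (number of low-state samples) x (sample interval);
    rejections carry a reason code.
    """
    if min_run > 1:
        states = denoise_states(states, min_run)
    runs = _runs(states)
    dt = track.dt_s
    while len(runs) > 3 and (runs[0][2] - runs[0][1]) * dt < edge_trim_s:
        runs = runs[1:]
    while len(runs) > 3 and (runs[-1][2] - runs[-1][1]) * dt < edge_trim_s:
        runs = runs[:-1]
    low_runs = [r for r in runs if r[0] == low_state]
    kw = dict(track_id=track.track_id, state_sequence=states)
    if not low_runs:
        return CapillaryCall(accepted=False, reason="no_low", **kw)
    if len(low_runs) > 1:
        return CapillaryCall(accepted=False, reason="multi_low", **kw)
    if len(runs) != 3 or runs[1][0] != low_state:
        return CapillaryCall(accepted=False, reason="no_flank", **kw)
    i, j = runs[1][1], runs[1][2]
    cht = (j - i) * dt
    interval = (float(track.t_s[i]), float(track.t_s[j - 1]))
    if cht < cht_min_s:
        return CapillaryCall(accepted=False, reason="too_short",
                             low_interval_s=interval, cht_s=cht, **kw)
    return CapillaryCall(accepted=True, reason="ok",
                         low_interval_s=interval, cht_s=cht, **kw)


def classify_tracks(tracks: Sequence[Track],
                    v_thresh_mm_s: float = V_THRESH_MM_S,
                    a_thresh_mm_s2: float | None = None,
                    cht_min_s: float = CHT_MIN_S,
                    standardized_length: int = 100,
                    model: HMMModel | None = None,
                    n_restarts: int = 5, seed: int = 0,
                    min_run: int = 0,
                    min_train: int = 10) -> tuple[list[CapillaryCall], HMMModel]:
    """Encode, (optionally) train, decode and categorize a batch of tracks.

    Training is unsupervised on the length-standardized symbol sequences of
    the whole batch (one batch = one acquisition buffer); decoding runs on
    each track's native-length sequence so dwell times are measured on the
    real time axis.  With ``a_thresh_mm_s2=None`` the acceleration
    threshold defaults to the batch median of |accel|.  A pre-trained
    ``model`` skips training.
    """
    tracks = [t for t in tracks if len(t) >= 3]
    if not tracks:
        return [], model
    if a_thresh_mm_s2 is None:
        all_acc = np.concatenate([track_acceleration(t) for t in tracks])
        a_thresh_mm_s2 = float(np.quantile(all_acc, ACCEL_QUANTILE))
        if a_thresh_mm_s2 <= 0:
            a_thresh_mm_s2 = 1e-9
    seqs = [encode_observations(t, v_thresh_mm_s, a_thresh_mm_s2)
            for t in tracks]
    std_seqs, _ = standardize_length(seqs, standardized_length)
    if model is None:
        if len(std_seqs) < min_train:
            log.warning("only %d sequences; training may be unstable",
                        len(std_seqs))
        model = fit_hmm(std_seqs, n_restarts=n_restarts, seed=seed)
    low = model.low_state()
    calls = []
    for t, s_std in zip(tracks, std_seqs):
        st = viterbi(s_std, model)
        if min_run > 1:
            st = denoise_states(st, min_run)   # at the standardized scale
        states = map_states_to_native(st, len(t))
        calls.append(categorize(t, states, low, cht_min_s=cht_min_s))
    return calls, model


def calls_to_frame(calls: Sequence[CapillaryCall]):
    import pandas as pd
    return pd.DataFrame([
        dict(track_id=c.track_id, accepted=c.accepted, reason=c.reason,
             cht_s=c.cht_s,
             t_start_s=c.low_interval_s[0] if c.low_interval_s else np.nan,
             t_end_s=c.low_interval_s[1] if c.low_interval_s else np.nan)
        for c in calls])
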