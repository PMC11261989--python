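"""Discrete HMM machinery and capillary-transit categorization."""

import itertools

import numpy as np
import pytest

from scareulm import hmm as H
from scareulm.pipeline import sample_hmm, synthetic_u_track

WELL_SEPARATED = H.HMMModel(
    transition=np.array([[0.95, 0.05], [0.10, 0.90]]),
    emission=np.array([[0.05, 0.05, 0.45, 0.45],
                       [0.45, 0.45, 0.05, 0.05]]),
    initial=np.array([0.5, 0.5]))


def brute_force_loglik(seq, model):
    """Sum over all 2^T state paths (exhaustive oracle)."""
    total = 0.0
    n = model.n_states
    for path in itertools.product(range(n), repeat=len(seq)):
        p = model.initial[path[0]] * model.emission[path[0], seq[0]]
        for a, b, o in zip(path[:-1], path[1:], seq[1:]):
            p *= model.transition[a, b] * model.emission[b, o]
        total += p
    return np.log(total)


def brute_force_viterbi(seq, model):
    best, best_p = None, -1.0
    n = model.n_states
    for path in itertools.product(range(n), repeat=len(seq)):
        p = model.initial[path[0]] * model.emission[path[0], seq[0]]
        for a, b, o in zip(path[:-1], path[1:], seq[1:]):
            p *= model.transition[a, b] * model.emission[b, o]
        if p > best_p:
            best, best_p = path, p
    return np.array(best)


class TestModel:
    def test_row_stochastic_enforced(self):
        with pytest.raises(ValueError):
            H.HMMModel(np.array([[0.9, 0.2], [0.1, 0.9]]),
                       WELL_SEPARATED.emission, WELL_SEPARATED.initial)

    def test_low_state_identification(self):
        assert WELL_SEPARATED.low_state() == 1

    def test_json_round_trip(self, tmp_path):
        p = tmp_path / "m.json"
        WELL_SEPARATED.to_json(str(p))
        back = H.HMMModel.from_json(str(p))
        assert np.allclose(back.transition, WELL_SEPARATED.transition)
        assert np.allclose(back.emission, WELL_SEPARATED.emission)


class TestEncoding:
    def test_constant_fast_track(self):
        t = synthetic_u_track(dwell_s=0.0, high_s=0.5, ramp_s=0.0,
                              v_low_mm_s=10.0)
        seq = H.encode_observations(t, 2.0, 1e9)
        assert set(seq) == {2}

    def test_constant_slow_track(self):
        t = synthetic_u_track(dwell_s=0.0, high_s=0.5, ramp_s=0.0,
                              v_high_mm_s=1.0, v_low_mm_s=1.0)
        seq = H.encode_observations(t, 2.0, 1e9)
        assert set(seq) == {0}

    def test_u_profile_symbol_structure(self):
        t = synthetic_u_track(dwell_s=0.5)
        seq = H.encode_observations(t, 2.0, 1e9)
        n = len(seq)
        assert np.all(seq[: n // 5] == 2)
        assert np.all(seq[n // 2 - 50: n // 2 + 50] == 0)
        assert np.all(seq[-n // 5:] == 2)

    def test_short_track_rejected(self):
        t = synthetic_u_track(dwell_s=0.3)
        t.t_s = t.t_s[:2]
        t.vx_mm_s = t.vx_mm_s[:2]
        t.vz_mm_s = t.vz_mm_s[:2]
        with pytest.raises(ValueError):
            H.encode_observations(t)


class TestStandardize:
    def test_exact_length_preserved_content(self):
        seq = np.array([0, 0, 1, 1, 2] * 20)
        out, kept = H.standardize_length([seq], len(seq))
        assert np.array_equal(out[0], seq)

    def test_run_proportions(self):
        seq = np.array([0] * 50 + [2] * 50)
        out, _ = H.standardize_length([seq], 10)
        assert list(out[0]) == [0] * 5 + [2] * 5

    def test_short_sequences_dropped(self):
        out, kept = H.standardize_length([np.array([1]), np.arange(4) % 4], 10)
        assert kept == [1]

    def test_run_order_never_permuted(self, rng):
        """Property: resampling preserves the order of symbol runs."""
        def runs(s):
            return [k for k, _ in itertools.groupby(s)]
        for _ in range(200):
            n = rng.integers(10, 400)
            seq = rng.integers(0, 4, n)
            out, _ = H.standardize_length([seq], 100)
            r_out = runs(out[0])
            r_in = runs(seq)
            # resampled runs are a subsequence of the input runs
            it = iter(r_in)
            assert all(any(x == y for y in it) for x in r_out)

    def test_native_mapping_round_trip(self):
        states = np.array([0] * 30 + [1] * 40 + [0] * 30)
        std, _ = H.standardize_length([states], 50)
        back = H.map_states_to_native(std[0], 100)
        assert np.mean(back == states) > 0.95


class TestForwardViterbi:
    @pytest.mark.parametrize("T", [1, 3, 7, 12])
    def test_forward_matches_brute_force(self, T, rng):
        for _ in range(5):
            seq = rng.integers(0, 4, T)
            ll = H.forward_loglik(seq, WELL_SEPARATED)
            assert ll == pytest.approx(brute_force_loglik(seq, WELL_SEPARATED),
                                       rel=1e-9)

    @pytest.mark.parametrize("T", [1, 4, 8, 12])
    def test_viterbi_matches_brute_force(self, T, rng):
        for _ in range(5):
            seq = rng.integers(0, 4, T)
            assert np.array_equal(H.viterbi(seq, WELL_SEPARATED),
                                  brute_force_viterbi(seq, WELL_SEPARATED))

    def test_length_one_sequence(self):
        seq = np.array([0])
        expect = int(np.argmax(WELL_SEPARATED.initial
                               * WELL_SEPARATED.emission[:, 0]))
        assert H.viterbi(seq, WELL_SEPARATED)[0] == expect

    def test_near_deterministic_decoding(self, rng):
        states, obs = sample_hmm(WELL_SEPARATED, 200, rng)
        sharp = H.HMMModel(WELL_SEPARATED.transition,
                           np.array([[0.01, 0.01, 0.49, 0.49],
                                     [0.49, 0.49, 0.01, 0.01]]),
                           WELL_SEPARATED.initial)
        _, obs2 = sample_hmm(sharp, 300, rng)
        states2, obs2 = sample_hmm(sharp, 300, rng)
        decoded = H.viterbi(obs2, sharp)
        assert np.mean(decoded == states2) > 0.9


class TestBaumWelch:
    def test_parameter_recovery(self, rng):
        """200 sequences of length 100 from a known 2-state model: the
        transition matrix is recovered within +-0.05 up to relabeling."""
        seqs = [sample_hmm(WELL_SEPARATED, 100, rng)[1] for _ in range(200)]
        model = H.fit_hmm(seqs, n_restarts=3, seed=0)
        A = model.transition
        target = WELL_SEPARATED.transition
        direct = np.abs(A - target).max()
        swapped = np.abs(A[::-1, ::-1] - target).max()
        assert min(direct, swapped) < 0.05

    def test_likelihood_monotone(self, rng):
        seqs = [rng.integers(0, 4, 50) for _ in range(10)]
        init = H.random_model(rng=np.random.default_rng(3))
        _, trace = H.baum_welch(seqs, init, max_iter=30)
        assert np.all(np.diff(trace) > -1e-8)

    def test_single_symbol_concentrates_emission(self):
        seqs = [np.zeros(50, dtype=int) for _ in range(12)]
        model, _ = H.baum_welch(seqs, WELL_SEPARATED, max_iter=50)
        assert np.all(model.emission[:, 0] > 0.99)

    def test_rows_stay_stochastic(self, rng):
        seqs = [rng.integers(0, 4, 60) for _ in range(15)]
        model, _ = H.baum_welch(seqs, H.random_model(rng=rng), max_iter=20)
        model.validate(tol=1e-9)


class TestCategorize:
    def run_states(self, track, spec):
        """spec: list of (state, seconds)."""
        dt = track.dt_s
        parts = [np.full(int(round(sec / dt)), st) for st, sec in spec]
        states = np.concatenate(parts)
        # pad/trim to track length
        if len(states) < len(track):
            states = np.concatenate(
                [states, np.full(len(track) - len(states), spec[-1][0])])
        return states[: len(track)]

    def test_clean_u_accepted(self):
        t = synthetic_u_track(dwell_s=0.3, high_s=0.5)
        states = self.run_states(t, [(1, 0.52), (0, 0.36), (1, 0.52)])
        call = H.categorize(t, states, low_state=0)
        assert call.accepted
        assert call.cht_s == pytest.approx(0.36, abs=0.01)

    def test_low_run_below_threshold_rejected(self):
        t = synthetic_u_track(dwell_s=0.08, high_s=0.5)
        states = self.run_states(t, [(1, 0.55), (0, 0.08), (1, 0.55)])
        call = H.categorize(t, states, low_state=0)
        assert not call.accepted and call.reason == "too_short"

    def test_all_high_rejected(self):
        t = synthetic_u_track(dwell_s=0.0, high_s=0.5, ramp_s=0.0,
                              v_low_mm_s=10.0)
        states = np.ones(len(t), dtype=int)
        call = H.categorize(t, states, low_state=0)
        assert not call.accepted and call.reason == "no_low"

    def test_two_dwells_rejected(self):
        t = synthetic_u_track(dwell_s=1.0, high_s=0.5)
        states = self.run_states(
            t, [(1, 0.5), (0, 0.4), (1, 0.4), (0, 0.4), (1, 0.5)])
        call = H.categorize(t, states, low_state=0)
        assert not call.accepted and call.reason == "multi_low"

    def test_edge_junk_runs_ignored(self):
        """Sub-0.2 s runs at the very ends (estimator warm-up artifacts)
        do not break the U-pattern."""
        t = synthetic_u_track(dwell_s=0.4, high_s=0.5)
        states = self.run_states(
            t, [(0, 0.05), (1, 0.5), (0, 0.45), (1, 0.45), (0, 0.05)])
        call = H.categorize(t, states, low_state=0)
        assert call.accepted

    def test_missing_flank_rejected(self):
        t = synthetic_u_track(dwell_s=0.5, high_s=0.5)
        states = self.run_states(t, [(0, 0.7), (1, 0.8)])
        call = H.categorize(t, states, low_state=0)
        assert not call.accepted and call.reason in ("no_flank", "multi_low")


class TestClassifyBatch:
    def test_dwell_threshold_sweep(self):
        """Synthetic U-tracks with dwells from 0.05 to 1.0 s: every
        accepted call reports a transit time of at least the 0.120 s
        minimum, and long dwells are accepted."""
        tracks = [synthetic_u_track(dwell_s=d, track_id=i)
                  for i, d in enumerate(np.arange(0.05, 1.001, 0.05))]
        calls, model = H.classify_tracks(tracks, seed=0)
        accepted = [c for c in calls if c.accepted]
        assert accepted
        assert min(c.cht_s for c in accepted) >= 0.120
        long_ids = {c.track_id for c in calls
                    if c.accepted and c.cht_s >= 0.3}
        assert len(long_ids) >= 10

    def test_pretrained_model_path(self):
        tracks = [synthetic_u_track(dwell_s=0.4, track_id=i)
                  for i in range(3)]
        calls, model = H.classify_tracks(tracks, model=WELL_SEPARATED)
        assert model is WELL_SEPARATED
        assert len(calls) == 3
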