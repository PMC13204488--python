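"""MFCC features, DTW alignment, normalization and Sigma-Delta encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurolsm import (
    EncoderConfig,
    FeatureMatrix,
    SigmaDeltaConfig,
    SpikeRaster,
    Waveform,
    align_to_length,
    dtw_warp,
    encode_utterance,
    extract_features,
    normalize_features,
    sigma_delta_encode,
    spike_metrics,
)
from neurolsm.encoding import _delta


def dtw_bruteforce(a, b):
    """Minimum cost over exhaustive enumeration of monotone warp paths."""
    a = np.atleast_2d(a.T).T if a.ndim == 1 else a
    na, nb = len(a), len(b)
    best = [np.inf]

    def cost(i, j):
        return float(np.linalg.norm(np.atleast_1d(a[i]) - np.atleast_1d(b[j])))

    def walk(i, j, acc):
        acc = acc + cost(i, j)
        if acc >= best[0]:
            return
        if i == na - 1 and j == nb - 1:
            best[0] = acc
            return
        if i + 1 < na:
            walk(i + 1, j, acc)
        if j + 1 < nb:
            walk(i, j + 1, acc)
        if i + 1 < na and j + 1 < nb:
            walk(i + 1, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def make_features(values, frame_step=0.01):
    values = np.asarray(values, dtype=float)
    if values.shape[0] != 39:
        full = np.zeros((39, values.shape[1]))
        full[: values.shape[0]] = values
        values = full
    return FeatureMatrix(values=values, frame_step=frame_step)


class TestExtractFeatures:
    def test_output_has_39_rows(self, audio_small):
        f = extract_features(audio_small.waveforms[0])
        assert f.values.shape[0] == 39
        assert f.n_frames > 10

    def test_constant_statics_zero_dynamics(self):
        static = np.tile(np.arange(13.0)[:, None], (1, 20))
        d1 = _delta(static, 2)
        assert np.allclose(d1, 0.0)
        assert np.allclose(_delta(d1, 2), 0.0)

    def test_cepstral_ramp_delta_closed_form(self):
        # c_t = a*t: central difference with N=2 gives exactly a at interior
        # frames ((1*2a + 2*4a) / (2*(1+4)) = a), and 0 second difference
        a = 0.37
        ramp = a * np.arange(30.0)[None, :]
        d1 = _delta(ramp, 2)
        assert np.allclose(d1[0, 2:-2], a, atol=1e-12)
        d2 = _delta(d1, 2)
        assert np.allclose(d2[0, 4:-4], 0.0, atol=1e-12)

    def test_too_short_waveform_rejected(self):
        w = Waveform(samples=np.zeros(50), sample_rate=12500)
        with pytest.raises(ValueError, match="short"):
            extract_features(w)


class TestDtw:
    def test_identical_sequences(self):
        x = np.random.default_rng(0).standard_normal((5, 3))
        d, path = dtw_warp(x, x)
        assert d == pytest.approx(0.0)
        assert path == [(i, i) for i in range(5)]

    def test_single_frames(self):
        d, path = dtw_warp(np.array([1.0]), np.array([2.0]))
        assert d == pytest.approx(1.0)
        assert path == [(0, 0)]

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            na, nb = rng.integers(1, 7, size=2)
            a = rng.standard_normal((na, 2))
            b = rng.standard_normal((nb, 2))
            d, path = dtw_warp(a, b)
            assert d == pytest.approx(dtw_bruteforce(a, b), abs=1e-10)
            assert path[0] == (0, 0) and path[-1] == (na - 1, nb - 1)
            steps = np.diff(np.array(path), axis=0)
            assert np.all(steps >= 0) and np.all(steps <= 1)

    def test_symmetric_for_symmetric_metric(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((4, 3))
        b = rng.standard_normal((6, 3))
        assert dtw_warp(a, b)[0] == pytest.approx(dtw_warp(b, a)[0])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            dtw_warp(np.empty((0, 3)), np.ones((2, 3)))


class TestAlign:
    def test_already_at_target_unchanged(self):
        f = make_features(np.random.default_rng(0).standard_normal((39, 10)))
        out = align_to_length(f, 10, reference=f)
        assert np.allclose(out.values, f.values)

    def test_self_reference_diagonal(self):
        f = make_features(np.random.default_rng(1).standard_normal((39, 10)))
        out = align_to_length(f, 10)
        assert np.allclose(out.values, f.values)

    def test_path_application_oracle(self):
        ramp = make_features(np.arange(6.0)[None, :] * np.ones((39, 1)))
        out = align_to_length(ramp, 3)
        from neurolsm.encoding import _uniform_stretch, dtw_warp as warp

        ref = _uniform_stretch(ramp.values, 3)
        _, path = warp(ramp.values.T, ref.T)
        expected = np.zeros((39, 3))
        counts = np.zeros(3)
        for i, j in path:
            expected[:, j] += ramp.values[:, i]
            counts[j] += 1
        expected /= counts
        assert np.allclose(out.values, expected)

    def test_alignment_preserves_frame_step(self):
        f = make_features(np.random.default_rng(2).standard_normal((39, 20)))
        out = align_to_length(f, 8)
        assert out.frame_step == f.frame_step
        assert out.n_frames == 8


class TestNormalize:
    def test_constant_column_all_zeros(self):
        f = make_features(np.full((39, 4), 3.3))
        out = normalize_features(f)
        # epsilon-guarded division leaves only ~1e-7 float residue
        assert np.allclose(out.values, 0.0, atol=1e-5)

    def test_columns_standardized(self):
        f = make_features(np.random.default_rng(0).standard_normal((39, 7)) * 5)
        out = normalize_features(f)
        assert np.all(np.abs(out.values.mean(axis=0)) < 1e-9)
        assert np.allclose(out.values.std(axis=0), 1.0, atol=1e-6)

    def test_three_feature_toy_column(self):
        # population SD of [1,2,3] is sqrt(2/3) -> normalized +-1.2247
        x = np.array([[1.0], [2.0], [3.0]])
        mu, sd = x.mean(), x.std()
        expected = (x - mu) / (sd + 1e-8)
        assert np.allclose(
            expected.ravel(), [-1.22474487, 0.0, 1.22474487], atol=1e-7
        )
        f = make_features(np.tile(x, (13, 1)))
        out = normalize_features(f, epsilon=1e-8)
        vals = np.unique(np.round(out.values, 7))
        assert np.allclose(vals, [-1.2247449, 0.0, 1.2247449])

    def test_idempotent_up_to_epsilon(self):
        f = make_features(np.random.default_rng(4).standard_normal((39, 5)))
        once = normalize_features(f)
        twice = normalize_features(once)
        assert np.allclose(once.values, twice.values, atol=1e-6)


class TestSigmaDelta:
    def test_zero_input_no_spikes(self):
        r = sigma_delta_encode(make_features(np.zeros((39, 50))))
        assert r.values.sum() == 0

    def test_constant_half_fifty_spikes(self):
        f = make_features(np.full((1, 100), 0.5))
        r = sigma_delta_encode(f, SigmaDeltaConfig(theta=1.0, alpha=0.0))
        assert r.values[0].sum() == 50
        # period-2 limit cycle: spikes on even steps (1-based), i.e. odd idx
        assert np.array_equal(np.unique(np.nonzero(r.values[0])[0] % 2), [1])

    def test_constant_one_every_step(self):
        f = make_features(np.ones((1, 100)))
        r = sigma_delta_encode(f, SigmaDeltaConfig(theta=1.0, alpha=0.0))
        assert r.values[0].sum() == 100

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=30, deadline=None)
    def test_deficit_bound(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(200)
        f = make_features(x[None, :])
        r = sigma_delta_encode(f, SigmaDeltaConfig(theta=1.0, alpha=0.0))
        y = r.values[0].astype(float)
        deficits = np.abs(np.cumsum(x - y))
        assert np.all(deficits <= 1.0 + 1.0 + 1e-9)

    def test_long_run_rate_tracks_input(self):
        # alpha=0, constant x in [0, theta]: spike rate -> x/theta
        n = 2000
        for x in [0.1, 0.35, 0.8]:
            f = make_features(np.full((1, n), x))
            r = sigma_delta_encode(f, SigmaDeltaConfig(theta=1.0, alpha=0.0))
            rate = r.values[0].mean()
            assert abs(rate - x) <= 1.0 / n + 1e-9

    def test_nonfinite_rejected(self):
        f = make_features(np.zeros((39, 5)))
        bad = f.values.copy()
        with pytest.raises(ValueError):
            FeatureMatrix(
                values=np.where(np.eye(39, 5) > 0, np.nan, bad), frame_step=0.01
            )


class TestSpikeMetrics:
    def test_all_zero_raster(self):
        r = SpikeRaster(values=np.zeros((39, 10), dtype=np.uint8), dt=0.01)
        count, sparsity = spike_metrics(r)
        assert count == 0 and sparsity == 1.0

    def test_arithmetic(self):
        values = np.zeros((39, 100), dtype=np.uint8)
        values[np.arange(39), np.arange(39)] = 1
        count, sparsity = spike_metrics(SpikeRaster(values=values, dt=0.01))
        assert count == 39
        assert sparsity == pytest.approx(0.99)

    def test_encoder_sparsity_on_synthetic_utterances(self, audio_small):
        sparsities = []
        for w in audio_small.waveforms[:10]:
            _, s = spike_metrics(encode_utterance(w))
            sparsities.append(s)
        assert np.mean(sparsities) >= 0.9


class TestEncodeUtterance:
    def test_deterministic(self, audio_small):
        w = audio_small.waveforms[0]
        r1 = encode_utterance(w)
        r2 = encode_utterance(w)
        assert np.array_equal(r1.values, r2.values)

    def test_channel_count(self, audio_small):
        assert encode_utterance(audio_small.waveforms[1]).n_channels == 39

    def test_composition_equals_pipeline(self, audio_small):
        w = audio_small.waveforms[2]
        cfg = EncoderConfig(target_frames=30)
        manual = sigma_delta_encode(
            normalize_features(
                align_to_length(
                    extract_features(
                        w,
                        frame_length=cfg.frame_length,
                        frame_step=cfg.frame_step,
                        n_mel=cfg.n_mel,
                        context_n=cfg.context_n,
                        n_cepstra=cfg.n_cepstra,
                        pre_emphasis=cfg.pre_emphasis,
                    ),
                    cfg.target_frames,
                ),
                epsilon=cfg.epsilon,
            ),
            cfg.sigma_delta,
        )
        auto = encode_utterance(w, cfg)
        assert np.array_equal(manual.values, auto.values)

    def test_spike_count_well_below_dense_bound(self, audio_small):
        ratios = []
        for w in audio_small.waveforms[:10]:
            r = encode_utterance(w)
            count, _ = spike_metrics(r)
            ratios.append(count / r.values.size)
        assert np.mean(ratios) <= 1.0 / 5.0
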