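"""Feature extraction, LPP, LDA and the consecutive-window brain switch."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import brainswitch as bs
from brainswitch.detection import DetectionEvent, lda_scores
from brainswitch.exceptions import DegenerateDataError, InvalidParameterError


def make_windows(vectors, fs=100.0, labels=None, step=0.1):
    vectors = np.asarray(vectors, dtype=float)
    n = vectors.shape[0]
    if labels is None:
        labels = np.full(n, "noise", dtype="<U8")
    ends = 2.0 + step * np.arange(n)
    return bs.WindowSet(windows=vectors, end_times=ends, labels=labels,
                        sampling_rate=fs, length=vectors.shape[1] / fs,
                        step=step)


class TestTimeseriesFeatures:
    def test_decimated_length(self, rng):
        ws = make_windows(rng.standard_normal((5, 2400)), fs=1200.0)
        feats = bs.make_timeseries_features(ws, 60)
        assert feats.vectors.shape == (5, 40)

    def test_factor_one_is_identity(self, rng):
        x = rng.standard_normal((3, 200))
        feats = bs.make_timeseries_features(make_windows(x), 1)
        assert np.array_equal(feats.vectors, x)

    def test_identical_windows_identical_vectors(self, rng):
        row = rng.standard_normal(200)
        feats = bs.make_timeseries_features(make_windows(np.tile(row, (4, 1))), 5)
        assert np.allclose(feats.vectors, feats.vectors[0])

    def test_overdecimation_rejected(self, rng):
        ws = make_windows(rng.standard_normal((2, 200)))
        with pytest.raises(InvalidParameterError):
            bs.make_timeseries_features(ws, 80)


class TestSubbandFeatures:
    def test_beta_band_has_fifteen_bins(self, rng):
        ws = make_windows(rng.standard_normal((4, 400)), fs=200.0)
        feats = bs.make_subband_features(ws, bs.CANONICAL_BANDS["beta"])
        assert feats.dim == 15  # integer frequencies 16..30 Hz

    def test_sinusoid_peaks_at_its_bin(self):
        fs = 200.0
        t = np.arange(400) / fs
        ws = make_windows(np.tile(np.sin(2 * np.pi * 20.0 * t), (3, 1)), fs=fs)
        feats = bs.make_subband_features(ws, bs.CANONICAL_BANDS["beta"])
        freqs = np.arange(16.0, 31.0)
        assert np.all(freqs[np.argmax(feats.vectors, axis=1)] == 20.0)

    def test_zero_window_gives_zero_vector(self):
        ws = make_windows(np.zeros((2, 400)), fs=200.0)
        feats = bs.make_subband_features(ws, bs.CANONICAL_BANDS["alpha"])
        assert np.all(feats.vectors == 0.0)

    def test_band_above_nyquist_rejected(self, rng):
        ws = make_windows(rng.standard_normal((2, 100)), fs=50.0)
        with pytest.raises(InvalidParameterError):
            bs.make_subband_features(ws, bs.CANONICAL_BANDS["gamma"])


def dense_lpp_oracle(x, m, k):
    """Straightforward dense LPP: full distance matrix, argsort k-NN graph,
    heat-kernel weights, dense generalized eigensolver."""
    from scipy.linalg import eigh

    n = x.shape[0]
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    width = d2[~np.eye(n, dtype=bool)].mean()
    w = np.zeros((n, n))
    for i in range(n):
        for j in np.argsort(d2[i])[1:k + 1]:
            w[i, j] = np.exp(-d2[i, j] / width)
    w = np.maximum(w, w.T)
    deg = np.diag(w.sum(1))
    lap = deg - w
    a, b = x.T @ lap @ x, x.T @ deg @ x
    evals, evecs = eigh(0.5 * (a + a.T), 0.5 * (b + b.T))
    return evecs[:, :m]


def principal_angles(u, v):
    qu, _ = np.linalg.qr(u)
    qv, _ = np.linalg.qr(v)
    s = np.clip(np.linalg.svd(qu.T @ qv, compute_uv=False), -1.0, 1.0)
    return np.arccos(s)


class TestLPP:
    def test_subspace_matches_dense_oracle(self, rng):
        x = rng.standard_normal((100, 20))
        model = bs.fit_lpp(x, m=3, k=5)
        oracle = dense_lpp_oracle(x, m=3, k=5)
        assert principal_angles(model.combined, oracle).max() < 1e-6

    def test_one_dimensional_embedding_separates_clouds(self, rng):
        a = rng.standard_normal((40, 5)) * 0.3
        b = rng.standard_normal((40, 5)) * 0.3 + 8.0
        x = np.vstack([a, b])
        model = bs.fit_lpp(x, m=1, k=4)
        z = bs.project_lpp(model, x).ravel()
        for i in range(80):
            others = np.delete(np.arange(80), i)
            nearest = others[np.argmin(np.abs(z[others] - z[i]))]
            assert (i < 40) == (nearest < 40)

    def test_projection_has_m_columns(self, rng):
        model = bs.fit_lpp(rng.standard_normal((50, 12)), m=4, k=5)
        assert model.combined.shape == (12, 4)

    def test_projection_is_linear(self, rng):
        model = bs.fit_lpp(rng.standard_normal((30, 8)), m=2, k=3)
        x = rng.standard_normal(8)
        assert np.allclose(bs.project_lpp(model, 3.0 * x),
                           3.0 * bs.project_lpp(model, x))
        assert np.allclose(bs.project_lpp(model, np.zeros(8)), 0.0)

    def test_rank_deficient_data_uses_pre_projection(self, rng):
        x = rng.standard_normal((30, 50))  # d > n
        model = bs.fit_lpp(x, m=5, k=4)
        assert model.pre_projection is not None
        assert bs.project_lpp(model, x).shape == (30, 5)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            bs.fit_lpp(rng.standard_normal((5, 8)), m=2, k=5)

    def test_zero_variance_features_degenerate(self):
        with pytest.raises(DegenerateDataError):
            bs.fit_lpp(np.ones((20, 6)), m=2, k=3)

    def test_dimension_mismatch_rejected(self, rng):
        model = bs.fit_lpp(rng.standard_normal((30, 8)), m=2, k=3)
        with pytest.raises(InvalidParameterError):
            bs.project_lpp(model, np.zeros(9))


class TestLDA:
    def test_matches_frozen_closed_form_on_toy_set(self):
        x = np.array([[0.0, 0.0], [1.0, 0.5], [0.5, -0.5], [-0.5, 0.2],
                      [0.2, 0.8], [3.0, 1.0], [2.5, 2.0], [3.5, 0.5],
                      [2.8, 1.5], [3.2, 1.2]])
        y = np.array(["noise"] * 5 + ["signal"] * 5)
        model = bs.fit_lda(x, y)
        # frozen from the closed form S^-1 (mu1 - mu0) on this fixed set
        assert model.weights == pytest.approx([15.65453897, 8.91772349])
        assert model.bias == pytest.approx(-31.78111404)

    def test_recovers_separation_direction(self, rng):
        n = 2000
        x = np.vstack([rng.standard_normal((n, 6)) - np.eye(6)[0],
                       rng.standard_normal((n, 6)) + np.eye(6)[0]])
        y = np.array([False] * n + [True] * n)
        w = bs.fit_lda(x, y).weights
        cos = abs(w[0]) / np.linalg.norm(w)
        assert np.degrees(np.arccos(cos)) < 5.0

    def test_duplicating_samples_leaves_model_unchanged(self, rng):
        x = rng.standard_normal((40, 4))
        y = rng.integers(0, 2, 40).astype(bool)
        y[:2] = [True, False]
        a = bs.fit_lda(x, y)
        b = bs.fit_lda(np.vstack([x, x]), np.concatenate([y, y]))
        assert np.allclose(a.weights, b.weights, rtol=0.2)
        assert np.allclose(a.mean_signal, b.mean_signal)
        # scores rank identically
        s_a, s_b = lda_scores(a, x), lda_scores(b, x)
        assert np.array_equal(np.argsort(s_a), np.argsort(s_b))

    def test_agrees_with_sklearn_direction(self, rng):
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis").LinearDiscriminantAnalysis
        x = rng.standard_normal((300, 5))
        y = rng.integers(0, 2, 300).astype(bool)
        x[y] += [1.0, 0.5, 0.0, -0.5, 0.2]
        ours = bs.fit_lda(x, y).weights
        theirs = sklearn_lda(solver="lsqr").fit(x, y).coef_.ravel()
        cos = ours @ theirs / (np.linalg.norm(ours) * np.linalg.norm(theirs))
        assert cos > 0.999

    def test_single_class_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            bs.fit_lda(rng.standard_normal((10, 3)), np.ones(10, dtype=bool))


class TestScoreWindows:
    def test_one_label_per_window_and_deterministic(self, rng):
        x = rng.standard_normal((60, 6))
        y = np.zeros(60, bool)
        y[:20] = True
        x[y] += 2.0
        lda = bs.fit_lda(x, y)
        flags = bs.score_windows(None, lda, x)
        assert flags.shape == (60,)
        assert np.array_equal(flags, bs.score_windows(None, lda, x))

    def test_separable_training_data_reproduced_exactly(self, rng):
        x = rng.standard_normal((80, 3))
        y = np.zeros(80, bool)
        y[:40] = True
        x[y] += 50.0  # overwhelming separation
        lda = bs.fit_lda(x, y)
        assert np.array_equal(bs.score_windows(None, lda, x), y)


def run_detector(bits, wn, refractory=2.0, step=0.1):
    labels = np.array(bits, dtype=bool)
    times = step * np.arange(1, labels.size + 1)
    cfg = bs.DetectorConfig(wn=wn, refractory=refractory)
    return [d.time for d in bs.run_online_detector(labels, times, cfg)]


class TestOnlineDetector:
    def test_single_run_fires_once_at_wn_th_window(self):
        assert run_detector([0, 1, 1, 1, 0], wn=3) == [pytest.approx(0.4)]

    def test_interrupted_runs_never_fire(self):
        assert run_detector([1, 1, 0, 1, 1, 0], wn=3) == []

    def test_refractory_suppresses_immediate_refire(self):
        assert len(run_detector([1] * 6, wn=3, refractory=0.4)) == 1

    def test_zero_refractory_refires_every_wn_windows(self):
        assert len(run_detector([1] * 6, wn=3, refractory=0.0)) == 2

    def test_wn_one_fires_on_every_unblocked_signal(self):
        assert len(run_detector([1, 0, 1], wn=1, refractory=0.0)) == 2

    @given(st.lists(st.booleans(), min_size=1, max_size=30),
           st.integers(min_value=1, max_value=5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_detection_count_non_increasing_in_wn(self, bits, wn):
        n_low = len(run_detector(bits, wn=wn))
        n_high = len(run_detector(bits, wn=wn + 1))
        assert n_high <= n_low

    def test_invalid_wn_rejected(self):
        with pytest.raises(InvalidParameterError):
            bs.DetectorConfig(wn=0)


class TestClassifyDetections:
    def test_latency_rule(self):
        events = [DetectionEvent(time=10.5), DetectionEvent(time=25.5)]
        out = bs.classify_detections(events, cues=[10.0, 24.0])
        assert out[0].label == "TP" and out[0].latency == pytest.approx(0.5)
        assert out[1].label == "FP" and out[1].latency == pytest.approx(1.5)

    def test_boundaries_are_half_open(self):
        out = bs.classify_detections([DetectionEvent(time=9.0),
                                      DetectionEvent(time=31.0)],
                                     cues=[10.0, 30.0])
        assert out[0].label == "FP"  # DL = -1 exactly -> excluded
        assert out[1].label == "TP"  # DL = +1 exactly -> included

    def test_one_tp_per_cue(self):
        events = [DetectionEvent(time=10.2), DetectionEvent(time=10.6)]
        out = bs.classify_detections(events, cues=[10.0])
        assert [e.label for e in out] == ["TP", "FP"]

    def test_detection_assigned_to_nearest_cue(self):
        out = bs.classify_detections([DetectionEvent(time=19.4)],
                                     cues=[10.0, 20.0])
        assert out[0].latency == pytest.approx(-0.6)
        assert out[0].label == "TP"
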