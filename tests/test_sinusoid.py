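"""Statistical sinusoid detection: peak features, models, tracks, SD features."""

import numpy as np
import pytest
from scipy import stats
from sklearn.mixture import GaussianMixture

from alarmdet import sinusoid, synth
from alarmdet.sinusoid import (
    PeakModels,
    detect_sinusoid_tracks,
    extract_peak_features,
    extract_sd_features,
    load_peak_models,
    save_peak_models,
    score_peak,
    score_peak_batch,
)
from alarmdet.spectral import compute_spectrogram

FS = 24000.0


def _tone_spec(freq, seconds=2.0, amp=1.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(seconds * FS)
    wave = amp * np.sin(2 * np.pi * freq * np.arange(n) / FS)
    if noise:
        wave = wave + noise * rng.standard_normal(n)
    return compute_spectrogram(wave, FS, "rectangular", 2048, 1024, 2048)


class TestPeakFeatures:
    def test_centre_element_of_magnitude_shape_is_one(self):
        spec = _tone_spec(1000.0, noise=0.05)
        for pf in extract_peak_features(spec, 5, M=6):
            assert pf.y1[6] == 1.0
            assert np.all(pf.y1 >= 0)
            assert np.all((pf.y2 > -np.pi) & (pf.y2 <= np.pi + 1e-12))

    def test_stationary_bin_centred_tone_has_zero_phase_residual(self):
        m = 340  # bin-centred on the padded grid
        spec = _tone_spec(m * FS / 4096)
        peaks = extract_peak_features(spec, 10, M=6)
        tone_peak = min(peaks, key=lambda p: abs(p.k_p - m))
        assert abs(tone_peak.k_p - m) <= 1
        assert tone_peak.y2[6] == pytest.approx(0.0, abs=1e-6)

    def test_noise_phase_residuals_are_uniform(self):
        # >= 1e4 noise peaks from NON-overlapping frames (overlap correlates
        # consecutive spectra and biases the phase difference towards the
        # deterministic advance): chi-square cannot reject uniformity
        rng = np.random.default_rng(7)
        spec = compute_spectrogram(
            rng.standard_normal(int(5.0 * FS)), FS, "rectangular", 2048, 2048, 2048
        )
        feats, _, _ = sinusoid._all_peak_features(spec, 6)
        centre = feats[:, 13 + 6]
        assert len(centre) >= 10_000
        counts, _ = np.histogram(centre, bins=20, range=(-np.pi, np.pi))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_phase_residual_disperses_for_noise_but_not_for_tones(self, peak_models):
        # variance of the centre phase residual: noise peaks vs tone peaks
        rng = np.random.default_rng(8)
        noise_spec = compute_spectrogram(
            rng.standard_normal(int(1.5 * FS)), FS, "rectangular", 2048, 1024, 2048
        )
        nf, _, _ = sinusoid._all_peak_features(noise_spec, 6)
        tone_spec = _tone_spec(1234.5, noise=0.02, seed=9)
        tf, kp, _ = sinusoid._all_peak_features(tone_spec, 6)
        near = np.abs(kp - 1234.5 * 4096 / FS) <= 1
        var_noise = np.var(nf[:, 13 + 6])
        var_tone = np.var(tf[near, 13 + 6])
        assert var_noise / var_tone >= 5.0

    def test_frame_zero_rejected(self):
        spec = _tone_spec(1000.0)
        with pytest.raises(ValueError, match="previous frame"):
            extract_peak_features(spec, 0, M=6)


class TestPeakModels:
    def test_model_dimension_follows_context(self, small_peak_models):
        assert small_peak_models.dim == 26  # 2*(2*6+1)

    def test_training_is_deterministic_under_seed(self):
        kw = dict(n_components=2, rng_seed=9, n_sinusoid_examples=30, n_noise_examples=6)
        a = sinusoid.train_peak_models(**kw)
        b = sinusoid.train_peak_models(**kw)
        assert np.array_equal(a.lambda_s.means_, b.lambda_s.means_)
        assert np.array_equal(a.lambda_n.covariances_, b.lambda_n.covariances_)

    def test_weights_sum_to_one(self, small_peak_models):
        assert small_peak_models.lambda_s.weights_.sum() == pytest.approx(1.0, abs=1e-9)
        assert small_peak_models.lambda_n.weights_.sum() == pytest.approx(1.0, abs=1e-9)

    def test_heldout_sinusoid_peaks_prefer_sinusoid_model(self, peak_models):
        corpus = synth.synth_sinusoid_corpus(
            40, seed=777, noise_fraction=0.0, snr_reference="unit_amplitude"
        )
        margins = []
        for ex in corpus:
            spec = compute_spectrogram(ex.wave, FS, "rectangular", 2048, 1024, 2048)
            feats, kp, _ = sinusoid._all_peak_features(spec, 6)
            true_bin = round(ex.freq * 4096 / FS)
            near = np.abs(kp - true_bin) <= 1
            if near.any():
                s, n = score_peak_batch(feats[near], peak_models)
                margins.append(np.mean(s - n))
        assert np.mean(margins) > 0

    def test_roundtrip_persistence(self, small_peak_models, tmp_path):
        path = tmp_path / "models.npz"
        save_peak_models(small_peak_models, path)
        loaded = load_peak_models(path)
        spec = _tone_spec(700.0, noise=0.1)
        pf = extract_peak_features(spec, 4, M=6)[0]
        assert score_peak(pf, loaded) == pytest.approx(score_peak(pf, small_peak_models))


class TestScorePeak:
    def test_standard_normal_loglik_closed_form(self):
        # 1 component, zero mean, identity covariance, zero input:
        # log N(0; 0, I) = -D/2 * log(2 pi), D = 26
        gmm = GaussianMixture(n_components=1, covariance_type="diag", reg_covar=1e-12)
        gmm.fit(np.random.default_rng(0).standard_normal((500, 26)))
        gmm.weights_ = np.array([1.0])
        gmm.means_ = np.zeros((1, 26))
        gmm.covariances_ = np.ones((1, 26))
        from sklearn.mixture._gaussian_mixture import _compute_precision_cholesky

        gmm.precisions_cholesky_ = _compute_precision_cholesky(gmm.covariances_, "diag")
        models = PeakModels(lambda_s=gmm, lambda_n=gmm, M=6, training_snr_db=-7.0)
        s, _ = score_peak_batch(np.zeros((1, 26)), models)
        assert s[0] == pytest.approx(-13.0 * np.log(2 * np.pi), abs=1e-9)
        assert s[0] == pytest.approx(-23.89, abs=1e-2)

    def test_batch_and_single_scoring_agree(self, small_peak_models):
        spec = _tone_spec(1500.0, noise=0.2)
        peaks = extract_peak_features(spec, 3, M=6)[:5]
        batch = score_peak_batch(np.array([p.vector for p in peaks]), small_peak_models)
        for i, pf in enumerate(peaks):
            s, n = score_peak(pf, small_peak_models)
            # scoring is pure; BLAS summation order differs with batch shape
            assert s == pytest.approx(batch[0][i], rel=1e-9)
            assert n == pytest.approx(batch[1][i], rel=1e-9)

    def test_dimension_mismatch_rejected(self, small_peak_models):
        with pytest.raises(ValueError, match="dimension mismatch"):
            score_peak_batch(np.zeros((1, 10)), small_peak_models)


class TestTracks:
    def test_clean_tone_yields_one_long_track(self, peak_models):
        spec = _tone_spec(2000.0, seconds=(2048 + 49 * 1024) / FS, noise=0.01, seed=1)
        assert spec.n_frames == 50
        tracks = detect_sinusoid_tracks(spec, peak_models)
        tone_bin = round(2000.0 * 4096 / FS)
        at_tone = [t for t in tracks if abs(t.bins[0] - tone_bin) <= 1]
        assert len(at_tone) == 1
        assert at_tone[0].duration >= 48
        # anything else a detector may report is the rectangular window's own
        # sidelobe structure, well below the main component
        main = at_tone[0].mean_energy_db
        assert all(t.mean_energy_db <= main - 10 for t in tracks if t is not at_tone[0])

    def test_short_blip_removed_by_duration_filter(self, peak_models):
        # tone present in only 2 frames
        n = 2048 + 9 * 1024
        wave = 0.02 * np.random.default_rng(3).standard_normal(n)
        start = 4 * 1024
        wave[start : start + 2 * 1024] += np.sin(
            2 * np.pi * 3000.0 * np.arange(2 * 1024) / FS
        )
        spec = compute_spectrogram(wave, FS, "rectangular", 2048, 1024, 2048)
        tracks = detect_sinusoid_tracks(spec, peak_models, min_frames=3)
        assert all(t.duration >= 3 for t in tracks)
        assert not any(abs(t.bins[0] - round(3000 * 4096 / FS)) <= 2 and t.duration < 3 for t in tracks)

    def test_energy_floor_removes_much_weaker_track(self, peak_models):
        n = int(2.0 * FS)
        t = np.arange(n) / FS
        wave = np.sin(2 * np.pi * 1000.0 * t) + 10 ** (-50 / 20) * np.sin(2 * np.pi * 3000.0 * t)
        wave += 1e-5 * np.random.default_rng(0).standard_normal(n)
        spec = compute_spectrogram(wave, FS, "rectangular", 2048, 1024, 2048)
        tracks = detect_sinusoid_tracks(spec, peak_models, energy_floor_db=40.0)
        bins = {round(tr.bins.mean() * FS / 4096 / 100) for tr in tracks}
        assert 10 in bins  # 1 kHz survives
        assert 30 not in bins  # 3 kHz is 50 dB down: filtered

    def test_empty_spectrogram_gives_no_tracks(self, small_peak_models):
        spec = compute_spectrogram(np.zeros(2048), FS, "rectangular", 2048, 1024, 2048)
        assert detect_sinusoid_tracks(spec, small_peak_models) == []


@pytest.fixture(scope="module")
def cls_two_freqs():
    return synth.AlarmClassSpec(
        "t2",
        (synth.AlarmVersion(tones=(synth.Tone((800.0, 2500.0), 0.3),), l_sil=0.4),),
    )


class TestSdFeatures:
    def test_feature_dimensions_by_mode(self, small_peak_models, cls_two_freqs):
        spec = _tone_spec(800.0, noise=0.1)
        for mode, dim in [("ratio", 2), ("llh", 4), ("llh_amp", 6)]:
            feats = extract_sd_features(spec, small_peak_models, cls_two_freqs, mode)
            assert feats.dim == dim
            assert feats.n_frames == spec.n_frames

    def test_single_tone_magnitude_concentrates_in_its_region(
        self, peak_models, cls_two_freqs
    ):
        spec = _tone_spec(800.0, noise=0.01, seed=2)
        feats = extract_sd_features(spec, peak_models, cls_two_freqs, "llh_amp")
        norm_mags = feats.vectors[5:, 2::3]
        assert np.all(norm_mags.sum(axis=1) == pytest.approx(1.0, abs=1e-9))
        assert np.all(norm_mags[:, 0] > 0.95)

    def test_amplitude_doubling_leaves_normalised_magnitudes(self, peak_models, cls_two_freqs):
        rng = np.random.default_rng(4)
        n = int(1.5 * FS)
        wave = np.sin(2 * np.pi * 800.0 * np.arange(n) / FS) + 0.1 * rng.standard_normal(n)
        s1 = compute_spectrogram(wave, FS, "rectangular", 2048, 1024, 2048)
        s2 = compute_spectrogram(2 * wave, FS, "rectangular", 2048, 1024, 2048)
        f1 = extract_sd_features(s1, peak_models, cls_two_freqs, "llh_amp")
        f2 = extract_sd_features(s2, peak_models, cls_two_freqs, "llh_amp")
        assert np.allclose(f1.vectors[:, 2::3], f2.vectors[:, 2::3], atol=1e-6)

    def test_out_of_band_region_rejected(self, small_peak_models):
        bad = synth.AlarmClassSpec(
            "bad", (synth.AlarmVersion(tones=(synth.Tone((13000.0,), 0.2),), l_sil=0.3),)
        )
        spec = _tone_spec(1000.0)
        with pytest.raises(ValueError, match="out of band"):
            extract_sd_features(spec, small_peak_models, bad)
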