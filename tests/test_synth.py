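"""Synthetic data generator: registry structure, alarms, scenes, corpora."""

import numpy as np
import pytest

from alarmdet import evaluate, io as adio, synth
from alarmdet.spectral import compute_spectrogram, region_bins
from alarmdet.synth import (
    SceneEvent,
    SceneSpec,
    default_registry,
    registry_from_yaml,
    registry_to_yaml,
    render_scene,
    synth_alarm,
    synth_sinusoid_corpus,
)

FS = 24000.0


class TestRegistry:
    def test_contains_exactly_the_studied_classes(self):
        ids = {c.class_id for c in default_registry()}
        assert ids == {"a1", "a3", "a6", "a7", "a8", "a10", "a16"}

    def test_only_a3_has_consecutive_tones(self):
        for cls in default_registry():
            n_tones = len(cls.versions[0].tones)
            assert n_tones >= 2 if cls.class_id == "a3" else n_tones == 1

    def test_a16_shares_its_single_frequency_with_a1_and_a8(self):
        reg = {c.class_id: c for c in default_registry()}
        a16 = reg["a16"].frequencies
        assert len(a16) == 1
        assert a16[0] in reg["a1"].frequencies
        assert a16[0] in reg["a8"].frequencies

    def test_a6_has_the_shortest_period(self):
        reg = default_registry()
        periods = {c.class_id: c.period for c in reg}
        assert min(periods, key=periods.get) == "a6"

    def test_versioned_classes(self):
        reg = {c.class_id: c for c in default_registry()}
        for cid in ("a1", "a3", "a7", "a10"):
            assert len(reg[cid].versions) >= 2
        # period structure holds in every version
        for cls in reg.values():
            for v in cls.versions:
                assert v.l_sig + v.l_sil == pytest.approx(v.period, abs=1e-3)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "registry.yaml"
        registry_to_yaml(default_registry(), path)
        loaded = registry_from_yaml(path)
        assert [c.class_id for c in loaded] == [c.class_id for c in default_registry()]
        assert loaded[0].frequencies == default_registry()[0].frequencies


class TestSynthAlarm:
    def test_period_start_spacing(self):
        cls = default_registry()[0]
        wave, onsets = synth_alarm(cls, 0, 3, FS)
        assert len(onsets) == 3
        assert np.allclose(np.diff(onsets), cls.period, atol=1e-6)
        assert len(wave) == pytest.approx(3 * cls.period * FS, abs=3)

    def test_silence_intervals_are_exactly_zero(self):
        cls = default_registry()[0]
        wave, _ = synth_alarm(cls, 0, 2, FS)
        sig_n = int(round(cls.l_sig * FS))
        per_n = int(round(cls.period * FS))
        margin = int(0.02 * FS)
        assert np.all(wave[sig_n + margin : per_n - margin] == 0)

    def test_band_power_concentrates_at_alarm_frequencies(self):
        cls = [c for c in default_registry() if c.class_id == "a10"][0]
        wave, _ = synth_alarm(cls, 0, 4, FS)
        spec = compute_spectrogram(wave, FS, "hann", 2048, 1024, 0)
        sig_frames = spec.magnitude[:, :3] ** 2  # inside the first signal interval
        lo, hi = region_bins(cls.frequencies[0], 20.0, spec)
        in_band = sig_frames[lo : hi + 1].sum()
        assert in_band / sig_frames.sum() >= 0.99

    def test_nyquist_violation_rejected(self):
        bad = synth.AlarmClassSpec(
            "bad", (synth.AlarmVersion(tones=(synth.Tone((20000.0,), 0.2),), l_sil=0.2),)
        )
        with pytest.raises(ValueError, match="out of band"):
            synth_alarm(bad, 0, 1, FS)


@pytest.fixture(scope="module")
def scene_and_spec(registry3):
    spec = SceneSpec(
        duration=20.0,
        events=[
            SceneEvent("a1", 0, 2.0, 8, 10.0),
            SceneEvent("a10", 0, 11.5, 6, 10.0),
            SceneEvent("a7", 0, 12.0, 5, 12.0),  # overlaps the a10 event
        ],
        seed=99,
    )
    return render_scene(spec, registry3), spec


class TestRenderScene:
    def test_target_snr_achieved_within_one_db(self, scene_and_spec, registry3):
        scene, _ = scene_and_spec
        sgram = compute_spectrogram(scene.inside, FS, "hann", 2048, 1024, 0)
        by_id = {c.class_id: c for c in registry3}
        rows = scene.annotations[scene.annotations.class_id == "a1"]
        snrs = [
            evaluate.local_snr(sgram, (r.onset_sec, r.offset_sec), by_id["a1"])
            for r in rows.itertuples()
        ]
        # measured on the mixture: 10*log10(10 + 1) = 10.4 dB for a 10 dB target
        assert np.mean(snrs) == pytest.approx(10.4, abs=1.0)

    def test_overlapping_events_all_annotated(self, scene_and_spec):
        scene, _ = scene_and_spec
        ann = scene.annotations
        assert set(ann.class_id) == {"a1", "a10", "a7"}
        a10 = ann[ann.class_id == "a10"]
        a7 = ann[ann.class_id == "a7"]
        assert a10.onset_sec.min() < a7.onset_sec.max()  # truly overlapping in time

    def test_same_seed_bit_identical(self, scene_and_spec, registry3, tmp_path):
        scene, spec = scene_and_spec
        again = render_scene(spec, registry3)
        assert np.array_equal(scene.outside, again.outside)
        assert np.array_equal(scene.inside, again.inside)
        adio.write_wav(tmp_path / "a.wav", scene.outside, FS)
        adio.write_wav(tmp_path / "b.wav", again.outside, FS)
        assert (tmp_path / "a.wav").read_bytes() == (tmp_path / "b.wav").read_bytes()

    def test_inside_channel_is_attenuated(self, scene_and_spec):
        scene, _ = scene_and_spec
        assert np.mean(scene.inside**2) < np.mean(scene.outside**2)

    def test_zero_background_rejected(self, registry3):
        spec = SceneSpec(duration=5.0, events=[SceneEvent("a1", 0, 1.0, 2, 10.0)],
                         seed=1, background_level=0.0)
        with pytest.raises(ValueError, match="zero background"):
            render_scene(spec, registry3)

    def test_event_exceeding_duration_rejected(self, registry3):
        spec = SceneSpec(duration=5.0, events=[SceneEvent("a1", 0, 2.0, 10, 10.0)], seed=1)
        with pytest.raises(ValueError, match="exceeds"):
            render_scene(spec, registry3)


class TestSinusoidCorpus:
    def test_per_example_broadband_snr_is_exact(self):
        corpus = synth_sinusoid_corpus(20, snr_db=-7.0, seed=3, noise_fraction=0.25)
        for ex in corpus:
            if not ex.is_sinusoid:
                continue
            n = len(ex.wave)
            t = np.arange(n) / FS
            # project out the known sinusoid to recover signal and noise parts
            basis = np.vstack([np.sin(2 * np.pi * ex.freq * t), np.cos(2 * np.pi * ex.freq * t)])
            coef = np.linalg.lstsq(basis.T, ex.wave, rcond=None)[0]
            sin_part = coef @ basis
            noise_part = ex.wave - sin_part
            snr = 10 * np.log10(np.mean(sin_part**2) / np.mean(noise_part**2))
            assert snr == pytest.approx(-7.0, abs=0.5)

    def test_labels_partition_examples(self):
        corpus = synth_sinusoid_corpus(40, seed=4, noise_fraction=0.5)
        assert sum(ex.is_sinusoid for ex in corpus) == 20
        for ex in corpus:
            assert ex.is_sinusoid == (ex.freq > 0)

    def test_frequencies_within_documented_range(self):
        corpus = synth_sinusoid_corpus(100, seed=5, noise_fraction=0.0)
        freqs = np.array([ex.freq for ex in corpus])
        assert np.all((freqs > 80.0) & (freqs < 11000.0))


class TestAnnotationRoundTrip:
    def test_write_read_identical_to_one_ms(self, tmp_path, registry3):
        spec = SceneSpec(
            duration=12.0, events=[SceneEvent("a7", 1, 1.0, 5, 15.0)], seed=5
        )
        scene = render_scene(spec, registry3)
        path = tmp_path / "ann.csv"
        adio.write_annotations(path, scene.annotations)
        loaded = adio.read_annotations(path)
        assert len(loaded) == len(scene.annotations)
        assert np.allclose(loaded.onset_sec, scene.annotations.onset_sec, atol=1e-3)
        assert np.allclose(loaded.offset_sec, scene.annotations.offset_sec, atol=1e-3)
        assert list(loaded.class_id) == list(scene.annotations.class_id)
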