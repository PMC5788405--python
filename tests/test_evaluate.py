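"""Evaluation metrics: frame rates, DET curves, PB-ERR, local SNR, CV harness."""

import numpy as np
import pytest

from alarmdet import evaluate, synth
from alarmdet.evaluate import (
    FrameCounts,
    PeriodCounts,
    cross_validate,
    det_curve,
    frame_metrics,
    local_snr,
    pb_err,
    stratify_by_snr,
)
from alarmdet.spectral import compute_spectrogram
from alarmdet.temporal import EventSet

FS = 24000.0


def _events(*ts):
    return EventSet(timestamps=np.array(ts, dtype=int))


class TestFrameMetrics:
    def test_perfect_detection(self):
        ref = np.array([0, 1, 1, 0, 1])
        mr, far, _ = frame_metrics(ref, ref)
        assert mr == 0.0 and far == 0.0

    def test_formula_on_constructed_labels(self):
        ref = np.concatenate([np.ones(100), np.zeros(900)])
        hyp = ref.copy()
        hyp[:10] = 0  # 10 misses
        hyp[100:109] = 1  # 9 false alarms
        mr, far, counts = frame_metrics(ref, hyp)
        assert mr == pytest.approx(0.10)
        assert far == pytest.approx(0.01)
        assert counts == FrameCounts(100, 900, 10, 9)

    def test_all_alarm_hypothesis(self):
        ref = np.array([1, 0, 0, 1])
        mr, far, _ = frame_metrics(ref, np.ones(4))
        assert mr == 0.0 and far == 1.0

    def test_absent_class_reports_nan(self):
        mr, far, _ = frame_metrics(np.zeros(5), np.zeros(5))
        assert np.isnan(mr) and far == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            frame_metrics(np.zeros(4), np.zeros(5))


class TestDetCurve:
    def test_separable_scores_touch_origin(self):
        scores = np.array([3.0, 2.5, 2.0, -1.0, -2.0])
        ref = np.array([1, 1, 1, 0, 0])
        curve = det_curve(scores, ref)
        assert any((m == 0 and f == 0) for m, f in zip(curve.miss_rate, curve.false_alarm_rate))
        assert curve.eer == 0.0

    def test_endpoint_operating_points(self):
        scores = np.array([0.1, 0.9, 0.4, 0.6])
        ref = np.array([0, 1, 0, 1])
        curve = det_curve(scores, ref)
        assert curve.miss_rate[0] == 0.0 and curve.false_alarm_rate[0] == 1.0
        assert np.all(np.diff(curve.miss_rate) >= 0)
        assert np.all(np.diff(curve.false_alarm_rate) <= 0)

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 1, 1000)
        ref = (rng.random(1000) < 0.3).astype(int)
        curve = det_curve(scores, ref)
        for thr, mr, far in zip(
            curve.thresholds[::97], curve.miss_rate[::97], curve.false_alarm_rate[::97]
        ):
            hyp = scores >= thr
            assert mr == np.mean(~hyp[ref == 1])
            assert far == np.mean(hyp[ref == 0])

    def test_consistent_with_frame_metrics_at_threshold(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(0, 1, 500)
        ref = (rng.random(500) < 0.5).astype(int)
        curve = det_curve(scores, ref)
        i = len(curve.thresholds) // 2
        mr, far, _ = frame_metrics(ref, scores >= curve.thresholds[i])
        assert mr == curve.miss_rate[i] and far == curve.false_alarm_rate[i]


class TestPbErr:
    def test_perfect_match_scores_zero(self):
        for ts in [(5,), (5, 30, 55)]:
            err, counts = pb_err(_events(*ts), _events(*ts), 4, 25)
            assert err == 0.0
            assert counts.n_correct == len(ts)

    def test_printed_formula_hand_case(self):
        # N_C=2, N_M=1, N_FA=1 -> 1 - 4/6
        err, counts = pb_err(_events(10, 40, 70), _events(11, 39, 200), 4, 30)
        assert counts == PeriodCounts(2, 1, 1, 4)
        assert err == pytest.approx(1.0 / 3.0)

    def test_empty_hypothesis_is_total_miss(self):
        err, _ = pb_err(_events(5, 25), _events(), 4, 20)
        assert err == 1.0

    def test_one_hypothesis_cannot_serve_two_references(self):
        err, counts = pb_err(_events(10, 14), _events(12), 3, 8)
        assert counts.n_correct == 1
        assert counts.n_miss == 1

    def test_tolerance_violating_half_period_rejected(self):
        with pytest.raises(ValueError, match="half-period"):
            pb_err(_events(5), _events(5), 10, 20)

    def test_error_non_increasing_in_tolerance(self):
        rng = np.random.default_rng(3)
        ref = _events(*np.sort(rng.choice(500, 20, replace=False)))
        hyp = _events(*np.sort(rng.choice(500, 25, replace=False)))
        errs = [pb_err(ref, hyp, t, 60)[0] for t in range(1, 29)]
        assert np.all(np.diff(errs) <= 1e-12)

    def test_bounds_and_zero_condition(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            ref = _events(*np.sort(rng.choice(300, rng.integers(1, 10), replace=False)))
            hyp = _events(*np.sort(rng.choice(300, rng.integers(0, 10), replace=False)))
            err, counts = pb_err(ref, hyp, 5, 40)
            assert 0.0 <= err <= 1.0
            assert (err == 0.0) == (counts.n_miss == 0 and counts.n_false_alarm == 0)


@pytest.fixture(scope="module")
def cls():
    return synth.AlarmClassSpec(
        "snr", (synth.AlarmVersion(tones=(synth.Tone((1000.0,), 1.0),), l_sil=0.5),)
    )


class TestLocalSnr:
    def test_tone_in_white_noise_matches_analytic_value(self, cls):
        rng = np.random.default_rng(0)
        n = int(2.0 * FS)
        sigma = 0.05
        amp = 0.02
        noise = rng.standard_normal(n) * sigma
        tone = amp * np.sin(2 * np.pi * 1000.0 * np.arange(n) / FS)
        spec = compute_spectrogram(tone + noise, FS, "hann", 2048, 1024, 0)
        # analytic: signal band mean per-bin power = tone power spread over the
        # band's bins + noise PSD; noise bands hold the noise PSD alone
        got = local_snr(spec, (0.0, 2.0), cls)
        lo, hi = evaluate.region_bins(1000.0, 20.0, spec)
        n_band = hi - lo + 1
        spec_noise = compute_spectrogram(noise, FS, "hann", 2048, 1024, 0)
        p_bin_noise = np.mean(np.abs(spec_noise.values[lo : hi + 1]) ** 2)
        spec_tone = compute_spectrogram(tone, FS, "hann", 2048, 1024, 0)
        p_bin_tone = np.mean(np.abs(spec_tone.values[lo : hi + 1]) ** 2)
        expected = 10 * np.log10((p_bin_tone + p_bin_noise) / p_bin_noise)
        assert got == pytest.approx(expected, abs=1.0)

    def test_equal_powers_give_zero_db(self, cls):
        # white noise alone: band and flank see the same PSD -> ~0 dB
        rng = np.random.default_rng(5)
        spec = compute_spectrogram(rng.standard_normal(int(4 * FS)), FS, "hann", 2048, 1024, 0)
        assert local_snr(spec, (0.0, 4.0), cls) == pytest.approx(0.0, abs=1.0)

    def test_power_decade_reads_ten_db(self, cls):
        rng = np.random.default_rng(6)
        n = int(3.0 * FS)
        noise = rng.standard_normal(n) * 0.05
        spec_n = compute_spectrogram(noise, FS, "hann", 2048, 1024, 0)
        lo, hi = evaluate.region_bins(1000.0, 20.0, spec_n)
        p_bin = np.mean(np.abs(spec_n.values[lo : hi + 1]) ** 2)
        # add a tone whose in-band mean per-bin power is 9x the noise PSD
        # (mixture then reads 10x = 10 dB)
        spec_t1 = compute_spectrogram(
            np.sin(2 * np.pi * 1000.0 * np.arange(n) / FS), FS, "hann", 2048, 1024, 0
        )
        p_t1 = np.mean(np.abs(spec_t1.values[lo : hi + 1]) ** 2)
        amp = np.sqrt(9.0 * p_bin / p_t1)
        wave = noise + amp * np.sin(2 * np.pi * 1000.0 * np.arange(n) / FS)
        spec = compute_spectrogram(wave, FS, "hann", 2048, 1024, 0)
        assert local_snr(spec, (0.0, 3.0), cls) == pytest.approx(10.0, abs=1.0)


class TestStratification:
    def test_bins_partition_samples(self):
        snrs = np.array([-3.0, 1.0, 4.9, 5.0, 12.0, 17.5])
        groups = stratify_by_snr(snrs, 5.0)
        all_idx = np.sort(np.concatenate(list(groups.values())))
        assert np.array_equal(all_idx, np.arange(len(snrs)))
        assert set(groups) == {-1, 0, 1, 2, 3}


class TestCrossValidate:
    @staticmethod
    def _fake_session(seed):
        rng = np.random.default_rng(seed)
        return {"ref": (rng.random(50) < 0.3).astype(int)}

    def test_identical_sessions_give_identical_folds(self):
        session = self._fake_session(1)

        def train(_):
            return "model"

        def evaluate_fn(model, s):
            ref = s["ref"]
            hyp = ref.copy()
            hyp[:5] = 1 - hyp[:5]
            _, _, fc = frame_metrics(ref, hyp)
            return {"a": (fc, PeriodCounts(3, 1, 1, 4))}

        res = cross_validate([session, session], train, evaluate_fn, ["a"])
        assert res["folds"][0] == res["folds"][1]
        assert res["per_class"]["a"]["pb_err"] == pytest.approx(1 - 12 / 16)

    def test_counts_accumulate_to_whole_corpus(self):
        sessions = [self._fake_session(s) for s in range(4)]

        def train(_):
            return None

        def evaluate_fn(model, s):
            ref = s["ref"]
            hyp = np.zeros_like(ref)
            _, _, fc = frame_metrics(ref, hyp)
            return {"a": (fc, PeriodCounts(0, int(ref.sum()), 0, 4))}

        res = cross_validate(sessions, train, evaluate_fn, ["a"])
        total_alarm = sum(s["ref"].sum() for s in sessions)
        assert res["per_class"]["a"]["frame_counts"].n_alarm == total_alarm
        assert res["per_class"]["a"]["miss_rate"] == 1.0

    def test_single_session_rejected(self):
        with pytest.raises(ValueError, match="2 sessions"):
            cross_validate([1], lambda s: None, lambda m, s: {}, [])
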