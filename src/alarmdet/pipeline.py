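"""End-to-end orchestration: one independent detector per alarm class.

A run configuration picks a feature scheme (generic FF-LFBE, sinusoid-
detection SD ratio / LLH / LLH & Amp, or NMF activations), a frame classifier
(GMM or NN) and a post-processing scheme (none, majority-vote smoothing,
temporal period modelling, or their combination).  Detectors never share
state across classes; overlapping detections are all reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import classify, evaluate, nmf, sinusoid, temporal
from .spectral import FeatureSequence, Spectrogram, compute_spectrogram, region_bins
from .synth import AlarmClassSpec, Scene

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ClassDetector",
    "TrainedSystem",
    "DetectionResult",
    "frame_labels_for_class",
    "reference_events",
    "compute_features",
    "train_system",
    "detect_scene",
    "evaluate_detection",
    "run_detection",
    "run_experiment_grid",
]

FEATURE_MODES = ("ff_lfbe", "sd_ratio", "sd_llh", "sd_llh_amp", "nmf")
CLASSIFIERS = ("gmm", "nn")
POSTPROC = ("none", "smooth", "temporal", "smooth_temporal")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a detection run."""

    feature: str = "sd_llh_amp"
    classifier: str = "gmm"
    postproc: str = "smooth_temporal"
    sample_rate: float = 24000.0
    frame_length: int = 2048
    hop: int = 1024
    zero_pad: int = 2048
    tolerance: float = 20.0  # Hz, alarm-frequency region half-width
    n_filters: int = 18
    nmf_r_alarm: int = 4
    nmf_r_nonalarm: int = 15
    nmf_beta: float = 1.0
    nmf_iters: int = 20
    t_tol_fraction: float = 0.49  # of the period, for PB-ERR
    seed: int = 0
    peak_model_components: int = 32
    peak_model_M: int = 6
    peak_model_snr_db: float = -7.0
    n_period_threshold_candidates: int = 25

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_MODES:
            raise ValueError(f"unknown feature mode {self.feature!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.postproc not in POSTPROC:
            raise ValueError(f"unknown post-processing {self.postproc!r}")

    @property
    def window(self) -> str:
        """SD features need the rectangular window's phase behaviour; the
        energy-based schemes use Hann frames."""
        return "rectangular" if self.feature.startswith("sd") else "hann"

    def frames_of(self, seconds: float) -> int:
        return max(int(round(seconds * self.sample_rate / self.hop)), 1)


@dataclass
class ClassDetector:
    """Everything one alarm class needs at test time."""

    cls: AlarmClassSpec
    detector: classify.GmmDetector | classify.NnDetector
    eer_threshold: float
    period_threshold: float
    nmf_model: nmf.NmfModel | None = None


@dataclass
class TrainedSystem:
    config: RunConfig
    detectors: dict[str, ClassDetector]
    peak_models: sinusoid.PeakModels | None = None


@dataclass
class DetectionResult:
    class_id: str
    frame_labels: np.ndarray
    events: temporal.EventSet
    scores: np.ndarray = field(repr=False, default=None)


def frame_labels_for_class(
    annotations: pd.DataFrame,
    class_id: str,
    n_frames: int,
    sample_rate: float,
    hop: int,
) -> np.ndarray:
    """Binary reference frame labels for one class at hop resolution."""
    labels = np.zeros(n_frames, dtype=int)
    for _, row in annotations[annotations["class_id"] == class_id].iterrows():
        l_on, l_off = evaluate.annotation_frames(
            row["onset_sec"], row["offset_sec"], sample_rate, hop
        )
        labels[max(l_on, 0) : min(l_off, n_frames)] = 1
    return labels


def reference_events(
    annotations: pd.DataFrame, class_id: str, sample_rate: float, hop: int
) -> temporal.EventSet:
    """Reference alarm-period start timestamps (each annotated signal interval
    marks one period)."""
    rows = annotations[annotations["class_id"] == class_id]
    ts = sorted(
        {int(round(o * sample_rate / hop)) for o in rows["onset_sec"].to_numpy()}
    )
    return temporal.EventSet(
        timestamps=np.asarray(ts, dtype=int), class_id=class_id, kind="reference"
    )


def _spectrogram(wave: np.ndarray, config: RunConfig) -> Spectrogram:
    return compute_spectrogram(
        wave,
        config.sample_rate,
        config.window,
        config.frame_length,
        config.hop,
        config.zero_pad if config.feature.startswith("sd") else 0,
    )


def _class_band_bins(spec: Spectrogram, cls: AlarmClassSpec, tolerance: float) -> np.ndarray:
    bins: set[int] = set()
    for f in cls.frequencies:
        lo, hi = region_bins(f, tolerance, spec)
        bins.update(range(lo, hi + 1))
    return np.asarray(sorted(bins))


def compute_features(
    spec: Spectrogram,
    config: RunConfig,
    cls: AlarmClassSpec | None = None,
    peak_models: sinusoid.PeakModels | None = None,
    nmf_model: nmf.NmfModel | None = None,
) -> FeatureSequence:
    """Per-frame features of one spectrogram under the configured scheme."""
    from .spectral import compute_ff_lfbe

    if config.feature == "ff_lfbe":
        return compute_ff_lfbe(spec, config.n_filters)
    if config.feature.startswith("sd"):
        if peak_models is None:
            raise ValueError(
                "SD features need trained peak models; run train_peak_models "
                "(CLI: alarmdet train-sinusoid) first"
            )
        mode = config.feature.removeprefix("sd_")
        return sinusoid.extract_sd_features(
            spec, peak_models, cls, mode=mode, tolerance=config.tolerance
        )
    if nmf_model is None:
        raise ValueError(
            "NMF features need trained bases; run train_nmf_bases "
            "(CLI: alarmdet train-nmf) first"
        )
    acts = nmf.infer_activations(
        nmf.band_magnitudes(spec, nmf_model.band_bins), nmf_model, rng_seed=config.seed
    )
    return nmf.extract_nmf_features(acts, nmf_model, frame_times=spec.frame_times)


def _train_nmf_for_class(
    scenes: list[Scene], cls: AlarmClassSpec, config: RunConfig
) -> nmf.NmfModel:
    """Alarm bases from the class's signal intervals, non-alarm bases from
    frames free of any alarm."""
    alarm_cols, clean_cols = [], []
    band_bins = None
    for scene in scenes:
        spec = _spectrogram(scene.outside, config)
        if band_bins is None:
            band_bins = _class_band_bins(spec, cls, config.tolerance)
        mags = spec.magnitude[band_bins, :]
        own = frame_labels_for_class(
            scene.annotations, cls.class_id, spec.n_frames, config.sample_rate, config.hop
        ).astype(bool)
        any_alarm = np.zeros(spec.n_frames, dtype=bool)
        for cid in scene.annotations["class_id"].unique():
            any_alarm |= frame_labels_for_class(
                scene.annotations, cid, spec.n_frames, config.sample_rate, config.hop
            ).astype(bool)
        alarm_cols.append(mags[:, own])
        clean_cols.append(mags[:, ~any_alarm])
    return nmf.train_nmf_bases(
        np.hstack(alarm_cols),
        np.hstack(clean_cols),
        r_alarm=config.nmf_r_alarm,
        r_nonalarm=config.nmf_r_nonalarm,
        beta=config.nmf_beta,
        n_iters=config.nmf_iters,
        rng_seed=config.seed,
        band_bins=band_bins,
    )


def _period_frames(cls: AlarmClassSpec, config: RunConfig) -> tuple[int, int, int]:
    l_sig = config.frames_of(cls.l_sig)
    l_sil = config.frames_of(cls.l_sil)
    return l_sig, l_sil, l_sig + l_sil


def _sweep_period_threshold(
    curves: list[np.ndarray],
    ref_events: list[temporal.EventSet],
    l_sig: int,
    l_sil: int,
    config: RunConfig,
    smoothed_labels: list[np.ndarray] | None = None,
) -> float:
    """Class-specific method-2 threshold minimising PB-ERR on training data.

    The sweep optimises the objective of the decision method actually in use:
    the period-peak events themselves, or — when method 2 only *confirms*
    smoothed frame decisions (combined scheme) — the combined decision, for
    which a lower threshold costs nothing and recall is what matters.
    """
    values = np.concatenate(curves)
    qs = np.linspace(0.5, 0.999, config.n_period_threshold_candidates)
    cands = np.unique(np.quantile(values, qs))
    period = l_sig + l_sil
    t_tol = max(int(config.t_tol_fraction * period), 1)
    min_sep = max(int(np.ceil(0.75 * period)), 1)
    best_thr, best_err = float(cands[-1]), np.inf
    for thr in cands[::-1]:  # ties favour the higher (more conservative) threshold
        counts = evaluate.PeriodCounts(0, 0, 0, t_tol)
        for i, (vals, ref) in enumerate(zip(curves, ref_events)):
            m2 = temporal.pick_period_peaks(
                temporal.PeriodCurve(vals, l_sig, l_sil), thr, period
            )
            if smoothed_labels is None:
                hyp = m2
            else:
                combined = temporal.combine_decisions(smoothed_labels[i], m2, l_sig)
                hyp = temporal.labels_to_events(combined, min_sep)
            _, c = evaluate.pb_err(ref, hyp, t_tol, period)
            counts = counts + c
        if counts.pb_err < best_err:
            best_err, best_thr = counts.pb_err, float(thr)
    return best_thr


def train_system(
    scenes: list[Scene],
    registry: list[AlarmClassSpec],
    config: RunConfig,
    peak_models: sinusoid.PeakModels | None = None,
) -> TrainedSystem:
    """Train one independent detector per registry class on training scenes."""
    if config.feature.startswith("sd") and peak_models is None:
        peak_models = sinusoid.train_peak_models(
            n_components=config.peak_model_components,
            M=config.peak_model_M,
            training_snr_db=config.peak_model_snr_db,
            rng_seed=config.seed,
            sample_rate=config.sample_rate,
            frame_length=config.frame_length,
            hop=config.hop,
            zero_pad=config.zero_pad,
        )
    detectors: dict[str, ClassDetector] = {}
    for cls in registry:
        nmf_model = (
            _train_nmf_for_class(scenes, cls, config) if config.feature == "nmf" else None
        )
        feats, labels = [], []
        curves, refs = [], []
        l_sig, l_sil, period = _period_frames(cls, config)
        for scene in scenes:
            spec = _spectrogram(scene.outside, config)
            fs = compute_features(spec, config, cls, peak_models, nmf_model)
            lab = frame_labels_for_class(
                scene.annotations, cls.class_id, fs.n_frames, config.sample_rate, config.hop
            )
            feats.append(fs.vectors)
            labels.append(lab)
        X = np.vstack(feats)
        y = np.concatenate(labels)
        if y.sum() < 2 or (len(y) - y.sum()) < 2:
            log.warning("class %s has no training alarms in any scene; skipped", cls.class_id)
            continue
        if config.classifier == "gmm":
            det = classify.train_gmm_detector(X, y, config.feature, cls.class_id)
        else:
            det = classify.train_nn_detector(
                X, y, rng_seed=config.seed, feature_kind=config.feature, class_id=cls.class_id
            )
        eer = classify.select_eer_threshold(classify.decision_scores(det, X), y)

        # method-2 threshold: swept on the training scenes, never on test data
        smoothed = [] if config.postproc == "smooth_temporal" else None
        for scene, fv in zip(scenes, feats):
            post = classify.frame_posteriors(det, fv)
            curve = temporal.period_probability(post, l_sig, l_sil)
            curves.append(curve.values)
            refs.append(
                reference_events(
                    scene.annotations, cls.class_id, config.sample_rate, config.hop
                )
            )
            if smoothed is not None:
                raw = (classify.decision_scores(det, fv) >= eer.threshold).astype(int)
                smoothed.append(temporal.majority_vote_smooth(raw, min(l_sig, l_sil)))
        period_thr = _sweep_period_threshold(
            curves, refs, l_sig, l_sil, config, smoothed
        )
        detectors[cls.class_id] = ClassDetector(
            cls=cls,
            detector=det,
            eer_threshold=eer.threshold,
            period_threshold=period_thr,
            nmf_model=nmf_model,
        )
        log.info(
            "%s: EER threshold %.3f (MR %.3f FAR %.3f), period threshold %.2f",
            cls.class_id, eer.threshold, eer.miss_rate, eer.false_alarm_rate, period_thr,
        )
    return TrainedSystem(config=config, detectors=detectors, peak_models=peak_models)


def detect_scene(system: TrainedSystem, scene: Scene) -> dict[str, DetectionResult]:
    """Run every class detector on one scene (outside channel)."""
    config = system.config
    results: dict[str, DetectionResult] = {}
    spec = _spectrogram(scene.outside, config)
    for cid, cd in system.detectors.items():
        feats = compute_features(spec, config, cd.cls, system.peak_models, cd.nmf_model)
        scores = classify.decision_scores(cd.detector, feats)
        l_sig, l_sil, period = _period_frames(cd.cls, config)
        min_sep = max(int(np.ceil(0.75 * period)), 1)

        raw = (scores >= cd.eer_threshold).astype(int)
        if config.postproc == "none":
            labels = raw
            events = temporal.labels_to_events(raw, min_sep, cid)
        elif config.postproc == "smooth":
            labels = temporal.majority_vote_smooth(raw, min(l_sig, l_sil))
            events = temporal.labels_to_events(labels, min_sep, cid)
        else:
            post = classify.frame_posteriors(cd.detector, feats)
            curve = temporal.period_probability(post, l_sig, l_sil)
            m2_events = temporal.pick_period_peaks(curve, cd.period_threshold, period, cid)
            if config.postproc == "temporal":
                labels = temporal.events_to_labels(m2_events, l_sig, feats.n_frames)
                events = m2_events
            else:  # smooth_temporal
                smoothed = temporal.majority_vote_smooth(raw, min(l_sig, l_sil))
                labels = temporal.combine_decisions(smoothed, m2_events, l_sig)
                events = temporal.labels_to_events(labels, min_sep, cid)
        results[cid] = DetectionResult(
            class_id=cid, frame_labels=labels, events=events, scores=scores
        )
    return results


def evaluate_detection(
    results: dict[str, DetectionResult], scene: Scene, system: TrainedSystem
) -> dict:
    """Frame and period metrics per class plus the class-averaged summary."""
    config = system.config
    per_class = {}
    for cid, res in results.items():
        cd = system.detectors[cid]
        l_sig, l_sil, period = _period_frames(cd.cls, config)
        ref_labels = frame_labels_for_class(
            scene.annotations, cid, len(res.frame_labels), config.sample_rate, config.hop
        )
        mr, far, fc = evaluate.frame_metrics(ref_labels, res.frame_labels)
        ref_ev = reference_events(scene.annotations, cid, config.sample_rate, config.hop)
        t_tol = max(int(config.t_tol_fraction * period), 1)
        err, pc = evaluate.pb_err(ref_ev, res.events, t_tol, period)
        if 0 < ref_labels.sum() < len(ref_labels):
            eer = evaluate.det_curve(res.scores, ref_labels).eer
        else:
            eer = float("nan")
        per_class[cid] = {
            "miss_rate": mr,
            "false_alarm_rate": far,
            "pb_err": err,
            "eer": eer,
            "frame_counts": fc,
            "period_counts": pc,
        }
    overall = {
        key: float(np.nanmean([v[key] for v in per_class.values()]))
        for key in ("miss_rate", "false_alarm_rate", "pb_err", "eer")
    }
    return {"per_class": per_class, "overall": overall}


def run_detection(
    config: RunConfig,
    train_scenes: list[Scene],
    test_scene: Scene,
    registry: list[AlarmClassSpec],
    peak_models: sinusoid.PeakModels | None = None,
) -> dict:
    """Train, detect and evaluate in one call; returns the metrics report."""
    system = train_system(train_scenes, registry, config, peak_models)
    results = detect_scene(system, test_scene)
    report = evaluate_detection(results, test_scene, system)
    report["config"] = config
    report["results"] = results
    return report


def run_experiment_grid(
    train_scenes: list[Scene],
    test_scene: Scene,
    registry: list[AlarmClassSpec],
    grid: list[RunConfig],
    peak_models: sinusoid.PeakModels | None = None,
) -> pd.DataFrame:
    """One row of class-averaged metrics per configuration; failures are
    marked and do not stop the remaining configurations."""
    if not grid:
        raise ValueError("empty grid")
    rows = []
    for cfg in grid:
        row = {"feature": cfg.feature, "classifier": cfg.classifier, "postproc": cfg.postproc}
        try:
            report = run_detection(cfg, train_scenes, test_scene, registry, peak_models)
            row.update(report["overall"])
            for cid, m in report["per_class"].items():
                row[f"pb_err_{cid}"] = m["pb_err"]
            row["failed"] = False
        except Exception as exc:  # noqa: BLE001 - grid rows fail independently
            log.exception("grid row failed: %s", row)
            row["failed"] = True
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
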