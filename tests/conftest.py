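"""Shared fixtures: trained peak models and synthetic scenes.

Expensive artefacts (the 32-component peak models, rendered scenes) are
session-scoped so the whole suite trains them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from alarmdet import pipeline, sinusoid, synth


def build_scene(
    seed: int,
    duration: float = 90.0,
    snr_db: float = 15.0,
    background: str = "white",
    class_ids: tuple[str, ...] = ("a1", "a7", "a10"),
    registry: list | None = None,
) -> synth.Scene:
    """Random alarm scene: events of the given classes tiled with gaps."""
    registry = registry or [c for c in synth.default_registry() if c.class_id in class_ids]
    by_id = {c.class_id: c for c in registry}
    rng = np.random.default_rng(seed)
    events = []
    t = 2.0
    while t < duration - 14.0:
        cid = class_ids[int(rng.integers(len(class_ids)))]
        cls = by_id[cid]
        version = int(rng.integers(len(cls.versions)))
        n_periods = int(rng.integers(4, 8))
        if t + n_periods * cls.versions[version].period < duration - 1.0:
            events.append(synth.SceneEvent(cid, version, t, n_periods, snr_db))
        t += n_periods * cls.versions[version].period + float(rng.uniform(1.0, 3.0))
    spec = synth.SceneSpec(duration=duration, events=events, seed=seed, background=background)
    return synth.render_scene(spec, registry)


@pytest.fixture(scope="session")
def registry3() -> list[synth.AlarmClassSpec]:
    return [c for c in synth.default_registry() if c.class_id in ("a1", "a7", "a10")]


@pytest.fixture(scope="session")
def peak_models() -> sinusoid.PeakModels:
    """Full default peak models, shared by detector-quality tests."""
    return sinusoid.train_peak_models(rng_seed=1)


@pytest.fixture(scope="session")
def small_peak_models() -> sinusoid.PeakModels:
    """Cheap models for plumbing tests that don't need detection quality."""
    return sinusoid.train_peak_models(
        n_components=4, rng_seed=1, n_sinusoid_examples=60, n_noise_examples=10
    )


@pytest.fixture(scope="session")
def clean_scenes(registry3):
    """Train/test scene pair at 15 dB in white noise."""
    return build_scene(11, 90.0, 15.0), build_scene(22, 90.0, 15.0)


@pytest.fixture(scope="session")
def trained_system(clean_scenes, registry3, peak_models):
    config = pipeline.RunConfig(feature="sd_llh_amp", postproc="smooth_temporal", seed=3)
    return pipeline.train_system([clean_scenes[0]], registry3, config, peak_models)
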