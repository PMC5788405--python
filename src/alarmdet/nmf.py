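"""Supervised non-negative matrix factorisation features.

Alarm bases ``W_A`` are trained on band-restricted magnitude spectra of alarm
signal intervals and non-alarm bases ``W_NA`` on alarm-free spectra, each by
multiplicative updates minimising the Kullback-Leibler divergence with an L1
sparsity penalty on the activations::

    min_{W,H >= 0}  D_KL(S || W H) + beta * |H|_1

At feature-extraction time the concatenated bases ``W = [W_A, W_NA]`` are held
fixed and only ``H`` is inferred.  Each activation column is normalised to sum
to one and the alarm rows ``H_A`` form the feature vector, which makes the
features invariant to the overall signal amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spectral import FeatureSequence, Spectrogram

log = logging.getLogger(__name__)

__all__ = [
    "NmfModel",
    "Activations",
    "kl_sparse_cost",
    "train_nmf_bases",
    "infer_activations",
    "extract_nmf_features",
    "band_magnitudes",
    "save_nmf_model",
    "load_nmf_model",
]

_EPS = 1e-12


@dataclass
class NmfModel:
    """Trained bases: alarm columns first, then non-alarm columns."""

    W: np.ndarray  # (n_bands, R_total), columns L1-normalised
    r_alarm: int
    r_nonalarm: int
    beta: float
    band_bins: np.ndarray  # bin indices the bases live on
    n_iters: int

    @property
    def r_total(self) -> int:
        return self.r_alarm + self.r_nonalarm

    @property
    def alarm_slice(self) -> slice:
        return slice(0, self.r_alarm)

    @property
    def nonalarm_slice(self) -> slice:
        return slice(self.r_alarm, self.r_total)


@dataclass
class Activations:
    """Non-negative per-frame basis activations (rows = bases, columns = frames)."""

    H: np.ndarray
    r_alarm: int

    @property
    def n_frames(self) -> int:
        return self.H.shape[1]


def kl_sparse_cost(S: np.ndarray, V: np.ndarray, beta: float, H: np.ndarray) -> float:
    """KL divergence D(S || V) plus beta * |H|_1, with 0*log0 = 0."""
    mask = S > 0
    kl = float(
        np.sum(S[mask] * np.log(S[mask] / np.maximum(V[mask], _EPS))) - S[mask].sum() + V.sum()
    )
    return kl + beta * float(H.sum())


def _multiplicative_fit(
    S: np.ndarray,
    R: int,
    beta: float,
    n_iters: int,
    rng: np.random.Generator,
    W: np.ndarray | None = None,
    rel_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Multiplicative KL+sparsity updates; W fixed if given.

    The classic multiplicative updates never increase the penalised objective,
    which is asserted property-wise in the test suite.
    """
    n_bands, T = S.shape
    update_w = W is None
    if update_w:
        W = rng.uniform(0.1, 1.1, size=(n_bands, R)) * (S.mean() + _EPS)
    H = rng.uniform(0.1, 1.1, size=(R, T)) * (S.mean() + _EPS)
    costs = []
    prev = None
    for _ in range(n_iters):
        V = W @ H
        H *= (W.T @ (S / np.maximum(V, _EPS))) / np.maximum(W.sum(axis=0)[:, None] + beta, _EPS)
        if update_w:
            V = W @ H
            W *= ((S / np.maximum(V, _EPS)) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        cost = kl_sparse_cost(S, W @ H, beta, H)
        costs.append(cost)
        if prev is not None and prev > 0 and (prev - cost) / max(abs(prev), _EPS) < rel_tol:
            break
        prev = cost
    return W, H, costs


def _normalise_columns(W: np.ndarray, H: np.ndarray | None = None):
    """Scale columns of W to unit L1 norm, compensating rows of H."""
    norms = W.sum(axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    W = W / norms
    if H is not None:
        H = H * norms[:, None]
    return W, H


def train_nmf_bases(
    alarm_spectra: np.ndarray,
    nonalarm_spectra: np.ndarray,
    r_alarm: int = 4,
    r_nonalarm: int = 15,
    beta: float = 1.0,
    n_iters: int = 20,
    rng_seed: int = 0,
    band_bins: np.ndarray | None = None,
) -> NmfModel:
    """Train alarm and non-alarm bases on their respective magnitude spectra.

    Both input matrices are (n_bands, n_frames) and must share the band
    dimension.  Bases are L1-normalised after training.
    """
    if r_alarm < 1 or r_nonalarm < 1:
        raise ValueError("need at least one basis per class")
    alarm_spectra = np.asarray(alarm_spectra, dtype=float)
    nonalarm_spectra = np.asarray(nonalarm_spectra, dtype=float)
    for name, mat in (("alarm", alarm_spectra), ("non-alarm", nonalarm_spectra)):
        if np.any(mat < 0):
            raise ValueError(f"non-negative input required ({name} spectra)")
        if not np.any(mat > 0):
            raise ValueError(f"degenerate training matrix ({name} spectra is all zero)")
    if alarm_spectra.shape[0] != nonalarm_spectra.shape[0]:
        raise ValueError("alarm and non-alarm spectra must share the band dimension")

    rng = np.random.default_rng(rng_seed)
    W_a, H_a, _ = _multiplicative_fit(alarm_spectra, r_alarm, beta, n_iters, rng)
    W_na, H_na, _ = _multiplicative_fit(nonalarm_spectra, r_nonalarm, beta, n_iters, rng)
    W_a, _ = _normalise_columns(W_a, H_a)
    W_na, _ = _normalise_columns(W_na, H_na)
    if band_bins is None:
        band_bins = np.arange(alarm_spectra.shape[0])
    return NmfModel(
        W=np.hstack([W_a, W_na]),
        r_alarm=r_alarm,
        r_nonalarm=r_nonalarm,
        beta=beta,
        band_bins=np.asarray(band_bins),
        n_iters=n_iters,
    )


def infer_activations(
    spec_bands: np.ndarray,
    model: NmfModel,
    n_iters: int | None = None,
    rng_seed: int = 0,
) -> Activations:
    """Estimate activations for band-restricted magnitudes with bases fixed.

    Initialisation is strictly positive uniform random scaled by the input
    mean, so activations scale exactly linearly with the input magnitude.
    """
    S = np.asarray(spec_bands, dtype=float)
    if np.any(S < 0):
        raise ValueError("non-negative input required")
    if S.shape[0] != model.W.shape[0]:
        raise ValueError("band mismatch with trained model")
    rng = np.random.default_rng(rng_seed)
    _, H, _ = _multiplicative_fit(
        S, model.r_total, model.beta, n_iters or model.n_iters, rng, W=model.W
    )
    return Activations(H=H, r_alarm=model.r_alarm)


def extract_nmf_features(
    acts: Activations, model: NmfModel, frame_times: np.ndarray | None = None
) -> FeatureSequence:
    """Frame-normalised alarm-basis activations as features (dim = R_alarm).

    Each activation column is normalised to sum to one; zero columns (silent
    frames) fall back to the uniform distribution 1/R_total.
    """
    if acts.H.shape[0] != model.r_total:
        raise ValueError("activations were not produced by this model")
    sums = acts.H.sum(axis=0, keepdims=True)
    if np.any(sums <= 0):
        log.debug("zero-activation frames normalised to uniform")
    norm = np.where(sums > 0, acts.H / np.maximum(sums, _EPS), 1.0 / model.r_total)
    return FeatureSequence(
        vectors=norm[model.alarm_slice].T, feature_kind="nmf_act", frame_times=frame_times
    )


def band_magnitudes(spec: Spectrogram, band_bins: np.ndarray) -> np.ndarray:
    """Magnitude spectrogram restricted to the alarm-specific band bins."""
    return spec.magnitude[np.asarray(band_bins), :]


def save_nmf_model(model: NmfModel, path: str | Path) -> None:
    np.savez(
        path,
        W=model.W,
        r_alarm=model.r_alarm,
        r_nonalarm=model.r_nonalarm,
        beta=model.beta,
        band_bins=model.band_bins,
        n_iters=model.n_iters,
    )


def load_nmf_model(path: str | Path) -> NmfModel:
    d = np.load(path, allow_pickle=False)
    return NmfModel(
        W=d["W"],
        r_alarm=int(d["r_alarm"]),
        r_nonalarm=int(d["r_nonalarm"]),
        beta=float(d["beta"]),
        band_bins=d["band_bins"],
        n_iters=int(d["n_iters"]),
    )
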