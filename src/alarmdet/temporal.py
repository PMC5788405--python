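"""Temporal structure of periodic alarms: aggregation and decision methods.

A periodic alarm alternates a signal interval of ``L_sig`` frames with a
silence interval of ``L_sil`` frames.  The frame-posterior contrast
``d(i) = P_A(i) - P_NA(i)`` is aggregated over one full period to score each
frame ``t`` as a candidate period start::

    P_period(t) = sum_{i=t}^{t+L_sig-1} d(i) - sum_{i=t+L_sig}^{t+L_sig+L_sil-1} d(i)

which peaks where the posterior sequence aligns with the signal-then-silence
pattern.  Three decision methods build on this:

1. frame thresholding at the EER point followed by majority-vote smoothing,
   period starts taken as onsets of alarm-label runs;
2. thresholding and peak-picking of ``P_period`` directly;
3. the combination: method-1 events not confirmed by a method-2 period within
   ``±L_sig/2`` frames are discarded.

Hypothesis events always respect a minimum separation of 75% of the period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import FramePosteriors

__all__ = [
    "PeriodCurve",
    "EventSet",
    "period_probability",
    "pick_period_peaks",
    "majority_vote_smooth",
    "labels_to_events",
    "events_to_labels",
    "combine_decisions",
]


@dataclass
class PeriodCurve:
    """P_period(t) for every frame where a full period window fits."""

    values: np.ndarray
    l_sig: int
    l_sil: int

    @property
    def valid_length(self) -> int:
        return len(self.values)


@dataclass
class EventSet:
    """Strictly increasing frame timestamps of alarm-period starts."""

    timestamps: np.ndarray
    class_id: str = ""
    kind: str = "hypothesis"
    scores: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=int)
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)


def period_probability(post: FramePosteriors, l_sig: int, l_sil: int) -> PeriodCurve:
    """Evaluate the period-start score for every valid frame.

    Implemented with cumulative sums; equal to the direct double sum to within
    accumulation round-off (checked property-wise in the tests).
    """
    if l_sig < 1 or l_sil < 1:
        raise ValueError("signal and silence lengths must be >= 1 frame")
    d = post.contrast
    T = len(d)
    period = l_sig + l_sil
    if T < period:
        raise ValueError("sequence shorter than one alarm period")
    c = np.concatenate([[0.0], np.cumsum(d)])
    t = np.arange(T - period + 1)
    sig = c[t + l_sig] - c[t]
    sil = c[t + period] - c[t + l_sig]
    return PeriodCurve(values=sig - sil, l_sig=l_sig, l_sil=l_sil)


def _local_maxima(v: np.ndarray) -> np.ndarray:
    """Strict local maxima (plateaus take the lowest index); endpoints count."""
    n = len(v)
    if n == 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.array([0])
    left_ok = np.empty(n, dtype=bool)
    left_ok[0] = True
    left_ok[1:] = v[1:] > v[:-1]
    right_ok = np.empty(n, dtype=bool)
    right_ok[-1] = True
    right_ok[:-1] = v[:-1] >= v[1:]
    return np.nonzero(left_ok & right_ok)[0]


def pick_period_peaks(
    curve: PeriodCurve, threshold: float, period_frames: int, class_id: str = ""
) -> EventSet:
    """Peaks of the period curve above a class-specific threshold.

    Candidates are accepted greedily in descending curve value (ties favour
    the earlier frame); a candidate closer than ``0.75 * period_frames`` to an
    already accepted peak is discarded.
    """
    if period_frames < 1:
        raise ValueError("period_frames must be >= 1")
    v = curve.values
    cand = _local_maxima(v)
    cand = cand[v[cand] > threshold]
    min_sep = 0.75 * period_frames
    order = cand[np.lexsort((cand, -v[cand]))]
    accepted: list[int] = []
    for t in order:
        if all(abs(t - a) >= min_sep for a in accepted):
            accepted.append(int(t))
    accepted.sort()
    ts = np.asarray(accepted, dtype=int)
    return EventSet(timestamps=ts, class_id=class_id, kind="hypothesis", scores=v[ts])


def majority_vote_smooth(labels: np.ndarray, window: int) -> np.ndarray:
    """Majority vote in a centred window (forced odd); edges use truncated windows.

    Ties in truncated edge windows keep the original label.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        window += 1
    y = np.asarray(labels).astype(int)
    n = len(y)
    if n == 0:
        return y
    half = window // 2
    c = np.concatenate([[0], np.cumsum(y)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    ones = c[hi + 1] - c[lo]
    count = hi - lo + 1
    out = y.copy()
    out[2 * ones > count] = 1
    out[2 * ones < count] = 0
    return out


def labels_to_events(
    labels: np.ndarray, min_sep: int = 1, class_id: str = "", kind: str = "hypothesis"
) -> EventSet:
    """Onsets of maximal runs of alarm labels; runs too close to the previous
    accepted onset are not emitted as new events."""
    y = np.asarray(labels).astype(bool)
    padded = np.concatenate([[False], y])
    onsets = np.nonzero(~padded[:-1] & y)[0]
    accepted: list[int] = []
    for t in onsets:
        if not accepted or t - accepted[-1] >= min_sep:
            accepted.append(int(t))
    return EventSet(timestamps=np.asarray(accepted, dtype=int), class_id=class_id, kind=kind)


def events_to_labels(events: EventSet, l_sig: int, length: int) -> np.ndarray:
    """Assign ``l_sig`` alarm frames after each period start, clipped at the end."""
    labels = np.zeros(length, dtype=int)
    for t in events.timestamps:
        if t < length:
            labels[max(t, 0) : min(t + l_sig, length)] = 1
    return labels


def combine_decisions(
    method1_labels: np.ndarray, method2_events: EventSet, l_sig: int
) -> np.ndarray:
    """Keep method-1 alarm runs only when confirmed by a method-2 period.

    A run whose onset has no method-2 timestamp within ``±ceil(l_sig/2)``
    frames is reassigned to the non-alarm class.
    """
    y = np.asarray(method1_labels).astype(int).copy()
    tol = int(np.ceil(l_sig / 2))
    padded = np.concatenate([[0], y, [0]])
    onsets = np.nonzero((padded[1:-1] == 1) & (padded[:-2] == 0))[0]
    offsets = np.nonzero((padded[1:-1] == 1) & (padded[2:] == 0))[0]
    t2 = method2_events.timestamps
    for on, off in zip(onsets, offsets):
        if len(t2) == 0 or np.min(np.abs(t2 - on)) > tol:
            y[on : off + 1] = 0
    return y
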