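"""Electrographic seizure detection on 1-s iEEG segments.

The feature vector per segment concatenates, in this fixed order:

1. ``logfft`` — per-channel log-magnitude spectrum, 1–47 Hz in 1-Hz bins
   (47 values per channel; bin *b* aggregates magnitude in [b−0.5, b+0.5) Hz);
2. ``tcorr`` — upper-triangle correlation coefficients of the raw channels
   (C(C−1)/2 values), then the eigenvalues of that correlation matrix
   sorted descending (C values);
3. ``fcorr`` — the same correlation/eigenvalue pair computed between the
   per-channel 1–47 Hz magnitude spectra.

Total length: 47·C + 2·(C(C−1)/2 + C), e.g. 208 for C=4. The classifier is
a 150-tree random forest; per-second probabilities are merged into detection
events for event-level evaluation (sensitivity, false-positive rate,
latency).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .devicesim import US, GroundTruthEvent

__all__ = [
    "feature_length",
    "det_features",
    "DetectorModel",
    "det_train",
    "det_classify",
    "merge_calls_to_events",
    "det_evaluate",
    "iter_segments",
]

LOG_FLOOR_FRAC = 1e-12  # of full scale, guards log(0)
N_TREES = 150
F_LO, F_HI = 1, 47  # Hz, inclusive bin centers


def feature_length(n_channels: int) -> int:
    c = n_channels
    return 47 * c + 2 * (c * (c - 1) // 2 + c)


def _binned_log_spectrum(segment: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (C, 47) binned magnitude spectrum and its log.

    Rectangular window over the full 1-s segment; bin b sums magnitude over
    FFT frequencies in [b-0.5, b+0.5) Hz.
    """
    C, n = segment.shape
    spec = np.abs(np.fft.rfft(segment.astype(np.float64), axis=1))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mags = np.empty((C, F_HI - F_LO + 1))
    for j, b in enumerate(range(F_LO, F_HI + 1)):
        sel = (freqs >= b - 0.5) & (freqs < b + 0.5)
        mags[:, j] = spec[:, sel].sum(axis=1)
    full_scale = 32768.0 * n
    log_mags = np.log(np.maximum(mags, LOG_FLOOR_FRAC * full_scale))
    return mags, log_mags


def _corr_and_eigs(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle correlations and descending eigenvalues of corr(rows).

    A zero-variance row's correlations are defined as 0 (its diagonal stays
    1) so degenerate segments classify without crashing.
    """
    C = rows.shape[0]
    sd = rows.std(axis=1)
    ok = sd > 0
    r = np.eye(C)
    if ok.sum() >= 2:
        sub = np.corrcoef(rows[ok])
        r[np.ix_(ok, ok)] = sub
    iu = np.triu_indices(C, k=1)
    coeffs = r[iu]
    eigs = np.sort(np.linalg.eigvalsh(r))[::-1]
    return coeffs, eigs


def det_features(segment: np.ndarray, fs: float) -> np.ndarray:
    """Feature vector for one gap-free 1-s multi-channel segment.

    ``segment`` has shape (C, fs) with C >= 2. Deterministic.
    """
    segment = np.asarray(segment)
    if segment.ndim != 2 or segment.shape[0] < 2:
        raise ValueError("segment must be (C, n) with C >= 2")
    if segment.shape[1] != int(round(fs)):
        raise ValueError("1-s segment must hold exactly fs samples per channel")
    mags, log_mags = _binned_log_spectrum(segment, fs)
    t_coeffs, t_eigs = _corr_and_eigs(segment.astype(np.float64))
    f_coeffs, f_eigs = _corr_and_eigs(mags)
    return np.concatenate([log_mags.reshape(-1), t_coeffs, t_eigs, f_coeffs, f_eigs])


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class DetectorModel:
    """150-tree random forest plus the training metadata it refuses to
    operate without (channel count and sampling rate must match)."""

    forest: RandomForestClassifier
    fs: float
    n_channels: int
    class_balance: dict[str, int]
    seed: int
    version: str = "detect-rf-1"

    def check_stream(self, n_channels: int, fs: float) -> None:
        if n_channels != self.n_channels or abs(fs - self.fs) > 1e-9:
            raise ValueError(
                f"model trained for C={self.n_channels}, fs={self.fs}; "
                f"got C={n_channels}, fs={fs}"
            )

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "DetectorModel":
        model = joblib.load(path)
        if not isinstance(model, DetectorModel):
            raise TypeError("not a detector model file")
        return model


def det_train(
    features: np.ndarray, labels: np.ndarray, seed: int, *, fs: float, n_channels: int
) -> DetectorModel:
    """Train the 150-tree forest. Both classes must be present; reproducible
    for a fixed seed; the returned model round-trips through save/load with
    identical predictions."""
    labels = np.asarray(labels).astype(int)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("training requires both classes present")
    forest = RandomForestClassifier(
        n_estimators=N_TREES, random_state=int(seed), n_jobs=1
    )
    forest.fit(np.asarray(features), labels)
    balance = {str(k): int((labels == k).sum()) for k in uniq}
    return DetectorModel(forest, fs, n_channels, balance, int(seed))


def iter_segments(signal: np.ndarray, fs: float, start_uutc: int):
    """Yield (uutc, 1-s segment) pairs from a continuous recording."""
    n_per = int(round(fs))
    for k in range(signal.shape[1] // n_per):
        yield start_uutc + k * US, signal[:, k * n_per:(k + 1) * n_per]


def det_classify(
    model: DetectorModel,
    segments,
    fs: float,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classify a stream of (uutc, segment) pairs.

    Returns (uutc array, probability array, binary call array); one entry per
    1-s segment. Deterministic: the same stream yields identical output.
    """
    times, feats = [], []
    for uutc, seg in segments:
        seg = np.asarray(seg)
        model.check_stream(seg.shape[0], fs)
        times.append(uutc)
        feats.append(det_features(seg, fs))
    if not times:
        return np.empty(0, np.int64), np.empty(0), np.empty(0, bool)
    probs = model.forest.predict_proba(np.asarray(feats))[:, 1]
    return np.asarray(times, np.int64), probs, probs >= threshold


# ---------------------------------------------------------------------------
# event-level evaluation
# ---------------------------------------------------------------------------

def merge_calls_to_events(
    times_uutc: np.ndarray, calls: np.ndarray, merge_gap_s: float = 30.0
) -> list[tuple[int, int]]:
    """Merge positive seconds separated by less than ``merge_gap_s`` into
    detection events, returned as (start_uutc, end_uutc) intervals."""
    pos = np.asarray(times_uutc)[np.asarray(calls, bool)]
    if len(pos) == 0:
        return []
    events = []
    start = prev = int(pos[0])
    gap_us = merge_gap_s * US
    for t in pos[1:]:
        if t - prev < gap_us:
            prev = int(t)
        else:
            events.append((start, prev + US))
            start = prev = int(t)
    events.append((start, prev + US))
    return events


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def det_evaluate(
    times_uutc: np.ndarray,
    calls: np.ndarray,
    ground_truth: list[GroundTruthEvent],
    merge_gap_s: float = 30.0,
) -> dict:
    """Event-level metrics against ground truth.

    A true seizure counts as detected if any detection event overlaps it;
    the false-positive rate is the fraction of detection events overlapping
    no true seizure. With no true seizures, sensitivity is ``None`` (not 0);
    with no detection events, the FPR is ``None``.
    """
    seizures = [(e.uutc_start, e.uutc_end) for e in ground_truth if e.label == "seizure"]
    events = merge_calls_to_events(times_uutc, calls, merge_gap_s)

    detected = 0
    latencies = []
    times = np.asarray(times_uutc)
    calls_b = np.asarray(calls, bool)
    for s0, s1 in seizures:
        if any(_overlaps(e0, e1, s0, s1) for e0, e1 in events):
            detected += 1
            inside = times[calls_b & (times >= s0) & (times < s1)]
            if len(inside):
                latencies.append((int(inside[0]) - s0) / US)
    false_events = sum(
        1 for e0, e1 in events if not any(_overlaps(e0, e1, s0, s1) for s0, s1 in seizures)
    )
    return {
        "n_seizures": len(seizures),
        "n_events": len(events),
        "event_sensitivity": (100.0 * detected / len(seizures)) if seizures else None,
        "event_false_positive_rate": (100.0 * false_events / len(events)) if events else None,
        "detection_latencies_s": latencies,
    }
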