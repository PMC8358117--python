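"""Seizure prediction on 10-min windows, and a delta-power sleep classifier.

Prediction features per window, concatenated in this fixed order:

1. ``icorr`` — upper-triangle interelectrode correlation coefficients over
   the whole window (C(C−1)/2 values);
2. ``specmag`` — per-channel FFT magnitude aggregated over 0.25–24 Hz in
   0.25-Hz bands (95 bands per channel; band j covers
   [0.25 + 0.25·j, 0.5 + 0.25·j) Hz).

Total length C(C−1)/2 + 95·C (386 for C=4). The classifier is logistic
regression: the model exposes a linear decision function (weights +
intercept) and a probability threshold. Windows are non-overlapping 10-min
spans; a window whose gap fraction exceeds the tolerance is skipped, never
imputed, and the pipeline is strictly causal (a window uses only samples
before its end time).

The sleep/wake classifier is deliberately minimal: mean delta-band
(0.5–4 Hz) relative power across channels against a threshold. It is a
placeholder for a trained classifier and is flagged as replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression

from .devicesim import US, GroundTruthEvent

__all__ = [
    "WINDOW_S",
    "pred_feature_length",
    "pred_features",
    "PredictorModel",
    "pred_train",
    "pred_classify",
    "sleep_classify",
    "delta_relative_power",
    "label_windows",
]

WINDOW_S = 600.0
N_BANDS = 95           # 0.25–24 Hz in 0.25-Hz bands
BAND_LO, BAND_W = 0.25, 0.25
MAX_GAP_FRACTION = 0.10
DELTA_BAND = (0.5, 4.0)
SLEEP_DELTA_THRESHOLD = 0.5  # relative power; "dominant delta"


def pred_feature_length(n_channels: int) -> int:
    return n_channels * (n_channels - 1) // 2 + N_BANDS * n_channels


class WindowSkipped(Exception):
    """Raised when a window cannot be featurized (gap fraction too high)."""


def pred_features(
    window: np.ndarray, fs: float, gap_fraction: float = 0.0,
    max_gap_fraction: float = MAX_GAP_FRACTION,
) -> np.ndarray:
    """Feature vector for one 10-min multi-channel window.

    ``window`` is (C, n) of the samples actually present (gap samples already
    excluded by the store reader); ``gap_fraction`` is the fraction of the
    nominal window they do not cover. Deterministic.
    """
    if gap_fraction > max_gap_fraction:
        raise WindowSkipped(f"gap fraction {gap_fraction:.2%} exceeds {max_gap_fraction:.0%}")
    window = np.asarray(window, dtype=np.float64)
    C, n = window.shape
    if C < 2 or n < int(fs):
        raise ValueError("window must be (C>=2, n) with at least 1 s of samples")

    sd = window.std(axis=1)
    r = np.eye(C)
    ok = sd > 0
    if ok.sum() >= 2:
        r[np.ix_(ok, ok)] = np.corrcoef(window[ok])
    icorr = r[np.triu_indices(C, k=1)]

    spec = np.abs(np.fft.rfft(window, axis=1))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    bands = np.empty((C, N_BANDS))
    for j in range(N_BANDS):
        lo = BAND_LO + BAND_W * j
        sel = (freqs >= lo) & (freqs < lo + BAND_W)
        bands[:, j] = spec[:, sel].sum(axis=1)
    # normalize by window length so features are comparable across gap sizes
    bands /= n
    return np.concatenate([icorr, bands.reshape(-1)])


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class PredictorModel:
    """Logistic-regression weights + intercept with training metadata and the
    High/Low decision threshold."""

    clf: LogisticRegression
    fs: float
    n_channels: int
    threshold: float
    seed: int
    version: str = "predict-lr-1"

    @property
    def weights(self) -> np.ndarray:
        return self.clf.coef_.reshape(-1)

    @property
    def intercept(self) -> float:
        return float(self.clf.intercept_[0])

    def decision(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features) @ self.weights + self.intercept

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "PredictorModel":
        model = joblib.load(path)
        if not isinstance(model, PredictorModel):
            raise TypeError("not a predictor model file")
        return model


def pred_train(
    features: np.ndarray, labels: np.ndarray, seed: int, *,
    fs: float = 250.0, n_channels: int = 4, threshold: float = 0.5,
    C: float = 1.0,
) -> PredictorModel:
    """Fit the logistic-regression predictor (labels: 1 = pre-ictal,
    0 = interictal). Both classes must be present."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both pre-ictal and interictal windows")
    clf = LogisticRegression(max_iter=5000, random_state=int(seed), C=C)
    clf.fit(np.asarray(features), labels)
    return PredictorModel(clf, fs, n_channels, threshold, int(seed))


def label_windows(
    window_starts_uutc: np.ndarray,
    ground_truth: list[GroundTruthEvent],
    preictal_lead_min: float = 60.0,
) -> np.ndarray:
    """Label each 10-min window: 1 if it lies inside the pre-ictal horizon
    (``preictal_lead_min`` minutes before an onset), −1 if it touches a
    seizure (excluded from training), else 0."""
    starts = np.asarray(window_starts_uutc, dtype=np.int64)
    ends = starts + int(WINDOW_S * US)
    labels = np.zeros(len(starts), dtype=int)
    lead = int(preictal_lead_min * 60 * US)
    for ev in ground_truth:
        if ev.label == "seizure":
            p0 = ev.uutc_start - lead
            pre = (starts >= p0) & (ends <= ev.uutc_start)
            labels[pre] = 1
    for ev in ground_truth:
        if ev.label == "seizure":
            hit = (starts < ev.uutc_end) & (ends > ev.uutc_start)
            labels[hit] = -1
    return labels


def pred_classify(
    model: PredictorModel,
    windows,
    fs: float,
    k_enter: int = 1,
    m_exit: int = 1,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Run the predictor over (uutc, window, gap_fraction) triples.

    Risk state enters High after ``k_enter`` consecutive windows at or above
    the threshold and returns to Low after ``m_exit`` consecutive below.
    Returns (uutc array, probability array, state list); skipped windows
    (gap fraction too high) carry probability NaN and hold the prior state.
    """
    times, probs, states = [], [], []
    state = "Low"
    above = below = 0
    for uutc, window, gap_fraction in windows:
        times.append(uutc)
        try:
            f = pred_features(window, fs)
        except WindowSkipped:
            probs.append(np.nan)
            states.append(state)
            continue
        p = float(model.clf.predict_proba(f.reshape(1, -1))[0, 1])
        probs.append(p)
        if p >= model.threshold:
            above += 1
            below = 0
            if state == "Low" and above >= k_enter:
                state = "High"
        else:
            below += 1
            above = 0
            if state == "High" and below >= m_exit:
                state = "Low"
        states.append(state)
    return np.asarray(times, np.int64), np.asarray(probs), states


# ---------------------------------------------------------------------------
# sleep / wake
# ---------------------------------------------------------------------------

def delta_relative_power(window: np.ndarray, fs: float) -> float:
    """Mean across channels of delta-band (0.5–4 Hz) power as a fraction of
    total power above 0.5 Hz."""
    window = np.asarray(window, dtype=np.float64)
    spec = np.abs(np.fft.rfft(window, axis=1)) ** 2
    freqs = np.fft.rfftfreq(window.shape[1], d=1.0 / fs)
    delta = spec[:, (freqs >= DELTA_BAND[0]) & (freqs < DELTA_BAND[1])].sum(axis=1)
    total = spec[:, freqs >= DELTA_BAND[0]].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, delta / total, 0.0)
    return float(frac.mean())


def sleep_classify(
    window: np.ndarray, fs: float, threshold: float = SLEEP_DELTA_THRESHOLD
) -> str:
    """'sleep' iff mean delta relative power reaches ``threshold``."""
    return "sleep" if delta_relative_power(window, fs) >= threshold else "wake"
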