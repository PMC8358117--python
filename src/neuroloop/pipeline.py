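"""End-to-end helpers tying the modules together.

These are the composition paths a deployment would run: simulate a
recording, push it through the link and the reorder buffer into the store,
and run the embedded detector pipeline over it. Kept here so the CLI, the
tests and the acceptance runs share one implementation.
"""

from __future__ import annotations

import numpy as np

from .devicesim import SimConfig, US, emit_packets, simulate_recording
from .telemetry import PacketBuffer, SampleRun
from .tsformat import ChannelStore, packets_to_json_lines
from .detect import det_evaluate
from .embedded import LdConfig, PowerBandConfig, band_power, calibrate_ld_threshold, run_ld

__all__ = [
    "record_to_stores",
    "band_feature_trace",
    "ld_detection_run",
    "compression_benchmark",
    "seizure_detection_benchmark",
]


def record_to_stores(
    config: SimConfig, root, window_s: float = 10.0
) -> tuple[list, list[ChannelStore], dict]:
    """Simulate, packetize through the link, reassemble, and write one
    ChannelStore per channel under ``root``.

    Returns (ground truth, stores, drop-statistics snapshot).
    """
    truth, signal = simulate_recording(config)
    delivered = emit_packets(signal, config)
    buf = PacketBuffer(config.fs, config.packet_ms, window_s)
    stores = [
        ChannelStore(f"{root}/ch{c}", channel_name=f"ch{c}", fs=config.fs,
                     uv_per_count=config.uv_per_count)
        for c in range(config.n_channels)
    ]
    def write(items):
        for item in items:
            if isinstance(item, SampleRun):
                for c, store in enumerate(stores):
                    store.append((item.start_uutc, item.samples[c]))
    for delivery_uutc, packet in delivered:
        buf.ingest(packet)
        write(buf.flush_ready(delivery_uutc))
    write(buf.drain())
    for store in stores:
        store.flush()
    return truth, stores, buf.drop_stats()


def band_feature_trace(
    signal: np.ndarray, fs: float, bands: list[PowerBandConfig], start_uutc: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-update (default 1-s) power-in-band features over a recording.

    Returns (uutc array, feature matrix of shape (n_updates, n_bands)).
    """
    step = int(round(bands[0].update_interval_s * fs))
    n_win = signal.shape[1] // step
    times = start_uutc + np.arange(n_win, dtype=np.int64) * int(bands[0].update_interval_s * US)
    feats = np.empty((n_win, len(bands)))
    for k in range(n_win):
        win = signal[:, k * step:(k + 1) * step]
        for j, b in enumerate(bands):
            feats[k, j] = band_power(win, fs, b)
    return times, feats


def ld_detection_run(
    config: SimConfig,
    bands: list[PowerBandConfig],
    ld_weights: tuple[float, ...] = (1.0, -1.0),
    calibration_config: SimConfig | None = None,
    merge_gap_s: float = 30.0,
) -> dict:
    """Full embedded-detector run: calibrate the LD threshold on a separate
    calibration recording, replay the evaluation recording through the FSM,
    and score event-level sensitivity/FPR against ground truth.

    Features are log power-in-band (the discriminant is linear in log power,
    which makes the seizure-band contrast amplitude-robust).
    """
    def log_feats(cfg: SimConfig):
        truth, signal = simulate_recording(cfg)
        times, feats = band_feature_trace(signal, cfg.fs, bands, cfg.start_uutc)
        return truth, times, np.log(np.maximum(feats, 1e-20))

    cal_cfg = calibration_config or config
    cal_truth, cal_times, cal_feats = log_feats(cal_cfg)
    in_sz = np.zeros(len(cal_times), bool)
    for ev in cal_truth:
        if ev.label == "seizure":
            in_sz |= (cal_times >= ev.uutc_start) & (cal_times < ev.uutc_end)
    threshold = calibrate_ld_threshold(ld_weights, 0.0, cal_feats[in_sz], cal_feats[~in_sz])
    ld = LdConfig(ld_weights, 0.0, threshold)

    truth, times, feats = (log_feats(config) if calibration_config is not None
                           else (cal_truth, cal_times, cal_feats))
    states = run_ld(ld, feats)
    calls = np.array([s == "High" for s in states])
    metrics = det_evaluate(times, calls, truth, merge_gap_s)
    metrics["threshold"] = threshold
    metrics["n_updates"] = len(times)
    return metrics


# ---------------------------------------------------------------------------
# standard benchmark runs
# ---------------------------------------------------------------------------

def compression_benchmark(seed: int, duration_s: float = 3600.0, root=None) -> dict:
    """One-hour (by default) four-channel recording at 250 Hz through the
    full path: JSON packet-log size vs block-compressed on-disk size, with an
    exact round-trip check on every channel before any ratio is reported."""
    import tempfile

    cfg = SimConfig(duration_s=duration_s, seed=seed)
    truth, signal = simulate_recording(cfg)
    json_bytes = len(packets_to_json_lines(emit_packets(signal, cfg)))

    def run(store_root) -> dict:
        _, stores, _ = record_to_stores(cfg, store_root)
        end = cfg.start_uutc + int(cfg.duration_s * US)
        for c, store in enumerate(stores):
            got, _, gaps = store.read_range(cfg.start_uutc, end)
            if gaps or not np.array_equal(got, signal[c].astype(np.int64)):
                raise AssertionError("lossless round trip failed")
        comp = sum(s.total_compressed_bytes() for s in stores)
        return {"ratio": json_bytes / comp, "json_bytes": json_bytes,
                "compressed_bytes": comp, "n_samples": signal.size}

    if root is not None:
        return run(root)
    with tempfile.TemporaryDirectory() as d:
        return run(d)


def seizure_detection_benchmark(seed: int, n_seizures: int = 50) -> dict:
    """The embedded-detector benchmark: a multi-hour recording with
    ``n_seizures`` injected seizures, the LD threshold calibrated on an
    independent recording (different seed, same conditions), and event-level
    sensitivity / false-positive rate scored against ground truth."""
    import dataclasses

    start = 1_600_000_000 * US
    onsets = tuple((start + int((200 + 230 * k) * US), 30.0) for k in range(n_seizures))
    duration_s = 200 + 230 * n_seizures
    eval_cfg = SimConfig(
        duration_s=duration_s, start_uutc=start, seizure_times=onsets,
        preictal_lead_min=0.0, seed=seed,
    )
    cal_cfg = dataclasses.replace(eval_cfg, seed=seed + 1000)
    bands = [
        PowerBandConfig(0, 3.0, 8.0),     # matched to the seizure rhythm band
        PowerBandConfig(0, 20.0, 47.0),   # high-frequency reference band
    ]
    return ld_detection_run(eval_cfg, bands, calibration_config=cal_cfg)
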