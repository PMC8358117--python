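"""Telemetry reassembly: out-of-order packet buffering with drop statistics.

Delivered packets enter a buffer spanning 5–10 s of signal time. The buffer
sorts them by generation timestamp (``gen_uutc``); a watermark trails the
flush clock by the window span, and order below the watermark is frozen.
A packet arriving with ``gen_uutc`` already below the watermark is "severely
delayed": it cannot be placed in order anymore and is discarded and counted.
Exact-duplicate timestamps (retransmission) are dropped with their own
counter. Flushing emits maximal contiguous sample runs; a missing packet
yields an explicit gap marker rather than interpolated samples.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np

from .devicesim import TelemetryPacket, US

__all__ = ["SampleRun", "GapMarker", "PacketBuffer"]


@dataclass(frozen=True)
class SampleRun:
    """A gap-free run of samples: shape (n_channels, n_samples) at fs Hz."""

    start_uutc: int
    fs: float
    samples: np.ndarray

    @property
    def end_uutc(self) -> int:
        return self.start_uutc + int(round(self.samples.shape[1] / self.fs * US))


@dataclass(frozen=True)
class GapMarker:
    start_uutc: int
    duration_us: int


class PacketBuffer:
    """Reorder buffer for delivered telemetry packets.

    Counter conservation holds at all times:
    ``received == emitted + discarded_late + duplicates + len(pending)``.
    """

    def __init__(self, fs: float, packet_ms: int, window_s: float = 10.0) -> None:
        if not 5.0 <= window_s <= 10.0:
            raise ValueError("window_s must be in [5, 10]")
        self.fs = fs
        self.packet_ms = packet_ms
        self.window_s = window_s
        self.watermark_uutc: int | None = None  # order frozen below this
        self._keys: list[int] = []              # sorted gen_uutc of pending
        self._pending: dict[int, TelemetryPacket] = {}
        self.counters = {"received": 0, "emitted": 0, "discarded_late": 0, "duplicates": 0}
        self._last_end_uutc: int | None = None  # end of the last emitted run

    # -- ingest -------------------------------------------------------------

    def ingest(self, packet: TelemetryPacket) -> None:
        self.counters["received"] += 1
        if self.watermark_uutc is not None and packet.gen_uutc < self.watermark_uutc:
            self.counters["discarded_late"] += 1
            return
        if packet.gen_uutc in self._pending:
            self.counters["duplicates"] += 1
            return
        bisect.insort(self._keys, packet.gen_uutc)
        self._pending[packet.gen_uutc] = packet

    # -- flush --------------------------------------------------------------

    def flush_ready(self, now_uutc: int) -> list[SampleRun | GapMarker]:
        """Emit everything older than ``now_uutc - window_s`` as contiguous
        runs with explicit gap markers between them; advances the watermark
        (which never decreases)."""
        new_mark = now_uutc - int(self.window_s * US)
        if self.watermark_uutc is not None:
            new_mark = max(new_mark, self.watermark_uutc)

        cut = bisect.bisect_left(self._keys, new_mark)
        ready_keys, self._keys = self._keys[:cut], self._keys[cut:]
        self.watermark_uutc = new_mark
        if not ready_keys:
            return []

        packet_us = int(round(self.packet_ms * 1000))
        out: list[SampleRun | GapMarker] = []
        run_pkts: list[TelemetryPacket] = []

        def close_run() -> None:
            if not run_pkts:
                return
            arr = np.concatenate([np.asarray(p.samples) for p in run_pkts], axis=1)
            out.append(SampleRun(run_pkts[0].gen_uutc, self.fs, arr))
            self.counters["emitted"] += len(run_pkts)
            run_pkts.clear()

        for k in ready_keys:
            p = self._pending.pop(k)
            expected = (run_pkts[-1].gen_uutc + packet_us) if run_pkts else self._last_end_uutc
            if expected is not None and p.gen_uutc != expected:
                close_run()
                out.append(GapMarker(expected, p.gen_uutc - expected))
            run_pkts.append(p)
        close_run()
        if out:
            last = out[-1]
            if isinstance(last, SampleRun):
                self._last_end_uutc = last.end_uutc
        return out

    def drain(self) -> list[SampleRun | GapMarker]:
        """Flush everything regardless of the window (end of session)."""
        far_future = (self._keys[-1] if self._keys else (self.watermark_uutc or 0)) \
            + int((self.window_s + 1) * US)
        return self.flush_ready(far_future)

    # -- stats --------------------------------------------------------------

    def drop_stats(self) -> dict[str, int]:
        snap = dict(self.counters)
        snap["pending"] = len(self._pending)
        assert snap["received"] == (
            snap["emitted"] + snap["discarded_late"] + snap["duplicates"] + snap["pending"]
        )
        return snap
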