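"""Segmented, block-compressed, CRC-protected time-series store.

The store keeps one directory per channel and one file per segment. Each
segment holds an ordered sequence of independently decodable blocks; each
block header carries the uUTC timestamp of its first sample, the sample
count, a CRC-32 of the compressed payload, and the statistical model (a byte
frequency table) needed to decode it. Compression is lossless
range-encoded differences (RED): first differences of the integer samples
are zigzag/varint byte-mapped and entropy-coded with a carry-less 32-bit
range coder driven by the per-block model.

Design properties:

* real-time: blocks are flushed whole, so a concurrent reader polling the
  file never sees a torn block and can read a segment while it grows;
* robust: every payload byte is covered by the block CRC; a corrupt or
  truncated block raises :class:`CorruptBlockError` naming its timestamp;
* prunable: old segment files may be deleted; readers skip missing indices.

The byte layout is fixed and little-endian throughout; see docs/FORMAT.md.
This is a documented local dialect — bit-compatibility with any external
electrophysiology format is a non-goal; losslessness and the header contract
are the tested surface.
"""

from __future__ import annotations

import io
import json
import os
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .devicesim import TelemetryPacket, US
from .telemetry import GapMarker, SampleRun

__all__ = [
    "BlockHeader",
    "CorruptBlockError",
    "encode_block",
    "decode_block",
    "ChannelStore",
    "packets_to_json_lines",
    "json_compression_ratio",
]

SEGMENT_MAGIC = b"NLTS"
FORMAT_VERSION = 1
BLOCK_MAGIC = b"BK"
FOOTER_MAGIC = b"EN"
_MASK32 = 0xFFFFFFFF
_TOP = 1 << 24
_BOT = 1 << 16
_MAX_TOTAL = 60000  # pre-quantization total-frequency ceiling (< 2**16 after rounding)

# Frequencies are stored as 1-byte codes: exact up to 16, then a geometric
# (4%-step) ladder. Both sides use the dequantized canonical values, so the
# quantization only costs a little compression, never correctness.
_QF_R = 1.04
_DEQ_TABLE = np.empty(256, dtype=np.int64)
_DEQ_TABLE[:17] = np.arange(17)
_DEQ_TABLE[17:] = np.rint(16.0 * _QF_R ** np.arange(1, 256 - 16)).astype(np.int64)
_FREQ_TO_CODE: dict[int, int] = {}
for _c in range(255, 0, -1):  # lowest code wins for duplicated values
    _FREQ_TO_CODE[int(_DEQ_TABLE[_c])] = _c


class CorruptBlockError(Exception):
    """Raised when a block fails its CRC, is truncated, or decodes to the
    wrong length. Carries the block's start timestamp when known."""

    def __init__(self, msg: str, start_uutc: int | None = None) -> None:
        super().__init__(msg if start_uutc is None else f"{msg} (block start_uutc={start_uutc})")
        self.start_uutc = start_uutc


# ---------------------------------------------------------------------------
# difference byte-mapping
# ---------------------------------------------------------------------------

def _zigzag(v: np.ndarray) -> np.ndarray:
    return (v << 1) ^ (v >> 63)


# Prediction: r_t = x_t - round((q1*x_{t-1} + q2*x_{t-2}) / 64), with r_0 = x_0
# and r_1 the plain first difference. (q1, q2) = (64, 0) is plain differencing;
# the encoder fits them per block (least squares, quantized to int8) so the
# residual variance tracks the local spectrum.

def _fit_predictor(x: np.ndarray) -> tuple[int, int]:
    if len(x) < 8:
        return 64, 0
    X = np.stack([x[1:-1], x[:-2]]).T.astype(np.float64)
    y = x[2:].astype(np.float64)
    try:
        a, *_ = np.linalg.lstsq(X, y, rcond=None)
    except np.linalg.LinAlgError:
        return 64, 0
    if not np.all(np.isfinite(a)):
        return 64, 0
    q1 = int(np.clip(round(a[0] * 64), -127, 127))
    q2 = int(np.clip(round(a[1] * 64), -127, 127))
    return q1, q2


def _residuals(x: np.ndarray, q1: int, q2: int) -> np.ndarray:
    r = np.empty(len(x), dtype=np.int64)
    r[0] = x[0]
    if len(x) > 1:
        r[1] = x[1] - x[0]
    if len(x) > 2:
        pred = (q1 * x[1:-1] + q2 * x[:-2] + 32) >> 6
        r[2:] = x[2:] - pred
    return r


def _residuals_to_bytes(r: np.ndarray) -> bytes:
    """Byte-map zigzagged residuals: values < 255 are one byte; 255 escapes
    to a LEB128 varint of the excess."""
    z = _zigzag(r)
    if len(z) == 0:
        return b""
    if int(z.max()) < 255:
        return z.astype(np.uint8).tobytes()
    parts = []
    last = 0
    for i in np.nonzero(z >= 255)[0]:
        parts.append(z[last:i].astype(np.uint8).tobytes())
        u = int(z[i]) - 255
        vb = bytearray([255])
        while u >= 0x80:
            vb.append((u & 0x7F) | 0x80)
            u >>= 7
        vb.append(u)
        parts.append(bytes(vb))
        last = int(i) + 1
    parts.append(z[last:].astype(np.uint8).tobytes())
    return b"".join(parts)


def _bytes_to_samples(raw: bytes, n_samples: int, q1: int, q2: int) -> np.ndarray:
    x = np.empty(n_samples, dtype=np.int64)
    pos = 0
    n_raw = len(raw)
    x1 = x2 = 0  # previous two reconstructed samples
    for i in range(n_samples):
        if pos >= n_raw:
            raise CorruptBlockError("residual stream truncated")
        s = raw[pos]
        pos += 1
        if s < 255:
            u = s
        else:
            u = 0
            shift = 0
            while True:
                if pos >= n_raw:
                    raise CorruptBlockError("residual stream truncated")
                b = raw[pos]
                pos += 1
                u |= (b & 0x7F) << shift
                if b < 0x80:
                    break
                shift += 7
            u += 255
        r = (u >> 1) ^ -(u & 1)
        if i == 0:
            v = r
        elif i == 1:
            v = x1 + r
        else:
            v = r + ((q1 * x1 + q2 * x2 + 32) >> 6)
        x[i] = v
        x2 = x1
        x1 = v
    if pos != n_raw:
        raise CorruptBlockError("residual stream has trailing bytes")
    return x


# ---------------------------------------------------------------------------
# carry-less range coder (order-0 static byte model)
# ---------------------------------------------------------------------------

def _quantize_freqs(counts: np.ndarray) -> np.ndarray:
    """Snap positive counts to the nearest canonical (1-byte-codable) value."""
    idx = np.searchsorted(_DEQ_TABLE, counts)
    idx = np.clip(idx, 1, 255)
    lower = _DEQ_TABLE[idx - 1]
    upper = _DEQ_TABLE[np.minimum(idx, 255)]
    use_lower = (counts - lower) <= (upper - counts)
    codes = np.where(use_lower & (idx - 1 >= 1), idx - 1, idx)
    return np.maximum(codes, 1)


def _build_model(raw: bytes) -> tuple[list[int], list[int]]:
    """Return (symbols, freqs): distinct byte values with scaled, quantized
    frequencies — every present symbol >= 1 and total < 2**16."""
    counts = np.bincount(np.frombuffer(raw, dtype=np.uint8), minlength=256)
    symbols = np.nonzero(counts)[0]
    total = int(counts.sum())
    n = len(symbols)
    freqs = counts[symbols].astype(np.int64)
    if total > _MAX_TOTAL:
        scale = (_MAX_TOTAL - n) / total
        freqs = 1 + np.floor(freqs * scale).astype(np.int64)
    codes = _quantize_freqs(freqs)
    return symbols.tolist(), _DEQ_TABLE[codes].tolist()


def _rc_encode(raw: bytes, symbols: list[int], freqs: list[int]) -> bytes:
    cum = {}
    c = 0
    for s, f in zip(symbols, freqs):
        cum[s] = (c, f)
        c += f
    total = c
    low = 0
    rng = _MASK32
    out = bytearray()
    append = out.append
    for byte in raw:
        cf, f = cum[byte]
        r = rng // total
        low = (low + r * cf) & _MASK32
        rng = r * f
        while True:
            if (low ^ (low + rng)) & _MASK32 < _TOP:
                pass
            elif rng < _BOT:
                rng = (-low) & (_BOT - 1)
            else:
                break
            append((low >> 24) & 0xFF)
            low = (low << 8) & _MASK32
            rng = (rng << 8) & _MASK32
    for _ in range(4):
        append((low >> 24) & 0xFF)
        low = (low << 8) & _MASK32
    return bytes(out)


def _rc_decode(payload: bytes, n_raw: int, symbols: list[int], freqs: list[int]) -> bytes:
    cumlist = [0]
    for f in freqs:
        cumlist.append(cumlist[-1] + f)
    total = cumlist[-1]
    import bisect as _bisect

    code = 0
    pos = 0
    for _ in range(4):
        code = ((code << 8) | (payload[pos] if pos < len(payload) else 0)) & _MASK32
        pos += 1
    low = 0
    rng = _MASK32
    out = bytearray()
    append = out.append
    npay = len(payload)
    for _ in range(n_raw):
        r = rng // total
        v = ((code - low) & _MASK32) // r
        if v >= total:
            raise CorruptBlockError("range decoder out of bounds")
        k = _bisect.bisect_right(cumlist, v) - 1
        cf = cumlist[k]
        f = freqs[k]
        append(symbols[k])
        low = (low + r * cf) & _MASK32
        rng = r * f
        while True:
            if (low ^ (low + rng)) & _MASK32 < _TOP:
                pass
            elif rng < _BOT:
                rng = (-low) & (_BOT - 1)
            else:
                break
            code = ((code << 8) | (payload[pos] if pos < npay else 0)) & _MASK32
            pos += 1
            low = (low << 8) & _MASK32
            rng = (rng << 8) & _MASK32
    return bytes(out)


# ---------------------------------------------------------------------------
# block encode / decode
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockHeader:
    """Self-describing header of one compressed block."""

    start_uutc: int
    n_samples: int
    raw_len: int               # residual byte-stream length before entropy coding
    comp_len: int              # payload bytes
    crc: int                   # CRC-32 (zlib polynomial) of the payload
    model: tuple[tuple[int, int], ...]  # (byte symbol, scaled frequency) pairs
    pred: tuple[int, int] = (64, 0)     # /64 fixed-point predictor taps

    # magic, start, n, raw, comp, crc, q1, q2, n_model
    _STRUCT = struct.Struct("<2sqIIIIbbH")

    def to_bytes(self) -> bytes:
        head = self._STRUCT.pack(
            BLOCK_MAGIC, self.start_uutc, self.n_samples,
            self.raw_len, self.comp_len, self.crc,
            self.pred[0], self.pred[1], len(self.model),
        )
        bitmap = bytearray(32)
        codes = bytearray()
        for s, f in self.model:
            bitmap[s >> 3] |= 1 << (s & 7)
            codes.append(_FREQ_TO_CODE[f])
        return head + bytes(bitmap) + bytes(codes)

    @classmethod
    def read(cls, fh: io.BufferedReader) -> "BlockHeader | None":
        head = fh.read(cls._STRUCT.size)
        if len(head) == 0:
            return None
        if len(head) < cls._STRUCT.size:
            raise _TruncatedTail()
        magic, start, n, raw, comp, crc, q1, q2, n_model = cls._STRUCT.unpack(head)
        if magic == FOOTER_MAGIC:
            raise _Footer()
        if magic != BLOCK_MAGIC:
            raise CorruptBlockError(f"bad block magic {magic!r}")
        mbytes = fh.read(32 + n_model)
        if len(mbytes) < 32 + n_model:
            raise _TruncatedTail()
        bitmap, codes = mbytes[:32], mbytes[32:]
        symbols = [s for s in range(256) if bitmap[s >> 3] & (1 << (s & 7))]
        if len(symbols) != n_model:
            raise CorruptBlockError("model bitmap inconsistent with symbol count", start)
        model = tuple(
            (s, int(_DEQ_TABLE[c])) for s, c in zip(symbols, codes)
        )
        return cls(start, n, raw, comp, crc, model, (q1, q2))


class _Footer(Exception):
    pass


class _TruncatedTail(Exception):
    """An incomplete record at end-of-file: expected while a writer is active."""


def encode_block(samples) -> tuple[BlockHeader, bytes]:
    """Losslessly compress one integer sample run into (header, payload)."""
    samples = np.asarray(samples, dtype=np.int64)
    if samples.ndim != 1 or len(samples) == 0:
        raise ValueError("encode_block requires a non-empty 1-D integer sequence")
    return _encode_block_at(samples, start_uutc=0)


def _encode_block_at(samples: np.ndarray, start_uutc: int) -> tuple[BlockHeader, bytes]:
    q1, q2 = _fit_predictor(samples)
    raw = _residuals_to_bytes(_residuals(samples, q1, q2))
    symbols, freqs = _build_model(raw)
    payload = _rc_encode(raw, symbols, freqs)
    header = BlockHeader(
        start_uutc=int(start_uutc),
        n_samples=len(samples),
        raw_len=len(raw),
        comp_len=len(payload),
        crc=zlib.crc32(payload) & _MASK32,
        model=tuple(zip(symbols, freqs)),
        pred=(q1, q2),
    )
    return header, payload


def decode_block(header: BlockHeader, payload: bytes) -> np.ndarray:
    """Exact inverse of :func:`encode_block`; validates CRC and length."""
    if len(payload) != header.comp_len:
        raise CorruptBlockError("payload truncated", header.start_uutc)
    if (zlib.crc32(payload) & _MASK32) != header.crc:
        raise CorruptBlockError("CRC mismatch", header.start_uutc)
    symbols = [s for s, _ in header.model]
    freqs = [f for _, f in header.model]
    try:
        raw = _rc_decode(payload, header.raw_len, symbols, freqs)
        samples = _bytes_to_samples(raw, header.n_samples, *header.pred)
    except (CorruptBlockError, OverflowError) as e:
        raise CorruptBlockError(str(e), header.start_uutc) from None
    return samples


# ---------------------------------------------------------------------------
# channel store: segments on disk
# ---------------------------------------------------------------------------

_SEG_HEAD = struct.Struct("<4sHdd I H")  # magic, version, fs, uv_per_count, index, name_len


def _segment_path(root: Path, index: int) -> Path:
    return root / f"segment-{index:06d}.nlts"


@dataclass
class _ReadBlock:
    header: BlockHeader
    offset: int  # payload offset in file


class ChannelStore:
    """One channel's on-disk store: a directory of segment files.

    Appends must be in time order (the telemetry layer guarantees this).
    Samples accumulate in a pending buffer and are written as whole blocks of
    ``block_span_s`` seconds; a gap (run not abutting the pending tail) closes
    the pending block early so block boundaries always fall on gaps.
    """

    def __init__(
        self,
        root: str | os.PathLike,
        channel_name: str = "ch0",
        fs: float = 250.0,
        uv_per_count: float = 0.5,
        block_span_s: float = 10.0,
        create: bool = True,
    ) -> None:
        self.root = Path(root)
        self.channel_name = channel_name
        self.fs = fs
        self.uv_per_count = uv_per_count
        self.block_span = int(round(block_span_s * fs))
        self._pend: np.ndarray = np.empty(0, dtype=np.int64)
        self._pend_start: int | None = None
        self._last_end: int | None = None
        self._fh: io.BufferedWriter | None = None
        self.segment_index = -1
        if create:
            self.root.mkdir(parents=True, exist_ok=True)
            existing = self._segment_indices()
            self.segment_index = (existing[-1] + 1) if existing else 0
            self._open_segment_file()

    # -- segment file plumbing ---------------------------------------------

    def _segment_indices(self) -> list[int]:
        out = []
        for p in self.root.glob("segment-*.nlts"):
            try:
                out.append(int(p.stem.split("-")[1]))
            except (IndexError, ValueError):
                continue
        return sorted(out)

    def _open_segment_file(self) -> None:
        path = _segment_path(self.root, self.segment_index)
        name = self.channel_name.encode()
        head = _SEG_HEAD.pack(SEGMENT_MAGIC, FORMAT_VERSION, self.fs,
                              self.uv_per_count, self.segment_index, len(name))
        self._fh = open(path, "wb")
        self._fh.write(head + name)
        self._fh.flush()

    # -- append -------------------------------------------------------------

    def append(self, run: SampleRun | tuple[int, np.ndarray]) -> None:
        """Append one contiguous sample run (single channel, 1-D samples)."""
        if isinstance(run, SampleRun):
            start, samples = run.start_uutc, np.asarray(run.samples).reshape(-1)
        else:
            start, samples = run
            samples = np.asarray(samples).reshape(-1)
        if len(samples) == 0:
            return
        if self._last_end is not None and start < self._last_end:
            raise ValueError("out-of-order append: run starts before last written sample")
        tick = US / self.fs
        pend_end = (
            None if self._pend_start is None
            else self._pend_start + int(round(len(self._pend) * tick))
        )
        contiguous = pend_end is not None and abs(start - pend_end) < tick / 2
        if self._pend_start is None:
            self._pend_start = start
            self._pend = samples.astype(np.int64)
        elif contiguous:
            self._pend = np.concatenate([self._pend, samples.astype(np.int64)])
        else:
            self._flush_pending()  # gap: close the open block
            self._pend_start = start
            self._pend = samples.astype(np.int64)
        self._last_end = start + int(round(len(samples) * tick))
        while len(self._pend) >= self.block_span:
            self._write_block(self._pend[: self.block_span], self._pend_start)
            self._pend = self._pend[self.block_span:]
            self._pend_start += int(round(self.block_span * tick))

    def _flush_pending(self) -> None:
        if self._pend_start is not None and len(self._pend) > 0:
            self._write_block(self._pend, self._pend_start)
        self._pend = np.empty(0, dtype=np.int64)
        self._pend_start = None

    def _write_block(self, samples: np.ndarray, start_uutc: int) -> None:
        header, payload = _encode_block_at(samples, start_uutc)
        assert self._fh is not None, "store is closed"
        self._fh.write(header.to_bytes() + payload)  # whole block in one write
        self._fh.flush()

    def flush(self) -> None:
        """Flush any pending partial block so readers can see it."""
        self._flush_pending()

    # -- segment rollover ---------------------------------------------------

    def roll_segment(self, now_uutc: int | None = None) -> list[dict]:
        """Finalize the open segment, verify it (full decode + CRC pass),
        quarantine it if bad, and open the next segment.

        Only the just-closed segment is verified — older segments may already
        be deleted. Returns a list of event dicts (for the annotation store);
        a verification failure yields a ``quarantine`` event but a new segment
        still opens (availability over completeness).
        """
        events: list[dict] = []
        prev_index = self.segment_index
        self._finalize_current()
        ok, err = self.verify_segment(prev_index)
        if not ok:
            path = _segment_path(self.root, prev_index)
            path.rename(path.with_suffix(".quarantined"))
            events.append({
                "type": "warning", "event": "segment_quarantined",
                "segment": prev_index, "error": err,
            })
        self.segment_index = prev_index + 1
        self._open_segment_file()
        events.append({"type": "status", "event": "segment_rolled",
                       "segment": self.segment_index})
        return events

    def _finalize_current(self) -> None:
        self._flush_pending()
        assert self._fh is not None
        self._fh.write(FOOTER_MAGIC + struct.pack("<qIIIIH", 0, 0, 0, 0, 0, 0)[: BlockHeader._STRUCT.size - 2])
        self._fh.flush()
        self._fh.close()
        self._fh = None

    def verify_segment(self, index: int) -> tuple[bool, str | None]:
        """Full consistency pass: decode every block and check its CRC."""
        path = _segment_path(self.root, index)
        if not path.exists():
            return False, "missing segment file"
        try:
            for header, payload in self._iter_blocks(path):
                decode_block(header, payload)
        except CorruptBlockError as e:
            return False, str(e)
        return True, None

    def delete_segment(self, index: int) -> None:
        _segment_path(self.root, index).unlink(missing_ok=True)

    def close(self) -> None:
        if self._fh is not None:
            self._finalize_current()

    # -- reading ------------------------------------------------------------

    @staticmethod
    def _iter_blocks(path: Path):
        with open(path, "rb") as fh:
            head = fh.read(_SEG_HEAD.size)
            if len(head) < _SEG_HEAD.size:
                return
            magic, version, fs, upc, index, name_len = _SEG_HEAD.unpack(head)
            if magic != SEGMENT_MAGIC:
                raise CorruptBlockError(f"bad segment magic in {path.name}")
            fh.read(name_len)
            while True:
                try:
                    header = BlockHeader.read(fh)
                except (_Footer, _TruncatedTail):
                    return  # finalized, or writer mid-block
                if header is None:
                    return
                payload = fh.read(header.comp_len)
                if len(payload) < header.comp_len:
                    return  # torn tail while writer active: stop before it
                yield header, payload

    def read_range(
        self, t0: int, t1: int
    ) -> tuple[np.ndarray, np.ndarray, list[GapMarker]]:
        """All stored samples with timestamps in ``[t0, t1)``, plus explicit
        gaps. Works across segment boundaries, on the open segment, and when
        early segments have been deleted (missing indices are skipped)."""
        if t0 >= t1:
            raise ValueError("read_range requires t0 < t1")
        self.flush()
        tick = US / self.fs
        pieces: list[tuple[int, np.ndarray]] = []
        indices = self._segment_indices()
        for idx in indices:
            for header, payload in self._iter_blocks(_segment_path(self.root, idx)):
                blk_end = header.start_uutc + int(round(header.n_samples * tick))
                if blk_end <= t0 or header.start_uutc >= t1:
                    continue
                samples = decode_block(header, payload)
                ts0 = header.start_uutc
                i0 = max(0, int(np.ceil((t0 - ts0) / tick - 1e-9)))
                i1 = min(header.n_samples, int(np.ceil((t1 - ts0) / tick - 1e-9)))
                if i1 > i0:
                    pieces.append((ts0 + int(round(i0 * tick)), samples[i0:i1]))
        pieces.sort(key=lambda p: p[0])
        if not pieces:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), []
        gaps: list[GapMarker] = []
        sample_arrays = []
        ts_arrays = []
        prev_end: int | None = None
        for start, samples in pieces:
            if prev_end is not None and start - prev_end >= tick / 2:
                gaps.append(GapMarker(prev_end, start - prev_end))
            sample_arrays.append(samples)
            ts_arrays.append(start + np.round(np.arange(len(samples)) * tick).astype(np.int64))
            prev_end = start + int(round(len(samples) * tick))
        return np.concatenate(sample_arrays), np.concatenate(ts_arrays), gaps

    def total_compressed_bytes(self) -> int:
        """On-disk size of every segment file, headers included."""
        return sum(p.stat().st_size for p in self.root.glob("segment-*.nlts"))

    def n_blocks(self) -> int:
        return sum(
            1 for idx in self._segment_indices()
            for _ in self._iter_blocks(_segment_path(self.root, idx))
        )


# ---------------------------------------------------------------------------
# JSON packet dialect & compression ratio
# ---------------------------------------------------------------------------

def packets_to_json_lines(packets) -> bytes:
    """Serialize a packet stream in the documented newline-delimited JSON
    dialect: one object per packet carrying every packet field under
    descriptive names, with per-channel sample arrays as decimal integers.
    This emulates the verbose JSON log a device API produces and is the
    uncompressed baseline against which the store's compression ratio is
    reported (see docs/FORMAT.md)."""
    lines = []
    for item in packets:
        p = item[1] if isinstance(item, tuple) else item
        if not isinstance(p, TelemetryPacket):
            raise TypeError("expected TelemetryPacket")
        lines.append(json.dumps({
            "gen_uutc": p.gen_uutc,
            "seq": p.seq,
            "stream": p.stream,
            "n_samples": p.n_samples,
            "channel_samples": {f"ch{c}": list(ch) for c, ch in enumerate(p.samples)},
        }, separators=(",", ":")))
    return ("\n".join(lines) + "\n").encode()


def json_compression_ratio(stores, json_bytes: int | bytes) -> float:
    """JSON-baseline compression ratio: total JSON bytes divided by the total
    on-disk compressed bytes (block headers and segment headers included)."""
    if isinstance(json_bytes, (bytes, bytearray)):
        json_bytes = len(json_bytes)
    store_list = [stores] if isinstance(stores, ChannelStore) else list(stores)
    for s in store_list:
        s.flush()
    if all(s.n_blocks() == 0 for s in store_list):
        raise ValueError("store is empty")
    comp = sum(s.total_compressed_bytes() for s in store_list)
    return json_bytes / comp
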