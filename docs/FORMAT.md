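# On-disk time-series format (`.nlts`)

One directory per channel; one file per segment, named
`segment-NNNNNN.nlts`. All integers are little-endian. Timestamps are uUTC
(microseconds since the Unix epoch, UTC). Query intervals are half-open
`[t0, t1)`.

## Segment file

| field         | type    | meaning                                   |
|---------------|---------|-------------------------------------------|
| magic         | 4 bytes | `NLTS`                                    |
| version       | u16     | format version (1)                        |
| fs            | f64     | sampling rate, Hz                         |
| uv_per_count  | f64     | microvolts per ADC count                  |
| index         | u32     | segment ordinal                           |
| name_len      | u16     | channel-name byte length                  |
| name          | bytes   | channel name (UTF-8)                      |

followed by zero or more blocks, optionally terminated by a footer record
whose first two bytes are `EN` (same total size as a block header). A file
without the footer is an open (non-finalized) segment and is still readable;
a reader stops cleanly at a truncated trailing record, which can only be the
block a concurrent writer is currently appending (blocks are written and
flushed whole).

Quarantined segments are renamed to `.quarantined` and ignored by readers.
Deleted segment indices are simply skipped.

## Block

| field     | type     | meaning                                          |
|-----------|----------|--------------------------------------------------|
| magic     | 2 bytes  | `BK`                                             |
| start_uutc| i64      | timestamp of the first sample                    |
| n_samples | u32      | samples in the block                             |
| raw_len   | u32      | residual byte-stream length before entropy coding|
| comp_len  | u32      | payload length in bytes                          |
| crc       | u32      | CRC-32 (zlib polynomial 0xEDB88320) of payload   |
| q1, q2    | i8 × 2   | predictor taps, /64 fixed point                  |
| n_model   | u16      | number of model symbols                          |
| bitmap    | 32 bytes | presence bitmap of byte symbols 0–255            |
| codes     | n_model×u8 | per-symbol frequency codes (see below)         |
| payload   | comp_len | range-coded residual bytes                       |

## Compression (lossless, RED-style)

1. **Prediction.** `r[0] = x[0]`, `r[1] = x[1] − x[0]`, and for t ≥ 2
   `r[t] = x[t] − ⌊(q1·x[t−1] + q2·x[t−2] + 32) / 64⌋` with the taps fitted
   per block by least squares and quantized to int8. `(q1, q2) = (64, 0)` is
   plain first differencing (the fallback for short or degenerate blocks).
2. **Byte mapping.** Residuals are zigzag-coded
   (`z = (r << 1) ^ (r >> 63)`); `z < 255` is one byte, otherwise byte 255
   followed by an LEB128 varint of `z − 255`.
3. **Entropy coding.** A carry-less 32-bit range coder with a static
   order-0 byte model stored in the header. Frequency codes 0–16 are exact
   counts; codes above 16 follow a geometric ladder
   `freq = round(16 · 1.04^(code−16))`. Raw counts are rescaled so the total
   stays below 2¹⁶ before quantization.

Every payload byte is covered by the CRC; any single bit flip is detected.
A block decodes independently of all others.

## JSON packet dialect (compression-ratio baseline)

The uncompressed baseline is the newline-delimited JSON log of the telemetry
packet stream, one object per packet, emulating the verbose per-packet JSON
a device API produces:

```json
{"gen_uutc":1600000000000000,"seq":0,"stream":"time_domain","n_samples":25,
 "channel_samples":{"ch0":[12,-3,...],"ch1":[...],"ch2":[...],"ch3":[...]}}
```

Samples are decimal integers (ADC counts). The reported ratio is total JSON
bytes divided by total on-disk compressed bytes, all headers included.
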