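# Methods

`neuroloop` is a desk-scale re-creation of a closed-loop epilepsy
neuromodulation platform: an implanted sensing/stimulation device streams
intracranial EEG (iEEG) to a bedside computer, which stores the data
losslessly, classifies brain state on several timescales, and adjusts
stimulation inside a clinician-defined safety envelope. Because the real
implant and radio are unavailable by construction, the package includes a
synthetic device whose recordings carry ground-truth labels; every analytic
is then evaluated against those labels.

## The synthetic device

The generator (`devicesim`) emits up to four channels of local field
potentials as signed 16-bit ADC counts (default 0.5 µV/count) at 250 Hz
(500/1000 Hz accepted). Brain states are injected as additive signatures on
a pink-noise (1/f) background of ~25 µV RMS — the canonical broadband shape
of field potentials:

* **seizure** — a shared rhythmic burst chirping from 8 down to 3 Hz at
  ~5× background RMS with a soft onset/offset envelope. This gives the two
  properties real electrographic seizures show on these features: raised
  per-second RMS/band power and raised inter-channel correlation.
* **pre-ictal** — the per-channel noise is mixed with a shared pink
  component so inter-channel correlation rises to ~0.6 (baseline ~0) for the
  configured lead time (default 60 min, abutting the onset) without a large
  power change. The lead default follows the reported observation that
  predictive iEEG signatures appear an hour or more before onset.
* **sleep** — a shared delta oscillation (~1–2 Hz, wandering) at ~3×
  background RMS, making delta-band relative power dominant.

These morphologies are deliberately simple: each analytic's target feature
is discriminative *by construction*. A green test therefore demonstrates
that the pipeline measures what it claims to measure (features, thresholds,
event logic, plumbing) — not that the classifiers would reach the same
numbers on real recordings, where class overlap, artifacts and
nonstationarity dominate. Battery drain is linear (configurable %/hour) — a
deliberately simple placeholder for real charge dynamics. The link model drops a
packet with probability `p_drop` and delays one with probability `p_delay`
by up to `max_delay_s`, never altering contents. The simulated clock is
explicit, so "30 minutes" of policy elapse in milliseconds of wall time.

## Telemetry reassembly

Packets (50 or 100 ms of samples with a generation timestamp) enter a 5–10 s
reorder buffer (default 10 s). A watermark trails the flush clock by the
window span; "severely delayed" is operationalized as arriving after the
watermark passed the packet's generation time — such packets can no longer
be placed in order and are discarded and counted. Exact-duplicate timestamps
are counted and dropped. Flushing emits maximal contiguous runs with
explicit gap markers; gaps are never interpolated (a forecasting-safe
choice). The counters satisfy
`received = emitted + discarded_late + duplicates + pending` at all times.

## Storage

The store writes per-channel segment files of independently decodable,
CRC-protected, block-compressed sample runs; docs/FORMAT.md specifies the
byte layout. Design points:

* **Blocks** default to 10 s and always break at gaps. Blocks are written
  and flushed whole, so a reader polling an open segment never sees a torn
  block (read-while-write).
* **Segments** roll on demand (a deployment rolls daily). Rolling finalizes
  the current segment, fully decodes and CRC-checks it, quarantines it on
  failure (renamed, logged, skipped by readers) and opens the next segment
  regardless — availability over completeness. Only the just-closed segment
  is verified, so older segments may be deleted freely.
* **Compression** is lossless: per-block least-squares two-tap linear
  prediction (plain first differencing as the degenerate case) with
  zigzag/cap-255 byte mapping and a static order-0 range coder whose byte
  model is stored in the header as a bitmap plus log-quantized frequency
  codes. The two-tap generalization of plain differencing was adopted after
  profiling showed first-difference residuals of pink noise retain
  predictable structure; it is worth ~0.2 bits/sample here and the format
  stays self-describing. On the pinned generator conditions the JSON-relative
  ratio is ~5.2 (the baseline dialect is defined in docs/FORMAT.md). That
  number is specific to these generator settings; it is not a claim about
  arbitrary signals.

## Analytics

**Detection** (1-s segments): per-channel log magnitude spectrum, 1–47 Hz in
1-Hz bins (rectangular window; bin b aggregates [b−0.5, b+0.5) Hz; log floor
10⁻¹² of full scale), plus upper-triangle correlations and descending
eigenvalues of the correlation matrices of both the raw channels and their
spectra — 208 features at C=4. The classifier is a 150-tree random forest
(seeded, serializable, refuses mismatched channel count or sampling rate).
A zero-variance channel's correlations are defined as 0. Per-second calls at
threshold 0.5 merge into events when closer than 30 s; event sensitivity,
event false-positive rate and onset latency are scored against ground truth.

**Prediction** (10-min non-overlapping windows, strictly causal):
upper-triangle interelectrode correlations plus per-channel spectral
magnitude 0.25–24 Hz in 0.25-Hz bands (386 features at C=4; band width is a
documented choice — only the range is prescribed). Windows with more than
10% gap are skipped, never imputed. The classifier is logistic regression
(near-unpenalized fits recover known generating weights in tests); the risk
state enters High after k consecutive windows at/above threshold and exits
after m below (defaults k = m = 1). Pre-ictal labels cover the 60-min
horizon before each onset; windows touching a seizure are excluded from
training.

**Sleep** is deliberately minimal and flagged replaceable: mean delta-band
(0.5–4 Hz) relative power across channels ≥ 0.5 ⇒ sleep. The threshold 0.5
encodes "delta dominates the spectrum above 0.5 Hz".

**Embedded detector**: two power-in-band features (default 1-s updates,
rectangular window; power scaled so an in-band sine of amplitude A reports
A²/2) through one linear discriminant with one threshold producing High/Low,
with optional onset/offset debounce counts (defaults 1, matching a bare
single-threshold detector). The benchmark uses log band power in the 3–8 Hz
seizure band against a 20–47 Hz reference band, weights (1, −1) — i.e. the
discriminant is the log band-power ratio — and calibrates the threshold as
the midpoint of class means on a separate calibration recording (different
seed, same conditions), emulating offline training before deployment.

## Stimulation governance

Programs (amplitude mA, rate Hz, pulse width µs, contacts) live in groups
A–D: A is the safe-mode baseline, B/C host the parameter trial, D is
adaptive. Validation is layered — desired vs clinician per-group bounds vs
global bounds — returns every violated bound, and runs both before any send
and inside every keepalive tick; the simulated device re-validates
independently, and a device rejection after a local pass raises a
discrepancy alarm. The adaptive lookup maps classified state (seizure >
pre-seizure > sleep/wake, in that priority) to pre-validated programs;
validation happens at configuration load, never at runtime.

The trial sequencer enumerates up to 24 combinations (≤3 amplitudes × ≤4
rates per set, two sets with their own pulse width and contacts; rates outer
loop, amplitudes inner — a stable documented order satisfying "every rate
with every amplitude"; sets run sequentially). Cycles alternate with rest
intervals at baseline; the cursor is persisted atomically (write + rename)
on every transition. After a crash the interrupted combination is re-run
from its start (the conservative reading of resume-from-last-tested); a
crash during rest resumes with the successor; a missing or corrupt cursor
restarts the trial with a warning. A stop command returns to safe mode
within one tick. Day/night parameter overlays use half-open local-time
windows `[start, end)`.

## Supervisor

The 30-s keepalive tick queries both batteries; disconnects streaming once,
on the crossing edge, when the implant battery reaches 25% (≤ 25% with a
fired-once latch — the threshold is prescribed, the edge semantics are a
documented choice; therapy continues, only streaming stops); warns when
streaming is expected but silent for 30 minutes (then re-arms rather than
warning every tick); re-sends desired stimulation parameters when the device
copy drifts (at most one re-send per tick, never an invalid program);
applies the day/night overlay; and emits an hourly status annotation aligned
to wall-clock hours. Reconnection is attempted only after more than three
consecutive failures and scans only previously paired devices. Impedance
testing accepts up to 16 contact pairs, rejects more before any state
change, pauses sensing and stimulation, restores the prior state exactly,
and annotates per-pair values.

Annotations are append-only events written atomically to a CSV file and a
SQLite database with row-for-row parity (buffered in memory across write
failures, flushed on recovery). Patient seizure/aura events call a pluggable
video-capture hook (a no-op stub here); SMS-style notification is likewise a
pluggable notifier. Reminders are pure functions of (schedule, now) and fire
once per occurrence.

## Numerical and testing choices

Timestamps are integer uUTC throughout; sample times are
`start + round(i·10⁶/fs)`. Benchmarks are sized for a single CPU: the
compression benchmark uses 1 h of 4-channel 250 Hz data (3.6 M samples);
the detector benchmark uses 50 seizures over ~3.2 simulated hours with an
equal-sized calibration recording. Property tests (hypothesis) are bounded
and seeded for determinism. Known limitations: the synthetic signatures are
far more separable than real iEEG, so the detector benchmark's 100%/0%
headroom over the ≥80%/≤20% requirement reflects the generator, not
expected clinical performance; the sleep classifier is a single-feature
threshold; accelerometer streams carry placeholders; radio physics,
charge-density safety and video/cloud plumbing are out of scope.
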