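# Methods

## The segmentation model

`beatwise` treats beat segmentation as event detection with a locally
rescaled window.  A window of length ω slides over the raw signal; each
slice is prepared into a fixed 512-sample vector and scored by a detector
for the probability P(B) of containing one complete, roughly centred
heartbeat.  When P(B) clears the confidence level p_b = 0.9, the slice's
*critical point* (cp) is located and, if its distance to the previous cp
is plausible, the beat is confirmed.  Each confirmation refreshes the
moving mean cp interval C̄ (arithmetic mean of the last K = 16 accepted
intervals) and re-derives every parameter from it:

| quantity | rule | default ratio |
|---|---|---|
| window length ω | η_w·C̄ | 0.9 |
| step s | η_s·C̄ | 3·0.9/11 ≈ 0.245 |
| next window start | cp + η_of·C̄ | 0.1 |
| too-close threshold | η_cmin·C̄ | 0.45 |
| too-far threshold | η_cmax·C̄ | 1.45 |
| tiny step (after a rejected cp) | η_sof·C̄ | η_s/3 |
| method-I segment length | η_δ·C̄, split η_ar : 1−η_ar | 0.9, 5/11 |
| method-II margins of beat j−1 | η_l·c_{j−1} left, η_r·c_j right | 0.5, 0.5 |

All ratios are configurable (`WindowConstants`); these defaults are the
published operating point of the method.  Two printed values for the
too-far ratio exist in the source material (1.4 and 1.45); the package
adopts 1.45, the value stated with the threshold definition, and leaves
it configurable.

**Critical-point rule.**  The cp of a window is an extremum selected
against the window median.  Read literally, the source rule picks the
extremum *nearer* the median, but that contradicts the intended
behaviour: an upright QRS has its median at the baseline, far from the R
peak.  The default (`cp_rule="dominant"`) therefore picks the extremum
*farther* from the median — the dominant deflection — and
`cp_rule="literal"` keeps the literal reading.  Ties break toward the
maximum; a constant window is flagged degenerate.

**Rounding.**  Every sample-valued quantity is rounded half-up at
assignment; C̄ stays real-valued internally.  Method-I margins are
derived from a single rounded segment length (`round(η_δ·C̄)`, then
`round(η_ar·length)` for the left share) rather than rounding the two
margin offsets independently; this makes "segment length =
round(η_δ·C̄)" an exact invariant instead of one that can drift by one
sample, and keeps the 5:6 split within a sample of exact.

**Rejection logic.**  A confident candidate closer than η_cmin·C̄ to the
previous cp is treated as a double detection: the window restarts just
past it (offset δ = round(η_of·C̄)) with tiny steps until the next
acceptance, and the candidate never enters the interval buffer.  A
candidate beyond η_cmax·C̄ is segmented with the current parameters —
the beat is real — but its interval is excluded from the mean, so pauses
cannot inflate the window.  ω is additionally capped at M samples, the
detector's fixed input length (the method's stated limitation: beats
longer than ≈1.4 s at 360 Hz exceed the input).

**Initialisation.**  Segmentation starts only after the rhythm is
acquired: a fixed window of 0.5 s (ω₀ = fs/2) scans from the start,
collecting K accepted cps without emitting boundaries; the running mean
uses all intervals collected so far during this phase.  Acquisition
succeeds when K cps are found within the first 30 s and the coefficient
of variation of their intervals is below 0.5; otherwise the pass restarts
with ω₀ grown by a factor e^0.01 (at most 100 restarts).  The 30 s span,
CV bound and restart cap are this package's criteria — the source
describes the restart rule but not the success test.  Initialisation cps
are reported as detections (they are real beats) but carry no boundaries.

## Segment preparation

Variable-length segments are centred in a length-M vector (M = 512,
≈1422 ms at 360 Hz), the slack filled by repeating the segment's endpoint
values with a ceil split (odd slack goes left), then min–max scaled to
[0, 1].  A constant segment maps to all zeros instead of raising, so
flatline dropouts flow through the detector as obvious non-beats.
Preparation is invariant to positive affine amplitude changes.  No
filtering or denoising is applied anywhere.

## Training-set construction

For each annotated beat with both neighbours, the triplet geometry sets
d1 (distance to the left cp), d2 (to the right cp) and the main-beat
length s = round(0.5·d1 + 0.6·d2).  The main segment is anchored with its
left margin 45% of d1 before the beat centre (left-short/right-long
placement); the exact anchoring is not specified in the source and is
configurable here.  Twelve positives: the main segment, ±4/8/12%-of-s
shifted copies, and five symmetric end-trims of {5, 10, 15, 20, 25}% of s
off both ends (the source says only "five end-trimmed versions"; a fixed
ladder makes the set deterministic).  Twelve negatives in three families
of four: halves cut at the beat centre and at ±5%-of-s from it, copies
shifted by ±45% and ±65% of s, and spans padded 15%/5% of s around the
(left, main) and (main, right) cp pairs so two critical points fall
inside.  Segments are clipped to the record and to length M.  First and
last beats of a record have no triplet and are skipped; a record
contributes 24·(B−2) examples, exactly 12:12 balanced per beat.

Fold assignment is record-wise.  An explicit fold table is honoured;
otherwise records are assigned round-robin over their sorted ids, which
is deterministic and balanced (ten records with k = 10 give one record
per fold — a stable hash modulo k would not guarantee that).

## The detectors

**CNN.**  Five conv(kernel 7, same padding)–ReLU–maxpool(2) blocks with
8/16/32/64/128 filters halve the 512-sample input to 16 positions, then
dropout (0.5) on the flattened features, one dense layer and a softmax
over {valid beat, non-valid beat}; P(B) is the valid-beat component, used
raw against p_b without calibration.  Layer sizes, optimiser (Adam,
lr 10⁻³, batch 256, cross-entropy) and dropout rate are this package's
choices — the source states only the block structure — sized as the
smallest stack that trains in minutes on one CPU.  The source places "a
fully-connected layer ... followed by a dropout layer"; dropout here acts
on the features entering the dense layer, the conventional placement (on
a 2-unit logit vector it would be degenerate).  The network and its
backpropagation are implemented directly in numpy (im2col convolutions);
training is deterministic given the seed.

**Oracle.**  A deterministic stand-in with the same interface for testing
the windowing logic without training: P(B) is the peak zero-normalised
cross-correlation of the (linearly detrended) window against a noiseless
beat template, raised to a concave power (0.5) and gated on the peak
position — full weight within ±10% of M around the window centre,
tapering to 0.75 at ±15%, penalised to 0.25 beyond.  The gate mirrors the
CNN's learned preference for centred beats; the square-root squash lets
clean-but-imperfect matches clear p_b = 0.9 while structureless windows
stay far below it.  The template is preprocessed exactly like an incoming
window, so a window identical to the template scores 1.0.

## The synthetic generator

Each beat is a sum of five Gaussians (P, Q, R, S, T) with typical
amplitudes/widths/offsets (R: 1 mV, σ = 12 ms); beat centres follow a
truncated-normal RR process (default mean 0.8 s, sd 0.05 s, floor
0.25 s).  Optional ingredients emulate ambulatory-recording pathologies:
ectopic beats (PVC-like — no P wave, wide inverted QRS — arriving at 55%
of the mean RR and followed by a 145% compensatory pause), additive white
noise at a configurable SNR (default 20 dB), and sinusoidal baseline
wander (default 0.3 mV at 0.3 Hz).  Ground truth is the exact R centre of
every beat.  The RR stream, ectopic placement, noise and wander phase use
independent seeded sub-streams, so a clean and an ectopic record with the
same seed share an identical underlying sinus rhythm — the paired
ectopic-robustness experiment compares like with like.

What the generator does *not* emulate: realistic arrhythmia sequences,
morphology drift, electrode motion artefacts, QRS-shaped noise bursts, or
multi-lead structure.  Tests passing on these records show the windowing
arithmetic, rejection logic and detector plumbing are correct under
rhythm variability, noise and wander; they do not certify performance on
clinical recordings, which depends on the CNN's training data.

## Reference experiments and sizes

The reference experiments (`beatwise.experiments`) fix the study
conditions: a 240 s / ~300-beat record at 360 Hz with 20 dB SNR and
0.3 mV wander for detection (scored at ±50 ms); the same record ±5%
ectopics for the robustness check (C̄ trajectories compared at matching
sinus beats); and CNN training with 3 epochs on ~20k augmented segments
from four 170 s records, tested on two held-out records — sizes chosen so
the full suite runs in minutes on one CPU while every moving part is
exercised.  Trajectory checks (running mean, boundary geometry) replay
the per-iteration log against brute-force recomputation and are exact.

## I/O conventions

All indices are 0-based with half-open [bl, br) spans.  Internal
processing is at 360 Hz; other native rates are polyphase-resampled on
load (annotation indices rescaled by the exact rational ratio, rounded
half-up) and the native rate is kept for back-mapping.  Lead selection
defaults to channel 0.  The WFDB codec supports text headers, format-16
signals and MIT-format annotations (including SKIP records for gaps
≥ 1024 samples); boundaries are written as CSV with a JSON sidecar
recording the rates and constants used.

## Known limitations

* The adaptive loop assumes a quasi-periodic rhythm; rhythms whose RR
  exceeds M/fs (≈1.4 s at 360 Hz) saturate the window cap and will be
  under-covered, and initialisation fails on signals with no detectable
  beats in the first 30 s (by design).
* The oracle detector is morphology-matched to its template family; it is
  a test double, not a clinical detector.
* Event-detection "accuracy" is defined as TP/(TP+FP+FN) since no true
  negatives exist; other conventions exist and the choice is
  configurable at the reporting layer.
* Boundary *quality* (margins on the isoelectric line, no overlap) is
  only guaranteed through the geometry rules; no automatic morphological
  check of the margins is performed.
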