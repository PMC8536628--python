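# Methods

## The signal model

A spreading depolarization (SD) crossing a subdural strip produces, on each
contact it passes, two coupled signatures in DC-coupled ECoG:

1. a **slow potential change (SPC)** — a bi- or triphasic transient of
   roughly five minutes and millivolt scale, visible in the infra-slow
   0.005–0.5 Hz band;
2. a **suppression** of spontaneous activity — a sustained drop of the
   0.5–45 Hz amplitude envelope that recovers after a cortical SD (CSD) and
   persists when the cortex is, or becomes, isoelectric (ISD).

The wave propagates at millimetres per minute, so on a strip with 10-mm
contact spacing the SPC arrives at successive contacts minutes apart.
Simultaneous arrival on most contacts is physiologically implausible and is
the signature of an artifact (the inspired-oxygen bolus being the canonical
example: an electrochemical, not cortical, transient that hits every
electrode at once and leaves spontaneous activity untouched).

## Waveband decomposition

Each channel is split with 4th-order Butterworth band-passes at 0.005–0.5 Hz
and 0.5–45 Hz, applied forward–backward (zero phase), so the effective
magnitude response is the square of the design and neither band lags the
raw time axis. The low band and the envelope (a causal 60-s RMS of the high
band) are carried at a 1 Hz working rate: SPCs are ~5-min events and
suppressions last tens of minutes, so nothing faster is informative and
hours-long records stay cheap. The 0.005 Hz corner implies a settling time
of a few hundred seconds; a `settle_s` prefix is marked on every
decomposition and excluded from detection, with a warning when the record is
shorter than ten settling times.

Channels are screened before detection: flat (envelope under 1 µV for more
than half the record) or saturated (beyond 90% of the nominal converter
span) channels are flagged bad, all-NaN channels missing; both reduce the
confidence of events detected on the remaining contacts.

## SPC detection: a matched filter in the observed domain

The canonical SPC kernel is two opposed raised-cosine lobes (second lobe 80%
of the first), optionally a small third lobe for the triphasic form. An
important numerical fact drives the detector design: a ~300-s transient has
its fundamental near 0.0033 Hz, *below* the 0.005 Hz high-pass corner, so
the squared (zero-phase) response removes most of it. What survives in the
low band is dominated by lobe-edge structure, and a template that ignores
this matches the observed waveform poorly (normalized correlation ~0.8 at
300 s, worse at 600 s), fragmenting long SPCs into spurious short
detections. The detector therefore scans, for each duration in
`spc_scan_durations_s` (default 120–600 s), a two-template bank: the raw
kernel and the same kernel passed through the low-band filter. On
noise-free fixtures the filtered template correlates with the observed SPC
at ≥ 0.9997.

Detection uses the absolute normalized cross-correlation at every 1-s lag
(polarity conventions differ between display systems, and the bipolar
montage inverts SPCs pairwise), gated at `spc_corr_threshold` (default 0.8)
and `spc_min_amplitude_mv` (default 0.5 mV peak-to-peak). Overlaps are
resolved greedily by correlation strength, with a one-minute exclusion
margin around each accepted window so filter ringing cannot re-trigger.
Onset is refined to the first departure beyond 10% of the window's peak
deviation; the lobe count of the 10-s-smoothed window assigns
biphasic/triphasic. Each candidate keeps a 128-point resampled snippet for
stereotype work.

SPC confidence (0–100) is `100·(0.6·corr + 0.4·min(1, p2p/2 mV))`: monotone
in both clarity and amplitude, saturating at a textbook-clean 2 mV event.

## Suppression detection

On the 1-Hz envelope, a suppression opens when the envelope stays below
`suppression_depth_ratio` (0.5) times the rolling baseline — the median of
the preceding 10 min, frozen at the moment the drop starts — for at least
120 s, and closes when the envelope recovers above 0.8 × baseline. An
absolute isoelectric floor (10 µV) additionally opens a suppression in
cortex that is already silent when the record begins, using the record's
awake envelope level (or twice the floor) as the reference baseline; without
this rule a record that starts suppressed would never show a drop. Events
still open at the record end are returned open-ended. Suppression
confidence is `100·(0.7·(1 − depth) + 0.3·min(1, duration/600 s))`.

The 10 µV floor was chosen to sit at or below suppressed-envelope levels
(a 50 µV background at depth 0.2 gives 10 µV) and safely below normal
envelopes; it is a config key like every other gate.

## Event assembly and classification

Within a channel, an SPC links to a suppression that opens within
[−60 s, +300 s] of its onset (*new_onset*) or that is already open at its
onset (*pre_existing*); otherwise *none*. Across channels, SPCs chain
greedily in onset order into one event while consecutive members are ≤ 10
min apart, the event spans ≤ 60 min, and each channel contributes at most
one SPC — a repeated channel starts the next event, which deterministically
splits consecutive overlapping SDs (the regime the original system
undercounted). Lone SPCs become single-channel events, retained but heavily
penalized.

Classification, in order: simultaneous flag (more than half the member
onsets within one 30-s window) ⇒ artifact; no suppression link anywhere ⇒
artifact; new-onset links only ⇒ CSD; pre-existing only ⇒ ISD; both ⇒
CSD/ISD. Event confidence is the mean of member SPC and linked suppression
confidences, scaled by participation (members ÷ good channels, floored at
0.4), channel quality (good ÷ total), and ×0.5 for single-channel events.

## Stereotyping

Genuine SDs repeat with stereotyped SPC shapes; artifacts tend to be
one-offs. Pairwise event similarity is the mean over shared channels of the
snippet cross-correlation at the lag of maximal |correlation| (keeping the
sign, so an inverted copy scores −1), mapped to [0, 1]; pairs sharing no
channel get an uninformative 0.5. Average-linkage agglomeration on
1 − similarity is cut at 0.25, and clusters of at least max(3, 25% of
events) are *major*: members gain 15 confidence points, outliers lose 15
(clamped to [0, 100]; classification is never changed by this step). The
0.25 cut reflects a property of max-lag correlation: even unrelated shapes
score ~0.7 similarity (distance ~0.3), while stereotyped repeats score
≥ 0.95, so the cut must fall between ~0.05 and ~0.3.

A final threshold (default 30; 60 is the stricter clinical alternative)
partitions candidates: accepted ⇔ confidence ≥ threshold and classification
is not artifact.

## Reporting

The heat map is a grid of 15-min blocks. An accepted event marks every
block its [first SPC onset, last SPC onset + duration] interval intersects
— an event straddling a block boundary marks both blocks — and the block
state is the maximum confidence among marking events. Physiology rows carry
the 15-min means flagged against clinician-defined target ranges, or
*missing*. Rendering is numeric; the state→bin mapping (green/orange/brown/
red confidence quartiles) is declared in the grid file rather than drawn.
Any window holding ≥ 3 accepted onsets within 2 h raises a cluster flag
(the stricter of the published 2-h/3-h definitions; configurable).

In streaming mode the detector and stereotyping re-run after every 15-min
epoch over a sliding history (default 24 h), so earlier blocks may be
re-graded up or down as the stereotype builds; every revision is logged with
the epoch that caused it. For records no longer than the history window the
final streamed grid equals the batch grid exactly. Streaming re-filters the
elapsed history each epoch (zero-phase filters are not chunk-causal), so its
cost grows quadratically with record length; it is intended for epoch-scale
emission, not high-rate callbacks.

## Evaluation conventions

Software events match annotations greedily, nearest-in-time, one-to-one,
within ±300 s. True negatives partition the record into 20-min periods (SDs
recur at most ~3/h, so one SD notionally occupies 20 min); periods without
a verified SD onset each count one TN. Sensitivity TP/(TP+FN) and
false-positive rate FP/TN are explicitly *undefined* (None) on zero
denominators, never silently zero. Record-level counts regress by
unconstrained OLS (software on truth) with t-based 95% CIs. The ROC sweeps
the threshold 0–100; its detection-rate denominator is the full annotation
list, so the curve's ceiling sits below 1.0 whenever candidate generation
missed events outright — the sweep measures the confidence system, not the
detector front end.

## The synthetic generator

The generator emulates the study conditions the detector assumes:
band-limited (0.5–45 Hz) Gaussian background at 50 µV RMS per channel with
a small (< 0.005 Hz, 5 µV RMS) drift — an SD-free record keeps well under
5% of its power below 0.4 Hz, so any SPC detection on it is a genuine false
positive. Scheduled SDs inject the raised-cosine SPC kernel per contact
along a propagation path with per-step delay = spacing/speed (default
10 mm at 5 mm/min → 120 s), end contacts at 4 mV and inner contacts at
2 mV peak-to-peak, plus a multiplicative envelope suppression (30-s ramp to
depth 0.2, 1200-s hold, 120-s-constant exponential recovery for CSD;
for ISD the gain drops 30 min before the wave arrives and never recovers).
FiO2 transients add one identical mV-scale kernel to *all* channels at once
with no gain modulation; movement bursts multiply the background; bad
channels are flat, missing channels NaN; degradation modes ramp the overall
amplitude down or toggle one contact's gain. Every scheduled event is
returned as ground truth (annotation + per-channel onsets), and a seed
fully determines the sample matrix.

The reference study condition (`default_validation_spec`) is a 24-h,
6-channel, 256-Hz record with 20 stereotyped CSDs and 2 FiO2 artifacts.
The CSD train uses a 40-min interval so each 20-min depression recovers
before the next wave; at the 21-min recurrence seen in dense clinical
clusters the depressions genuinely overlap and later events present as
pre-existing suppression — that regime is exercised separately via
`make_stereotyped_train`, not baked into the CSD reference condition.

### What the generator does not emulate

Real pathology: electrode pop/chewing/mains artifacts with SPC-like
morphology, non-stationary background spectra, evolving SPC shapes after
heavy artifact periods, amplitude asymmetries beyond the end/inner-contact
split, and true DC drifts of electrochemical origin. Passing the synthetic
recovery tests therefore demonstrates internal consistency of the pipeline
under its own signal model — not clinical performance, which in the
original study required expert-scored records and showed ~79% count
sensitivity.

## Problem sizes and numerical choices

Tests run the full pipeline on 24-h records at the spec's native 256 Hz
(ten seeds for parameter recovery) and shorter 0.5–3.5-h records elsewhere;
the acceptance script uses three 24-h records plus smaller batteries. The
1-Hz working rate makes everything downstream of filtering linear-time and
small. Filtering is float64 throughout (the 0.005-Hz corner is numerically
delicate; single precision makes the SOS sections singular). Ties in the
greedy SPC resolution break toward earlier onsets; clustering ties are
broken by scipy's deterministic condensed-matrix order; all randomness in
the generator flows from one `SeedSequence`, with noise and schedule
jitter drawn from independent child streams so the background does not
change when the schedule does.

## Known limitations

Single-channel SDs are retained but scored near the floor (16 with default
weights), below the default threshold — mirroring the original prototype,
which excluded such patients. Overlapping SD trains are split by the greedy
channel-reuse rule, which restores countability but can misattribute a
member SPC when two waves cross mid-strip. The similarity measure uses SPC
shape only; the original system may also have used cross-channel sequence
timing. The EDF writer emits plain continuous EDF (16-bit) and cannot carry
NaN; missing channels round-trip through CSV/HDF5 only.
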