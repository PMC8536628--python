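# sddetect

Automated detection of **spreading depolarizations (SDs)** in multichannel
DC-coupled subdural electrocorticography (ECoG).

SDs are waves of mass neuronal and glial depolarization that cross injured
cortex at millimetres per minute, depress the ECoG, and are independently
associated with worse outcome after traumatic brain injury, subarachnoid
hemorrhage and malignant hemisphere stroke. Detecting them currently
requires continuous expert review of multichannel ECoG over days. This
package implements an automated detector aimed at that monitoring problem,
for neurocritical-care and neurophysiology researchers: it flags candidate
SDs in real time or in archive mode, classifies them, and summarizes them
for non-specialists as a 15-min heat-map grid.

## Method

Each channel of raw full-band data is split into a low (0.005–0.5 Hz, slow
potential) and a high (0.5–45 Hz, spontaneous activity) waveband with
zero-phase Butterworth filters. Two low-level features are sought per
channel, each scored 0–100:

* **SPC** — a bi/triphasic slow potential change of ≈5 min and mV scale,
  found by normalized cross-correlation against a canonical biphasic kernel
  (and against that kernel as the low-band filter renders it);
* **suppression** — a sustained drop of the high-band amplitude envelope
  below half of its rolling 10-min baseline (or below an absolute
  isoelectric floor), with hysteresis on recovery.

SPCs link to coincident suppressions in the same channel, then chain across
channels in onset order into high-level events honoring propagation timing.
Classification follows the link pattern: new-onset suppressions ⇒ CSD,
pre-existing (already-suppressed cortex) ⇒ ISD, both ⇒ CSD/ISD, no links or
near-simultaneous multichannel onsets ⇒ artifact (the FiO₂-bolus signature).
Event confidence combines member confidences with participation and
channel-quality factors; a similarity matrix over SPC snippets is clustered
(average linkage) and major-cluster members gain confidence while outliers
lose it — *stereotyping*, the key discriminator between repeating genuine
SDs and one-off artifacts. A final threshold (default 30) partitions
candidates into accepted SDs and rejected artifacts.

Scoring against ground truth uses greedy one-to-one onset matching (±300 s),
a 20-min-period true-negative convention (sensitivity = TP/(TP+FN),
false-positive rate = FP/TN, both explicitly undefined on zero
denominators), unconstrained OLS of per-record counts, and a 0–100 ROC
threshold sweep.

A seeded synthetic-ECoG generator (`sddetect.synthetic`) renders known SD
schedules — propagation paths, stereotyped trains, pre-suppressed (ISD)
cortex, FiO₂ artifacts, bad/missing channels, signal degradation — with
feature-level ground truth, so the whole pipeline is testable without
clinical data. See `docs/methods.md` for the model, parameter defaults and
limitations.

## Worked example

```python
from sddetect import DetectorConfig, detect
from sddetect.synthetic import (SyntheticSpec, ArtifactItem,
                                make_stereotyped_train, generate_recording)
from sddetect.evaluation import evaluate_record

# a 3-h, 6-channel record: three stereotyped CSDs plus one FiO2 bolus
spec = make_stereotyped_train(SyntheticSpec(duration_s=3 * 3600.0, seed=7),
                              family=1, n=3, interval_s=2400.0, start_s=1800.0)
spec = spec.replace(artifact_schedule=[ArtifactItem(onset_s=9000.0)])
rec, annotations, _ = generate_recording(spec)

result = detect(rec, DetectorConfig())
for ev in result.candidates:
    print(f"{ev.onset_s:7.0f} s  {ev.classification:8s}  "
          f"confidence {ev.confidence:5.1f}")
report = evaluate_record(result.accepted, annotations, rec.duration_s)
print(f"sensitivity {report.sensitivity:.2f}  "
      f"false-positive rate {report.fpr:.3f}")
```

prints

```
   1799 s  CSD       confidence  95.0
   4199 s  CSD       confidence  95.0
   6599 s  CSD       confidence  95.0
   8999 s  artifact  confidence 100.0
sensitivity 1.00  false-positive rate 0.000
```

All three injected depolarizations are recovered at the scheduled onsets
with the full contact order, and the oxygen-bolus transient — identical on
all channels, with no accompanying suppression — is classified artifact and
excluded, despite its high feature confidence. The three onsets fall within
a 2-h window, so `detect_sd_clusters` additionally raises one SD-cluster
flag, the pattern of greatest pathogenic concern.

The same pipeline is available from the shell:

```bash
sddetect simulate --out rec.h5 --truth truth.csv --seed 7
sddetect run --input rec.h5 --out-dir out --threshold 30
sddetect evaluate --events out/events.csv --truth truth.csv --duration-h 24
sddetect roc --events out/events.csv --truth truth.csv --duration-h 24
```

`run` writes the event log (CSV), the heat-map grid (CSV + JSON with the
confidence→color bins), SD-cluster flags and a reproducibility manifest;
`--stream` switches to epoch-by-epoch emission with retrospective
re-grading.

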