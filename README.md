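# ppgfuse

Pulse-rate detection from a four-sensor photoplethysmography (PPG) array of
the kind embedded in the top surface of a computer mouse. Palm PPG is
convenient but fragile: vasculature differs under each sensor, and mouse
movement and clicking inject motion artifacts and contact dropouts. This
package implements and evaluates a real-time-style detection chain for such
multi-channel recordings:

1. **Preprocessing** — each raw channel passes a 40th-order low-pass FIR
   filter (5 Hz cutoff at 200 Hz sampling, Hamming windowed-sinc, unit DC
   gain) to strip high-frequency noise.
2. **Fusion** — the four channels are mixed into one waveform, either as the
   plain average `S_mix[n] = Σᵢ Sᵢ[n] / 4` or as the quality-weighted
   average `S_mix[n] = Σᵢ Wᵢ[n]·Sᵢ[n] / Σᵢ Wᵢ[n]`, where each channel's
   weight rises by α = 2 whenever its own beat detector finds a plausible
   peak, falls by α on implausible peaks or missed beats, and is clamped to
   [2, 20].
3. **Peak detection** — a sample-by-sample state machine on the slope
   (first difference) of the mixed waveform: a slope above a dynamic
   threshold arms the detector; the first non-positive slope afterwards
   marks a pulse peak; the threshold is refreshed from the maximum slope of
   that upstroke. Each peak-to-peak interval (PPI) must fall strictly
   inside (0.7, 1.3) × the previous accepted PPI, and pulse rate follows as
   `PR = 60·fs / PPI` beats per minute.
4. **Evaluation** — detections are matched one-to-one to reference beats
   within a tolerance; sensitivity `Se = 100·TP/(TP+FN)`, positive
   predictivity `+P = 100·TP/(TP+FP)` and failed detection rate
   `FDR = 100·FP/TP` are scored after discarding the first and last 5 s of
   each record.

Because no palm recordings from the original hardware are public, the
package ships a **synthetic-data module** that simulates 1-minute,
4-channel, 200 Hz records with known beat times under six usage conditions
(rest, slow/rapid × horizontal/vertical movement, document browsing with
clicks), including per-channel amplitude differences, baseline wander,
Poisson motion-artifact bursts and contact-loss dropouts. Everything is
testable against ground truth.

Intended users: researchers in wearable/peripheral vital-sign sensing who
want a reference implementation of slope-based adaptive-threshold beat
detection and detection-quality-weighted sensor fusion, with a simulator to
probe failure modes.

## Worked example

```sh
ppgfuse simulate --scenario rest --seed 42 --out rec.csv
# wrote 12000 samples x 4 channels (60 s at 200 Hz), 89 reference beats -> rec.csv

ppgfuse detect --in rec.csv --method weighted --out peaks.txt
# 86 candidates, 86 accepted, median PR 88.8889 bpm -> peaks.txt

ppgfuse evaluate --peaks peaks.txt --ref rec.ann --fs 200 --n-samples 12000 --out metrics.json
# TP 75  FP 0  FN 0  Se 100%  +P 100%  FDR 0%
```

The simulated resting record beats at 89 bpm; the weighted pipeline detects
86 peak candidates (the first ~2 s calibrate the detector threshold, so the
earliest beats are not emitted), all of which pass the PPI gate, and the
median pulse rate of 88.9 bpm recovers the simulated rate. Scoring inside
the trimmed window (samples 1000–10999) finds all 75 reference beats with no
false detections. The same works from Python:

```python
import numpy as np
from ppgfuse import RunConfig, scenario_preset, generate_record, detect_on_mixed

config = RunConfig()
record = generate_record(scenario_preset("rest", seed=42))
mixed, peaks, pr = detect_on_mixed(record, "weighted", config)
print(np.median(pr))   # 88.888...
```

`ppgfuse report --in <dir>` batch-scores every annotated record in a
directory for each single channel and both fusion methods, printing a
Se/+P/FDR table per scenario × method.

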