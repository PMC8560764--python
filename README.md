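# hfokit

Interictal iEEG biomarker pipeline: detection and time–frequency
classification of high-frequency oscillations (HFOs) and sharp-spikes in
stereo-EEG, with seizure-onset-zone (SOZ) classification statistics,
spatial-reliability testing, and resection-outcome scoring.  A synthetic
cohort generator with planted, ground-truth-labeled events makes every stage
verifiable without clinical recordings.

## Pipeline

| Stage | Module | What it does |
|---|---|---|
| simulate | `hfokit.synth` | 1/f background (+ delta slow waves in sleep), Gabor-atom oscillations (ripple 80–250 Hz, fast-ripple 250–600 Hz), biphasic sharp-spikes, and composites, planted at Poisson rates elevated on SOZ channels; two conditions per patient with log-scale condition effects |
| preprocess | `hfokit.preprocess` | bipolar montage from declared contact pairs; FastICA-based attenuation of shared broadband artifact components |
| detect | `hfokit.detect` | Hilbert detector: 1000th-order symmetric FIR band-pass (80–600 and 250–600 Hz), analytic envelope, moving-average smoothing, whole-series z-scoring, skewness-defined threshold, onset/offset extraction |
| classify | `hfokit.classify` | Morlet scalogram topography: an event is a genuine oscillation only if its above-threshold time–frequency region is a closed island that does not extend below 80 Hz (rejecting Gibbs ringing from filtered sharp transients); categories RonO/RonS/fRonO/fRonS/SharpSpike/Artifact |
| rates / roc | `hfokit.ratestats` | events/min per contact × category × condition; linear mixed models of log power/frequency (random intercept per contact); mixed two-way ANOVA of rates (condition × SOZ/lobe); SOZ ROC with Mann–Whitney AUROC, channel bootstrap CIs, McClish partial AUROC |
| reliability | `hfokit.reliability` | normalized scalar product of per-contact rate maps across conditions with a channel-permutation null (N = 2000, add-one smoothed p) |
| outcome | `hfokit.outcome` | 95th-percentile positive regions per patient, resection containment vs Engel outcome, contingency metrics with Clopper–Pearson CIs |

## CLI

Each stage is a subcommand; `run-all` chains them:

```sh
hfokit run-all --seed 5 --out runs/demo
hfokit simulate --config config.yaml --seed 1 --out runs/sim
hfokit detect --data runs/sim --out runs/detect
hfokit classify --data runs/sim --candidates runs/detect/candidates.csv --out runs/classify
hfokit rates --data runs/sim --events runs/classify/classified.csv --out runs/stats
hfokit roc --data runs/sim --rates runs/stats/rates.csv --out runs/stats
hfokit reliability --rates runs/stats/rates.csv --out runs/stats
hfokit outcome --data runs/sim --rates runs/stats/rates.csv --out runs/stats
```

Configuration is YAML (see `hfokit.core.config.PipelineConfig`); every run
writes a manifest (config hash, seed, package version) next to its outputs.
Signals are read/written as EDF or as raw float32 + JSON sidecar; tables are
CSV, statistical results JSON.

## Conventions

Times are seconds from recording start, sample indices 0-based, event
intervals half-open `[onset, offset)`, amplitudes in microvolts.  Resection
status is tri-state (true/false/unknown); surgical failure is Engel class
IIa or worse.  The `Artifact` category is kept in catalogs for audit but
excluded from all rate statistics.
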