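# swallowscreen

Analysis pipeline for accelerometry-based swallow screening: from dual-axis
cervical accelerometry recordings and videofluoroscopy (VFSS) reference
ratings to per-consistency classifiers of impaired swallowing **safety**
(Penetration–Aspiration Scale 3–8) and **efficiency** (≥ 50% vallecular or
pyriform residue), evaluated by participant-stratified Monte-Carlo repeated
random sub-sampling.

Because the underlying clinical recordings are proprietary, the package
ships a first-class synthetic-data subsystem: a cohort simulator calibrated
to the published outcome structure, a burst-plus-noise signal generator with
ground-truth annotations and a tunable class-conditional effect, and a
deterministic fixture cohort that reproduces the published prevalence table
and detection-curve structure exactly (where arithmetically attainable).

## Layout

| module | contents |
| --- | --- |
| `swallowscreen.core` | domain types (`Recording`, `BolusTrial`, `CohortDataset`, …) and `PipelineConfig` |
| `swallowscreen.io` | cohort CSV dialect and plain-text/HDF5 recording dialect, bit-exact round trips |
| `swallowscreen.vfss` | label binarization, participant roll-up, protocol stopping rules, prevalence / silent-aspiration / cumulative-detection summaries |
| `swallowscreen.signals` | zero-phase Butterworth preprocessing (0.1 Hz high-pass, 1 kHz low-pass), RMS energy envelope, hysteresis segmentation |
| `swallowscreen.features` | 30-dimensional per-bolus feature vectors (time-domain moments, spectral shape, Haar wavelet subband energies, cross-axis correlation) |
| `swallowscreen.rlda` | shared-covariance regularized LDA with analytic (Ledoit–Wolf) shrinkage and exact Gaussian posteriors |
| `swallowscreen.evaluate` | stratified splits, tie-aware AUC, operating points, the 10,000-iteration Monte-Carlo evaluator, six-task suite, validation sample-size design |
| `swallowscreen.synthetic` | cohort/signal simulators and `make_table2_fixture()` |
| `swallowscreen.cli` | `swallowscreen` command-line entry point and manifest-driven runs |

## CLI

```sh
# deterministic fixture cohort + published-table-shaped summary
swallowscreen make-fixtures --out fixture.csv
swallowscreen summarize --cohort fixture.csv

# synthetic end-to-end run
swallowscreen simulate-cohort --participants 40 --seed 1 --out cohort.csv
swallowscreen simulate-signals --cohort cohort.csv --seed 1 --out signals.csv
swallowscreen featurize --cohort signals.csv --out features.csv
swallowscreen evaluate --cohort signals.csv --features features.csv \
    --iterations 200 --seed 1

# reproducible pipeline run from a JSON manifest
swallowscreen run --manifest manifest.json
```

Exit codes: `0` success, `2` configuration error, `3` data error.

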