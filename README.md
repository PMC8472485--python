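# errp — single-trial error-related potential decoding

`errp` is a tested, reusable pipeline for studying how well feedback
**error-related potentials (ErrPs)** can be decoded from single EEG trials,
and — the harder question — how well a decoder *transfers*: across days of
the same person and across people.  ErrP detection matters for
brain–computer interfaces (BCIs), where recognizing that the system made an
error can be used to correct actions or to label data for continuous
classifier adaptation, e.g. during BCI-based stroke rehabilitation.

The package is aimed at BCI/neural-engineering researchers who want a fully
controlled, simulation-backed version of this experiment: every stage is a
pure function of its inputs and a seed, and the ground truth (ERP
amplitudes, latencies, participant/day variability) is known by
construction.

## What it implements

- **Simulation** (`errp.simulate`): sham-feedback sessions — 400 trials at
  an exact 70/30 correct/error ratio, feedback-locked ERP templates with a
  negative peak at 350 ms and a positive peak at 450 ms (the ErrP carries a
  deeper negative peak), fronto-central scalp topography, 1/f background
  noise, artifact epochs, bad channels, and hierarchical
  participant/day/trial variability.  Cohorts of N participants × D days.
- **Preprocessing** (`errp.preprocess`): 0.05–10 Hz zero-phase order-8
  Butterworth band-pass; bad-channel exclusion (mean |amplitude| >
  mean + 3 SD across channels); [100, 500) ms feedback-locked epochs;
  rejection of epochs exceeding 150 µV; per-epoch mean subtraction;
  NonErrP subsampling to exact class balance.
- **Features** (`errp.features`): the epoch waveform downsampled to 50 Hz,
  or the entire epoch, flattened channel-major with per-column
  (channel, time) provenance.
- **Classifiers** (`errp.mlp`, `errp.slda`, `errp.scg`): a 5-layer MLP
  (hidden 100-50-25, tanh, sigmoid output) trained full-batch by **scaled
  conjugate gradient** on the binary cross-entropy, and **shrinkage LDA**

      Σ(γ) = (1 − γ) S + γ (tr S / d) I,   w = Σ(γ)⁻¹ (μ₁ − μ₀),

  with the Ledoit–Wolf analytic γ.  Both are implemented from scratch and
  are deterministic given a seed.
- **Evaluation** (`errp.evaluation`): within-day (stratified 10-fold CV),
  between-day (train one day, test the other, both directions), and
  across-participant (leave-one-participant-out) calibration; binomial
  chance level at α = 0.05; grand averages with standard error; Pearson
  test–retest and Spearman accuracy–impairment correlations.
- **Orchestration** (`errp.pipeline`, `errp.cli`): one master seed derives
  every stage seed; tidy results CSV, exclusion log, and run manifest.

See `docs/methods.md` for the model, assumptions, and numerical choices.

## Worked example

```python
from errp import ExperimentConfig, VariabilityProfile
from errp.pipeline import run_experiment

cfg = ExperimentConfig(
    n_participants=3, n_days=2, n_per_movement=50, fs_hz=200.0,
    montage=["Fz", "F1", "F2", "FCz", "FC1", "FC2", "Cz", "C1", "C2"],
    profile=VariabilityProfile(bad_channel_rate=0.0),
    methods=("slda-features",), master_seed=42,
)
results, exclusions = run_experiment(cfg)
print(results.groupby("scheme").agg(mean_accuracy=("accuracy", "mean"),
                                    chance=("chance_level", "mean")).round(3))
```

prints

```
                    mean_accuracy  chance
scheme
across-participant          0.513   0.597
between-day                 0.571   0.592
within-day                  0.668   0.592
```

Read: with session-to-session variability switched on, a decoder calibrated
and tested **within the same day** classifies 66.8% of trials correctly —
above the 59.2% binomial chance threshold for this test-set size — while
training on the *other* day drops accuracy to 57.1% and training on *other
participants* to 51.3%.  That ordering (within-day ≫ between-day,
across-participant) is the structural finding the simulation is built to
reproduce; its strength depends on the configured day- and participant-level
variability.  The exclusion table in the same run records, per session, how
many epochs the 150 µV rule rejected and how many survived balancing.

The same experiment is available from a shell:

```sh
errp simulate --config cohort.yaml --out cohort/ --seed 1
errp run --scheme within-day --method slda-features --seed 1 --out results/
errp report --in results/results.csv
```

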