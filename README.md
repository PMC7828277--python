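# cuffdrift

Simulation pipeline for studying **chronic signal drift in multi-contact
nerve-cuff recordings** and for comparing strategies that keep a neural
pathway classifier calibrated as that drift progresses.

Spiral nerve-cuff electrodes wrapped around a peripheral nerve (here, a
7-ring × 8-contact cuff on a rat sciatic nerve model, 56 channels) can
discriminate which fascicle — tibial, peroneal or sural — produced a
compound action potential (CAP), by classifying the per-CAP spatiotemporal
signature (channels × time window around the CAP peak).  After chronic
implantation two factors degrade that signature: fibrotic **encapsulation
tissue** growing between nerve and cuff, and **rotation** of the cuff around
the nerve.  A classifier calibrated at implant time slowly goes stale.

`cuffdrift` synthesizes this whole study end to end:

1. **Volume conductor** — analytic leadfield `L[i,j] = 1/(4π σ_eff d)` for
   point sources in a layered nerve model (anisotropic endoneurium,
   perineurium, epineurium, encapsulation annulus, saline), with
   encapsulation fill and cuff rotation as perturbations.
2. **CAP simulator** — charge-balanced source templates fired synchronously
   at nodes of Ranvier (A-alpha: 1.70 mm spacing, 94.86 m/s; A-beta:
   1.16 mm, 64.72 m/s), tripole-referenced 56-channel recordings, long
   event series, and white Gaussian noise at whole-series SNR −5/−10/−15 dB.
3. **Dataset builder** — 56×100 signatures (3.333 ms at 30 kHz) normalized
   into [−1, 1], stratified 5-fold splits, spatial/temporal channel
   orderings, and cross-time-point interpolation.
4. **Classifiers** — a fast multinomial softmax baseline and a dual-branch
   convolutional network (spatial + temporal input orderings), both
   implemented in numpy with seeded, warm-startable training.
5. **Strategy engine** — *baseline calibration* (train once), *periodic
   recalibration* (supervised warm-start retraining at every time point)
   and *self-learning* (retraining on the model's own predictions with
   confidence ≥ 0.95, halting when any class drops below 200 self-labelled
   samples), evaluated by cross-validated macro F1, plus the
   training-frequency / initial-performance slope analysis.

See `docs/methods.md` for the models, parameters and limitations.

## Worked example

Rotation scenario at −5 dB, desk scale (3000 CAPs per time point, linear
classifier), comparing a frozen baseline model against periodic supervised
recalibration:

```python
from cuffdrift import orchestration as orch, strategy_engine as se

cfg = orch.RunConfig(n_per_class=1000, master_seed=1)
inputs = orch.build_study_inputs(cfg)
seq = orch.build_sequence(cfg, inputs, "rotation", -5.0)
seed = orch.derive_seed(cfg.master_seed, "train/rotation/-5.0")
bs = se.train_base_states(seq, "linear_baseline", seed)
rb = se.run_baseline_calibration(seq, seed=seed, base_states=bs)
rp = se.run_periodic_recalibration(seq, seed=seed, base_states=bs)
print("timepoint  baseline  periodic")
for tp in seq.ids:
    print(f"{tp:>9}  {rb.mean_f1(tp):.3f}     {rp.mean_f1(tp):.3f}")
```

prints

```
timepoint  baseline  periodic
       R0  1.000     1.000
       R5  1.000     1.000
      R10  0.920     0.985
      R15  0.730     0.992
      R20  0.584     0.994
      R25  0.637     0.992
      R30  0.639     0.993
      R35  0.508     1.000
      R40  0.433     1.000
      R45  0.402     0.999
```

Each row is the mean 5-fold cross-validated macro F1 at one rotation step
(R10 = 10° of cuff rotation).  The frozen baseline collapses as contacts
move away from their calibration positions — by a full 45° slot pitch the
channels are exactly permuted and the frozen model is near chance — while
supervised recalibration tracks the drift.  Self-learning
(`se.run_self_learning`) sits between the two and stops itself once too few
confident samples remain per class.

The same API runs the encapsulation scenario
(`build_sequence(..., "encapsulation", ...)` with time points Base, ET1,
ET2, ET3).  Under this package's ray-approximated leadfield, encapsulation
shifts channel gains by only a few percent, so desk-scale F1 stays flat
across fills — see `docs/methods.md` for why that differs from a
finite-element treatment.

A CLI mirrors the library: `cuffdrift simulate`, `cuffdrift build-datasets`,
`cuffdrift run-strategy`, `cuffdrift slopes`, `cuffdrift full-study`,
`cuffdrift report`.

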