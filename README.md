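# bestmcg

In-silico evaluation of biomagnetic sensor-array geometries via simulated
lesion detection.

## The problem

Magnetocardiography (MCG) sensors — SQUIDs, optically pumped magnetometers,
fluxgates — do not sample the field at a point.  Each integrates over a
sensing volume (its *effective domain*): the pickup coil, the atomic vapour
cell, the magnetic core.  How does that volume's geometry, together with
the array's stand-off distance from the heart, affect the array's ability
to detect small tissue lesions?  `bestmcg` answers this with a fully
simulated diagnostic experiment: a sensor geometry's score is the
validation accuracy of a classifier trained to tell normal from lesioned
hearts using only that geometry's readouts.

## The model

The heart is a current-dipole source.  A dipole with moment **ρ** produces
the field

&nbsp;&nbsp;&nbsp;&nbsp;**B**(**r**_f) = μ₀ (**ρ** × **r**) / (4π r³),&nbsp;&nbsp;&nbsp;&nbsp;**r** = **r**_f − **r**_dipole,

and fields superpose linearly.  A normal heart is one strong fixed dipole
(position (12, 12, 0) cm, orientation (1, 0, 0), intensity 10); a lesioned
heart adds 1–10 weak dipoles (intensity ≤ 1) with random positions,
orientations and strengths in a small box around it.  Volume-conductor
effects are neglected for the measured z-component.

A virtual array holds 6×6 sensors at 4-cm pitch, each a cuboid effective
domain of bottom edge *a* and height *h* (cm) whose bottom plane sits *d*
cm above the main-dipole plane.  A sensor's readout is the plain average of
B_z over a 1-mm lattice of field points filling its cuboid (the smallest
0.5 cm³ sensor holds 125 points).  Readouts are paired one-to-one with
Gaussian noise matrices, optionally upsampled 6×6 → 128×128 by bicubic
splines, split 80/20 into training and validation sets, and fed to a
classifier (a DenseNet-style CNN with squeeze-and-excitation attention, or
a fast quadratic-feature logistic baseline).  Accuracy tables over (a, h,
d) are interpolated into surfaces and summarised by ordinary-least-squares
slopes with two-tailed t-tests on H₀: β₁ = 0.

## Worked example

```python
import numpy as np
import bestmcg as bm

grid = bm.field_point_grid(bm.SensorSpec(a=0.5, h=0.5), center=(2, 2), d=2.0)
print(f"field points per sensor: {grid.n}")

sets = bm.sample_lesion_sets(500, np.random.default_rng(0))
normal, abnormal = bm.measure_models(
    bm.HeartModel(), sets, bm.ArrayConfig(d=2.0), bm.SensorSpec(a=0.5, h=0.5)
)
sigma = bm.calibrate_sigma()
print(f"calibrated noise sigma: {sigma:.4f}")

bank = bm.generate_noise_bank(500, sigma, np.random.default_rng(1))
maps = bm.assemble_final_measurements(normal, abnormal, bank)
dataset = bm.split_dataset(maps)   # warns: scaled-down counts use the 80% rule
print(f"split: {len(dataset.training)} training / {len(dataset.validation)} validation maps")

result = bm.train_classifier(
    dataset, bm.ClassifierConfig(architecture="logistic_baseline", epochs=30, seed=0)
)
print(f"best validation accuracy: {result.best_accuracy:.3f} (epoch {result.best_epoch})")

far = bm.run_sweep(
    "cubic", [(0.5, 0.5, d) for d in (2.0, 3.0, 5.0)],
    bm.PipelineConfig(n_per_class=500, sigma=sigma,
                      classifier=bm.ClassifierConfig(epochs=30)),
    master_seed=0,
)
for p in far.points:
    print(f"d = {p.d} cm -> accuracy {p.accuracy:.3f}")
```

prints

```
field points per sensor: 125
calibrated noise sigma: 0.0435
split: 800 training / 200 validation maps
best validation accuracy: 0.695 (epoch 30)
d = 2.0 cm -> accuracy 0.595
d = 3.0 cm -> accuracy 0.560
d = 5.0 cm -> accuracy 0.515
```

The 125 points are the 5×5×5 lattice of the smallest sensor; sigma is
calibrated to 10% of the peak noiseless readout at the reference geometry;
and accuracy falls as the array moves away from the source — the field
decays, the signal-to-noise ratio drops, and lesions become harder to see.

The same pipeline is scriptable from the shell:

```bash
bestmcg simulate --n 1000 --seed 0 --out lesions.csv
bestmcg build-dataset --a 0.5 --h 0.5 --d 2 --n-per-class 1000 --seed 0 --out data.h5
bestmcg train --dataset data.h5 --epochs 30 --out training.csv
bestmcg sweep --out sweep_artifacts/          # desk-scale preset
bestmcg report --sweep-dir sweep_artifacts/ --out surface.png
```

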