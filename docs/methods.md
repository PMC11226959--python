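# Methods

## Source model

The heart is modelled phenomenologically as a set of current dipoles in a
24×24×32 cm torso box. A dipole with moment **ρ** = intensity × orientation
produces **B**(**r**_f) = k (**ρ** × **r**) / r³ with **r** the displacement
from the dipole to the field point; fields superpose linearly. The normal
heart is a single main dipole fixed at (12, 12, 0) cm with orientation
(1, 0, 0) and intensity 10 (arbitrary units). A lesioned heart adds N weak
dipoles, N uniform on {1, …, 10}, each with position uniform in
x, y ∈ [10, 14] cm, z ∈ [−1, 1] cm, orientation uniform on the unit sphere
(normalised 3-D Gaussian — the unbiased reading of "randomly selected"),
and intensity uniform on (0, 1] (zero is excluded so every lesion dipole is
a genuine source). A draw landing exactly on the main-dipole position is
rejected and redrawn.

**Units.** The prefactor k = μ₀/4π is set to 1: no absolute field unit is
fixed anywhere in the pipeline, and classification performance depends only
on the ratio of lesion signal to noise, so any global rescaling of k,
intensities, and sigma cancels. k is a parameter of every field routine for
users who want SI values.

**Assumptions.** Dipoles are static (no cardiac cycle); the volume
conductor is ignored, which is a standard approximation for the z-component
of the field outside the torso; sensors measure B_z only.

## Sensor model

Each sensor's effective domain is a cuboid with bottom edge a and height h
(cm), bottom face at height d above the main-dipole plane. The readout is
the unweighted mean of B_z over a 1-mm lattice filling the cuboid:

- x–y points are the global 1-mm lattice of the torso rectangle restricted
  to the sensor's square footprint. The footprint is **closed** on both
  edges by default. For half-millimetre edges (a = 0.5 at even-cm centres)
  the convention is immaterial and yields the 5×5 = 25 points per plane
  that make the smallest sensor's 125-point count; for integer-edge
  footprints both edges are included (a = 1 → 11 points per axis, 605 in
  total), and a `closed=False` flag switches to the half-open reading.
  Lattice membership is decided in integer 0.1-mm units, never by
  floating-point comparison.
- z planes are d + k·0.1 cm for k = 0 … 10h − 1, i.e. the half-open
  interval [d, d + h). This reproduces the plane list {2.0, …, 2.4} cm for
  h = 0.5 at d = 2.
- The 36 sensors sit on a 6×6 grid at 4-cm pitch starting at (2, 2) cm,
  enumerated row-major (x outer, y inner).

The batched readout kernel (all lesion sets × all sensors) is jit-compiled
with numba when available; a vectorised numpy path produces identical
values (tested to 1e-12 relative) and is used otherwise. The batched
kernels omit the point-coincides-with-dipole singularity guard that the
scalar routines keep, which is safe whenever the sensor planes sit above
the source region (d > 1 cm covers every supported geometry).

## Noise and datasets

Measurement noise is additive i.i.d. Gaussian per sensor. The field scale
is arbitrary, so sigma is defined **relative to the signal**: by default
sigma = 0.1 × max |noiseless normal readout| at the reference geometry
(d = 2, a = h = 0.5 cm), computed once per run (0.0435 in simulation
units). This is an explicit convention — the noise amplitude is otherwise a
free parameter of the protocol — and any fixed sigma can be supplied
instead.

One noise matrix i is added to both the single normal readout and abnormal
readout i, so each pair shares its noise realisation and differs only by
the lesion contribution. The split takes the first 80% of each class in
pair order (16,000 train / 4,000 validation at the full scale of 10,000
pairs; proportional with a warning otherwise); both members of a pair
always land in the same split, and there is no cross-validation or
shuffling across the boundary. Maps are optionally upsampled 6×6 → 128×128
with bicubic splines whose nodes sit at the sensor centres {2, 6, …, 22}
cm and whose output grid spans [2, 22] cm inclusive; splines reproduce
node values and polynomials up to cubic degree exactly but can overshoot
between nodes, so no range bound is asserted.

## Classifiers

Both architectures share one seeded training loop (Adam, lr 1e-3, batch
64, reshuffled each epoch), per-sensor input standardisation fitted on the
training split, and one epoch record per epoch: mean training loss, mean
validation loss, validation confusion matrix at the p ≥ 0.5 threshold, and
accuracy A = (TP + TN)/total. The geometry's score is the best validation
accuracy over all epochs, earliest epoch on ties. The per-sample loss is
−[y log p + (1 − y) log(1 − p)] with p the predicted probability of the
abnormal class (y = 1), clamped at 1e-12. (Some presentations of this loss
define p as the normal-class probability while keeping y = 1 for abnormal,
which inverts the formula; the standard convention is implemented.)

**dense_se_cnn.** A 3×3 convolutional stem + batch norm + ReLU + a
squeeze-and-excitation (SE) gate; three dense blocks of four dense layers
(each: BN-ReLU-1×1 bottleneck, BN-ReLU-3×3 producing 12 feature maps, SE on
the new maps); transition layers halving channels with 2×2 average
pooling; global average pooling into a 2-way linear head. Depth, growth
and widths are configurable; the defaults are a small budget sized for
128×128 single-channel maps on one CPU. The layers are implemented
directly in numpy with manual backpropagation (verified against central
finite differences), so no deep-learning framework is required.

**logistic_baseline.** Softmax regression on the flattened standardised
map, augmented by default with its elementwise squares. The quadratic
features matter: lesion orientations are zero-mean, so the two classes
have identical mean readouts and differ only in (co)variance; the
likelihood-ratio detector for an equal-mean variance shift is quadratic in
the data, and a purely linear model is at chance in population regardless
of geometry. With squares included the baseline is a genuine shallow
detector (≈0.70 at d = 2 versus ≈0.53 at d = 5 under the default
calibration) and runs a full 30-epoch fit in well under a second, which is
what makes desk-scale sweeps practical. `quadratic_features=False`
restores the purely linear variant.

## Sweeps, surfaces and regressions

Sweep families mirror the study design: `cubic` (a = h over
{0.5, 1, 1.5, 2, 2.5, 3, 4} × d ∈ {2, 2.5, 3, 4, 5}), `cuboid_h_fixed`
(h = 0.5), and `d4_grid` (d = 4, full a × h grid). Within one replicate
the same sampled lesion-set collection and noise bank are reused across
all geometries — one simulated cohort measured by every candidate array —
and replicates redraw everything from a spawned seed sequence. The default
is a single replicate; regressions pool whatever rows are present.

Accuracy surfaces are interpolated for visualisation with d on [2, 5] cm
at 301 nodes (300 intervals) and a on [0, 4] cm at 401 nodes; the d = 4
family maps h and a each onto [0, 4] at 401 nodes. The cubic-sensor family
uses bicubic splines; the cuboid families use bilinear interpolation,
which avoids spline overshoot at the data edges.

Each one-parameter slice is summarised by OLS y = β₀ + β₁x with
SE(β₁) = √(SSE/(n−2)/Sxx), t = β₁/SE and a two-tailed p from the exact
t distribution with n − 2 degrees of freedom (n is as small as 5, so no
normal approximation). Star labels use strict thresholds: *** p < 0.001,
** p < 0.01, * p < 0.05, else n.s. A perfect fit (SSE at rounding-noise
scale relative to the response variance) is flagged degenerate with
SE = 0, |t| = ∞, p = 0 rather than dividing by zero. A constant response
returns β₁ = 0, t = 0, p = 1.

## Scaled-down evaluation sizes

Full-scale runs (10,000 pairs per geometry, 30-epoch CNN on 128×128 maps,
35–49 geometries) are a cluster-sized computation and are emitted as the
`full_scale_config()` preset. The package's own end-to-end checks and
`scripts/acceptance.py` use a desk-scale regime chosen to keep the trend
statistics meaningful on one CPU: 1,000 samples per class, the
quadratic-logistic baseline, 30 epochs, 5 replicate seeds, distance swept
at the smallest cubic sensor and edge length swept at h = 0.5, d = 4.
Under these conditions the distance trend (accuracy falls with d,
regression slope < 0) and the edge-length flatness (|t| below the 5%
critical value in the majority of replicates) reproduce qualitatively;
numeric slopes at full scale additionally depend on the chosen noise
amplitude and on CNN training stochasticity, and are not desk-reproducible
targets.

## What the generator does and does not emulate

The synthetic cohort captures the geometry-dependent physics: field decay
with distance, spatial averaging over the effective domain, and the
masking/offsetting of weak dipoles inside large sensing volumes. It does
not emulate cardiac dynamics (static dipoles only), physiological noise or
correlated sensor noise (i.i.d. Gaussian only), sensor tilt or
sensitivity variation within the domain, or volume-conductor currents.
Passing tests therefore demonstrate the protocol's behaviour under the
stated model, not the performance of any physical sensor on real MCG
recordings.

## Known limitations

- The CNN is trained in float64 numpy; full-scale 128×128 training is
  possible but slow compared with GPU frameworks, and is not exercised by
  the default test run.
- Lesion detectability under the logistic baseline rests on variance
  features; classifiers without quadratic capacity (or datasets without
  shared-noise pairing) will sit near chance.
- The closed-footprint lattice convention is pinned by the 125-point case
  only; integer-edge counts (e.g. 605) are convention-dependent and the
  half-open variant is provided.
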