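# Methods

`prfocus` simulates and solves the calibration problem of transcranial
focused-ultrasound (TUS) phased arrays: the skull imposes element-dependent
amplitude and phase aberration, summarized by a complex transfer matrix
(TM) `H` whose entry `h_ln` is the single-frequency response from array
element `n` to control point `l`.  Once a row of `H` is known, time
reversal (driving each element with the conjugated response, `E0 =
conj(H_l)`) is the Cauchy–Schwarz-optimal focus.  The package estimates
that row from *intensity-only* sonication readouts, warm-started from a
degraded acoustic model of the head such as one synthesized from
ultrashort-echo-time (UTE) MRI, and evaluates the focus against the
gold standard (GS): the time-reversal drive of the true, CT-model TM.

## Forward model

Subject-scale TUS planning normally runs a full-wave pseudo-spectral
solver; this package deliberately uses a straight-ray phase-screen model
instead, so that a complete three-phantom study runs in minutes on one
CPU:

    h_ln = (A / r_ln) * exp(-∫ α ds) * exp(-i 2π f ∫ ds / c(x)),

with both line integrals taken along the straight element-to-target ray
through the voxelized speed/attenuation volumes (midpoint rule, sampling
step = half the smallest voxel spacing, nearest-voxel lookup).  In uniform
water this is exactly the free-space Green's function; through the skull it
reproduces the integrated delay and absorption that drive aberration.  It
ignores refraction, reverberation, mode conversion and element directivity.
The calibration algorithm consumes only a complex TM, so none of its logic
depends on how the TM was produced; what the substitution changes is the
*statistics* of the rows, which the phantom generator is tuned to keep
skull-like (below).

Spatial reciprocity holds exactly (the sampled ray is symmetric under
swapping endpoints), and the time-reversal drive is normalized to unit L2
norm throughout, which makes the GS the optimal unit-norm input and bounds
the recovery ratio `R%NS ≤ 100` as a theorem rather than a convention.

## Synthetic head phantoms

A phantom is an ellipsoidal skull shell in water on a 2 mm grid
(110 × 110 × 96 voxels), with CT-like values in Hounsfield units clamped to
[0, 2400].  Default geometry: outer radii (80, 95, 75) mm centred at
(0.11, 0.11, 0.09) m; shell thickness 7 mm modulated by ±60 % (peak) with a
30 mm-correlation random field; trabecular HU texture of 800 HU standard
deviation and 20 mm correlation around a 1700 HU base.  All fields are
seeded and bit-reproducible.

These scales were chosen to land the transfer-matrix rows in the regime a
real adult skull produces at 250 kHz, and on which the whole method is
predicated: inter-element phase spread ≈ 1 rad (vault thickness genuinely
varies over roughly 3–10 mm), aberration correlated across neighbouring
elements (element pitch ≈ 22 mm on this array, aberration correlation
2–3 cm), and negligible conjugate symmetry of the row.  The last point
matters more than it may appear: with real ±1 probes, magnitudes cannot
distinguish a row from its conjugate, and a row with strong conjugate
overlap (phase spread well below ~0.8 rad) is ill-conditioned for
magnitude-only recovery at any probe budget.  Early, gentler parameter
choices produced exactly that degeneracy; the defaults were calibrated once
to the identifiable regime and then frozen.

What the phantom does *not* emulate: anatomical shape, sutures and inner
tables, soft tissue, refraction at the skull surface.  Passing tests
therefore show that the calibration algorithm behaves as designed on
skull-like aberration statistics — not that any specific subject would
reach the same numbers.

## Acoustic property mapping

With porosity `φ = 1 − HU/2400`, speed and density interpolate linearly in
`1 − φ` between water (1500 m/s, 1000 kg/m³) and cortical bone (3100 m/s,
1900 kg/m³).  Attenuation inside bone rises with porosity,
`α = α_min + (α_max − α_min) φ^0.5` with (10, 40) Np/m at 250 kHz, and
applies only above a 150 HU bone-mask threshold; voxels below it keep the
water value (0.03 Np/m).  The threshold exists because extrapolating the
trabecular-scattering law to near-zero HU would assign maximal absorption
to plain water, and any infinitesimal background noise in a degraded
pseudo-CT would then discontinuously change the model.  All constants are
configurable (`PropertyMap`).

## The degraded (UTE-like) model and warm-start calibration

The pseudo-CT of a phantom is produced by resampling the CT to a 2×
coarser grid (matching the CT/UTE resolution ratio), mapping through the
log-linear UTE/CT regression `log(UTE) = 7.3170e-4·HU + 5.0211`, adding
Gaussian model error in the log domain, inverting the regression, clamping
and nearest-neighbour upsampling.  The error is two-scale: 60 % of the
variance in a smooth 25 mm-correlation anatomical-bias field and 40 % in
voxel-scale scatter, mirroring the fact that the regression is weak
(its fit explains only a minority of intensity variance) while
segmentation/registration bias is smooth.

The error std is then *calibrated per phantom* so that the time-reversal
drive of the degraded model recovers 68 ± 1 % of the GS maximum pressure —
the documented focusing quality of a UTE-only model, and the warm start of
every closed-loop experiment.  Because the seeded error field is fixed and
merely scaled, recovery is a continuous deterministic function of the std
and a bracketing Brent solve lands inside the tolerance.

## Phase retrieval

One TM row `h ∈ C^N` is estimated from magnitudes `P = |E h|` of `m` probe
drives (rows of `E`; Bernoulli ±1 in the main protocol) by minimizing

    ½ ‖P − |E h|‖²  +  (λ/2) Re[hᴴ(h − D(h))]  +  (μ/2) ‖h − h_prior‖²,

an amplitude loss plus a regularization-by-denoising (RED) penalty built
from a pluggable denoiser `D` and, optionally, a quadratic anchor to a
prior row.  The solver is an accelerated proximal-gradient (FASTA-style)
method using the amplitude subgradient `z − P∘z/|z|` (defined as `z` where
`z = 0`) pulled back through `Eᴴ`; steps are backtracked so the objective
is monotonically non-increasing, with momentum restarts on failure;
iteration stops when the objective improvement falls below `tol`
(default 1e-12 relative to the initial value) or at the cap (1500).

Denoisers see the row reshaped to a two-channel (real, imaginary) 16 × 8
image in *aperture order* — elements sorted into elevation bands and by
azimuth within each band — so that the smooth aperture structure of skull
aberration is visible to the prior.  The shipped denoisers are identity,
3 × 3 median (default) and channel-coupled total variation; a trained
network can be passed as a callable.  Defaults λ = 1 with the median
denoiser were chosen because, without a trained convolutional prior, the
RED term must be strong enough for the regularized objective to
discriminate the true basin from the spurious amplitude-flow fixed points
that appear near the identifiability boundary m = 2N.

Two further stages matter in that regime:

* **Perturbation restarts** (batch estimation only): the solve is repeated
  from seeded perturbations of the initialization with growing radius and
  the lowest regularized objective wins (default 24 restarts in the
  experiment runners).  Spurious fixed points fit the data but pay a
  higher RED penalty, so the objective is a usable discriminator.
* **Polish**: the winning estimate is refined by a data-only (λ = 0, μ = 0)
  solve, removing the denoiser bias; noiseless problems at m ≥ 3N then
  recover the row to ~1e-7 relative error.

Global phase is unidentifiable and harmless; conjugation is
unidentifiable with real probes and *not* harmless for focusing.  Wherever
a recovery ratio is evaluated, both candidate time-reversal drives
(`conj(g)` and `g`) are sent through the measurement oracle and the better
one is kept — one extra sonication of a physically measurable quantity.

## The closed calibration loop

`AdaptiveCalibration` reproduces the sonicate–estimate–check protocol:
starting from the degraded-model row, each step adds one Bernoulli probe,
re-solves on all probes so far (warm-started from the current estimate,
anchored to the warm start with μ = 0.5, restarts and polish disabled —
inside the loop the problem is massively underdetermined, and without the
anchor repeated re-solves drift away from the prior model), measures the
recovery ratio, and stops at a target ratio or at the probe budget.  The
anchor plus the smoothness prior is what lets a handful of probes help:
corrections are effectively confined to the smooth, low-dimensional
component of the warm-start error, which a few random magnitude
constraints can pin down; the voxel-scale error component is only
recovered as `m` approaches `2N`.

Because every step's time-reversal drive is actually sonicated and its
target pressure read out, the protocol state ratchets: the best drive
measured so far is retained, and the trace reports both the retained
recovery (`r_ns_pct`, monotone by construction) and the raw per-step
estimate (`r_ns_step_pct`).  The stop rule reads the retained value.

The fixed-budget noise experiments (recovery vs noise std and the
four-encoding comparison) run the same anchored protocol at one probe
count, with the anchor weight set by the Bayesian balance between
measurement noise and prior quality, `μ = μ0 + N σ² / δ²`, where `σ` is
the normalized noise std and `δ² = 2(1 − R_warm/100)` is the squared
relative error of the warm start (0.64 at 68 %).  Noisier readouts thus
lean on the model prior instead of over-fitting magnitudes; without this
scaling, recovery *decreases* with the probe budget at σ ≳ 0.5, which is
qualitatively wrong for a posterior-style estimator.

## Evaluation metrics

* `MSE = ‖y − |Ĥ E|‖² / ‖y‖²` on the observed magnitudes.
* `Corr`: Pearson correlation of estimated vs reference row after optimal
  global-phase alignment, computed on concatenated real and imaginary
  parts; a `moduli_only` variant correlates magnitudes instead (the
  measurement-domain reading of the same statistic).
* `R%NS = 100 · p / GS` with both drives unit-norm.
* `Δr`: Euclidean distance in mm between the argmax voxel centres of two
  field maps on a shared grid; argmax ties break to the lowest linear
  index.
* Measurement noise is Gaussian on the unit-RMS-normalized magnitude
  scale, clamped at zero and rescaled; std 0 is the identity.

## Baseline encodings

Hadamard (truncated Sylvester rows), Zernike (unit-magnitude phase modes
`exp(iπ Z_j)` in Noll order, sampled at elements projected onto the
aperture disk) and uniform-random-phase probes feed the identical solver
with λ = 0, so comparisons isolate encoding plus denoiser value.  A
structural caveat discovered during testing: truncated Sylvester rows
repeat up to sign, so magnitude-only Hadamard probing carries at most ~N
distinct equations regardless of the probe count — it can never reach the
exact-recovery regime the diverse encodings reach at m = 4N, and it ranks
accordingly in the noise sweep.

## Problem sizes and reproducibility

The default study is three seeded phantoms, a 128-element hemispherical
array of 0.1 m radius centred on the thalamic target (0.11, 0.11, 0.08) m,
250 kHz, 2 mm grid (three points per wavelength in water).  The test suite
and the acceptance script run this full design with 10 repeats per phantom
for the stochastic quantities; these sizes keep a complete run in the
minutes range on a single CPU while leaving the Monte-Carlo error of the
reported means well below the margins being checked.  Every run is
reproducible from (config, seed): all randomness flows through seeds
derived from one master seed, and runner CSVs are byte-identical across
reruns.

## Known limitations

* The ray model omits refraction and multiple scattering, so absolute
  pressures and focal-spot shapes are stylized; only relative recovery and
  shift statistics are meaningful.
* The shipped denoisers are weaker priors than a trained network; the
  main visible consequence is at the identifiability boundary m = 2N,
  where mean row correlation saturates near ~0.9 rather than above it.
* The phantom is geometric, not anatomical; per-subject conclusions are
  out of scope.
* Measurement noise is Gaussian on magnitudes; structured ARFI artefacts
  are not modelled.
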