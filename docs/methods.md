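# Methods

## The measurement model

Magnetic induction tomography (MIT) drives eddy currents in a conductive
body with an AC magnetic field and reads the secondary field with receiver
coils. The phantom here is a torso-sized cuboid (50 × 28 × 24 cm) with a
background conductivity of 0.5 S/m — the mid-range of biological tissue at
the 1.5 MHz working frequency — containing up to two cuboid anomalies at
0.0 S/m (air, e.g. a pneumothorax) or 1.0 S/m (blood-like, e.g. internal
bleeding). The body travels through a 256 cm measuring range between a
fixed exciter and a fixed receiver array, one signal sample per
centimetre; 25 uninformative positions are trimmed from each end, leaving
206 positions × 6 receivers = 1,236 values per scan.

### Fields and coils

The exciter is an undulator: 11 vertical parallel wires with antiparallel
currents, producing a primary field that alternates along the travel
direction. Receivers are butterfly (figure-eight) coils, three wide and
three narrow, whose counter-wound lobes are stacked vertically and share a
horizontal edge. Because the primary field of long vertical wires is
nearly uniform in y, it couples to the two lobes almost equally and
cancels as common mode; the localized eddy-current field does not. The
package verifies this gradiometric property numerically: primary coupling
into every butterfly is at least 20 dB below a same-sized single-lobe coil
even when the array is displaced off the midline, and exactly zero when
centred.

The published hardware drawings for the coil dimensions are not
reproduced here; the package uses a documented surrogate geometry (wire
pitch 5.5 cm, 100 cm wires, receiver lobes 11 cm / 3.7 cm wide at 5 cm /
7 cm standoff) and every dimension is a configuration field, so measured
geometry can be substituted without code changes.

All vector potentials come from the closed-form Biot–Savart solution for
a straight segment, per unit current, with a 1 mm exclusion radius around
the wire axis (voxel centres never approach wires in the default
geometries; clamps are counted). Because scan offsets and the voxel
lattice are commensurate, each coil's potential is evaluated once on an
extended lattice and per-position samples are index shifts — this is the
single most important performance optimisation in the forward model.

### Eddy currents by nodal analysis

Under the quasistatic weak-coupling approximation the electric field is
E = −iω(A − ∇ψ) with A the exciter potential; charge conservation
∇·(σ(A − ∇ψ)) = 0 determines the scalar potential. Discretised on the
1 cm voxel grid this is a resistor network: one node per conducting voxel,
edge conductance = harmonic mean of the two adjacent conductivities ×
face area / centre distance (series resistors — an edge touching a
σ = 0 voxel carries nothing), and the exciter potential acting as a
per-edge EMF, evaluated at the edge midpoint (a two-point trapezoid rule
is config-selectable). Kirchhoff's current law gives a sparse symmetric
system; one node per connected component is pinned by adding a unit
diagonal entry, which selects ψ = 0 there without perturbing the
(compatible) solution. The solve uses SuperLU with symmetric-mode
minimum-degree ordering; all scan positions share one factorisation.

Because A and σ are real, the physical phasors are φ = −iωψ with J and S
purely in quadrature; the package stores real quadrature amplitudes
throughout (half the memory, no information loss under weak coupling).
The receiver signal is the Geselowitz reciprocity integral
S = ∫ J · A_R dV, evaluated by the midpoint rule over voxel centres. The
overall gain is an arbitrary constant: absolute receiver units are not
recoverable without the hardware chain, and only standardised signals
reach the network.

∇ψ uses central differences where both along-axis neighbours conduct and
one-sided differences at conducting-region boundaries; J ≡ 0 wherever
σ = 0.

## Synthetic corpus

For every geometric case, cuboids with integer edge lengths drawn
uniformly from 6–10 cm are placed uniformly on the fine lattice, fully
inside the body, non-overlap enforced by rejection sampling (cap 1,000
attempts); touching is allowed, and objects may touch the body surface
(a margin parameter, default 0, can forbid this). The signal is computed
for every conductivity combination of the case's objects (2 per 1-object
case, 4 per 2-object case) because 1.0 S/m objects yield much weaker
signals than 0.0 S/m ones and would otherwise be under-represented. The
default corpus is 3,000 one-object cases and 15,000 two-object cases →
66,000 samples.

White Gaussian noise at 60 dB SNR (RMS of the full 6 × P matrix) is
injected independently into the perturbed scan and the background scan
before subtraction, so the differential signal carries twice the
single-scan noise variance. Targets are the fine conductivities averaged
2×2×2 onto the 2 cm grid and Fortran-flattened (4,200 values). Simulating
on the fine grid while reconstructing on the coarse one, plus the noise,
avoids the inverse crime.

Splits are 65 % train / 25 % test / 10 % validation, assigned **per
geometric case** so no geometry appears in two splits. (The historical
absolute counts 49,500/16,500 are mutually inconsistent with those
fractions; a `paper_counts` mode reproduces the absolute counts, leaving
no validation samples, and the fractional split is the default.)
Standardisation is per measurement feature with population statistics
fitted on the training split only; constant features are floored at
1e−12 and flagged.

## Reconstruction network

The 1,236-vector is reshaped to 6 × 206 (receiver rows, position columns)
so convolution sees all receivers of one position together. The network:
5×5 conv stem (64 filters, ELU, batch norm) → 2×2 max pool → residual
blocks of three 3×5 convs (conv → ELU → BN, identity skip) alternating
with bottleneck blocks (first conv and the 1×1 skip conv strided 1×3 to
compress the position axis) → 2×2 average pool → two dense sigmoid layers
of 5,172 units → 4,200-unit hard-sigmoid output, hard sigmoid being
clip(0.2x + 0.5, 0, 1) so the conductivity bounds 0 and 1 are reached
exactly. The block plan ([res 64, bott 128, res 128, bott 256, res 256]
by default) is configurable; sources for the original design leave the
block count open, so the default doubles the width at each bottleneck in
the usual residual-network fashion.

Training is two-phase Huber regression with NADAM (lr 1e−3): phase 1
δ = 1.0, batch 64, 50 epochs (with errors bounded by 1, this is exactly
½·MSE pretraining); phase 2 δ = 0.05, batch 32, 50 epochs. The learning
rate is cut ×0.1 (floor 1e−5) when the validation correlation coefficient
fails to improve for 7 epochs; training stops early when the validation
loss fails to improve for 15 epochs ("does not decrease" is read as "does
not improve" — the literal reading would stop on any improvement); the
best-validation-loss weights are kept after each phase.

Weight initialisation N(0, 1) is the documented default of the original
recipe; it reliably saturates deep nets at reduced scale, so the `init`
config field also offers fan-averaged ("scaled") normal initialisation,
which the desk profile uses.

The layers themselves (conv via kernel-offset im2col, batch norm, ELU,
pooling, dense, Huber, NADAM) are implemented in numpy inside
`mitreco.nn`; gradient correctness is property-tested against numerical
differentiation.

## Metrics

MAE, MSE, per-sample Pearson CC and a global (windowless) SSIM with
K1 = 0.01, K2 = 0.03, L = 1 (C1 = 1e−4, C2 = 9e−4), computed on coarse
conductivity vectors in native units. The reported CC is the mean of
per-sample CCs, not the CC of pooled vectors; samples with a constant
prediction (CC undefined) are excluded and counted rather than scored 0.
SSIM uses population moments; the cross-check against scikit-image uses
a single full-size window with sample covariance disabled.

Robustness is probed with two synthetic cases pushed through the standard
forward + noise + coarsening path: (1) two overlapping 0.0 S/m cuboids
forming a single non-cuboid object of 13 cm maximum extent (longer than
any training object), and (2) a single cuboid at the never-trained
conductivity 0.8 S/m. The acceptance check requires their metrics to lie
within 3 SD of the test-set per-sample distribution.

## The desk profile (reduced study)

Full-scale training (66,000 samples, 5,172-unit dense head) is far beyond
a single-CPU session, so the packaged `desk` profile scales the study
down proportionally; it is the configuration exercised by the test suite
and the acceptance script:

- body 24 × 12 × 12 cm (1 cm fine grid: 3,456 voxels; 2 cm coarse grid:
  432 voxels); perturbation edge lengths 4–8 cm (roughly half-scale);
- scan of 96 positions (4× the body length, as in the full setup) with
  8 trimmed per side → 80 kept → input 6 × 80; undulator pitch 3 cm,
  wires 40 cm; receiver lobes 6 cm / 2 cm wide at 4 cm / 6 cm standoff;
- corpus of 500 one-object + 750 two-object cases → 4,000 samples at the
  same 60 dB noise, same conductivities, same coarsening and splits;
- block plan [res 16, bott 32, res 32, bott 64, res 64] with a 768-unit
  dense pair and scaled initialisation; the same two-phase Huber schedule
  with 30 + 30 epoch caps (chosen so corpus generation, training and
  evaluation together stay in the tens of minutes on one CPU).

The block plan and width were fixed after comparing configurations:
tripling the parameter count or repositioning the receiver array moved
the held-out correlation only marginally, while the second bottleneck
stage gave a clear gain — at this corpus size the experiment is
data-limited rather than capacity-limited, so the defaults favour the
smallest network on the plateau.

A consequence worth stating plainly: the full-scale study's headline
error statistics do not transfer to the reduced scale. Its training
corpus is over ten times larger than the desk corpus (generalisation
here is data-limited), and its mean squared error benefits from a body
in which objects occupy a far smaller volume fraction — at desk scale
the 2 cm partial-volume shell of a typical object alone contributes
several times the full-scale MSE figure, even for a reconstruction with
perfect localisation and conductivity class. The desk experiment should
therefore be read through its own measured numbers (reported by the
acceptance script and test suite: correlation, MSE, centroid-recovery
rate, robustness-case placement), not through the full-scale targets.

What the reduced study does and does not show: it preserves the physics
(same equations, same solver, same inverse-crime precautions, same noise
level), the data-generation protocol and the training recipe, so passing
it demonstrates that the pipeline can learn the MIT inverse map under the
stated study conditions. It does not demonstrate full-scale image
quality: the coarse image has 432 instead of 4,200 voxels, and the signal
diversity of the small receiver array is lower. The synthetic corpus also
idealises real data: perfectly cuboid anomalies on-lattice, exact
background knowledge in the differential signal, and stationary white
noise; real measurements add amplitude miscalibration and model mismatch
that the original study handles only qualitatively.

## Numerical choices and degenerate inputs

- Sparse solves: SuperLU, symmetric-mode MMD ordering; Kirchhoff residual
  checked (< 1e−10 relative) in verification paths.
- An all-σ=0 body yields an empty network and an exactly zero signal.
- Noise for an all-zero signal takes its RMS from the paired background
  scan (the zero-signal case cannot define its own SNR).
- Isolated conducting islands are grounded per connected component.
- Constant standardiser features are floored (1e−12) and flagged.
- Rejection-sampling placement failures abort with the generator state
  named after 1,000 attempts.
- The network runs in float32; metrics and physics in float64.

## Known limitations

- No complex-valued electrodynamics: displacement currents, charge
  density and receiver-receiver coupling are outside the quasistatic
  weak-coupling model.
- Coil geometry is a surrogate; absolute signal units are arbitrary.
- The full-scale profile's training cost is documented but not exercised
  by the test suite; only structural properties (shapes, counts, forward
  passes) are checked at full scale.
- SSIM is windowless by design; a sliding-window 3D SSIM would weight
  local structure differently.
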