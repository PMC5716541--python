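# Methods

`eitpost` simulates and reconstructs two-dimensional time-difference
electrical impedance tomography (EIT) on a 16-electrode tank, and
implements a post-processing scheme in which a radial-basis-function (RBF)
network, trained entirely on simulated phantoms, sharpens the image
produced by a linear one-step Gauss–Newton (GN) solver.  This note records
the models, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## Forward model

The quasi-static conduction equation `∇·σ∇u = 0` is discretized with
piecewise-linear triangular finite elements and piecewise-constant
conductivity.  Only the real part of the admittivity is modeled: at the
100 kHz carrier of the emulated hardware the capacitive (permittivity)
contribution is negligible for the saline/tissue regimes of interest, so
the solve is real-valued and frequency enters the package only through the
raw-signal noise model.

**Mesh.** The domain is a disc of unit diameter centered at the origin
(all distances in the package are fractions of this diameter).  Meshes are
structured: ring `i` of `R` carries `4i` nodes, giving exactly `4R²`
elements and `1 + 2R(R+1)` nodes; `R = 20` yields the reference
discretization of 1600 elements and 841 nodes.  The same ring topology is
reused for star-shaped domains described by Fourier descriptors
`r(θ) = r₀(1 + Σₙ aₙ cos nθ + bₙ sin nθ)`: only node positions move, so a
distorted forward mesh and the undistorted reconstruction mesh share
element indexing — which is what lets the generator carry a scene's truth
image between them without resampling.

A consequence of the exact 841-node count is worth recording: no
triangulation with 841 nodes can be invariant under rotation by one
electrode spacing (840 non-center nodes is not divisible by 16).  The mesh
is exactly invariant under a quarter turn, and the test suite asserts
one-electrode rotational symmetry of homogeneous-disc frames at the
discretization-error level (2%) while asserting quarter-turn symmetry at
solver precision.

**Electrodes.** Sixteen electrodes are short arcs of contiguous boundary
nodes (two nodes each on the reference mesh), equally spaced in boundary
arclength.  The electrode model is gap/shunt: injected current is split
across an arc's nodes in proportion to attached segment length, and the
electrode potential is the matching weighted average.  Contact impedance
is not modeled; time-difference imaging is insensitive to it, and the
choice avoids the extra unknowns of the complete electrode model.  The
drive amplitude is a nominal 1 mA — it cancels in difference images but is
fixed for reproducibility.

**Protocol.** Adjacent drive pairs `(k, k+1)`, adjacent measurement pairs,
256 channels per frame of which `N(N−3)/2 = 104` are independent; all 256
are kept, as is standard, to average noise.  The all-Neumann nullspace is
removed by a Lagrange multiplier enforcing zero-mean potential per drive.

**Jacobian.** Because adjacent measurement patterns coincide with drive
patterns, the adjoint fields are scaled forward fields and one
factorization yields the full sensitivity matrix:
`∂V(d,m)/∂σₑ = −(areaₑ/I) ∇u_d·∇u_m`.  This identity is exact for the
discrete system; the test suite verifies it entry-wise against central
finite differences at `δ = 10⁻⁶σ₀` on a 196-element mesh.

## Inverse solvers

**One-step GN.** The reconstruction matrix
`RM = (JᵀWJ + αP)⁻¹JᵀW` is factorized once per mesh/prior; a
reconstruction is then a single matrix product, so the method is
real-time.  Defaults: `W = I` (no channel covariance estimate is assumed),
`P = diag(JᵀJ)^0.5` (the NOSER prior, penalizing low-sensitivity interior
elements), and `α` set so that `α·mean(diag P) = 10⁻² · mean(diag JᵀWJ)`
— a dimensionless 10⁻² on the scale of the data term, a standard default
for this prior family.  All three are configurable.

**PDIPM comparator.** The total-variation comparator minimizes
`½‖Jx − δv‖² + λ Σ|(Lx)ₖ|` (L = element edge-difference operator) with a
primal-dual interior-point iteration run for exactly five iterations:
smoothed TV with `β = 10⁻⁴`, dual variables kept strictly inside (−1, 1),
and a backtracking primal step that guarantees the smoothed objective is
non-increasing.  The Newton system is solved with a Woodbury split (sparse
TV part factorized, rank-256 data term folded in), keeping the five
iterations at ~0.2 s on the 1600-element mesh.  `λ` is expressed relative
to `max|Jᵀδv|`; the default 0.3 sits at the L-curve corner (maximum
curvature of the log-log misfit/TV trade-off after the five iterations) on
the standard centered-inclusion fixture, the same selection principle used
for the GN `α`.  The implementation is a faithful-in-spirit five-iteration
TV solver, not a bit-exact replica of any particular toolbox.

## Synthetic worlds

A dataset sample is produced by the chain: random scene → distorted
forward mesh → forward solves (target and homogeneous reference) →
optional raw-signal noise → difference frame → GN reconstruction on the
*undistorted* mesh.  The mismatch between the distorted forward geometry
and the circular inverse geometry is deliberate: it is the modeling error
the post-processor must learn to tolerate.

**Scenes.** One or two targets (ellipse, triangle, rectangle — drawn
uniformly), each covering 5–40% of the domain area, aspect ratio uniform
in [1, 2], centers uniform over the disc, rejection-sampled until fully
inside and non-overlapping.  The shape is drawn *before* rejection
sampling so each shape keeps frequency `1/|shapes|` even though compact
shapes are easier to place at large sizes.  Conductivity regimes:
`phantom` — saline background 0.9 S/m with near-insulating targets
(log-uniform in [10⁻³, 0.09] S/m, emulating acrylic rods; exact zeros are
rejected because the forward solve needs σ > 0); `lungs` — tissue
resistivity uniform in 700–2500 Ω·cm.  The defaults used in the study are
the phantom regime.

**Boundary distortion.** Harmonics 2–8 of the Fourier boundary receive
i.i.d. Gaussian cosine/sine amplitudes with relative standard deviation
0.03.  Draws that fold a boundary sliver of the radially-mapped mesh
(negative element area; about one draw in several hundred) are rejected
and redrawn, exactly as out-of-domain targets are.

**Noise.** Per channel, the simulator synthesizes the 100 kHz carrier at
the channel's clean amplitude, 20 samples per period, adds white Gaussian
noise scaled to the channel SNR (`σ² = (v²/2)·10^(−SNR/10)`), applies a
tenth-order Butterworth bandpass (±10% around the carrier, zero-phase),
and keeps the highest filtered peak with the clean sign.  The narrowband
filter rings for tens of carrier periods, so the window is 64 periods with
24 discarded at each end; the noise-free round-trip then returns the input
within 0.3% (filter ripple), and the SNR estimator
`10 log₁₀(mean s²/mean (m−s)²)` recovers an injected 50 dB within 1 dB
when averaged over 500 frames.  The per-channel SNR profile is a raised
cosine in electrode-ring distance between drive and measurement pairs,
anchored at 55 dB next to the drive and 8 dB diametrically opposite —
a smooth synthesis of the anchor levels hardware of this class exhibits.
The same fixed profile provides the "constant noise" of the validation
study.  Physiological (non-Gaussian) noise is out of scope; an optional
drift+WGN mixture is deliberately not fitted to any measurement.

## RBF network

A single hidden layer of Gaussian units
`φₖ(x) = exp(−(‖x−tₖ‖/s)²)` feeds a linear output layer.  Distances are
per-feature RMS (Euclidean divided by √p) in standardized input space, so
the dimensionless spread default `s = 1` is meaningful at any input width
— with plain Euclidean distance in 841 dimensions every response would
underflow.  The two roles share one architecture (400 hidden units for the
reference configuration): *direct* (input = 256-channel difference frame)
and *postprocess* (input = GN image averaged onto the 841 nodes;
element→node averaging is area-weighted, so constants map to constants and
each node value is a convex combination of its incident elements).

Normalization exploits the linearity of the difference-imaging chain: each
input is divided by its max-absolute amplitude and the paired training
output by the same factor, separating geometry from contrast; predictions
are rescaled by the input amplitude.  This choice was selected by held-out
validation error during development and frozen.  In direct mode the
restored amplitude is only approximate (the voltage-to-image amplitude
ratio varies between scenes); the study's figures of merit are
amplitude-invariant by construction, and the shape/position content of the
prediction is what the method is evaluated on.  Centers are chosen by
seeded k-means on the normalized inputs (the training toolbox behavior the
reference configuration came from is undocumented, so weight-level
equivalence is not attempted — only behavioral equivalence on the error
study).  The output layer is ridge-regularized least squares
(ridge 10⁻⁸); training is deterministic given the seed.

## Figures of merit

Images are resampled onto a 32×32 grid spanning the domain's bounding
square (element images point-sampled at pixel centers; node images
linearly interpolated), and the reconstructed object is the
quarter-amplitude set: pixels at ≥ 25% of the maximum absolute value.  The
threshold is sign-agnostic so conductive and resistive targets behave
alike, and all three errors are invariant under positive scaling of the
image.  Per target:

* **PE** = 100·‖centroid(recon) − centroid(true)‖ / diameter, with
  centroids pixel-area weighted over the boolean masks;
* **RES** = √(mask pixels / inside pixels), and |ΔRES| =
  100·|RES_recon − RES_true|;
* **SD** = 100·|recon \ true| / |recon| — the fraction of the
  reconstructed object outside the true target region.  (The alternative
  equal-area-circle reference common in the GREIT literature is not the
  default; the true-region reading matches the error's description as
  "does not fit in the expected position".)

True-target masks come from rasterizing the known scene polygon onto the
same grid — not from thresholding the truth image — which removes
threshold ambiguity for sharp targets.  Two-target images are split by the
perpendicular bisector of the true centers before scoring.  An image whose
thresholded mask is empty on one side yields a "no-target" sentinel that
aggregation excludes (and counts) rather than averaging a NaN.

## The study and its scale

The full study trains both network roles on 2000 simulated scenes
(single-target, distortion on, channel noise on) and evaluates one-step
GN, PDIPM, the direct network, and GN+network on 2000 fresh single-target
scenes with the same distortion and the fixed noise profile, reporting
mean ± sample standard deviation of PE, |ΔRES| and SD per method.  A
single master seed fans out to named substreams (training scenes, network
seeds, validation scenes), so every number is reproducible bit-for-bit
from (config, seed).  `scripts/acceptance.py` runs exactly this at
2000/2000 in roughly ten minutes on one CPU.  The test suite runs the same
pipeline with 500 validation scenes (training kept at 2000 samples, since
network quality is what training size buys) to keep the default `pytest`
run to a few minutes; at 500 scenes the standard error of a mean PE is a
few tenths of a percent, small against the differences between methods.

What passing shows — and what it does not: the experiments demonstrate the
post-processor's robustness to *modeled* disturbances (smooth
Fourier-descriptor boundary distortion, channel-dependent white Gaussian
noise on the carrier).  Real tanks and thoraxes add contact-impedance
variation, electrode placement error, non-Gaussian physiological noise and
genuinely 3D current paths, none of which the generator emulates; results
here bound what simulation can claim, not clinical performance.

## Known limitations

* Gap/shunt electrodes only; no complete electrode model.
* The PDIPM comparator is under-converged by design (five iterations) and
  its TV weight is a package default, not a reproduced setting.
* The element↔node maps are smoothing/averaging maps; a constant image
  round-trips exactly but a general image does not.
* Two-target scenes are generated and scored, but the headline study uses
  single-target validation scenes.
* Absolute (non-difference) EIT, 3D meshes, and complex admittivity are
  out of scope.
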