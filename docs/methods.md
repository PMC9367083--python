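# Methods

## Problem setting

Real-time cardiac cine MRI acquires dynamic images fast enough to resolve
heart motion without ECG gating or breath-holds. With a tiny-golden-angle
radial readout at 12 spokes per frame and a 144×144 matrix (2×2 mm², 37.7 ms
per frame), each frame is undersampled by a Cartesian-equivalent factor of
144/12 = 12, and direct gridding reconstructions carry strong streaking
artifacts. This package implements, at desk scale, the full computational
chain of a deep-learning de-aliasing approach to that problem — synthetic
training-pair generation, NUFFT gridding reconstruction, adaptive coil
combination, a 3D U-Net artifact-suppression network — together with a GRASP
compressed-sensing baseline, on NumPy/SciPy only.

## Radial trajectory and NUFFT

Spoke *j* has angle *j·ψ* mod 2π with ψ the tiny golden angle
180°/(φ + N − 1); order N = 5 gives 32.0399…°, commonly printed rounded as
32.049°. Angles accumulate continuously across frames; frame membership is
purely an index grouping. Each spoke is a full diameter of `n_readout`
(default 2×matrix) samples spanning k ∈ [−π, π) radians/pixel, DC at index
`n_readout/2`.

The NUFFT is Kaiser–Bessel gridding on a 2× oversampled FFT grid with the
Beatty shape parameter. Forward and adjoint share one sparse interpolation
matrix, and every stage (deapodization, centered zero-padding, unitary FFT,
interpolation) is adjointed individually, so the adjoint identity
⟨Fx, y⟩ = ⟨x, Fᴴy⟩ holds to machine precision by construction.

*Neighbor count.* The kernel width is configurable (2–6 points per
dimension). Two-point interpolation at 2× oversampling — the configuration
used by inline scanner implementations for speed — has an intrinsic
interpolation ripple of several percent (measured ≈13% relative ℓ2 error
against a direct non-uniform DFT, ≈6% even with least-squares-optimal
two-tap weights), which would dominate every downstream error measurement.
The package therefore defaults to 4 neighbors (≈8·10⁻⁴ relative error) and
leaves 2 available as the fast configuration.

*Density compensation.* `ramp_dcf` provides the conventional Ram-Lak ramp,
|k| with a half-bin DC value, mean-normalized — the preconditioner used for
relative weighting. For the *regridding reconstruction* (`apply_dcf=True`)
the adjoint instead uses the absolute polar area element
w(ρ) = ρ·Δθ·Δρ/(2π)², i.e. `|bin| · π / (spokes_per_frame · n_readout²)`,
with one refinement: the M spokes of a frame share a single coincident DC
sample whose cell integrates |k| to a **quarter**-bin value, not a half-bin.
Using the half-bin value there double-counts DC energy and leaves a flat
image pedestal (dense-spoke reconstruction NRMSE ≈0.12 instead of ≈0.03).
With the quadrature-exact weights the gridding reconstruction is unit-gain
and converges to the true image as the spoke count approaches the Nyquist
number ⌈π/2·n⌉. The DCF is never applied inside the GRASP data-fidelity
gradient, which uses the pure adjoint.

## Phantom

The synthetic training corpus is a deterministic dynamic phantom: static
background ellipses (body, lungs, liver), a myocardial annulus whose inner
radius varies sinusoidally between its diastolic and systolic values with the
heart period, a bright blood pool, and an optional vertical respiratory
translation with a 4 s period. All shapes are rendered analytically with a
one-pixel linear anti-aliasing ramp so that staircase artifacts do not
contaminate NUFFT error measurements. The truth image carries a fixed smooth
second-order polynomial phase map — the de-aliasing method is explicitly
complex-valued, so tests must exercise nontrivial phase. Multi-coil data are
the truth times smooth unit-norm coil sensitivities (Gaussian lobes at
equispaced angles around the FOV edge, smooth per-coil phase, phase-referenced
to the first coil) plus circularly-symmetric complex Gaussian noise.

Defaults (144 px, 2 mm, 37.7 ms, ~905 ms heart period, 8 coils, noise SD 1%
of peak) emulate the segmented-cine corpus the phantom substitutes for;
geometry defaults give an epicardial diameter of ≈68 mm and an end-diastolic
cavity of ≈48 mm. The phantom intentionally does not span patient pathology
diversity, arrhythmia, or through-plane motion: passing tests demonstrate
method correctness on piecewise-smooth periodic anatomy, not clinical
generalization.

## Coil maps and combination

Sensitivities are estimated from the time-averaged multi-coil image by the
adaptive (eigenvector) method configured with **no spatial smoothing**
(1×1 pixelwise sample covariance) and a **single power iteration** started
from the coil vector itself; for the rank-one pixelwise covariance this
collapses to the normalized coil vector. Maps are unit-norm per pixel and
phase-referenced so the first-coil projection is real-nonnegative; the
per-pixel global phase of the truth is therefore absorbed into the maps, and
the estimate→combine round trip recovers the truth *magnitude* exactly (and
the complex truth up to that documented reference). Combination is
x̂ = Σ conj(S_c)y_c / Σ|S_c|², with the pure matched filter available via a
flag.

## Training pairs

Target branch: spatial k-space crop/zero-pad (sinc) resampling to 2 mm and
linear temporal interpolation to 37.7 ms, then coil combination. Input
branch: identical except a backward/forward NUFFT on that frame's spokes
(12 per frame at full scale) with DCF-weighted gridding back — the streak
generator. Both branches share the maps estimated from the clean
time-averaged coils, so input and target differ only by the spoke-projection
round trip; in the Nyquist-dense limit the input converges to the target.
Series are center-cropped to 144×144 and 20 frames (uniform random start
when longer; cyclic wrap when shorter — cardiac cine is periodic, making
wrap-around the natural pad). Both members are divided by the 95th
percentile magnitude of the *input's* central 48×48 region pooled across
frames (linear-interpolation percentile): at inference only the aliased
image exists, so train and test normalization must match.

## U-Net

Input/output are single-channel real tensors 2n×n×n_t: real over imaginary
parts concatenated along the first spatial axis. The C_H unit is
conv(3³, stride 1, pad 1, bias) → batch-norm → dropout(0.15) → ReLU, in that
order; encoder E_H–E_2H–E_4H (two C_H units per stage, 2³/stride-2 maxpool
after the first two stages), decoder D_2H–D_H (2³/stride-2 transposed
convolution, channel-concatenated with the matching pre-maxpool encoder
output, then two C_H units), and a final 1³ single-channel convolution with
bias and no activation. Extents must be divisible by 4; inference pads
symmetrically with zeros and crops the output otherwise. The base width H is
configurable (conventional default 64; tests and the scaled demonstration
use 4–8, where training fits in CPU minutes).

All layers, backpropagation and Adam are implemented directly on float32
NumPy arrays; 3×3×3 convolutions run as a single BLAS matrix product over
im2col columns (27·C contiguous slice copies), and the 2³/stride-2
transposed convolution is a non-overlapping tensor contraction. Batch-norm
keeps running statistics (momentum 0.1) for inference; dropout is inverted
and inactive at inference, so inference is deterministic.

Training: MSE on the normalized plane representation, Adam, initial learning
rate 0.001 decayed 5% every 100 iterations (lr(i) = 0.001·0.95^⌊i/100⌋).
Each iteration draws `batch_size` *distinct* sources, one temporal window
per source. The full-scale schedule (batch 16, 2900 iterations) is exposed
as defaults; it is not executed in tests.

## GRASP baseline

f(x) = Σ_f ‖F_f S x_f − y_f‖² + λ Σ √(|D_t x|² + ε), with D_t the circular
temporal first difference (cine periodicity; one-sided available), λ = 0.02 ×
the peak magnitude of the DCF-gridded initial image (the relative convention
of the original framework — an absolute 0.02 would be meaningless without a
scale), and ε = 10⁻¹⁵ of the squared peak. Minimization is Polak–Ribière
nonlinear conjugate gradient with a nonnegativity restart, initialized at
the gridded coil-combined image, with an Armijo backtracking line search
(sufficient decrease 0.01, backtrack factor 0.6, warm-started step, at most
150 objective evaluations per iteration, 30 outer iterations). A failed
line search accepts a zero step and restarts on steepest descent, so the
objective trace is non-increasing by construction. The gradient follows
Wirtinger calculus: ∇ = 2AᴴA(x) − 2Aᴴy + λ Dᵀ(D x/√(|Dx|²+ε)), verified
against central finite differences.

## Scaled-down demonstration sizes

CPU-scale problem sizes are package choices made once: operator accuracy at
16×16 with 4 spokes against an O(N²M) direct NDFT; gridding limits and GRASP
at 64 px, 4–8 frames, 4 coils; the U-Net demonstration trains H = 8 on 16
phantom slices of 64×64×4 at **5 spokes per frame** — preserving the
method's 12× Cartesian-equivalent acceleration (64/5 ≈ 12.8) rather than the
absolute spoke count, since the streak severity the network must remove is
set by the acceleration factor — for 300 iterations at batch 4, then
evaluates on a held-out phantom. All runs are seeded; identical seeds give
identical results on one machine.

## Known limitations

* The phantom's pathology diversity is nil; U-Net results demonstrate the
  training/inference machinery and artifact-removal capacity on this family,
  not clinical image quality.
* The 2-neighbor interpolation configuration trades several percent forward
  accuracy for speed and is not used where accuracy is asserted.
* GRASP line-search constants are documented defaults of this
  implementation, not values asserted by any external protocol.
* Batch-norm inference statistics come from 300-iteration running averages
  in the scaled demonstration; very short trainings can leave them slightly
  stale relative to batch statistics.
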