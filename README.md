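# radcine

Reconstruction toolkit for highly accelerated **real-time radial cine MRI**:
tiny-golden-angle trajectories, NUFFT gridding, adaptive coil combination, a
GRASP compressed-sensing baseline, and a 3D U-Net that removes radial
undersampling (streaking) artifacts from complex cine images — plus a
deterministic dynamic cardiac phantom that synthesizes the training data.

Real-time cine acquires each cardiac frame in tens of milliseconds without
ECG gating or breath-holds by sampling only a few radial k-space spokes per
frame. At 12 spokes for a 144×144 matrix (2×2 mm², 37.7 ms/frame) the
Cartesian-equivalent undersampling factor is R = 144/12 = 12, and direct
gridding reconstructions are dominated by streaks. The toolkit implements
the chain that turns such k-space into artifact-suppressed images, for
researchers studying dynamic MRI reconstruction who want a self-contained,
CPU-only, fully tested reference implementation.

## The core methods

**Gridding (NUFFT).** Spoke *j* sits at angle *jψ* mod 2π with
ψ = 180°/(φ+4) ≈ 32.04° (tiny golden angle, order 5). The forward model is
the non-uniform DFT `s(k) = Σ_x f(x) e^{−i k·(x−c)}`, implemented as
Kaiser–Bessel interpolation on a 2× oversampled FFT grid; the adjoint is
exact by construction, and the density-compensated adjoint (Ram-Lak ramp,
polar area-element scaling) is the direct reconstruction.

**Coil combination.** Sensitivities come from the time-averaged coil images
by the pixelwise adaptive (eigenvector) method — no smoothing, one power
iteration — and images are combined as x̂ = Σ conj(S_c)y_c / Σ|S_c|².

**GRASP baseline.** Temporal-total-variation compressed sensing,
`min_x Σ_f ‖F_f S x_f − y_f‖² + λ Σ √(|D_t x|² + ε)` with λ = 0.02 relative
to the initial gridded image's peak, solved by 30 nonlinear conjugate
gradient iterations with a 150-evaluation backtracking line search.

**U-Net de-aliasing.** A complex cine is split into real and imaginary
parts concatenated along one spatial axis (2n×n×n_t, single channel) and
passed through a 3D U-Net — encoder E_H–E_2H–E_4H, decoder D_2H–D_H, final
1×1×1 convolution; each unit is conv(3³)→batch-norm→dropout(0.15)→ReLU —
trained with MSE and Adam (lr 0.001, −5% every 100 iterations) on synthetic
pairs: the target is a coil-combined phantom cine, the input the same cine
after a backward/forward NUFFT on the undersampled spokes. The network
(and its backpropagation) is implemented directly in NumPy, so everything
runs on a plain CPU.

## Worked example

Simulate a 4-coil beating-heart phantom, acquire 12 spokes/frame, and
reconstruct with gridding and GRASP:

```python
import numpy as np
from radcine.phantom import PhantomConfig, make_cardiac_phantom
from radcine.radial import build_trajectory, nufft_forward, acceleration_factor
from radcine.pipeline import ReconRequest, reconstruct, write_kspace, nrmse

phantom = make_cardiac_phantom(
    PhantomConfig(matrix_size=64, n_frames=4, n_coils=4, noise_sd=0.0, seed=3)
)
traj = build_trajectory(32.049, 12, 4, 128)
kspace = nufft_forward(phantom.multicoil, traj)
write_kspace("kspace.h5", kspace, traj, 64)

print(f"acceleration R = {acceleration_factor(64, 12):.1f}")
for method in ("nufft", "grasp"):
    cine, meta = reconstruct(ReconRequest(kspace="kspace.h5", method=method))
    print(f"{method:6s} NRMSE vs truth = {nrmse(phantom.truth, cine):.3f}")
```

Output:

```
acceleration R = 5.3
nufft  NRMSE vs truth = 0.226
grasp  NRMSE vs truth = 0.105
```

The gridding reconstruction of the 12-spoke data carries a 22.6% normalized
RMS error (streaks); GRASP's temporal regularization halves it. Training
the U-Net on 16 phantom slices and de-aliasing a held-out phantom at 12×
acceleration is demonstrated end-to-end by `scripts/acceptance.py` and in
`tests/test_acceptance.py` (in the scaled demonstration the network lowers
held-out NRMSE from ≈0.37 to ≈0.17).

The same flows are available from the shell:

```bash
radcine simulate-phantom --n 144 --frames 40 --coils 8 --seed 1 --out ph.h5
radcine make-training-data --sources 16 --out data/
radcine train --data data/ --iters 300 --batch 4 --h 8 --seed 1 --out ckpt.npz
radcine reconstruct --kspace kspace.h5 --method grasp --out recon.h5
radcine evaluate --ref truth.h5 --test recon.h5
```

## Layout

```
src/radcine/
  phantom.py    dynamic multi-coil cardiac phantom + HDF5 container
  radial.py     trajectories, ramp DCF, Kaiser–Bessel NUFFT (exact adjoint)
  coils.py      adaptive sensitivity estimation, SENSE combination
  synthsim.py   training-pair synthesis (resample, alias, crop, normalize)
  dealias.py    3D U-Net, Adam training loop, complex inference wrapper
  grasp.py      temporal-TV nonlinear-CG reconstruction
  pipeline.py   end-to-end chain, k-space/cine HDF5 formats, metrics,
                Bland–Altman agreement
  cli.py        command-line interface
```

See `docs/methods.md` for the model assumptions, parameter conventions, and
known limitations.
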