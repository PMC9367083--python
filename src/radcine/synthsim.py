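"""Synthesis of aliased/reference training pairs for the de-aliasing network.

Reproduces the real-time training-pair pipeline: ground-truth multi-coil
cine series are spatially and temporally resampled (to 2 x 2 mm^2 and
37.7 ms by default), the aliased branch applies a backward/forward NUFFT
round trip on a 12-spoke-per-frame tiny-golden-angle trajectory before coil
combination, both branches are coil-combined with the same sensitivity
maps, center-cropped to 144 x 144 x 20, and jointly normalized by the 95th
percentile magnitude of the aliased member's central 48 x 48 region.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import h5py
import numpy as np

from radcine.coils import coil_combine, estimate_sensitivities_adaptive
from radcine.phantom import PhantomConfig, make_cardiac_phantom
from radcine.radial import build_trajectory, nufft_adjoint, nufft_forward

TINY_GOLDEN_ANGLE_PRINTED = 32.049  # degrees, the scanner-protocol value
NORM_REGION = 48  # central region edge for the percentile normalization
NORM_PERCENTILE = 95.0


@dataclass
class TrainingPair:
    """An aliased input cine and its artifact-free target, jointly normalized."""

    input: np.ndarray  # complex (n, n, n_t), streaked
    target: np.ndarray  # complex (n, n, n_t), reference
    norm_constant: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input.shape != self.target.shape:
            raise ValueError(
                f"input {self.input.shape} and target {self.target.shape} differ"
            )
        if not self.norm_constant > 0:
            raise ValueError("norm_constant must be positive")


def resample_cine(
    cine: np.ndarray,
    src_spacing: float,
    src_dt: float,
    dst_spacing: float = 2.0,
    dst_dt: float = 37.7,
) -> np.ndarray:
    """Resample a complex cine to a new pixel spacing and frame interval.

    Spatial resampling is sinc interpolation — centered zero-pad or crop in
    k-space to the grid implied by ``dst_spacing``.  Temporal resampling is
    linear interpolation of real and imaginary parts onto a uniform
    ``dst_dt`` grid spanning the original time range.

    ``cine``: ``(..., n, n, n_t)`` complex.
    """
    if min(src_spacing, src_dt, dst_spacing, dst_dt) <= 0:
        raise ValueError("spacings and frame intervals must be positive")
    cine = np.asarray(cine, dtype=np.complex128)
    n_src = cine.shape[-3]
    if cine.shape[-2] != n_src:
        raise ValueError(f"cine must be spatially square, got {cine.shape}")
    n_dst = int(round(n_src * src_spacing / dst_spacing))
    n_dst -= n_dst % 2  # keep the grid even for the shared center convention
    if n_dst < 2:
        raise ValueError("destination spatial grid would be empty")
    out = cine
    if n_dst != n_src:
        k = np.fft.fftshift(
            np.fft.fft2(np.fft.ifftshift(out, axes=(-3, -2)), axes=(-3, -2)),
            axes=(-3, -2),
        )
        if n_dst < n_src:  # truncate high frequencies
            lo = n_src // 2 - n_dst // 2
            k = k[..., lo : lo + n_dst, lo : lo + n_dst, :]
        else:  # zero-pad
            pad = np.zeros(k.shape[:-3] + (n_dst, n_dst, k.shape[-1]), dtype=k.dtype)
            lo = n_dst // 2 - n_src // 2
            pad[..., lo : lo + n_src, lo : lo + n_src, :] = k
            k = pad
        out = np.fft.fftshift(
            np.fft.ifft2(np.fft.ifftshift(k, axes=(-3, -2)), axes=(-3, -2)),
            axes=(-3, -2),
        )
        out = out * (n_dst**2 / n_src**2)  # value-preserving scaling

    n_t = out.shape[-1]
    if n_t > 1 and dst_dt != src_dt:
        t_src = np.arange(n_t) * src_dt
        t_dst = np.arange(0.0, t_src[-1] + 1e-9, dst_dt)
        if len(t_dst) < 1:
            raise ValueError("destination temporal grid would be empty")
        idx = np.clip(np.searchsorted(t_src, t_dst, side="right") - 1, 0, n_t - 2)
        w = (t_dst - t_src[idx]) / src_dt
        out = out[..., idx] * (1.0 - w) + out[..., idx + 1] * w
    return out


def simulate_aliasing(
    multicoil_cine: np.ndarray,
    spokes_per_frame: int = 12,
    psi: float = TINY_GOLDEN_ANGLE_PRINTED,
    n_readout: int | None = None,
    numpoints: int = 4,
) -> np.ndarray:
    """Backward/forward NUFFT round trip that imprints radial streaking.

    Per coil and per frame, the image is projected onto that frame's spokes
    (forward NUFFT) and gridded back (DCF-weighted adjoint).  Spoke angles
    advance continuously across frames.  Output shape equals input shape.
    """
    cine = np.asarray(multicoil_cine, dtype=np.complex128)
    single_coil = cine.ndim == 3
    if single_coil:
        cine = cine[None]
    n = cine.shape[-3]
    n_t = cine.shape[-1]
    if n_readout is None:
        n_readout = 2 * n
    traj = build_trajectory(psi, spokes_per_frame, n_t, n_readout)
    samples = nufft_forward(cine, traj, numpoints=numpoints)
    out = nufft_adjoint(samples, traj, n, apply_dcf=True, numpoints=numpoints)
    if single_coil:
        out = out[0]
    return out


def crop_or_pad(
    cine: np.ndarray,
    target_xy: int = 144,
    target_t: int = 20,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, int]:
    """Spatial center crop (zero-padding first if needed) and temporal windowing.

    If the series has at least ``target_t`` frames, a window of ``target_t``
    consecutive frames starts at an offset drawn uniformly from
    ``[0, n_t - target_t]``; shorter series are padded cyclically
    (wrap-around — cardiac cine is periodic).

    Returns the cropped cine and the temporal start offset used.
    """
    cine = np.asarray(cine)
    n = cine.shape[-3]
    if cine.shape[-2] != n:
        raise ValueError(f"cine must be spatially square, got {cine.shape}")
    if n < target_xy:  # zero-pad, then the center crop below is the identity
        pad = np.zeros(
            cine.shape[:-3] + (target_xy, target_xy, cine.shape[-1]), dtype=cine.dtype
        )
        lo = target_xy // 2 - n // 2
        pad[..., lo : lo + n, lo : lo + n, :] = cine
        cine = pad
        n = target_xy
    lo = n // 2 - target_xy // 2
    cine = cine[..., lo : lo + target_xy, lo : lo + target_xy, :]

    n_t = cine.shape[-1]
    if n_t >= target_t:
        if rng is None:
            rng = np.random.default_rng()
        start = int(rng.integers(0, n_t - target_t + 1))
        cine = cine[..., start : start + target_t]
    else:
        start = 0
        reps = -(-target_t // n_t)
        cine = np.concatenate([cine] * reps, axis=-1)[..., :target_t]
    return cine, start


def norm_constant_of(cine: np.ndarray, region: int = NORM_REGION) -> float:
    """95th-percentile magnitude over the central region, pooled across frames.

    The percentile uses linear interpolation between order statistics.  For
    grids smaller than ``region`` the whole image is used.
    """
    n = cine.shape[-3]
    r = min(region, n)
    lo = n // 2 - r // 2
    central = np.abs(cine[..., lo : lo + r, lo : lo + r, :])
    return float(np.percentile(central.ravel(), NORM_PERCENTILE))


def normalize_pair(
    input_cine: np.ndarray, target_cine: np.ndarray, provenance: dict | None = None
) -> TrainingPair:
    """Divide input and target by the input's central-region percentile.

    The constant is computed from the aliased input member (at inference
    only the aliased image exists, so train and test normalization must
    match) and applied to both members; it is recorded for inverse scaling.
    """
    if input_cine.shape != target_cine.shape:
        raise ValueError("input and target shapes differ")
    c = norm_constant_of(input_cine)
    if not c > 0:
        raise ValueError("degenerate input: normalization constant is zero")
    return TrainingPair(
        input=np.asarray(input_cine) / c,
        target=np.asarray(target_cine) / c,
        norm_constant=c,
        provenance=provenance or {},
    )


def make_training_pair(
    config: PhantomConfig,
    spokes_per_frame: int = 12,
    psi: float = TINY_GOLDEN_ANGLE_PRINTED,
    target_xy: int = 144,
    target_t: int = 20,
    rng: np.random.Generator | None = None,
    numpoints: int = 4,
) -> TrainingPair:
    """Full pair synthesis from one phantom configuration.

    target = coil_combine(resampled multi-coil truth);
    input = coil_combine(simulate_aliasing(same)); both cropped and jointly
    normalized.  Sensitivities are estimated from the time-averaged clean
    multi-coil images, so both branches share the same maps and differ only
    by the spoke projection round trip.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    data = make_cardiac_phantom(config)
    clean = resample_cine(
        data.multicoil, config.pixel_spacing, config.frame_duration
    )
    sens = estimate_sensitivities_adaptive(clean.mean(axis=-1))
    aliased = simulate_aliasing(clean, spokes_per_frame, psi, numpoints=numpoints)
    target = coil_combine(clean, sens)
    inp = coil_combine(aliased, sens)
    both = np.stack([inp, target])
    both, start = crop_or_pad(both, target_xy, target_t, rng)
    return normalize_pair(
        both[0],
        both[1],
        provenance={
            "seed": config.seed,
            "start_frame": start,
            "matrix_size": config.matrix_size,
            "spokes_per_frame": spokes_per_frame,
            "psi_degrees": psi,
        },
    )


def build_training_set(
    phantom_configs: list[PhantomConfig],
    out_dir: str,
    spokes_per_frame: int = 12,
    psi: float = TINY_GOLDEN_ANGLE_PRINTED,
    target_xy: int = 144,
    target_t: int = 20,
    seed: int = 0,
    numpoints: int = 4,
) -> str:
    """Generate and persist a dataset of training pairs plus a JSON manifest.

    One HDF5 file per pair (``/input``, ``/target`` complex64 and provenance
    attributes).  During training, a batch draws each element from a
    distinct source file, one randomly selected temporal window per source.
    Returns the manifest path.
    """
    if not phantom_configs:
        raise ValueError("need at least one phantom configuration")
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = {"seed": seed, "pairs": []}
    for i, cfg in enumerate(phantom_configs):
        pair = make_training_pair(
            cfg, spokes_per_frame, psi, target_xy, target_t, rng, numpoints
        )
        fname = f"pair_{i:04d}.h5"
        path = os.path.join(out_dir, fname)
        try:
            with h5py.File(path, "w") as fh:
                fh.create_dataset("input", data=pair.input.astype(np.complex64))
                fh.create_dataset("target", data=pair.target.astype(np.complex64))
                for k, v in pair.provenance.items():
                    fh.attrs[k] = v
                fh.attrs["norm_constant"] = pair.norm_constant
        except OSError as exc:
            raise OSError(f"failed writing training pair to {path}: {exc}") from exc
        manifest["pairs"].append(
            {
                "file": fname,
                "source": i,
                "norm_constant": pair.norm_constant,
                **{k: v for k, v in pair.provenance.items()},
            }
        )
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest_path


def load_training_set(out_dir: str) -> list[TrainingPair]:
    """Load all pairs referenced by the manifest in ``out_dir``."""
    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    pairs = []
    for entry in manifest["pairs"]:
        path = os.path.join(out_dir, entry["file"])
        with h5py.File(path, "r") as fh:
            pairs.append(
                TrainingPair(
                    input=fh["input"][...].astype(np.complex128),
                    target=fh["target"][...].astype(np.complex128),
                    norm_constant=float(fh.attrs["norm_constant"]),
                    provenance={
                        k: v for k, v in fh.attrs.items() if k != "norm_constant"
                    },
                )
            )
    return pairs
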