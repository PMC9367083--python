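"""End-to-end reconstruction chain, file formats, metrics and agreement stats.

The desk-scale analogue of an inline scanner reconstruction: multi-coil
radial k-space -> DCF-gridded NUFFT per coil and frame -> coil sensitivities
from the time-averaged coil images -> SENSE combination -> optional
de-aliasing (GRASP or the trained U-Net).  Frames and coils are processed
as independent batch items; per-stage wall times are recorded as metadata
(informational only).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import h5py
import numpy as np

from radcine.coils import coil_combine, estimate_sensitivities_adaptive
from radcine.grasp import GraspConfig, grasp_reconstruct
from radcine.radial import RadialTrajectory, build_trajectory, nufft_adjoint

METHODS = ("nufft", "grasp", "unet")


@dataclass
class ReconRequest:
    """Everything needed to turn k-space into a cine.

    ``kspace`` may be a path to the native HDF5 container or an in-memory
    array ``(n_coils, n_frames, spokes_per_frame, n_readout)`` with a
    matching trajectory.
    """

    kspace: str | np.ndarray
    method: str = "nufft"
    traj: RadialTrajectory | None = None
    matrix_size: int | None = None
    grasp_config: GraspConfig | None = None
    checkpoint: str | None = None
    network: object | None = None  # a UNet3D, if already in memory
    numpoints: int = 4
    output: str | None = None
    log_path: str | None = None


@dataclass
class AgreementResult:
    """Bland-Altman agreement between two measurement methods."""

    mean_difference: float
    loa_low: float
    loa_high: float
    n_pairs: int


def nrmse(ref: np.ndarray, test: np.ndarray, on_magnitude: bool = True) -> float:
    """Normalized root-mean-square error ``||test - ref|| / ||ref||``.

    In magnitude mode (default) the difference of magnitudes is used;
    otherwise the complex difference.
    """
    ref = np.asarray(ref)
    test = np.asarray(test)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    denom = np.linalg.norm(np.abs(ref))
    if denom == 0:
        raise ValueError("zero reference")
    if on_magnitude:
        return float(np.linalg.norm(np.abs(test) - np.abs(ref)) / denom)
    return float(np.linalg.norm(test - ref) / denom)


def bland_altman(pairs) -> AgreementResult:
    """Mean difference and 1.96-SD limits of agreement of paired measurements.

    Differences are ``a - b`` per pair; the SD uses the n-1 denominator.
    """
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (a, b) pairs")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    d = arr[:, 0] - arr[:, 1]
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        mean_difference=mean,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n_pairs=arr.shape[0],
    )


# ---------------------------------------------------------------------------
# native HDF5 k-space container
# ---------------------------------------------------------------------------

def write_kspace(
    path: str,
    kspace: np.ndarray,
    traj: RadialTrajectory,
    matrix_size: int,
    fov_mm: float | None = None,
) -> None:
    """Native layout: /kspace (coil, spoke, readout) + /traj/{angles,kcoords,dcf}."""
    nc = kspace.shape[0]
    flat = kspace.reshape(nc, -1, traj.n_readout)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("kspace", data=flat.astype(np.complex64))
        g = fh.create_group("traj")
        g.create_dataset("angles", data=traj.angles)
        g.create_dataset("kcoords", data=traj.kcoords)
        g.create_dataset("dcf", data=traj.dcf)
        fh.attrs["spokes_per_frame"] = traj.spokes_per_frame
        fh.attrs["psi_degrees"] = traj.psi_degrees
        fh.attrs["matrix"] = matrix_size
        fh.attrs["fov_mm"] = fov_mm if fov_mm is not None else 2.0 * matrix_size


def read_kspace(path: str) -> tuple[np.ndarray, RadialTrajectory, dict]:
    """Read the native container; returns (kspace grouped by frame, traj, attrs)."""
    with h5py.File(path, "r") as fh:
        if "traj" not in fh:
            raise ValueError(f"{path}: missing /traj group (unknown layout)")
        if "kspace" not in fh:
            raise ValueError(f"{path}: missing /kspace dataset (unknown layout)")
        flat = fh["kspace"][...]
        angles = fh["traj/angles"][...]
        kcoords = fh["traj/kcoords"][...]
        dcf = fh["traj/dcf"][...]
        attrs = dict(fh.attrs)
    spf = int(attrs["spokes_per_frame"])
    total_spokes, n_readout = flat.shape[1], flat.shape[2]
    if total_spokes % spf:
        raise ValueError(f"{path}: spoke count {total_spokes} not divisible by {spf}")
    n_frames = total_spokes // spf
    traj = RadialTrajectory(
        psi_degrees=float(attrs["psi_degrees"]),
        spokes_per_frame=spf,
        n_frames=n_frames,
        n_readout=n_readout,
        angles=angles,
        kcoords=kcoords,
        dcf=dcf,
    )
    kspace = flat.reshape(flat.shape[0], n_frames, spf, n_readout)
    return kspace.astype(np.complex128), traj, attrs


def read_ismrmrd_style(path: str) -> tuple[np.ndarray, RadialTrajectory, dict]:
    """Read a simplified ISMRMRD-style HDF5 raw-data layout.

    Expects ``/dataset/data`` (acquisition-major: (n_acq, n_coils,
    n_readout) complex), ``/dataset/trajectory`` ((n_acq, n_readout, 2)
    k-space coordinates in radians) and attributes ``spokes_per_frame``,
    ``psi_degrees``, ``matrix`` on the group.  Acquisitions are spokes in
    continuous order.
    """
    with h5py.File(path, "r") as fh:
        if "dataset" not in fh or "data" not in fh["dataset"]:
            raise ValueError(f"{path}: no /dataset/data (unknown layout)")
        data = fh["dataset/data"][...]
        traj_coords = fh["dataset/trajectory"][...]
        attrs = dict(fh["dataset"].attrs)
    n_acq, n_coils, n_readout = data.shape
    spf = int(attrs["spokes_per_frame"])
    if n_acq % spf:
        raise ValueError(f"{path}: {n_acq} acquisitions not divisible by {spf}")
    n_frames = n_acq // spf
    psi = float(attrs.get("psi_degrees", 0.0))
    ref = build_trajectory(psi, spf, n_frames, n_readout)
    traj = RadialTrajectory(
        psi_degrees=psi,
        spokes_per_frame=spf,
        n_frames=n_frames,
        n_readout=n_readout,
        angles=ref.angles,
        kcoords=traj_coords,
        dcf=ref.dcf,
    )
    kspace = data.transpose(1, 0, 2).reshape(n_coils, n_frames, spf, n_readout)
    return kspace.astype(np.complex128), traj, attrs


def write_cine(path: str, cine: np.ndarray, attrs: dict | None = None) -> None:
    """Write a reconstructed cine (complex64) with optional scalar attributes."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("cine", data=np.asarray(cine).astype(np.complex64))
        for k, v in (attrs or {}).items():
            fh.attrs[k] = v


def read_cine(path: str) -> tuple[np.ndarray, dict]:
    with h5py.File(path, "r") as fh:
        if "cine" not in fh:
            raise ValueError(f"{path}: missing /cine dataset")
        return fh["cine"][...], dict(fh.attrs)


# ---------------------------------------------------------------------------
# reconstruction chain
# ---------------------------------------------------------------------------

def gridded_multicoil(
    kspace: np.ndarray,
    traj: RadialTrajectory,
    matrix_size: int,
    numpoints: int = 4,
) -> np.ndarray:
    """DCF-weighted NUFFT gridding of every coil and frame."""
    return nufft_adjoint(
        kspace, traj, matrix_size, apply_dcf=True, numpoints=numpoints
    )


def reconstruct(request: ReconRequest) -> tuple[np.ndarray, dict]:
    """Run the full chain for one of the methods {nufft, grasp, unet}.

    Returns the complex cine ``(n, n, n_t)`` and a metadata dict with
    per-stage wall times and the method settings.
    """
    if request.method not in METHODS:
        raise ValueError(f"unknown method {request.method!r}; choose from {METHODS}")
    meta: dict = {"method": request.method, "timings_s": {}}

    t0 = time.perf_counter()
    if isinstance(request.kspace, str):
        kspace, traj, attrs = read_kspace(request.kspace)
        matrix = int(attrs["matrix"])
    else:
        kspace = np.asarray(request.kspace, dtype=np.complex128)
        traj = request.traj
        matrix = request.matrix_size
        if traj is None or matrix is None:
            raise ValueError("in-memory k-space needs traj and matrix_size")
    meta["timings_s"]["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    coil_imgs = gridded_multicoil(kspace, traj, matrix, request.numpoints)
    meta["timings_s"]["gridding"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sens = estimate_sensitivities_adaptive(coil_imgs.mean(axis=-1))
    combined = coil_combine(coil_imgs, sens)
    meta["timings_s"]["coil_combine"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if request.method == "nufft":
        cine = combined
    elif request.method == "grasp":
        cfg = request.grasp_config or GraspConfig(numpoints=request.numpoints)
        cine, trace = grasp_reconstruct(kspace, sens, traj, cfg, x0=combined)
        meta["grasp_objective_trace"] = trace
    else:  # unet
        from radcine.dealias import dealias, load_checkpoint

        net = request.network
        if net is None:
            if request.checkpoint is None:
                raise ValueError("method 'unet' needs a checkpoint or network")
            net, _ = load_checkpoint(request.checkpoint)
        cine = dealias(combined, net)
    meta["timings_s"][request.method] = time.perf_counter() - t0

    if request.output:
        write_cine(request.output, cine, {"method": request.method})
    if request.log_path:
        with open(request.log_path, "a") as fh:
            fh.write(json.dumps(meta, default=float) + "\n")
    return cine, meta
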