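"""Adaptive coil-sensitivity estimation and complex coil combination.

Sensitivities are estimated pixelwise from a time-averaged multi-coil image
by the adaptive (eigenvector) method, configured with no spatial smoothing
window (1x1 pixelwise covariance) and a single power iteration.  Combination
is the sensitivity-weighted (SENSE-style) matched filter.
"""

from __future__ import annotations

import numpy as np


def estimate_sensitivities_adaptive(time_avg_multicoil: np.ndarray) -> np.ndarray:
    """Pixelwise adaptive sensitivity maps from a time-averaged coil image.

    Per pixel, the dominant eigenvector of the coil sample covariance
    ``R = y y^H`` (no spatial smoothing) is obtained with exactly one power
    iteration started from the coil vector ``y`` itself — for the rank-one
    pixelwise covariance this is ``R y / ||R y|| = y / ||y||``.  Maps are
    unit-norm per pixel, and phase-referenced so the projection onto the
    first coil is real-nonnegative.

    Parameters
    ----------
    time_avg_multicoil : complex array ``(n_coils, n, n)``.

    Returns
    -------
    maps : complex ``(n_coils, n, n)``, zero rows at zero-signal pixels.
    """
    y = np.asarray(time_avg_multicoil, dtype=np.complex128)
    if y.ndim != 3:
        raise ValueError(f"expected (n_coils, n, n), got shape {y.shape}")
    # one power iteration on R = y y^H starting from y: v = y (y^H y)
    v = y * np.sum(np.abs(y) ** 2, axis=0)
    norm = np.sqrt(np.sum(np.abs(v) ** 2, axis=0))
    if not np.any(norm > 0):
        raise ValueError("all-zero image: cannot estimate sensitivities")
    nonzero = norm > 0
    maps = np.zeros_like(v)
    np.divide(v, norm, out=maps, where=nonzero)
    # phase reference: first-coil projection real-nonnegative
    ref = maps[0].copy()
    mag0 = np.abs(ref)
    phase_ok = mag0 > 0
    factor = np.ones_like(ref)
    np.divide(np.conj(ref), mag0, out=factor, where=phase_ok)
    maps *= factor
    return maps


def coil_combine(
    multicoil: np.ndarray, sens: np.ndarray, normalize: bool = True
) -> np.ndarray:
    """Sensitivity-weighted complex combination of multi-coil images.

    ``x_hat = sum_c conj(S_c) y_c / sum_c |S_c|^2`` (matched filter plus
    normalization; with unit-norm maps the denominator is 1 wherever signal
    exists).  Pixels where ``sum |S_c|^2 = 0`` combine to zero.

    Parameters
    ----------
    multicoil : ``(n_coils, n, n)`` or ``(n_coils, n, n, n_t)`` complex.
    sens : ``(n_coils, n, n)`` complex.
    normalize : divide by ``sum |S_c|^2`` (default); ``False`` gives the pure
        matched filter.
    """
    y = np.asarray(multicoil, dtype=np.complex128)
    s = np.asarray(sens, dtype=np.complex128)
    if y.shape[:3] != s.shape:
        raise ValueError(
            f"multicoil shape {y.shape} does not match sensitivities {s.shape}"
        )
    dynamic = y.ndim == 4
    sc = np.conj(s)[..., None] if dynamic else np.conj(s)
    num = np.sum(sc * y, axis=0)
    if not normalize:
        return num
    den = np.sum(np.abs(s) ** 2, axis=0)
    if dynamic:
        den = den[..., None]
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out
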