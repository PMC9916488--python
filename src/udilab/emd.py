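"""Empirical mode decomposition and Hilbert spectral analysis.

Classic EMD by sifting: cubic-spline envelopes through the local extrema
(mirror-extended at the boundaries), the candidate mode is the signal minus
the envelope mean, and sifting stops when the normalised squared difference
between consecutive candidates drops below ``sd_thresh`` (Cauchy-type
criterion) or after ``max_siftings`` passes.  Decomposition ends when the
residual has fewer than three extrema or ``max_imfs`` modes were extracted.
The Hilbert stage attaches an analytic-signal instantaneous amplitude and
frequency to every intrinsic mode function (IMF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from .exceptions import ConvergenceError, DegenerateInputError

__all__ = ["HilbertSpectrum", "emd", "hilbert_huang"]


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (strict sign changes of the slope)."""
    d = np.diff(x)
    # collapse zero slopes so flat tops still register as a single extremum
    nz = np.flatnonzero(d != 0.0)
    if nz.size < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    s = np.sign(d[nz])
    turn = np.flatnonzero(s[1:] != s[:-1])
    idx = nz[turn] + 1
    maxima = idx[s[turn] > 0]
    minima = idx[s[turn] < 0]
    return maxima, minima


def _mirror_extend(idx: np.ndarray, vals: np.ndarray, n: int,
                   nsym: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Reflect up to ``nsym`` extrema about each end of the support."""
    k = min(nsym, idx.size)
    left_idx = (-idx[:k])[::-1]  # reflect about sample 0
    right_idx = (2 * (n - 1) - idx[-k:])[::-1]
    ext_idx = np.concatenate([left_idx, idx, right_idx])
    ext_vals = np.concatenate([vals[:k][::-1], vals, vals[-k:][::-1]])
    # keep strictly increasing support for the spline
    keep = np.concatenate([[True], np.diff(ext_idx) > 0])
    return ext_idx[keep], ext_vals[keep]


def _envelope_mean(x: np.ndarray) -> np.ndarray | None:
    maxima, minima = _local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    n = x.size
    mi, mv = _mirror_extend(maxima, x[maxima], n)
    ni, nv = _mirror_extend(minima, x[minima], n)
    grid = np.arange(n)
    upper = CubicSpline(mi, mv)(grid)
    lower = CubicSpline(ni, nv)(grid)
    return 0.5 * (upper + lower)


def emd(
    x: np.ndarray,
    max_imfs: int = 10,
    sd_thresh: float = 0.2,
    max_siftings: int = 10,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Decompose ``x`` into intrinsic mode functions plus a residual.

    Returns ``(imfs, residual)`` with ``sum(imfs) + residual == x`` to
    floating-point accuracy (the decomposition is complete by construction).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise DegenerateInputError("series too short for decomposition (< 16 samples)")
    if not np.all(np.isfinite(x)):
        raise ConvergenceError(
            "sifting aborted: non-finite samples; SD stopping criterion undefined"
        )
    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_imfs):
        h = residual
        for _ in range(max_siftings):
            mean = _envelope_mean(h)
            if mean is None:
                break
            h_new = h - mean
            denom = float(np.sum(h**2))
            if denom == 0.0:
                break
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < sd_thresh:
                break
        if not np.all(np.isfinite(h)):
            raise ConvergenceError(
                "sifting diverged to non-finite values (SD criterion never met)"
            )
        maxima, minima = _local_extrema(h)
        if maxima.size + minima.size < 2:
            break  # residual is (near-)monotone: done
        imfs.append(h)
        residual = residual - h
        rmax, rmin = _local_extrema(residual)
        if rmax.size + rmin.size < 3:
            break
    return imfs, residual


@dataclass
class HilbertSpectrum:
    """Hilbert-Huang representation of a signal.

    ``inst_amplitude``/``inst_frequency_hz`` are ``(n_imfs, n_samples)``
    arrays; ``sum(imfs) + residual`` reconstructs the input.
    """

    imfs: list[np.ndarray]
    residual: np.ndarray
    inst_amplitude: np.ndarray
    inst_frequency_hz: np.ndarray
    time_s: np.ndarray
    sampling_rate_hz: float

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def hilbert_huang(
    emg: np.ndarray,
    sampling_rate_hz: float,
    time_s: np.ndarray | None = None,
    **emd_kwargs,
) -> HilbertSpectrum:
    """Empirical mode decomposition followed by analytic-signal demodulation."""
    emg = np.asarray(emg, dtype=float)
    imfs, residual = emd(emg, **emd_kwargs)
    n = emg.size
    if time_s is None:
        time_s = np.arange(n) / sampling_rate_hz
    if imfs:
        analytic = hilbert(np.vstack(imfs), axis=1)
        amp = np.abs(analytic)
        phase = np.unwrap(np.angle(analytic), axis=1)
        freq = np.gradient(phase, axis=1) * sampling_rate_hz / (2.0 * np.pi)
    else:
        amp = np.zeros((0, n))
        freq = np.zeros((0, n))
    return HilbertSpectrum(
        imfs=imfs,
        residual=residual,
        inst_amplitude=amp,
        inst_frequency_hz=freq,
        time_s=np.asarray(time_s, dtype=float),
        sampling_rate_hz=float(sampling_rate_hz),
    )
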