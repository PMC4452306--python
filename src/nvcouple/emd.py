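"""Empirical mode decomposition by cubic-spline sifting.

Implements the classic sifting scheme: upper and lower signal envelopes are
cubic splines through the local maxima and minima, the envelope mean is
subtracted, and sifting repeats until a Cauchy-type standard-deviation
criterion falls below tolerance. Spline end conditions use mirror extension
of the outermost extrema to limit edge swings.

Intrinsic mode functions (IMFs) come out fastest-first; the residual is
whatever remains after the last extracted mode. By construction
``signal == sum(imfs) + residual`` to machine precision.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .timeseries import TimeSeries

__all__ = ["emd", "sift_once", "find_extrema"]


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of ``x``.

    Flat-topped extrema (ties) report the first sample of the plateau.
    """
    dx = np.diff(x)
    # collapse zero slopes onto the sign of the next nonzero slope so
    # plateaus produce a single extremum
    sign = np.sign(dx)
    nz = sign != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    idx = np.where(nz, np.arange(sign.size), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, sign[np.maximum(idx, 0)], 0)
    turns = np.diff(filled)
    maxima = np.where(turns < 0)[0] + 1
    minima = np.where(turns > 0)[0] + 1
    return maxima, minima


def _mirror_extend(idx: np.ndarray, val: np.ndarray, n: int, n_mirror: int = 2):
    """Reflect up to ``n_mirror`` extrema about both signal ends."""
    left_i = (2 * 0 - idx[:n_mirror])[::-1]
    left_v = val[:n_mirror][::-1]
    right_i = (2 * (n - 1) - idx[-n_mirror:])[::-1]
    right_v = val[-n_mirror:][::-1]
    ext_i = np.concatenate([left_i, idx, right_i])
    ext_v = np.concatenate([left_v, val, right_v])
    # de-duplicate in case an extremum sits exactly on an endpoint
    ext_i, keep = np.unique(ext_i, return_index=True)
    return ext_i, ext_v[keep]


def _envelope(idx: np.ndarray, x: np.ndarray) -> np.ndarray:
    ext_i, ext_v = _mirror_extend(idx, x[idx], x.size)
    return CubicSpline(ext_i, ext_v)(np.arange(x.size))


def sift_once(x: np.ndarray) -> np.ndarray | None:
    """One sifting pass: subtract the mean of the two spline envelopes.

    Returns None when there are too few extrema to build the envelopes,
    which signals that ``x`` is a residual (monotone or near-monotone).
    """
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    mean_env = 0.5 * (_envelope(maxima, x) + _envelope(minima, x))
    return x - mean_env


def emd(
    ts: TimeSeries,
    max_imfs: int = 10,
    sift_tol: float = 0.2,
    max_sifts: int = 10,
) -> tuple[list[TimeSeries], TimeSeries]:
    """Decompose ``ts`` into intrinsic mode functions plus a residual.

    Parameters
    ----------
    ts : TimeSeries
        Input signal; length must be at least 8 samples.
    max_imfs : int
        Stop after this many modes even if the residual still oscillates.
    sift_tol : float
        Cauchy criterion: sifting of one mode stops when
        ``sum((prev - cur)**2) / sum(prev**2) < sift_tol``.
    max_sifts : int
        Hard cap on sifting passes per mode.

    Returns
    -------
    (imfs, residual)
        ``imfs`` ordered fastest-first; ``sum(imfs) + residual == ts``.
    """
    if len(ts) < 8:
        raise ValueError("emd requires at least 8 samples")
    residual = ts.values.astype(float).copy()
    imfs: list[TimeSeries] = []
    for _ in range(max_imfs):
        h = sift_once(residual)
        if h is None:
            break
        for _ in range(max_sifts - 1):
            denom = float(np.sum(h * h))
            if denom == 0.0:
                break
            h_new = sift_once(h)
            if h_new is None:
                break
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < sift_tol:
                break
        imfs.append(ts.copy_with(h))
        residual = residual - h
        rmax, rmin = find_extrema(residual)
        if rmax.size < 2 or rmin.size < 2:
            break
    return imfs, ts.copy_with(residual)
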