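"""Gamma-kernel coupling model and the two-step per-epoch estimator.

The forward model maps a neural-rhythm amplitude envelope ``g(t)`` to a
hemodynamic trace ``f(t)`` by causal convolution with a gamma-family kernel

    h(t; tau, n, d) = ((t-d)/tau)**(n-1) * exp(-(t-d)/tau) / (tau*(n-1)!)

for ``t >= d`` (0 before), followed by gain ``a`` and offset ``b``:
``f = a*(g*h) + b``. Estimation is two-step: an exhaustive scan over a
coarse (tau, n, d) grid with gain/offset solved in closed form per
candidate, then a Nelder-Mead joint refinement of all five parameters. The
shape ``n`` is an integer in the model definition; during refinement it is
relaxed to a positive real by replacing ``(n-1)!`` with ``gamma(n)`` and
both the continuous estimate and its nearest integer are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft
from scipy.optimize import minimize
from scipy.special import gammaln

from .timeseries import TimeSeries

__all__ = [
    "GammaParams",
    "FitGrid",
    "FitResult",
    "EpochPair",
    "gamma_kernel",
    "forward_predict",
    "solve_gain_offset",
    "grid_fit",
    "simplex_refine",
    "fit_epoch",
]


@dataclass(frozen=True)
class GammaParams:
    """Gamma kernel parameters: peak-time constant, shape, pure delay."""

    tau: float
    n: int
    d: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n}")
        object.__setattr__(self, "n", int(self.n))
        if self.d < 0:
            raise ValueError(f"delay d must be non-negative, got {self.d}")


@dataclass(frozen=True)
class FitGrid:
    """Brute-force search grid over (tau, n, d)."""

    tau_range: tuple[float, float] = (0.1, 0.6)
    tau_step: float = 0.05
    n_values: tuple[int, ...] = (1, 2, 3, 4)
    d_range: tuple[float, float] = (0.5, 3.0)
    d_step: float = 0.25

    def __post_init__(self) -> None:
        if self.tau_range[0] > self.tau_range[1] or self.d_range[0] > self.d_range[1]:
            raise ValueError("grid ranges must be (low, high) with low <= high")
        if self.tau_step <= 0 or self.d_step <= 0:
            raise ValueError("grid steps must be positive")
        if not self.n_values:
            raise ValueError("n_values must be non-empty")

    @staticmethod
    def _axis(lo: float, hi: float, step: float) -> np.ndarray:
        return np.round(np.arange(lo, hi + step / 2, step), 10)

    def candidates(self) -> list[GammaParams]:
        taus = self._axis(*self.tau_range, self.tau_step)
        ds = self._axis(*self.d_range, self.d_step)
        return [
            GammaParams(float(t), int(n), float(d))
            for n in self.n_values
            for t in taus
            for d in ds
        ]


@dataclass
class EpochPair:
    """Aligned, normalized envelope (input) and HbO (output) for one epoch.

    ``context`` optionally carries envelope samples immediately preceding
    the epoch; they prime the convolution so predictions inside the epoch
    are free of the left-edge zero-padding transient. The context samples
    themselves are never scored.
    """

    envelope: TimeSeries
    hbo: TimeSeries
    stim_onset_s: float = 0.0
    stim_dur_s: float = 0.0
    eeg_channel: str = "eeg0"
    nirs_channel: str = "nirs0"
    epoch_id: int = 0
    context: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.envelope.fs != self.hbo.fs:
            raise ValueError("envelope and hbo must share a sampling rate")
        if len(self.envelope) != len(self.hbo):
            raise ValueError("envelope and hbo must have equal length")
        if self.context is not None:
            self.context = np.asarray(self.context, dtype=float)

    @property
    def fs(self) -> float:
        return self.envelope.fs


@dataclass
class FitResult:
    """One epoch's fitted kernel parameters and goodness of fit."""

    params: GammaParams
    a: float
    b: float
    sse: float
    r: float
    n_refined: float
    epoch_id: int = 0
    eeg_channel: str = "eeg0"
    nirs_channel: str = "nirs0"
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be non-negative")


def _kernel_values(
    tau: float, n: float, d: float, fs: float, duration_s: float | None
) -> np.ndarray:
    if tau <= 0 or n <= 0:
        raise ValueError("gamma kernel requires tau > 0 and n > 0")
    if d < 0:
        raise ValueError("gamma kernel requires d >= 0")
    if duration_s is None:
        # cover the Erlang tail to ~exp(-40)
        duration_s = d + tau * (n + 40.0)
    t = np.arange(int(math.ceil(duration_s * fs)) + 1) / fs
    s = np.maximum(t - d, 0.0) / tau
    with np.errstate(divide="ignore"):
        log_h = (n - 1) * np.where(s > 0, np.log(s), 0.0) - s
    h = np.exp(log_h - math.log(tau) - gammaln(n))
    h[t < d] = 0.0
    # value exactly at t == d: 1/tau when n == 1 (0**0 == 1), 0 when n > 1
    at_d = (t >= d) & (s == 0.0)
    if n > 1:
        h[at_d] = 0.0
    elif n == 1:
        h[at_d] = 1.0 / tau
    return h


def gamma_kernel(
    gp: GammaParams, fs: float, duration_s: float | None = None
) -> np.ndarray:
    """Sample the gamma kernel at rate ``fs``.

    ``duration_s`` defaults to ``d + tau*(n + 40)``, long enough that the
    truncated tail mass is negligible. Point sampling of the continuous
    density: the discrete sum times ``1/fs`` approaches 1 as fs grows.
    """
    return _kernel_values(gp.tau, gp.n, gp.d, fs, duration_s)


def _convolve_causal(
    g: np.ndarray, kernel: np.ndarray, dt: float, n_context: int
) -> np.ndarray:
    full = np.convolve(g, kernel)[: g.size] * dt
    return full[n_context:]


def forward_predict(
    g: TimeSeries, gp: GammaParams, a: float, b: float
) -> TimeSeries:
    """Predicted hemodynamic trace ``a*(g*h) + b`` truncated to g's length."""
    kernel = gamma_kernel(gp, g.fs)
    return g.copy_with(a * _convolve_causal(g.values, kernel, g.dt, 0) + b)


def solve_gain_offset(x, y) -> tuple[float, float]:
    """Ordinary least-squares gain and offset minimizing ``sum((y-a*x-b)**2)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    xm, ym = x.mean(), y.mean()
    varx = float(np.mean((x - xm) ** 2))
    if varx == 0.0:
        raise ValueError("regressor is constant; gain/offset are unidentifiable")
    a = float(np.mean((x - xm) * (y - ym)) / varx)
    return a, float(ym - a * xm)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


@lru_cache(maxsize=8)
def _kernel_bank(grid: FitGrid, fs: float, nfft: int):
    """rfft of every grid candidate's kernel, padded to ``nfft``."""
    cands = grid.candidates()
    lengths = []
    spectra = np.empty((len(cands), nfft // 2 + 1), dtype=complex)
    for i, gp in enumerate(cands):
        k = gamma_kernel(gp, fs)
        if k.size > nfft:
            k = k[:nfft]
        lengths.append(k.size)
        spectra[i] = rfft(k, nfft)
    return cands, spectra


def grid_fit(epoch: EpochPair, grid: FitGrid) -> FitResult:
    """Exhaustive scan of the grid; gain/offset by least squares per candidate.

    Returns the minimum-SSE candidate. All candidate predictions are formed
    in one batched FFT convolution for speed.
    """
    cands = grid.candidates()
    if not cands:
        raise ValueError("empty parameter grid")
    ctx = epoch.context if epoch.context is not None else np.empty(0)
    g_full = np.concatenate([ctx, epoch.envelope.values])
    y = epoch.hbo.values
    n_ctx = ctx.size
    fs, dt = epoch.fs, epoch.envelope.dt

    max_klen = max(
        int(math.ceil((gp.d + gp.tau * (gp.n + 40.0)) * fs)) + 1 for gp in cands
    )
    nfft = next_fast_len(g_full.size + max_klen - 1)
    cands, spectra = _kernel_bank(grid, fs, nfft)

    G = rfft(g_full, nfft)
    X = irfft(spectra * G, nfft)[:, n_ctx : g_full.size] * dt

    N = y.size
    xm = X.mean(axis=1)
    ym = y.mean()
    cov = X @ y / N - xm * ym
    varx = np.mean(X * X, axis=1) - xm * xm
    ok = varx > 1e-300
    a = np.where(ok, cov / np.where(ok, varx, 1.0), 0.0)
    b = ym - a * xm
    resid = y[None, :] - a[:, None] * X - b[:, None]
    sse = np.einsum("ij,ij->i", resid, resid)
    best = int(np.argmin(sse))
    gp = cands[best]
    r = _pearson(a[best] * X[best] + b[best], y)
    return FitResult(
        params=gp,
        a=float(a[best]),
        b=float(b[best]),
        sse=float(sse[best]),
        r=r,
        n_refined=float(gp.n),
        epoch_id=epoch.epoch_id,
        eeg_channel=epoch.eeg_channel,
        nirs_channel=epoch.nirs_channel,
    )


def _epoch_sse(
    theta: np.ndarray, epoch: EpochPair, g_full, n_ctx, G, nfft, box
) -> float:
    tau, n, d, a, b = theta
    tau_hi, n_hi, d_hi = box
    if tau <= 1e-4 or n <= 0.05 or d < 0 or tau > tau_hi or n > n_hi or d > d_hi:
        # outside the admissible box: steep finite penalty
        viol = (
            max(1e-4 - tau, 0) + max(0.05 - n, 0) + max(-d, 0)
            + max(tau - tau_hi, 0) + max(n - n_hi, 0) + max(d - d_hi, 0)
        )
        return 1e12 * (1.0 + viol)
    kernel = _kernel_values(tau, n, d, epoch.fs, None)
    if kernel.size + g_full.size - 1 <= nfft:
        conv = irfft(rfft(kernel, nfft) * G, nfft)[n_ctx : g_full.size]
        x = conv * epoch.envelope.dt
    else:
        x = _convolve_causal(g_full, kernel, epoch.envelope.dt, n_ctx)
    resid = epoch.hbo.values - (a * x + b)
    return float(resid @ resid)


def simplex_refine(
    start: FitResult,
    epoch: EpochPair,
    xatol: float = 1e-6,
    fatol: float = 1e-12,
    maxfev: int = 2000,
    grid: FitGrid | None = None,
) -> FitResult:
    """Joint Nelder-Mead refinement of (tau, n, d, a, b) from a grid start.

    ``n`` is treated as a positive real (gamma-function relaxation); the
    returned ``params.n`` is its nearest admissible integer while
    ``n_refined`` keeps the continuous value. The refined SSE is never
    allowed to exceed the starting SSE.

    The search is confined to a box somewhat wider than the grid's
    predefined ranges (tau up to 2x its upper bound, n up to max+1, d up to
    max+1): the kernel family has a near-flat ridge (large n with
    compensating tau and d gives almost the same shape), and an unbounded
    joint search drifts along it under noise, destroying parameter
    identifiability.
    """
    grid = grid or FitGrid()
    box = (
        2.0 * grid.tau_range[1],
        float(max(grid.n_values)) + 1.0,
        grid.d_range[1] + 1.0,
    )
    ctx = epoch.context if epoch.context is not None else np.empty(0)
    g_full = np.concatenate([ctx, epoch.envelope.values])
    n_ctx = ctx.size
    theta0 = np.array(
        [start.params.tau, float(start.params.n), start.params.d, start.a, start.b]
    )
    # generous FFT budget: kernels up to twice the signal length stay exact
    nfft = next_fast_len(3 * g_full.size)
    G = rfft(g_full, nfft)
    res = minimize(
        _epoch_sse,
        theta0,
        args=(epoch, g_full, n_ctx, G, nfft, box),
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev, "maxiter": maxfev},
    )
    tau, n, d, a, b = res.x
    sse = float(res.fun)
    if not np.isfinite(sse) or sse > start.sse:
        return FitResult(
            params=start.params,
            a=start.a,
            b=start.b,
            sse=start.sse,
            r=start.r,
            n_refined=start.n_refined,
            epoch_id=epoch.epoch_id,
            eeg_channel=epoch.eeg_channel,
            nirs_channel=epoch.nirs_channel,
            converged=False,
        )
    kernel = _kernel_values(tau, n, d, epoch.fs, None)
    pred = a * _convolve_causal(g_full, kernel, epoch.envelope.dt, n_ctx) + b
    return FitResult(
        params=GammaParams(float(tau), max(1, int(round(n))), float(max(d, 0.0))),
        a=float(a),
        b=float(b),
        sse=sse,
        r=_pearson(pred, epoch.hbo.values),
        n_refined=float(n),
        epoch_id=epoch.epoch_id,
        eeg_channel=epoch.eeg_channel,
        nirs_channel=epoch.nirs_channel,
        converged=bool(res.success),
    )


def fit_epoch(epoch: EpochPair, grid: FitGrid | None = None) -> FitResult:
    """Two-step estimate: grid scan followed by simplex refinement."""
    if grid is None:
        grid = FitGrid()
    return simplex_refine(grid_fit(epoch, grid), epoch, grid=grid)
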