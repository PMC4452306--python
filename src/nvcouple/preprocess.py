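"""Signal conditioning for raw EEG and NIRS recordings.

EEG chain: zero-phase Butterworth band-pass (mu band), empirical mode
decomposition, Hilbert magnitude of the first mode, anti-aliased
downsampling onto the NIRS clock. NIRS chain: motion rejection by
Chauvenet's criterion on deviations from a short moving average, modified
Beer-Lambert inversion to chromophore concentration changes, linear
detrending and a low-pass to suppress cardiac oscillations. Epoching,
smoothing and per-epoch normalization follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt, hilbert, detrend as _detrend
from scipy.stats import norm

from .emd import emd  # noqa: F401  (re-exported as part of the preprocessing API)
from .timeseries import TimeSeries

__all__ = [
    "RawNIRSRecord",
    "DEFAULT_EXTINCTION",
    "DEFAULT_DPF",
    "butterworth_filter",
    "emd",
    "hilbert_envelope",
    "downsample",
    "moving_average",
    "chauvenet_threshold",
    "chauvenet_clean",
    "mbll",
    "mbll_forward",
    "extract_epochs",
    "smooth_normalize",
    "select_channels",
]

#: Molar extinction coefficients [1/(cm*M)] for (HbO, HbR) at the four
#: instrument wavelengths. Literature values (Prahl compilation, via the
#: tabulations commonly shipped with NIRS analysis toolboxes); override via
#: RawNIRSRecord.extinction if your instrument calibration differs.
DEFAULT_EXTINCTION: dict[float, tuple[float, float]] = {
    690.0: (276.0, 2051.96),
    785.0: (735.4, 1098.3),
    808.0: (866.0, 761.8),
    830.0: (974.0, 693.04),
}

#: Differential pathlength factors per wavelength (adult head, literature
#: consensus values; configurable).
DEFAULT_DPF: dict[float, float] = {690.0: 6.2, 785.0: 6.0, 808.0: 5.9, 830.0: 5.8}


@dataclass
class RawNIRSRecord:
    """Raw light intensities for one source-detector channel.

    ``intensities`` maps wavelength (nm) to a positive intensity sequence;
    all wavelengths must share length and the 25 Hz clock.
    """

    intensities: dict[float, np.ndarray]
    fs: float = 25.0
    source_detector_mm: float = 33.0
    dpf: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_DPF))
    extinction: dict[float, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EXTINCTION)
    )
    channel: str = "nirs0"

    def __post_init__(self) -> None:
        self.intensities = {
            float(w): np.asarray(v, dtype=float) for w, v in self.intensities.items()
        }
        if len(self.intensities) < 2:
            raise ValueError("MBLL needs at least 2 wavelengths")
        lengths = {v.size for v in self.intensities.values()}
        if len(lengths) != 1:
            raise ValueError("all wavelength series must share a length")
        for w, v in self.intensities.items():
            if not (v > 0).all():
                raise ValueError(f"non-positive intensity at {w} nm")
            if w not in self.extinction:
                raise ValueError(f"no extinction coefficients for {w} nm")
            if w not in self.dpf:
                raise ValueError(f"no DPF for {w} nm")

    @property
    def wavelengths(self) -> list[float]:
        return sorted(self.intensities)


def butterworth_filter(
    ts: TimeSeries,
    band: tuple[float | None, float | None],
    order: int = 4,
    kind: str = "bandpass",
) -> TimeSeries:
    """Zero-phase (forward-backward) Butterworth filtering.

    ``kind='bandpass'`` uses ``band=(low, high)``; ``kind='lowpass'`` uses
    ``band=(None, cutoff)`` or a scalar-like pair.
    """
    nyq = ts.fs / 2
    if order < 1:
        raise ValueError("filter order must be >= 1")
    if kind == "bandpass":
        low, high = band
        if low is None or high is None or not (0 < low < high):
            raise ValueError(f"bandpass needs 0 < low < high, got {band}")
        if high >= nyq:
            raise ValueError(f"band edge {high} Hz is at/above Nyquist {nyq} Hz")
        sos = butter(order, [low, high], btype="bandpass", fs=ts.fs, output="sos")
    elif kind == "lowpass":
        cutoff = band[1] if band[1] is not None else band[0]
        if cutoff is None or cutoff <= 0:
            raise ValueError(f"lowpass needs a positive cutoff, got {band}")
        if cutoff >= nyq:
            raise ValueError(f"cutoff {cutoff} Hz is at/above Nyquist {nyq} Hz")
        sos = butter(order, cutoff, btype="lowpass", fs=ts.fs, output="sos")
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    return ts.copy_with(sosfiltfilt(sos, ts.values))


def hilbert_envelope(ts: TimeSeries) -> TimeSeries:
    """Magnitude of the analytic signal (instantaneous amplitude)."""
    return ts.copy_with(np.abs(hilbert(ts.values)))


def downsample(ts: TimeSeries, target_fs: float) -> TimeSeries:
    """Anti-aliased resampling onto a coarser uniform grid.

    A zero-phase Butterworth low-pass at 0.4x the target rate precedes
    linear interpolation onto the target grid.
    """
    if target_fs > ts.fs:
        raise ValueError(f"target rate {target_fs} exceeds input rate {ts.fs}")
    if target_fs == ts.fs:
        return ts.copy_with(ts.values.copy())
    filtered = butterworth_filter(
        ts, (None, 0.4 * target_fs), order=8, kind="lowpass"
    )
    n_out = int(round(len(ts) * target_fs / ts.fs))
    t_out = ts.t0 + np.arange(n_out) / target_fs
    return TimeSeries(np.interp(t_out, ts.times, filtered.values), target_fs, ts.t0)


def moving_average(values: np.ndarray, span: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if span < 1:
        raise ValueError("span must be >= 1")
    kernel = np.ones(min(span, values.size))
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / counts


def chauvenet_threshold(n: int) -> float:
    """Deviation-ratio threshold of Chauvenet's criterion for n samples."""
    if n < 2:
        raise ValueError("need at least 2 samples")
    return float(norm.ppf(1.0 - 1.0 / (4.0 * n)))


def chauvenet_clean(
    ts: TimeSeries, span_points: int = 30
) -> tuple[TimeSeries, np.ndarray]:
    """Reject motion artifacts by Chauvenet's criterion and splice.

    Deviations are the raw signal minus its moving average (span 30 points
    = 1.2 s at 25 Hz); the deviation ratio is the deviation divided by the
    standard deviation of all deviations. Samples whose |ratio| exceeds the
    criterion threshold are dropped and the survivors are concatenated onto
    a contiguous time base.
    """
    if len(ts) <= span_points:
        raise ValueError("signal must be longer than the smoothing span")
    deviations = ts.values - moving_average(ts.values, span_points)
    sd = float(np.std(deviations))
    if sd == 0.0:
        return ts.copy_with(ts.values.copy()), np.ones(len(ts), dtype=bool)
    ratio = deviations / sd
    kept = np.abs(ratio) <= chauvenet_threshold(len(ts))
    return TimeSeries(ts.values[kept], ts.fs, ts.t0), kept


def mbll_forward(
    hbo_um: np.ndarray,
    hbr_um: np.ndarray,
    fs: float = 25.0,
    source_detector_mm: float = 33.0,
    dpf: dict[float, float] | None = None,
    extinction: dict[float, tuple[float, float]] | None = None,
    baseline_intensity: float = 1.0,
    channel: str = "nirs0",
) -> RawNIRSRecord:
    """Generate raw intensities that encode known concentration changes.

    The exact inverse of the MBLL solve when the same reference intensity is
    supplied on inversion; used for synthesizing NIRS inputs and for
    round-trip validation.
    """
    dpf = dict(dpf or DEFAULT_DPF)
    extinction = dict(extinction or DEFAULT_EXTINCTION)
    path_cm = source_detector_mm / 10.0
    hbo_m = np.asarray(hbo_um, dtype=float) * 1e-6
    hbr_m = np.asarray(hbr_um, dtype=float) * 1e-6
    intensities = {}
    for w, (eps_hbo, eps_hbr) in extinction.items():
        od = path_cm * dpf[w] * (eps_hbo * hbo_m + eps_hbr * hbr_m)
        intensities[w] = baseline_intensity * 10.0 ** (-od)
    return RawNIRSRecord(
        intensities,
        fs=fs,
        source_detector_mm=source_detector_mm,
        dpf=dpf,
        extinction=extinction,
        channel=channel,
    )


def mbll(
    rec: RawNIRSRecord,
    baseline: tuple[float, float] | None = None,
    reference: dict[float, float] | float | None = None,
    detrend: bool = True,
    lowpass_hz: float | None = 0.5,
    lowpass_order: int = 3,
) -> tuple[TimeSeries, TimeSeries]:
    """Modified Beer-Lambert inversion to (dHbO, dHbR) in micromolar.

    Optical density changes ``-log10(I/I_baseline)`` at each wavelength are
    solved per time point, in the least-squares sense, for the two
    chromophore concentration changes, scaled by the source-detector
    distance and per-wavelength differential pathlength factor. Outputs are
    linearly detrended and low-pass filtered (0.5 Hz, 3rd order, zero-phase)
    unless disabled.

    ``baseline`` optionally gives a (start, stop) time window in seconds
    over which the reference intensity is averaged; default is the whole
    recording mean. ``reference`` instead fixes the reference intensity
    directly (per wavelength or shared scalar), for exact round trips.
    """
    wavelengths = rec.wavelengths
    path_cm = rec.source_detector_mm / 10.0
    n = next(iter(rec.intensities.values())).size

    od = np.empty((len(wavelengths), n))
    design = np.empty((len(wavelengths), 2))
    for i, w in enumerate(wavelengths):
        intensity = rec.intensities[w]
        if reference is not None:
            ref = reference[w] if isinstance(reference, dict) else reference
        elif baseline is None:
            ref = intensity.mean()
        else:
            i0 = int(round(baseline[0] * rec.fs))
            i1 = int(round(baseline[1] * rec.fs))
            ref = intensity[i0:i1].mean()
        od[i] = -np.log10(intensity / ref)
        eps_hbo, eps_hbr = rec.extinction[w]
        design[i] = (path_cm * rec.dpf[w] * eps_hbo, path_cm * rec.dpf[w] * eps_hbr)

    if np.linalg.matrix_rank(design) < 2:
        raise ValueError(
            f"extinction system is singular for wavelengths {wavelengths}"
        )
    conc, *_ = np.linalg.lstsq(design, od, rcond=None)  # molar
    hbo = conc[0] * 1e6
    hbr = conc[1] * 1e6
    if detrend:
        hbo = _detrend(hbo)
        hbr = _detrend(hbr)
    hbo_ts = TimeSeries(hbo, rec.fs)
    hbr_ts = TimeSeries(hbr, rec.fs)
    if lowpass_hz is not None:
        hbo_ts = butterworth_filter(hbo_ts, (None, lowpass_hz), lowpass_order, "lowpass")
        hbr_ts = butterworth_filter(hbr_ts, (None, lowpass_hz), lowpass_order, "lowpass")
    return hbo_ts, hbr_ts


def extract_epochs(
    ts: TimeSeries,
    onsets,
    stim_dur: float = 15.0,
    pre: float = 5.0,
    post: float = 5.0,
) -> list[TimeSeries]:
    """Fixed-length slices time-locked to stimulus onsets.

    Each epoch spans ``[onset - pre, onset + stim_dur + post)`` and must lie
    entirely within the recording.
    """
    epochs = []
    n_samples = int(round((pre + stim_dur + post) * ts.fs))
    for onset in onsets:
        start = onset - pre
        i0 = ts.index_of(start)
        if i0 < 0 or i0 + n_samples > len(ts):
            raise ValueError(
                f"epoch for onset {onset} s ([{start}, {start + pre + stim_dur + post}) s) "
                "falls outside the recording"
            )
        epochs.append(
            TimeSeries(ts.values[i0 : i0 + n_samples], ts.fs, t0=ts.t0 + i0 / ts.fs)
        )
    return epochs


def smooth_normalize(epoch: TimeSeries, window_s: float = 4.0) -> TimeSeries:
    """Moving-average smoothing then division by the smoothed signal's std."""
    span = int(round(window_s * epoch.fs))
    if span >= len(epoch):
        raise ValueError("smoothing window must be shorter than the epoch")
    smoothed = moving_average(epoch.values, max(span, 1))
    sd = float(np.std(smoothed))
    if sd == 0.0:
        raise ValueError("degenerate epoch: zero variance after smoothing")
    return epoch.copy_with(smoothed / sd)


def select_channels(
    envelopes: dict[str, TimeSeries],
    hbo_channels: dict[str, TimeSeries],
    pulse: TimeSeries,
    r_min: float = 0.3,
    hbo_min_um: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Keep informative channels.

    EEG envelopes are ranked by |Pearson r| against the stimulus pulse
    sequence and kept when ``|r| >= r_min``. NIRS channels are kept when
    their peak-to-baseline concentration change (max minus median) reaches
    ``hbo_min_um`` micromolar.
    """
    ranked: list[tuple[float, str]] = []
    for name, env in envelopes.items():
        n = min(len(env), len(pulse))
        r = np.corrcoef(env.values[:n], pulse.values[:n])[0, 1]
        if np.isfinite(r) and abs(r) >= r_min:
            ranked.append((abs(r), name))
    eeg_ids = [name for _, name in sorted(ranked, reverse=True)]

    nirs_ids = []
    for name, hbo in hbo_channels.items():
        swing = float(np.max(hbo.values) - np.median(hbo.values))
        if swing >= hbo_min_um:
            nirs_ids.append(name)

    if not eeg_ids or not nirs_ids:
        warnings.warn("channel selection produced an empty set", stacklevel=2)
    return eeg_ids, nirs_ids
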