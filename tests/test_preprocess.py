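import numpy as np
import pytest
from scipy.stats import norm

from nvcouple.preprocess import (
    DEFAULT_EXTINCTION,
    RawNIRSRecord,
    butterworth_filter,
    chauvenet_clean,
    chauvenet_threshold,
    downsample,
    emd,
    extract_epochs,
    hilbert_envelope,
    mbll,
    mbll_forward,
    moving_average,
    select_channels,
    smooth_normalize,
)
from nvcouple.timeseries import TimeSeries


class TestButterworth:
    def test_dc_rejection(self):
        ts = TimeSeries(np.full(5000, 10.0), fs=256.0)
        out = butterworth_filter(ts, (5.0, 14.0), order=4, kind="bandpass")
        trim = slice(256, -256)
        assert np.max(np.abs(out.values[trim])) < 1e-6 * 10.0

    def test_passband_gain_near_unity(self):
        fs = 256.0
        t = np.arange(0, 30, 1 / fs)
        ts = TimeSeries(np.sin(2 * np.pi * 9 * t), fs)
        out = butterworth_filter(ts, (5.0, 14.0), order=4, kind="bandpass")
        interior = out.values[int(2 * fs) : -int(2 * fs)]
        amplitude = np.max(np.abs(interior))
        assert abs(amplitude - 1.0) < 0.02

    def test_zero_phase(self):
        fs = 256.0
        t = np.arange(0, 10, 1 / fs)
        x = np.sin(2 * np.pi * 9 * t)
        out = butterworth_filter(TimeSeries(x, fs), (5.0, 14.0), 4, "bandpass").values
        trim = slice(int(fs), -int(fs))
        lags = np.arange(-20, 21)
        xc = [np.dot(x[trim], np.roll(out, lag)[trim]) for lag in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_band_edge_at_nyquist_rejected(self):
        ts = TimeSeries(np.zeros(100), fs=25.0)
        with pytest.raises(ValueError):
            butterworth_filter(ts, (5.0, 13.0), 4, "bandpass")

    def test_lowpass(self):
        fs = 25.0
        t = np.arange(0, 60, 1 / fs)
        slow = np.sin(2 * np.pi * 0.1 * t)
        fast = np.sin(2 * np.pi * 5.0 * t)
        out = butterworth_filter(TimeSeries(slow + fast, fs), (None, 0.5), 3, "lowpass")
        interior = slice(int(5 * fs), -int(5 * fs))
        rmse = np.sqrt(np.mean((out.values[interior] - slow[interior]) ** 2))
        assert rmse < 0.05


class TestHilbertEnvelope:
    def test_constant_amplitude_tone(self):
        fs = 256.0
        t = np.arange(0, 10, 1 / fs)
        env = hilbert_envelope(TimeSeries(3.0 * np.sin(2 * np.pi * 9 * t), fs))
        interior = env.values[int(fs) : -int(fs)]
        assert np.all(np.abs(interior - 3.0) < 0.02 * 3.0)

    def test_zero_signal(self):
        env = hilbert_envelope(TimeSeries(np.zeros(100), 25.0))
        np.testing.assert_array_equal(env.values, 0.0)

    def test_ramp_amplitude_tracking(self):
        fs = 256.0
        t = np.arange(0, 10, 1 / fs)
        amp = 1.0 + t / 10.0
        env = hilbert_envelope(TimeSeries(amp * np.sin(2 * np.pi * 9 * t), fs))
        interior = slice(int(fs), -int(fs))
        rmse = np.sqrt(np.mean((env.values[interior] - amp[interior]) ** 2))
        assert rmse < 0.03 * amp.max()


class TestDownsample:
    def test_constant_preserved(self):
        out = downsample(TimeSeries(np.full(2048, 3.3), 2048.0), 25.0)
        np.testing.assert_allclose(out.values, 3.3, atol=1e-9)
        assert out.fs == 25.0

    def test_output_length(self):
        n = 20480
        out = downsample(TimeSeries(np.zeros(n), 2048.0), 25.0)
        assert abs(len(out) - round(n * 25 / 2048)) <= 1

    def test_sine_round_trip(self):
        fs = 2048.0
        t = np.arange(0, 20, 1 / fs)
        out = downsample(TimeSeries(np.sin(2 * np.pi * 1.0 * t), fs), 25.0)
        expected = np.sin(2 * np.pi * 1.0 * out.times)
        interior = slice(25, -25)
        r = np.corrcoef(out.values[interior], expected[interior])[0, 1]
        assert r > 0.999

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            downsample(TimeSeries(np.zeros(100), 25.0), 50.0)


class TestChauvenet:
    def test_constant_signal_keeps_all(self):
        ts = TimeSeries(np.full(500, 2.0), 25.0)
        cleaned, kept = chauvenet_clean(ts)
        assert kept.all()
        np.testing.assert_array_equal(cleaned.values, ts.values)

    def test_threshold_closed_form(self):
        # standard criterion: Phi^-1(1 - 1/(4N))
        assert chauvenet_threshold(100) == pytest.approx(norm.ppf(1 - 1 / 400))
        assert chauvenet_threshold(100) == pytest.approx(2.807, abs=5e-3)

    def test_single_spike_removed(self):
        fs = 25.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 0.1 * t)
        spike_at = 700
        x[spike_at] += 20.0
        _, kept = chauvenet_clean(TimeSeries(x, fs))
        removed = np.flatnonzero(~kept)
        assert spike_at in removed
        assert removed.size <= 3  # spike plus at most its immediate shoulder

    def test_gaussian_noise_removal_rate(self, rng):
        ts = TimeSeries(rng.standard_normal(10000), 25.0)
        _, kept = chauvenet_clean(ts)
        assert (~kept).sum() < 0.01 * len(ts)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            chauvenet_clean(TimeSeries(np.zeros(10), 25.0), span_points=30)


class TestMBLL:
    def test_constant_intensity_gives_zero(self):
        rec = RawNIRSRecord({w: np.full(500, 0.7) for w in DEFAULT_EXTINCTION})
        hbo, hbr = mbll(rec, detrend=False, lowpass_hz=None)
        np.testing.assert_allclose(hbo.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(hbr.values, 0.0, atol=1e-12)

    def test_round_trip_exact(self, rng):
        t = np.arange(0, 40, 1 / 25.0)
        hbo_true = 0.8 * np.sin(2 * np.pi * 0.05 * t)
        hbr_true = -0.3 * np.sin(2 * np.pi * 0.05 * t + 0.4)
        rec = mbll_forward(hbo_true, hbr_true)
        hbo, hbr = mbll(rec, reference=1.0, detrend=False, lowpass_hz=None)
        np.testing.assert_allclose(hbo.values, hbo_true, atol=1e-9)
        np.testing.assert_allclose(hbr.values, hbr_true, atol=1e-9)

    def test_round_trip_random_tables(self, rng):
        # least-squares inversion must be exact for any nonsingular table
        for _ in range(5):
            ext = {
                float(w): tuple(rng.uniform(100, 2000, size=2))
                for w in (660, 730, 810, 850)
            }
            dpf = {float(w): rng.uniform(4, 7) for w in (660, 730, 810, 850)}
            hbo_true = rng.standard_normal(200) * 0.5
            hbr_true = rng.standard_normal(200) * 0.2
            rec = mbll_forward(hbo_true, hbr_true, dpf=dpf, extinction=ext)
            hbo, hbr = mbll(rec, reference=1.0, detrend=False, lowpass_hz=None)
            np.testing.assert_allclose(hbo.values, hbo_true, atol=1e-8)
            np.testing.assert_allclose(hbr.values, hbr_true, atol=1e-8)

    def test_two_wavelength_closed_form(self, rng):
        wl = (690.0, 830.0)
        ext = {w: DEFAULT_EXTINCTION[w] for w in wl}
        hbo_true = rng.standard_normal(100) * 0.4
        hbr_true = rng.standard_normal(100) * 0.3
        rec = mbll_forward(hbo_true, hbr_true, extinction=ext,
                           dpf={690.0: 6.2, 830.0: 5.8})
        hbo, hbr = mbll(rec, reference=1.0, detrend=False, lowpass_hz=None)
        # explicit 2x2 solve
        path_cm = 3.3
        A = np.array(
            [[path_cm * 6.2 * ext[690.0][0], path_cm * 6.2 * ext[690.0][1]],
             [path_cm * 5.8 * ext[830.0][0], path_cm * 5.8 * ext[830.0][1]]]
        )
        od = np.stack([-np.log10(rec.intensities[w]) for w in wl])
        conc = np.linalg.solve(A, od) * 1e6
        np.testing.assert_allclose(hbo.values, conc[0], atol=1e-8)
        np.testing.assert_allclose(hbr.values, conc[1], atol=1e-8)

    def test_singular_system_rejected(self):
        ext = {690.0: (500.0, 1000.0), 830.0: (250.0, 500.0)}  # rank 1
        rec = RawNIRSRecord(
            {w: np.full(100, 0.9) for w in ext},
            dpf={690.0: 6.0, 830.0: 6.0},
            extinction=ext,
        )
        with pytest.raises(ValueError, match="singular"):
            mbll(rec)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            RawNIRSRecord({w: np.zeros(10) for w in DEFAULT_EXTINCTION})


class TestEpochs:
    def test_epoch_length(self):
        ts = TimeSeries(np.arange(2500.0), 25.0)
        epochs = extract_epochs(ts, [40.0], stim_dur=15.0, pre=5.0, post=5.0)
        assert len(epochs) == 1
        assert len(epochs[0]) == 625  # 25 s x 25 Hz

    def test_onset_at_start_rejected(self):
        ts = TimeSeries(np.zeros(2500), 25.0)
        with pytest.raises(ValueError, match="onset 0"):
            extract_epochs(ts, [0.0])

    def test_slices_match_direct_indexing(self):
        values = np.arange(5000.0)
        ts = TimeSeries(values, 25.0)
        epochs = extract_epochs(ts, [20.0, 100.0])
        np.testing.assert_array_equal(epochs[0].values, values[15 * 25 : 40 * 25])
        np.testing.assert_array_equal(epochs[1].values, values[95 * 25 : 120 * 25])


class TestSmoothNormalize:
    def test_unit_std(self, rng):
        epoch = TimeSeries(rng.standard_normal(625), 25.0)
        out = smooth_normalize(epoch)
        assert np.std(out.values) == pytest.approx(1.0, abs=1e-12)

    def test_constant_epoch_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            smooth_normalize(TimeSeries(np.ones(625), 25.0))

    def test_smoothing_raises_autocorrelation(self, rng):
        x = rng.standard_normal(625)
        epoch = TimeSeries(x, 25.0)
        out = smooth_normalize(epoch).values

        def lag1(v):
            v = v - v.mean()
            return np.dot(v[:-1], v[1:]) / np.dot(v, v)

        assert lag1(out) > lag1(x)


class TestSelectChannels:
    def _pulse(self, n=1000, fs=25.0):
        values = np.zeros(n)
        values[100:400] = 1.0
        return TimeSeries(values, fs)

    def test_negated_pulse_selected(self):
        pulse = self._pulse()
        env = pulse.copy_with(-pulse.values)
        eeg_ids, _ = select_channels(
            {"e1": env}, {"n1": pulse.copy_with(pulse.values)}, pulse
        )
        assert eeg_ids == ["e1"]

    def test_weak_hbo_excluded(self):
        pulse = self._pulse()
        weak = pulse.copy_with(0.4 * pulse.values)  # max swing 0.4 uM
        strong = pulse.copy_with(0.8 * pulse.values)
        _, nirs_ids = select_channels(
            {"e1": pulse.copy_with(-pulse.values)},
            {"weak": weak, "strong": strong},
            pulse,
        )
        assert nirs_ids == ["strong"]

    def test_ranking_matches_brute_force(self, rng):
        pulse = self._pulse()
        envs = {}
        for i in range(5):
            mix = rng.uniform(0.2, 1.0)
            noise = rng.standard_normal(len(pulse))
            envs[f"e{i}"] = pulse.copy_with(-mix * pulse.values + (1 - mix) * noise)
        eeg_ids, _ = select_channels(
            envs, {"n0": pulse.copy_with(pulse.values)}, pulse, r_min=0.0
        )
        brute = sorted(
            envs,
            key=lambda k: -abs(np.corrcoef(envs[k].values, pulse.values)[0, 1]),
        )
        assert eeg_ids == brute

    def test_empty_selection_warns(self):
        pulse = self._pulse()
        with pytest.warns(UserWarning):
            select_channels({}, {}, pulse)


class TestLinearityAndChain:
    @pytest.mark.parametrize(
        "op",
        [
            lambda ts: butterworth_filter(ts, (5.0, 14.0), 4, "bandpass"),
            lambda ts: downsample(ts, 25.0),
            lambda ts: ts.copy_with(moving_average(ts.values, 30)),
        ],
        ids=["bandpass", "downsample", "moving_average"],
    )
    def test_linearity(self, op, rng):
        fs = 256.0
        x = TimeSeries(rng.standard_normal(2560), fs)
        y = TimeSeries(rng.standard_normal(2560), fs)
        alpha, beta = 2.5, -1.25
        combined = op(TimeSeries(alpha * x.values + beta * y.values, fs))
        separate = alpha * op(x).values + beta * op(y).values
        scale = np.max(np.abs(separate)) or 1.0
        np.testing.assert_allclose(combined.values, separate, atol=1e-9 * scale)

    def test_full_eeg_chain_recovers_envelope(self, small_dataset, small_sim_cfg):
        ds = small_dataset
        band = butterworth_filter(ds.eeg, (5.0, 14.0), 4, "bandpass")
        imfs, residual = emd(band, max_imfs=1)
        imf1 = imfs[0] if imfs else residual
        env = downsample(hilbert_envelope(imf1), small_sim_cfg.nirs_fs)
        n = min(len(env), len(ds.true_envelope))
        target = np.abs(ds.true_envelope.values[:n])
        fs = small_sim_cfg.nirs_fs
        interior = slice(int(2 * fs), n - int(2 * fs))
        r = np.corrcoef(env.values[interior], target[interior])[0, 1]
        assert r > 0.95
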