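"""Filter chain: decimation, notch/band-pass responses, normalization,
end-to-end mains rejection, causality and streaming equivalence."""

import numpy as np
import pytest

import emgrec as er
from emgrec import PreprocessConfig, Recording
from emgrec.preprocess import CHAIN_STAGES, build_calibration


CFG = PreprocessConfig()


def _sine(freq, fs, dur=2.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _rec3(x, fs):
    return Recording(np.vstack([x, x, x]), fs)


def _steady_rms(x, skip_frac=0.5):
    tail = x[int(len(x) * skip_frac):]
    return np.sqrt(np.mean(tail**2))


def _dft_amplitude(x, freq, fs):
    """Single-bin DFT amplitude oracle at an exact bin frequency."""
    n = len(x)
    k = int(round(freq * n / fs))
    return 2 * np.abs(np.fft.rfft(x)[k]) / n


class TestDownsample:
    def test_length_arithmetic(self):
        rec = _rec3(np.zeros(40_000), 20_000)
        out = er.downsample(rec, 1000.0, CFG)
        assert out.fs == 1000.0 and out.n_samples == 2000

    def test_inband_tone_amplitude_preserved(self):
        """100 Hz unit tone survives decimation with amplitude within 2%,
        checked by a single-bin DFT."""
        rec = _rec3(_sine(100, 20_000, dur=4.0), 20_000)
        out = er.downsample(rec, 1000.0, CFG)
        tail = out.samples[0, out.n_samples // 2:]
        assert abs(_dft_amplitude(tail, 100, 1000.0) - 1.0) < 0.02

    def test_identity_when_rate_matches(self):
        rec = _rec3(np.random.default_rng(0).standard_normal(500), 1000.0)
        out = er.downsample(rec, 1000.0, CFG)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            er.downsample(_rec3(np.zeros(100), 1500.0), 1000.0, CFG)


class TestNotch:
    def test_50hz_attenuated_30db(self):
        rec = _rec3(_sine(50, 1000, dur=4.0), 1000.0)
        out = er.notch(rec, CFG)
        ratio = _steady_rms(out.samples[0]) / _steady_rms(rec.samples[0])
        assert 20 * np.log10(ratio) <= -30

    def test_dc_passes(self):
        rec = _rec3(np.full(2000, 0.7), 1000.0)
        out = er.notch(rec, CFG)
        assert abs(np.mean(out.samples[0][-500:]) / 0.7 - 1) < 0.01

    def test_100hz_gain_near_unity(self):
        rec = _rec3(_sine(100, 1000, dur=4.0), 1000.0)
        out = er.notch(rec, CFG)
        gain = _steady_rms(out.samples[0]) / _steady_rms(rec.samples[0])
        assert abs(gain - 1) < 0.05

    def test_wrong_rate_rejected(self):
        with pytest.raises(ValueError):
            er.notch(_rec3(np.zeros(100), 2000.0), CFG)
        with pytest.raises(ValueError):
            PreprocessConfig(notch_freq=600.0)  # at/above Nyquist


class TestBandpass:
    def test_5hz_attenuated(self):
        rec = _rec3(_sine(5, 1000, dur=6.0), 1000.0)
        out = er.bandpass(rec, CFG)
        ratio = _steady_rms(out.samples[0]) / _steady_rms(rec.samples[0])
        assert 20 * np.log10(ratio) <= -12

    def test_200hz_passband_gain(self):
        rec = _rec3(_sine(200, 1000, dur=4.0), 1000.0)
        out = er.bandpass(rec, CFG)
        gain = _steady_rms(out.samples[0]) / _steady_rms(rec.samples[0])
        assert abs(gain - 1) < 0.10

    def test_zero_in_zero_out(self):
        out = er.bandpass(_rec3(np.zeros(1000), 1000.0), CFG)
        assert np.all(out.samples == 0)

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(band_low=0.0)
        with pytest.raises(ValueError):
            PreprocessConfig(band_high=600.0)


class TestNormalize:
    def test_constant_at_calibration_max_becomes_ones(self):
        calib = er.CalibrationProfile(max_abs=np.array([0.5, 0.5, 0.5]))
        rec = _rec3(np.full(100, 0.5), 1000.0)
        out = er.normalize(rec, calib)
        assert np.all(out.samples == 1.0)

    def test_clipping_contract(self):
        calib = er.CalibrationProfile(max_abs=np.array([1.0, 1.0, 1.0]))
        rec = _rec3(np.linspace(-2, 2, 101), 1000.0)
        out = er.normalize(rec, calib)
        assert out.samples.max() == 1.0 and out.samples.min() == -1.0
        assert np.all(np.abs(out.samples) <= 1.0)

    def test_self_calibration_max_is_one(self, rng):
        x = rng.standard_normal((3, 500))
        rec = Recording(x, 1000.0)
        calib = er.CalibrationProfile(max_abs=np.max(np.abs(x), axis=1))
        out = er.normalize(rec, calib)
        # brute-force max over samples
        assert np.allclose(np.max(np.abs(out.samples), axis=1), 1.0)

    def test_zero_calibration_rejected(self):
        calib = er.CalibrationProfile(max_abs=np.array([1.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            er.normalize(_rec3(np.ones(10), 1000.0), calib)


class TestChain:
    def test_stage_order_contract(self):
        assert CHAIN_STAGES == ("downsample", "notch", "bandpass", "normalize")

    def test_end_to_end_mains_rejection(self):
        """A trial with a strong 50 Hz line loses >= 25 dB of 50 Hz power
        through the chain (pre/post periodogram ratio at the mains bin)."""
        params = er.SynthParams(mains_amplitude=0.5)
        rec = er.make_trial("EF", params, seed=13)
        calib = build_calibration(
            er.make_contraction_calibration(params, seed=14), None, CFG)
        out = er.run_chain(rec, CFG, calib)

        def line_power(x, fs):
            freqs = np.fft.rfftfreq(len(x), 1 / fs)
            spec = np.abs(np.fft.rfft(x))**2 / len(x)
            return spec[np.abs(freqs - 50) <= 1].sum()

        for ch in range(3):
            # compare normalized shapes: scale out by calibration max_abs
            pre = line_power(rec.samples[ch], rec.fs)
            post = line_power(out.samples[ch] * calib.max_abs[ch], out.fs)
            assert 10 * np.log10(post / pre) <= -25

    def test_all_zero_passthrough(self):
        calib = er.CalibrationProfile(max_abs=np.ones(3))
        rec = _rec3(np.zeros(20_000), 20_000.0)
        out = er.run_chain(rec, CFG, calib)
        assert np.all(out.samples == 0) and out.fs == 1000.0

    def test_second_pass_near_identity_inband(self):
        """Re-running the chain on already-clean 1 kHz content changes an
        in-band tone's steady-state gain by < 10%."""
        calib = er.CalibrationProfile(max_abs=np.ones(3))
        rec = _rec3(_sine(200, 1000, dur=4.0, amp=0.5), 1000.0)
        once = er.run_chain(rec, CFG, calib)
        twice = er.run_chain(once, CFG, calib)
        gain = _steady_rms(twice.samples[0]) / _steady_rms(once.samples[0])
        assert abs(gain - 1) < 0.10

    def test_causality_truncation_equivalence(self, rng):
        """Filtering a prefix equals the prefix of filtering the whole:
        no output sample depends on future input."""
        x = rng.standard_normal((3, 30_000))
        calib = er.CalibrationProfile(max_abs=np.ones(3))
        full = er.run_chain(Recording(x, 20_000.0), CFG, calib)
        half = er.run_chain(Recording(x[:, :15_000], 20_000.0), CFG, calib)
        np.testing.assert_allclose(full.samples[:, :half.n_samples],
                                   half.samples, atol=1e-12)

    def test_linearity_before_normalization(self, rng):
        x = rng.standard_normal((3, 10_000))
        a = 3.7
        stages = lambda r: er.bandpass(er.notch(er.downsample(r, 1000.0, CFG), CFG), CFG)
        out1 = stages(Recording(x, 20_000.0))
        out2 = stages(Recording(a * x, 20_000.0))
        np.testing.assert_allclose(out2.samples, a * out1.samples, rtol=1e-9)


class TestStreaming:
    @pytest.mark.parametrize("chunk", [1, 7, 300, 1024])
    def test_streaming_equals_batch(self, rng, chunk):
        x = rng.standard_normal((3, 20_000))
        calib = er.CalibrationProfile(max_abs=np.full(3, 2.0))
        batch = er.run_chain(Recording(x, 20_000.0), CFG, calib)
        sp = er.StreamingPreprocessor(20_000.0, 3, CFG, calib)
        parts = [sp.process(x[:, i:i + chunk]) for i in range(0, x.shape[1], chunk)]
        streamed = np.concatenate([p for p in parts if p.size], axis=1)
        np.testing.assert_allclose(streamed, batch.samples, atol=1e-13)

    def test_streaming_at_target_rate(self, rng):
        x = rng.standard_normal((3, 3000))
        calib = er.CalibrationProfile(max_abs=np.ones(3))
        batch = er.run_chain(Recording(x, 1000.0), CFG, calib)
        sp = er.StreamingPreprocessor(1000.0, 3, CFG, calib)
        streamed = np.concatenate([sp.process(c) for c in np.array_split(x, 11, axis=1)], axis=1)
        np.testing.assert_allclose(streamed, batch.samples, atol=1e-13)
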