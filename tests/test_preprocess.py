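"""Unit and property tests for the signal-conditioning chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecgident as eid
from ecgident.preprocess import iir_notch

from conftest import make_template

FS = 500.0


def steady_rms(x, fs=FS, skip_s=0.5):
    """RMS after discarding the filter transient at both ends."""
    n = int(skip_s * fs)
    core = np.asarray(x)[n:-n]
    return math.sqrt(float(np.mean(core * core)))


class TestRemoveBaseline:
    @pytest.mark.parametrize(
        "signal,expected",
        [([5, 5, 5, 5], [0, 0, 0, 0]), ([1, 2, 3], [-1, 0, 1])],
    )
    def test_forced_examples(self, signal, expected):
        np.testing.assert_allclose(eid.remove_baseline(signal), expected, atol=1e-12)

    def test_random_signal_mean_annihilated(self):
        # independent oracle: pairwise (cascade) summation of the output
        rng = np.random.default_rng(7)
        x = rng.normal(3.0, 2.0, size=1000)
        out = eid.remove_baseline(x)
        assert abs(math.fsum(out)) / len(out) < 1e-9 * x.std()

    def test_empty_rejected(self):
        with pytest.raises(eid.InvalidInputError):
            eid.remove_baseline([])


class TestPowerline:
    def test_zero_signal_maps_to_zero(self):
        out = eid.suppress_powerline(np.zeros(1000), FS)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_mains_tone_attenuated_20db(self):
        t = np.arange(int(4 * FS)) / FS
        tone = np.sin(2 * np.pi * 50 * t)
        out = eid.suppress_powerline(tone, FS)
        assert steady_rms(out) <= 0.1 * steady_rms(tone)

    @pytest.mark.parametrize("freq", [10.0, 100.0])
    def test_passband_preserved_within_1db(self, freq):
        t = np.arange(int(4 * FS)) / FS
        tone = np.sin(2 * np.pi * freq * t)
        out = eid.suppress_powerline(tone, FS)
        ratio = steady_rms(out) / steady_rms(tone)
        assert 10 ** (-1 / 20) <= ratio <= 10 ** (1 / 20)

    def test_notch_above_nyquist_rejected(self):
        with pytest.raises(eid.InvalidConfigError):
            eid.suppress_powerline(np.ones(100), 80.0)

    def test_iir_notch_variant_kills_mains(self):
        t = np.arange(int(4 * FS)) / FS
        tone = np.sin(2 * np.pi * 50 * t)
        out = iir_notch(tone, FS)
        assert steady_rms(out) <= 0.1 * steady_rms(tone)


class TestHighpass:
    def test_constant_offset_removed(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=int(6 * FS))
        a = eid.highpass_filter(x, FS)
        b = eid.highpass_filter(x + 3.0, FS)
        n = int(0.5 * FS)
        np.testing.assert_allclose(a[n:-n], b[n:-n], atol=1e-6)

    def test_passband_tone_amplitude_preserved(self):
        # long tone: the 0.5 Hz filter settles over seconds, so the
        # steady-state segment must sit well inside the record
        t = np.arange(int(20 * FS)) / FS
        tone = np.sin(2 * np.pi * 40 * t)
        out = eid.highpass_filter(tone, FS)
        peak = np.max(np.abs(out[int(5 * FS): -int(5 * FS)]))
        assert abs(peak - 1.0) < 0.05

    def test_zero_signal(self):
        np.testing.assert_allclose(eid.highpass_filter(np.zeros(800), FS), 0.0, atol=1e-12)

    def test_nonfinite_rejected(self):
        x = np.ones(500)
        x[10] = np.nan
        with pytest.raises(eid.InvalidInputError):
            eid.highpass_filter(x, FS)


class TestMinMax:
    @pytest.mark.parametrize(
        "signal,expected",
        [([0, 5, 10], [-1, 0, 1]), ([-1, 1], [-1, 1])],
    )
    def test_affine_examples(self, signal, expected):
        np.testing.assert_allclose(eid.minmax_normalize(signal), expected, atol=1e-12)

    def test_exact_bounds(self):
        out = eid.minmax_normalize(np.random.default_rng(1).normal(size=500))
        assert out.min() == -1.0 and out.max() == 1.0

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50).filter(lambda v: max(v) > min(v)))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, values):
        once = eid.minmax_normalize(values)
        twice = eid.minmax_normalize(once)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(eid.DegenerateInputError):
            eid.minmax_normalize([2.0, 2.0, 2.0])


class TestPipelineComposition:
    def test_range_and_mains_suppression(self):
        tpl = make_template(bpm=72)
        rec, _ = eid.synthesize_record(
            tpl, 20, FS, eid.NoiseSpec(baseline_amp=0.2, powerline_amp=0.3, white_sigma=0.0, seed=4)
        )
        clean = eid.preprocess_record(rec)
        assert clean.samples.min() == -1.0 and clean.samples.max() == 1.0
        assert clean.samples.size == rec.samples.size
        # discrete-Fourier magnitude at the 50 Hz bin, interior window
        n = int(2 * FS)
        seg_in = rec.samples[n:-n] - rec.samples[n:-n].mean()
        seg_out = clean.samples[n:-n] - clean.samples[n:-n].mean()
        freqs = np.fft.rfftfreq(seg_in.size, 1 / FS)
        bin50 = np.argmin(np.abs(freqs - 50.0))
        amp_in = np.abs(np.fft.rfft(seg_in))[bin50] / np.max(np.abs(np.fft.rfft(seg_in)))
        amp_out = np.abs(np.fft.rfft(seg_out))[bin50] / np.max(np.abs(np.fft.rfft(seg_out)))
        assert amp_out <= amp_in / 10

    def test_rpeak_ordinals_unchanged_on_clean_train(self):
        tpl = make_template(bpm=60, rr_jitter_ms=0.0)
        rec, truth = eid.synthesize_record(tpl, 20, FS, eid.NoiseSpec.none())
        clean = eid.preprocess_record(rec)
        # argmax-per-window oracle around each planted peak
        half = int(0.15 * FS)
        for r in truth:
            lo, hi = max(0, r - half), min(clean.samples.size, r + half)
            assert abs(lo + np.argmax(clean.samples[lo:hi]) - r) <= 1

    def test_constant_record_rejected(self):
        rec = eid.RawRecord(samples=np.zeros(4000), fs=FS, subject_id="x")
        with pytest.raises(eid.DegenerateInputError):
            eid.preprocess_record(rec)


class TestLinearity:
    @pytest.mark.parametrize("op", ["baseline", "notch", "highpass"])
    def test_filters_linear_on_random_pairs(self, op):
        rng = np.random.default_rng(11)
        func = {
            "baseline": eid.remove_baseline,
            "notch": lambda x: eid.suppress_powerline(x, FS),
            "highpass": lambda x: eid.highpass_filter(x, FS),
        }[op]
        for _ in range(5):
            x, y = rng.normal(size=(2, 1500))
            a, b = rng.normal(size=2)
            lhs = func(a * x + b * y)
            rhs = a * func(x) + b * func(y)
            np.testing.assert_allclose(lhs, rhs, atol=1e-6 * max(1, abs(a) + abs(b)))

    @pytest.mark.parametrize("op", ["baseline", "notch", "highpass"])
    def test_length_preserved(self, op):
        func = {
            "baseline": eid.remove_baseline,
            "notch": lambda x: eid.suppress_powerline(x, FS),
            "highpass": lambda x: eid.highpass_filter(x, FS),
        }[op]
        x = np.random.default_rng(2).normal(size=1234)
        assert func(x).size == x.size
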