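"""Spectral timing: peak accuracy, Weber law, envelope, duration windows."""

import numpy as np
import pytest

from songmem.spectral_timing import (ConditioningProtocol, ISIRangeError,
                                     NoDurationError, SpectrumConfig,
                                     TimingSpectrum, population_output,
                                     spectral_response, timed_duration, train)
from conftest import trained_spectrum


class TestSpectralResponse:
    def test_zero_at_stimulus_onset(self):
        assert spectral_response(2.0, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_faster_cells_peak_earlier(self):
        t = np.linspace(0.001, 5.0, 2000)
        g_fast = spectral_response(8.0, t)
        g_slow = spectral_response(2.0, t)
        assert t[np.argmax(g_fast)] < t[np.argmax(g_slow)]

    def test_gated_signal_is_unimodal(self):
        t = np.linspace(0.001, 6.0, 3000)
        g = spectral_response(3.0, t)
        above = g > 0.02 * g.max()
        sign = np.sign(np.diff(g[above]))
        changes = np.sum(np.abs(np.diff(sign[sign != 0])) > 0)
        assert changes <= 1

    def test_spectrum_peak_times_cover_configured_range(self):
        sp = TimingSpectrum()
        assert sp.peak_times[0] == pytest.approx(sp.config.min_peak_time, rel=0.05)
        assert sp.peak_times[-1] == pytest.approx(sp.config.max_peak_time, rel=0.05)
        assert np.all(np.diff(sp.rates) < 0)  # later peaks = slower rates


class TestTraining:
    def test_zero_trials_leave_weights_unchanged(self):
        sp = TimingSpectrum()
        z0 = sp.weights.copy()
        train(sp, ConditioningProtocol(ISI=0.4, n_trials=0))
        assert np.array_equal(sp.weights, z0)

    def test_learning_concentrates_at_the_isi(self, spectrum_400ms):
        best_cell = int(np.argmax(spectrum_400ms.weights))
        assert spectrum_400ms.peak_times[best_cell] == pytest.approx(0.4, rel=0.1)

    def test_more_trials_never_reduce_total_weight(self):
        totals = []
        for n in (1, 3, 5, 10):
            sp = TimingSpectrum()
            train(sp, ConditioningProtocol(ISI=0.5, n_trials=n))
            totals.append(sp.weights.sum())
        assert all(b >= a for a, b in zip(totals, totals[1:]))

    def test_out_of_range_isi_raises(self):
        sp = TimingSpectrum()
        with pytest.raises(ISIRangeError):
            train(sp, ConditioningProtocol(ISI=50.0))


class TestPopulationOutput:
    def test_untrained_output_is_zero(self):
        sp = TimingSpectrum()
        out = population_output(sp, np.linspace(0.001, 2.0, 500))
        assert np.all(out.R == 0.0)

    def test_output_peaks_at_trained_isi(self, spectrum_400ms):
        t = np.arange(1, 2001) / 1000.0
        out = population_output(spectrum_400ms, t)
        peak = t[np.argmax(out.R)]
        assert abs(peak - 0.4) / 0.4 <= 0.05

    @pytest.mark.parametrize("isi", [0.2, 0.4, 0.6, 0.8, 1.0])
    def test_peak_accuracy_across_isi_grid(self, isi):
        sp = trained_spectrum(isi)
        t = np.linspace(0.001, 4 * isi, 3000)
        out = population_output(sp, t)
        assert abs(t[np.argmax(out.R)] - isi) / isi <= 0.05

    def test_weber_law_width_grows_with_isi(self):
        widths = []
        for isi in (0.2, 0.4, 0.8, 1.6):
            sp = trained_spectrum(isi)
            t = np.linspace(0.001, 4 * isi, 4000)
            R = population_output(sp, t).R
            half = t[R >= 0.5 * R.max()]
            widths.append(half[-1] - half[0])
        assert all(b > a for a, b in zip(widths, widths[1:]))

    def test_amplitude_envelope_is_inverted_u(self):
        amps = []
        for isi in (0.06, 0.2, 2.0, 4.0):
            sp = trained_spectrum(isi)
            t = np.linspace(0.001, max(4 * isi, 0.5), 3000)
            amps.append(population_output(sp, t).R.max())
        assert amps[1] > amps[0]   # rising limb below the fastest peak time
        assert amps[1] > amps[2] > amps[3]  # falling limb toward slow edge


class TestTimedDuration:
    def test_zero_output_raises_no_duration(self):
        sp = TimingSpectrum()
        out = population_output(sp, np.linspace(0.001, 1.0, 200))
        with pytest.raises(NoDurationError):
            timed_duration(out)

    def test_threshold_above_peak_raises_no_duration(self, spectrum_400ms):
        out = population_output(spectrum_400ms, np.arange(1, 2001) / 1000.0)
        with pytest.raises(NoDurationError):
            timed_duration(out, threshold=2 * out.R.max())

    @pytest.mark.parametrize("beats", [1, 2, 4])
    def test_window_rounds_to_notated_beats(self, beats):
        """An interval of n beat periods is recalled as n beats."""
        beat = 0.5
        sp = trained_spectrum(beats * beat)
        t = np.linspace(0.001, 3.5 * beats * beat, 4000)
        out = population_output(sp, t)
        d = timed_duration(out, beat_period=beat)
        assert d["duration_beats"] == beats

    def test_window_brackets_the_peak(self, spectrum_400ms):
        t = np.arange(1, 2001) / 1000.0
        out = population_output(spectrum_400ms, t)
        d = timed_duration(out)
        assert d["start"] < 0.4 < d["end"]

    def test_ltd_convention_reports_identical_window(self, spectrum_400ms):
        t = np.arange(1, 2001) / 1000.0
        out_exc = population_output(spectrum_400ms, t, convention="excitatory_R")
        out_ltd = population_output(spectrum_400ms, t, convention="inverted_LTD")
        d1, d2 = timed_duration(out_exc), timed_duration(out_ltd)
        assert d1["start"] == pytest.approx(d2["start"], abs=1e-9)
        assert d1["end"] == pytest.approx(d2["end"], abs=1e-9)

    def test_disinhibition_equals_learned_signal(self, spectrum_400ms):
        out = population_output(spectrum_400ms, np.arange(1, 1001) / 1000.0,
                                convention="inverted_LTD")
        assert np.allclose(out.disinhibition, out.R)


def test_small_spectrum_rejected():
    with pytest.raises(ValueError):
        TimingSpectrum(config=SpectrumConfig(n_cells=10))
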