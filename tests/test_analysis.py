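import numpy as np
import pytest

from phonosim.analysis import (
    VoiceMetrics,
    dominant_frequency,
    phase_average,
    pod,
    quarter_wave_formants,
    spectrum,
    waveform_metrics,
)


class TestFormants:
    def test_default_tract_values(self):
        f = quarter_wave_formants(0.174, 352.0, 3)
        assert np.allclose(f, [505.747, 1517.241, 2528.736], atol=0.01)
        assert [int(v) for v in f] == [505, 1517, 2528]

    def test_linear_in_sound_speed(self):
        f1 = quarter_wave_formants(0.2, 340.0, 4)
        f2 = quarter_wave_formants(0.2, 680.0, 4)
        assert np.allclose(f2, 2 * f1)

    def test_quarter_wavelength_tube(self):
        assert quarter_wave_formants(0.25, 1.0, 1)[0] == pytest.approx(1.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            quarter_wave_formants(-1.0, 340.0)


class TestSpectrum:
    def test_pure_tone_peak_within_a_bin(self):
        fs, f0 = 10000.0, 200.0
        t = np.arange(4096) / fs
        freq, amp = spectrum(np.sin(2 * np.pi * f0 * t), fs)
        assert abs(freq[np.argmax(amp)] - f0) <= freq[1]
        assert amp.max() == pytest.approx(1.0, rel=0.05)

    def test_dominant_of_two_tones(self):
        fs = 10000.0
        t = np.arange(8192) / fs
        s = 1.0 * np.sin(2 * np.pi * 200 * t) + 2.0 * np.sin(2 * np.pi * 600 * t)
        assert dominant_frequency(s, fs) == pytest.approx(600, abs=fs / 8192)

    def test_multi_tone_matches_direct_dft(self):
        rng = np.random.default_rng(11)
        fs, n = 2000.0, 512
        t = np.arange(n) / fs
        comps = [(125.0, 0.7), (250.0, 1.3), (437.5, 0.4)]  # exact bin centers
        s = sum(a * np.cos(2 * np.pi * f * t) for f, a in comps)
        freq, amp = spectrum(s, fs, window=None)
        # oracle: direct DFT summation at each component bin
        for f0, a0 in comps:
            k = int(round(f0 * n / fs))
            direct = abs(np.sum(s * np.exp(-2j * np.pi * k * np.arange(n) / n))) / n * 2
            assert amp[k] == pytest.approx(direct, rel=1e-9)
            assert amp[k] == pytest.approx(a0, rel=1e-9)

    def test_parseval_energy_identity(self):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(1024)
        freq, amp = spectrum(s, 1.0, window=None)
        # one-sided amplitudes back to total power
        power = amp[0] ** 2 + 0.5 * np.sum(amp[1:] ** 2)
        if s.size % 2 == 0:  # Nyquist bin is not doubled
            power += 0.5 * amp[-1] ** 2 - 0.25 * amp[-1] ** 2 * 2
        assert power == pytest.approx(np.mean(s**2), rel=1e-2)


class TestPhaseAverage:
    def test_periodic_signal_reproduced(self):
        fs, f0 = 50000.0, 200.0
        t = np.arange(int(20 * fs / f0)) / fs
        s = np.sin(2 * np.pi * f0 * t) + 0.3 * np.sin(4 * np.pi * f0 * t)
        centers, avg = phase_average(t, s, f0, n_bins=100)
        expected = np.sin(2 * np.pi * centers) + 0.3 * np.sin(4 * np.pi * centers)
        assert np.abs(avg - expected).max() < 0.02  # piecewise-constant bins

    def test_noise_variance_shrinks_with_cycles(self):
        rng = np.random.default_rng(2)
        fs, f0, n_cycles = 20000.0, 100.0, 100
        t = np.arange(int(n_cycles * fs / f0)) / fs
        clean = np.cos(2 * np.pi * f0 * t)
        noisy = clean + rng.standard_normal(t.size)
        _, avg = phase_average(t, noisy, f0, n_bins=50)
        _, clean_avg = phase_average(t, clean, f0, n_bins=50)
        residual = np.nanvar(avg - clean_avg)
        # each bin averages ~n_cycles*samples_per_bin_cycle noise samples
        per_bin = t.size / 50
        assert residual < 3.0 / per_bin

    def test_constant_signal_constant_bins(self):
        t = np.linspace(0, 1, 5000)
        _, avg = phase_average(t, np.full_like(t, 3.3), 40.0, n_bins=32)
        assert np.allclose(avg, 3.3)


class TestWaveformMetrics:
    @staticmethod
    def _record(t, opening, q_inc, q_total=None):
        return {
            "t": t,
            "opening": opening,
            "q_inc": q_inc,
            "q_total": q_inc if q_total is None else q_total,
        }

    def test_square_wave_opening_recovers_f0_and_open_quotient(self):
        fs, f0, duty = 100000.0, 200.0, 0.60
        t = np.arange(int(40 * fs / f0)) / fs
        phase = (t * f0) % 1.0
        opening = np.where(phase < duty, 1.0e-3, 1.0e-4)
        q = np.where(phase < duty, 3.0e-4, 0.0) * np.sin(np.pi * phase / duty) ** 2
        m = waveform_metrics(self._record(t, opening, q))
        assert m.F0 == pytest.approx(f0, rel=0.01)
        assert m.tau0 == pytest.approx(duty, abs=0.015)

    def test_asymmetric_triangle_skewness(self):
        # 2 ms rise, 1 ms fall -> skewness quotient 2.0
        fs = 200000.0
        T, rise = 3.0e-3, 2.0e-3
        t = np.arange(int(30 * T * fs)) / fs
        phase = (t / T) % 1.0
        q = np.where(phase < rise / T, phase / (rise / T), (1 - phase) / (1 - rise / T))
        opening = 1e-3 * (0.5 + 0.5 * np.sin(2 * np.pi * phase))
        m = waveform_metrics(self._record(t, opening, q * 1e-4))
        assert m.F0 == pytest.approx(1 / T, rel=0.01)
        assert m.tau_s == pytest.approx(2.0, rel=0.05)

    def test_polynomial_pulse_train_all_metrics(self):
        # glottal-style pulse q(s) = s^2 (1 - s) on the open fraction of the
        # cycle; closed-form: peak at s = 2/3, rise/fall = 2, mean/max known
        fs, f0, oq = 200000.0, 150.0, 0.6
        T = 1.0 / f0
        t = np.arange(int(50 * T * fs)) / fs
        phase = (t * f0) % 1.0
        s = np.clip(phase / oq, 0.0, 1.0)
        pulse = np.where(phase < oq, s**2 * (1 - s), 0.0)
        q_max = (2 / 3) ** 2 * (1 / 3)  # max of s^2(1-s)
        scale = 3.0e-4 / q_max  # peak flow 300 mL/s in m^3/s
        q = pulse * scale
        opening = np.where(phase < oq, np.sin(np.pi * s) * 1e-3, 0.0) + 2e-4
        m = waveform_metrics(self._record(t, opening, q))
        assert m.F0 == pytest.approx(f0, rel=0.02)
        # mean of s^2(1-s) over the cycle: oq * (1/3 - 1/4)
        q_mean = scale * oq * (1 / 3 - 1 / 4)
        assert m.Q_mean == pytest.approx(q_mean * 1e6, rel=0.02)
        assert m.Q_max == pytest.approx(300.0, rel=0.02)
        # the open threshold sits 5% of the range above the minimum, which
        # shaves sin(pi s) flanks: tau0 = oq * (1 - (2/pi) asin(0.05))
        tau0_expect = oq * (1 - 2 / np.pi * np.arcsin(0.05))
        assert m.tau0 == pytest.approx(tau0_expect, abs=0.01)
        # rise/fall quotient with the 1%-of-peak onset threshold: solve
        # s^2(1-s) = 0.01 q_max for the onset and end of the pulse
        from scipy.optimize import brentq

        f = lambda s: s**2 * (1 - s) - 0.01 * q_max
        s0 = brentq(f, 1e-6, 2 / 3)
        s1 = brentq(f, 2 / 3, 1 - 1e-9)
        expected = (2 / 3 - s0) / (s1 - 2 / 3)
        assert m.tau_s == pytest.approx(expected, rel=0.05)

    def test_aperiodic_signal_rejected(self):
        rng = np.random.default_rng(0)
        t = np.arange(5000) / 1e4
        sig = rng.standard_normal(5000) * 1e-5 + 1e-3
        with pytest.raises(ValueError, match="aperiodic"):
            waveform_metrics(self._record(t, sig, sig))

    def test_quotients_invariant_to_amplitude_scaling(self):
        fs, f0 = 100000.0, 120.0
        t = np.arange(int(25 * fs / f0)) / fs
        phase = (t * f0) % 1.0
        opening = 1e-3 * np.maximum(np.sin(2 * np.pi * phase), 0.05)
        q = 1e-4 * np.maximum(np.sin(2 * np.pi * phase) ** 2, 0.0)
        m1 = waveform_metrics(self._record(t, opening, q))
        m2 = waveform_metrics(self._record(t, 7.5 * opening, 3.2 * q))
        assert m1.tau0 == pytest.approx(m2.tau0, abs=1e-12)
        # one-bin slack: the onset threshold is a knife edge under scaling
        assert m1.tau_s == pytest.approx(m2.tau_s, rel=0.05)

    def test_metric_invariants_enforced(self):
        with pytest.raises(ValueError):
            VoiceMetrics(F0=0.0, Q_mean=1, Q_max=2, tau0=0.5, tau_s=1.0)
        with pytest.raises(ValueError):
            VoiceMetrics(F0=100.0, Q_mean=3, Q_max=2, tau0=0.5, tau_s=1.0)
        with pytest.raises(ValueError):
            VoiceMetrics(F0=100.0, Q_mean=1, Q_max=2, tau0=1.5, tau_s=1.0)


class TestPOD:
    def test_rank_one_field(self):
        rng = np.random.default_rng(1)
        shape = rng.standard_normal(40)
        a = np.sin(np.linspace(0, 20, 150))
        snaps = np.outer(a, shape)
        r = pod(snaps)
        assert r.energy[0] == pytest.approx(1.0, abs=1e-10)
        # coefficients proportional to a(t) (mean removed)
        ac = a - a.mean()
        corr = np.corrcoef(r.coefficients[:, 0], ac)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)

    def test_two_orthogonal_modes_energy_split(self):
        rng = np.random.default_rng(4)
        n_dof = 64
        q, _ = np.linalg.qr(rng.standard_normal((n_dof, 2)))
        a1 = rng.standard_normal(4000) * np.sqrt(7.0)
        a2 = rng.standard_normal(4000) * np.sqrt(3.0)
        snaps = np.outer(a1, q[:, 0]) + np.outer(a2, q[:, 1])
        r = pod(snaps, n_modes=2)
        assert r.energy[0] == pytest.approx(0.7, abs=0.02)
        assert r.energy[1] == pytest.approx(0.3, abs=0.02)

    def test_modes_orthonormal_and_energy_sums_to_one(self, rng):
        snaps = rng.standard_normal((30, 20))
        r = pod(snaps)
        gram = r.modes @ r.modes.T
        assert np.allclose(gram, np.eye(len(r.energy)), atol=1e-10)
        assert r.energy.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(r.energy) <= 1e-12)

    def test_full_reconstruction(self, rng):
        snaps = rng.standard_normal((25, 40))
        r = pod(snaps)
        rec = r.reconstruct()
        assert np.abs(rec - snaps).max() < 1e-10 * np.abs(snaps).max()

    def test_identical_snapshots_rejected(self):
        snaps = np.ones((10, 5))
        with pytest.raises(ValueError, match="rank"):
            pod(snaps)
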