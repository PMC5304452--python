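"""Derived quantities of a phonation run.

Covers the standard voice-source measures (fundamental frequency, mean and
peak flow, open quotient, skewness quotient), spectra and phase averages of
glottal waveforms, the quarter-wave resonator formula for an open-closed
tube, and snapshot proper orthogonal decomposition (POD) of the vocal fold
vibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VoiceMetrics",
    "PODResult",
    "quarter_wave_formants",
    "spectrum",
    "dominant_frequency",
    "phase_average",
    "waveform_metrics",
    "pod",
]

ML_PER_M3 = 1.0e6


@dataclass
class VoiceMetrics:
    """Glottal-waveform summary.

    F0 in Hz, flows in mL/s; tau0 = open fraction of the cycle; tau_s =
    flow rise duration over fall duration (computed from the
    incompressible flow component).
    """

    F0: float
    Q_mean: float
    Q_max: float
    tau0: float
    tau_s: float

    def __post_init__(self) -> None:
        if not (self.F0 > 0):
            raise ValueError("F0 must be positive")
        if self.Q_max < self.Q_mean:
            raise ValueError("Q_max must be >= Q_mean")
        if not (0 < self.tau0 <= 1):
            raise ValueError("tau0 must lie in (0, 1]")
        if not (self.tau_s > 0):
            raise ValueError("tau_s must be positive")

    def as_dict(self) -> dict:
        return {
            "F0_Hz": self.F0,
            "Q_mean_mL_per_s": self.Q_mean,
            "Q_max_mL_per_s": self.Q_max,
            "open_quotient": self.tau0,
            "skewness_quotient": self.tau_s,
        }


@dataclass
class PODResult:
    mean: np.ndarray          # (n_dof,)
    modes: np.ndarray         # (n_modes, n_dof), orthonormal rows
    energy: np.ndarray        # (n_modes,), fractions of total variance
    coefficients: np.ndarray  # (n_snapshots, n_modes)

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        k = self.modes.shape[0] if k is None else k
        return self.mean + self.coefficients[:, :k] @ self.modes[:k]


# ---------------------------------------------------------------------------


def quarter_wave_formants(L: float, c: float, n_max: int = 3) -> np.ndarray:
    """Resonances F_n = (2n - 1) c / (4 L) of an open-closed tube, n = 1..n_max."""
    if L <= 0 or c <= 0 or n_max < 1:
        raise ValueError("L, c must be positive and n_max >= 1")
    n = np.arange(1, n_max + 1)
    return (2 * n - 1) * c / (4.0 * L)


def spectrum(series: np.ndarray, sample_rate: float, window: str = "hann"):
    """One-sided amplitude spectrum of a time series.

    Returns ``(frequency, amplitude)`` with the window's coherent gain
    compensated, so a unit-amplitude sine reports amplitude ~1 at its bin.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 64:
        raise ValueError("need at least 64 samples for a spectrum")
    n = series.size
    if window == "hann":
        w = np.hanning(n)
    elif window in (None, "boxcar"):
        w = np.ones(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    coherent_gain = w.mean()
    spec = np.fft.rfft(series * w) / (n * coherent_gain)
    amp = np.abs(spec)
    amp[1:] *= 2.0  # fold negative frequencies
    freq = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    return freq, amp


def dominant_frequency(
    series: np.ndarray,
    sample_rate: float,
    f_min: float = 0.0,
    detrend: bool = True,
) -> float:
    """Frequency of the largest spectral peak, parabolically interpolated."""
    series = np.asarray(series, dtype=float)
    if detrend:
        series = series - series.mean()
    freq, amp = spectrum(series, sample_rate)
    sel = freq >= max(f_min, freq[1] * 0.5)
    idx = np.flatnonzero(sel)
    k = idx[np.argmax(amp[idx])]
    if 0 < k < len(amp) - 1 and amp[k] > 0:
        a, b, c = np.log(np.maximum(amp[k - 1 : k + 2], 1e-300))
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float((k + delta) * (freq[1] - freq[0]))


def _autocorr_f0(series: np.ndarray, sample_rate: float) -> float:
    s = series - series.mean()
    ac = np.correlate(s, s, mode="full")[s.size - 1 :]
    # first maximum after the first zero crossing
    below = np.flatnonzero(ac < 0)
    if below.size == 0:
        raise ValueError("aperiodic signal: autocorrelation never decays")
    k = below[0] + np.argmax(ac[below[0] :])
    return sample_rate / float(k)


def phase_average(
    t: np.ndarray, signals: dict | np.ndarray, F0: float, n_bins: int = 64
):
    """Fold samples into phase [0, 1) at frequency F0 and bin-average.

    ``signals`` may be a single array or a mapping of name -> array.
    Returns ``(phase_centers, averaged)`` with ``averaged`` matching the
    input structure.
    """
    t = np.asarray(t, dtype=float)
    phase = (t * F0) % 1.0
    bins = np.clip((phase * n_bins).astype(int), 0, n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    counts[counts == 0] = np.nan

    def avg(sig):
        return np.bincount(bins, weights=np.asarray(sig, float), minlength=n_bins) / counts

    centers = (np.arange(n_bins) + 0.5) / n_bins
    if isinstance(signals, dict):
        return centers, {k: avg(v) for k, v in signals.items()}
    return centers, avg(signals)


def _rise_fall_quotient(phase_wave: np.ndarray) -> float:
    """Rise/fall duration ratio of a single (circular) cycle waveform.

    Rise runs from the pulse onset (last near-minimum bin before the
    peak) to the peak; fall from the peak to the next near-minimum bin,
    so a flat closed phase does not count toward either duration.
    """
    n = phase_wave.size
    k_max = int(np.argmax(phase_wave))
    lo, hi = phase_wave.min(), phase_wave.max()
    if hi <= lo:
        raise ValueError("degenerate waveform: no distinct rise/fall phases")
    # normalize before thresholding so amplitude scaling cancels
    near_min = (phase_wave - lo) / (hi - lo) <= 0.01
    if not near_min.any() or near_min.all():
        raise ValueError("degenerate waveform: no distinct rise/fall phases")
    # circular scan backward from the peak for the onset ...
    rise = 0
    for step in range(1, n):
        if near_min[(k_max - step) % n]:
            rise = step
            break
    # ... and forward for the end of the fall
    fall = 0
    for step in range(1, n):
        if near_min[(k_max + step) % n]:
            fall = step
            break
    if rise == 0 or fall == 0:
        raise ValueError("degenerate waveform: no distinct rise/fall phases")
    return rise / fall


def waveform_metrics(record, n_cycles: int | None = None, n_bins: int = 200) -> VoiceMetrics:
    """Voice-source metrics from a glottal record.

    ``record`` needs attributes/keys ``t`` (s), ``opening`` (m),
    ``q_total`` and ``q_inc`` (m^3/s).  F0 is taken from the periodicity of
    the opening signal (flow-rate periodicity is contaminated by acoustic
    ripples); tau0 from the opening waveform with an open threshold of the
    cycle minimum plus 5% of the peak-to-min range (robust to the small
    artificial leakage gap); tau_s from the phase-averaged incompressible
    flow rate.  Flow values are reported in mL/s.
    """
    t = np.asarray(_get(record, "t"), dtype=float)
    opening = np.asarray(_get(record, "opening"), dtype=float)
    q_total = np.asarray(_get(record, "q_total"), dtype=float)
    q_inc = np.asarray(_get(record, "q_inc"), dtype=float)
    if t.size < 64:
        raise ValueError("record too short for waveform metrics")
    fs = 1.0 / np.mean(np.diff(t))

    freq, amp = spectrum(opening - opening.mean(), fs)
    # background level: upper decile of the spectrum, robust against the
    # heavy tail of broadband noise
    background = np.percentile(amp[1:], 90)
    if amp[1:].max() < 3.0 * max(background, 1e-300):
        raise ValueError("aperiodic signal: no spectral peak 3x above background")
    F0 = dominant_frequency(opening, fs)

    if n_cycles is not None:
        t_keep = t[-1] - n_cycles / F0
        sel = t >= t_keep
        t, opening, q_total, q_inc = t[sel], opening[sel], q_total[sel], q_inc[sel]

    _, op_phase = phase_average(t, opening, F0, n_bins)
    _, qi_phase = phase_average(t, q_inc, F0, n_bins)
    op_phase = op_phase[~np.isnan(op_phase)]
    qi_phase = qi_phase[~np.isnan(qi_phase)]

    op_min, op_max = op_phase.min(), op_phase.max()
    threshold = op_min + 0.05 * (op_max - op_min)
    tau0 = float(np.count_nonzero(op_phase > threshold)) / op_phase.size
    tau_s = _rise_fall_quotient(qi_phase)

    return VoiceMetrics(
        F0=float(F0),
        Q_mean=float(q_total.mean() * ML_PER_M3),
        Q_max=float(q_total.max() * ML_PER_M3),
        tau0=tau0,
        tau_s=float(tau_s),
    )


def _get(record, key):
    if hasattr(record, key):
        return getattr(record, key)
    return record[key]


# ---------------------------------------------------------------------------


def pod(snapshots: np.ndarray, n_modes: int | None = None) -> PODResult:
    """Snapshot proper orthogonal decomposition.

    ``snapshots`` is (n_snapshots, n_dof); the temporal mean is removed,
    the fluctuation matrix decomposed by SVD (equivalent to the snapshot-
    covariance eigenproblem), and energies reported as fractions of the
    total fluctuation variance.
    """
    X = np.asarray(snapshots, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 snapshots of a consistent node set")
    mean = X.mean(axis=0)
    Xc = X - mean
    total = float(np.sum(Xc * Xc))
    if total <= 1e-28 * max(1.0, float(np.sum(X * X))):
        raise ValueError("rank-deficient snapshot set: all snapshots identical")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = s**2
    lam_total = lam.sum()
    keep = lam > lam[0] * 1e-24
    if n_modes is not None:
        keep[n_modes:] = False
    U, s, Vt, lam = U[:, keep], s[keep], Vt[keep], lam[keep]
    return PODResult(
        mean=mean,
        modes=Vt,
        energy=lam / lam_total,
        coefficients=U * s,
    )
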