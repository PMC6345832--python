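"""Morlet-wavelet time-frequency decomposition, trial averaging, and
condition-specific relative baseline correction.

The wavelet at centre frequency ``f`` is a complex exponential under a
Gaussian envelope of temporal SD ``sigma_t = n_cycles / (2*pi*f)``,
normalized to unit energy, so white noise yields frequency-flat expected
power. Power is the squared magnitude of the complex convolution, sampled
on a regular output time grid. Samples within 3 sigma_t of an epoch edge
are marked invalid (NaN) rather than zero-filled; downstream statistics
avoid them by analyzing the 1-3 s retention window.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .containers import EpochSet, TimeFrequencyMap, TrialPower

__all__ = [
    "default_freqs",
    "morlet_transform",
    "average_power",
    "baseline_correct",
    "wavelet_sigma_t",
    "wavelet_response",
]


def default_freqs(fmin: float = 4.0, fmax: float = 30.0, step: float = 0.5) -> np.ndarray:
    """The 4-30 Hz grid in 0.5 Hz steps."""
    return np.arange(fmin, fmax + step / 2, step)


def wavelet_sigma_t(freq: float, n_cycles: float) -> float:
    """Temporal SD of the Gaussian envelope at ``freq``."""
    return n_cycles / (2 * np.pi * freq)


def wavelet_response(f: np.ndarray, f0: float, n_cycles: float) -> np.ndarray:
    """Closed-form magnitude of the unit-energy wavelet's Fourier transform.

    |psi_hat(f)| = (4*pi*sigma_t^2)^(1/4) * exp(-2*pi^2*sigma_t^2*(f-f0)^2),
    a Gaussian of spectral SD sigma_f = f0 / n_cycles around the centre
    frequency. Used by the synthetic-data calibration and by tests.
    """
    st = wavelet_sigma_t(f0, n_cycles)
    return (4 * np.pi * st**2) ** 0.25 * np.exp(-2 * np.pi**2 * st**2 * (np.asarray(f) - f0) ** 2)


def _morlet_kernel(freq: float, n_cycles: float, sfreq: float) -> np.ndarray:
    """Discrete unit-energy complex Morlet wavelet sampled at sfreq,
    truncated at 5 sigma_t."""
    st = wavelet_sigma_t(freq, n_cycles)
    half = int(np.ceil(5 * st * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * st**2))
    w /= np.sqrt(np.sum(np.abs(w) ** 2) / sfreq)  # unit energy: sum |w|^2 dt = 1
    return w


def morlet_transform(
    epochs: EpochSet,
    freqs: np.ndarray | None = None,
    n_cycles: float = 4.0,
    time_step: float = 0.008,
    edge_sigmas: float = 3.0,
) -> TrialPower:
    """Single-trial wavelet power on a channel x frequency x time grid.

    Parameters
    ----------
    epochs : EpochSet
        Trial segments; the epoch must be longer than ``2*edge_sigmas``
        wavelet SDs at the lowest frequency, otherwise no valid samples
        would remain.
    freqs : array, optional
        Analysis frequencies in Hz; default 4-30 Hz in 0.5 Hz steps.
        Must lie strictly inside (0, Nyquist).
    n_cycles : float
        Wavelet width in cycles (sigma_t = n_cycles / (2 pi f)).
    time_step : float
        Output grid step in seconds; rounded to a whole number of input
        samples.
    """
    freqs = default_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    sfreq = epochs.sampling_rate
    nyq = sfreq / 2
    if np.any(freqs <= 0) or np.any(freqs >= nyq):
        raise ValueError(f"analysis frequencies must lie in (0, {nyq}) Hz")
    duration = (epochs.n_times - 1) / sfreq
    min_len = 2 * edge_sigmas * wavelet_sigma_t(freqs.min(), n_cycles)
    if duration <= min_len:
        raise ValueError(
            f"epoch of {duration:.3f} s too short for {freqs.min()} Hz: "
            f"needs > {min_len:.3f} s ({2 * edge_sigmas} wavelet SDs)"
        )
    step = max(1, int(round(time_step * sfreq)))
    keep = np.arange(0, epochs.n_times, step)
    times_out = epochs.t0 + keep / sfreq

    n_trials, n_ch, n_times = epochs.data.shape
    dt = 1.0 / sfreq
    kernels = [_morlet_kernel(f, n_cycles, sfreq) for f in freqs]
    nfft = next_fast_len(n_times + max(len(k) for k in kernels) - 1)

    x = epochs.data.reshape(n_trials * n_ch, n_times)
    power = np.empty((n_trials * n_ch, len(freqs), len(keep)))
    chunk = max(1, int(2e7 // nfft))  # bound scratch memory
    for lo in range(0, x.shape[0], chunk):
        X = fft(x[lo : lo + chunk], nfft, axis=1)
        for fi, k in enumerate(kernels):
            K = fft(k, nfft)
            y = ifft(X * K[None, :], axis=1)
            off = (len(k) - 1) // 2  # 'same' alignment of the full convolution
            y = y[:, off : off + n_times][:, keep]
            power[lo : lo + chunk, fi, :] = (np.abs(y) * dt) ** 2

    power = power.reshape(n_trials, n_ch, len(freqs), len(keep))
    t_start, t_end = epochs.times[0], epochs.times[-1]
    for fi, f in enumerate(freqs):
        margin = edge_sigmas * wavelet_sigma_t(f, n_cycles)
        bad = (times_out < t_start + margin) | (times_out > t_end - margin)
        power[:, :, fi, bad] = np.nan

    return TrialPower(
        power=power,
        freqs=freqs,
        times=times_out,
        sample_onset=epochs.sample_onset,
        condition=epochs.condition.copy(),
        subject_id=epochs.subject_id,
        channel_names=epochs.channel_names,
    )


def average_power(trial_power: TrialPower) -> dict:
    """Arithmetic mean of single-trial power within each condition.

    Returns a mapping ``condition -> TimeFrequencyMap`` (baseline state
    "raw"). Invalid (NaN) edge samples propagate through the mean.
    """
    out = {}
    for cond in trial_power.conditions():
        sel = trial_power.condition == cond
        if not sel.any():
            continue
        out[cond] = TimeFrequencyMap(
            power=trial_power.power[sel].mean(axis=0),
            freqs=trial_power.freqs.copy(),
            times=trial_power.times.copy(),
            baseline_state="raw",
            n_trials=int(sel.sum()),
            condition=str(cond),
            subject_id=trial_power.subject_id,
            channel_names=trial_power.channel_names,
            sample_onset=trial_power.sample_onset,
        )
    if not out:
        raise ValueError("no trials to average")
    return out


def baseline_correct(
    tfr: TimeFrequencyMap,
    baseline_window: tuple = (-0.150, -0.050),
    mode: str = "relative-change",
) -> TimeFrequencyMap:
    """Condition-specific relative baseline correction.

    ``P_rel(t) = (P(t) - P_b) / P_b`` per channel and frequency, with
    ``P_b`` the mean raw power over the baseline window (given in seconds
    relative to *sample-array onset*; the study uses 150-50 ms before the
    sample array). ``mode="ratio"`` yields the pure ratio ``P / P_b``
    instead. Raises if the map is already corrected, if the window is not
    fully covered by valid samples, or if any baseline mean is
    non-positive.
    """
    if mode not in ("relative-change", "ratio"):
        raise ValueError(f"unknown baseline mode {mode!r}")
    if tfr.baseline_state != "raw":
        raise ValueError("map is already baseline-corrected")
    lo = tfr.sample_onset + baseline_window[0]
    hi = tfr.sample_onset + baseline_window[1]
    sel = (tfr.times >= lo - 1e-9) & (tfr.times <= hi + 1e-9)
    if not sel.any():
        raise ValueError(
            f"baseline window [{lo:.3f}, {hi:.3f}] s contains no samples of the time grid"
        )
    base = tfr.power[:, :, sel]
    if np.isnan(base).any():
        raise ValueError("baseline window overlaps invalid edge samples")
    pb = base.mean(axis=2, keepdims=True)
    if np.any(pb <= 0):
        raise ValueError("baseline power is zero; cannot normalize")
    if mode == "ratio":
        return tfr.copy_with(power=tfr.power / pb, baseline_state="ratio")
    return tfr.copy_with(power=(tfr.power - pb) / pb, baseline_state="relative-change")
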