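"""Synthetic study generator: behavior, EEG epochs, and structural scalars.

The generator emulates the statistical structure the analysis chain
assumes, so every downstream stage is testable without any recording:

* Behavior follows an equal-variance Gaussian signal-detection model with
  criterion c: a change trial is a hit with probability Phi(d'/2 - c) and
  a no-change trial a false alarm with probability Phi(-d'/2 - c), so the
  generator's inverse model matches the d' scorer's forward model by
  construction. Reaction times are shifted log-normal with load-specific
  location.
* EEG epochs are 1/f^beta background noise (synthesized in the frequency
  domain with random phases, independent per channel, then smoothed once
  over the sensor adjacency graph) plus an oscillatory component:
  band-pass-filtered white noise whose amplitude switches at retention
  onset. The retention amplitude is calibrated per subject and load —
  through the closed-form wavelet response to the known noise and
  oscillation spectra — so that the measured relative power change from
  the pre-sample baseline equals the configured target in expectation.
* Structural scalars (age, gray matter, tract connectivity) are drawn
  from a multivariate normal matched to a target correlation matrix,
  conditioning on the already-generated d' and power columns, which are
  left byte-identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import CONDITIONING_VARIABLES, SimulationConfig
from .containers import EpochSet, TrialOutcomes
from .errors import ConfigurationError
from .layout import SensorLayout
from .seeding import child_rng
from .spectral import wavelet_response

__all__ = [
    "subject_ids",
    "generate_behavior",
    "subject_relchange",
    "generate_eeg",
    "generate_structure",
    "null_condition_maps",
]


def subject_ids(cfg: SimulationConfig) -> list:
    return [f"S{i:02d}" for i in range(cfg.n_subjects)]


# ---------------------------------------------------------------------------
# behavior


def _subject_dprime_targets(cfg: SimulationConfig, s_idx: int) -> dict:
    """Per-subject target d' per load: population mean plus a subject
    ability factor shared across loads plus a load-specific deviation."""
    rng = child_rng(cfg.seed, "ability", s_idx)
    shared = rng.standard_normal()
    out = {}
    for load in cfg.loads:
        load_specific = rng.standard_normal()
        sh = cfg.dprime_shared_frac
        out[load] = cfg.target_dprime_by_load[load] + cfg.dprime_subject_sd * (
            np.sqrt(sh) * shared + np.sqrt(1 - sh) * load_specific
        )
    return out


def generate_behavior(cfg: SimulationConfig) -> TrialOutcomes:
    """Simulate the change-detection task for every subject and load.

    Returns a :class:`TrialOutcomes` whose ``trials`` attribute holds the
    trial-level table (subject_id, load, trial_type, response, correct,
    rt_ms). Reproducible for a fixed config seed.
    """
    if cfg.trials_per_load % 2:
        raise ValueError("trials_per_load must be even")
    half = cfg.trials_per_load // 2
    rows = []
    for s_idx, sid in enumerate(subject_ids(cfg)):
        rng = child_rng(cfg.seed, "behavior", s_idx)
        targets = _subject_dprime_targets(cfg, s_idx)
        rt_subject = rng.normal(0.0, cfg.rt_subject_sd)
        for load in cfg.loads:
            d = targets[load]
            p_hit = stats.norm.cdf(d / 2 - cfg.criterion)
            p_fa = stats.norm.cdf(-d / 2 - cfg.criterion)
            trial_type = np.array(["change"] * half + ["no-change"] * half)
            rng.shuffle(trial_type)
            is_change = trial_type == "change"
            said_change = np.where(
                is_change,
                rng.random(cfg.trials_per_load) < p_hit,
                rng.random(cfg.trials_per_load) < p_fa,
            )
            loc = cfg.rt_location_by_load[load]
            mu = np.log(loc - cfg.rt_shift_ms) + rt_subject
            rt = cfg.rt_shift_ms + np.exp(rng.normal(mu, cfg.rt_sigma, cfg.trials_per_load))
            for k in range(cfg.trials_per_load):
                resp = "change" if said_change[k] else "no-change"
                rows.append(
                    {
                        "subject_id": sid,
                        "load": load,
                        "trial_type": trial_type[k],
                        "response": resp,
                        "correct": bool(resp == trial_type[k]),
                        "rt_ms": float(rt[k]),
                    }
                )
    return TrialOutcomes.from_trials(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# EEG


def _spectrum_bin_variances(amp: np.ndarray, n: int) -> np.ndarray:
    """Per-positive-bin variance contributions of a signal synthesized by
    irfft of ``amp``-scaled unit phasors, after normalization to unit
    total variance."""
    a2 = amp**2
    weights = 2 * a2
    weights[0] = 0.0
    if n % 2 == 0:
        weights[-1] = a2[-1]
    total = weights.sum() / n**2
    return (weights / n**2) / total  # sums to 1


class _EegCalibration:
    """Expected wavelet band power of the background and the unit-variance
    oscillation, used to solve for retention amplitudes."""

    def __init__(self, cfg: SimulationConfig, n_cycles: float = 4.0):
        n = cfg.n_samples
        f = np.fft.rfftfreq(n, 1.0 / cfg.sampling_rate)
        with np.errstate(divide="ignore"):
            noise_amp = np.where(f > 0, f, np.inf) ** (-cfg.noise_exponent / 2)
        noise_amp[0] = 0.0
        lo, hi = cfg.oscillation_band
        osc_amp = ((f >= lo) & (f <= hi)).astype(float)
        if osc_amp.sum() < 2:
            raise ConfigurationError("oscillation band contains fewer than two FFT bins")
        self.bin_freqs = f
        self.noise_amp = noise_amp
        self.osc_amp = osc_amp
        v_noise = _spectrum_bin_variances(noise_amp, n)
        v_osc = _spectrum_bin_variances(osc_amp, n)
        probe = np.arange(lo, hi + 0.25, 0.5)  # band probed in 0.5 Hz steps
        resp2 = np.array([wavelet_response(f, f0, n_cycles) ** 2 for f0 in probe])
        self.p_noise = 0.5 * resp2 @ v_noise  # expected power per probe freq
        self.p_osc = 0.5 * resp2 @ v_osc
        # baseline oscillation amplitude from the band signal-to-noise target
        self.a0 = float(
            np.sqrt(cfg.oscillation_snr * self.p_noise.mean() / self.p_osc.mean())
        )

    def retention_amplitude(self, relchange: float) -> float:
        """Amplitude for which the band-mean relative power change from
        baseline equals ``relchange`` in expectation (closed form: the
        band-mean ratio is linear in amplitude^2)."""
        denom = self.p_noise + self.a0**2 * self.p_osc
        c_noise = float((self.p_noise / denom).mean())
        c_osc = float((self.p_osc / denom).mean())
        gamma2 = (1.0 + relchange - c_noise) / c_osc
        if gamma2 < -1e-9:
            raise ValueError(
                f"relative change {relchange} is below the background-noise floor"
            )
        gamma2 = max(gamma2, 0.0)
        return float(np.sqrt(gamma2))


def subject_relchange(cfg: SimulationConfig) -> pd.DataFrame:
    """Per-subject target relative power change per load (the latent
    oscillatory reactivity). Regenerable independently of the EEG draw:
    the same child seeds are used by :func:`generate_eeg`."""
    rows = []
    sh = cfg.relchange_shared_frac
    for s_idx, sid in enumerate(subject_ids(cfg)):
        rng = child_rng(cfg.seed, "relchange", s_idx)
        shared = rng.standard_normal()
        row = {"subject_id": sid}
        for load in cfg.loads:
            load_specific = rng.standard_normal()
            r = cfg.oscillation_relchange_by_load[load] + cfg.relchange_subject_sd * (
                np.sqrt(sh) * shared + np.sqrt(1 - sh) * load_specific
            )
            row[f"relchange_{load}"] = float(np.clip(r, -0.9, 4.0))
        rows.append(row)
    return pd.DataFrame(rows)


def _mixing_matrix(layout: SensorLayout, weight: float) -> np.ndarray:
    """One smoothing pass over the adjacency graph:
    x_i <- (1-w) x_i + w * mean of x over neighbors of i."""
    deg = layout.adjacency.sum(axis=1).astype(float)
    m = (1 - weight) * np.eye(layout.n_channels)
    m += weight * layout.adjacency / deg[:, None]
    return m


def _synth_trials(
    rng: np.random.Generator, amp: np.ndarray, n_trials: int, n_ch: int, n: int
) -> np.ndarray:
    """Unit-variance signals with spectral amplitude profile ``amp``,
    independent per trial and channel."""
    n_bins = len(amp)
    z = (rng.standard_normal((n_trials, n_ch, n_bins)) + 1j * rng.standard_normal((n_trials, n_ch, n_bins))) / np.sqrt(2)
    if n % 2 == 0:
        z[..., -1] = z[..., -1].real * np.sqrt(2)
    z[..., 0] = 0.0
    x = np.fft.irfft(z * amp, n, axis=-1)
    w = 2 * amp**2
    w[0] = 0.0
    if n % 2 == 0:
        w[-1] = amp[-1] ** 2
    return x / np.sqrt(w.sum() / n**2)


def generate_eeg(cfg: SimulationConfig, layout: SensorLayout) -> list:
    """Synthesize one :class:`EpochSet` per subject.

    Each trial is spatially smoothed 1/f^beta background noise plus a
    narrowband (theta-alpha by default) oscillation whose amplitude drops
    from its baseline value to a per-subject, per-load retention value at
    retention onset, so that the baseline-normalized band power change
    matches the configured (latent) relative change in expectation.
    """
    if layout.n_channels != cfg.n_channels:
        raise ValueError(
            f"layout has {layout.n_channels} channels, config expects {cfg.n_channels}"
        )
    cal = _EegCalibration(cfg)
    rel = subject_relchange(cfg).set_index("subject_id")
    mix = _mixing_matrix(layout, cfg.spatial_mixing)
    n = cfg.n_samples
    t0 = cfg.epoch_window[0]
    times = t0 + np.arange(n) / cfg.sampling_rate
    retention = times >= 0
    out = []
    for s_idx, sid in enumerate(subject_ids(cfg)):
        rng = child_rng(cfg.seed, "eeg", s_idx)
        blocks, labels = [], []
        for load in cfg.loads:
            gamma = cal.retention_amplitude(rel.loc[sid, f"relchange_{load}"])
            profile = np.where(retention, gamma, cal.a0)
            noise = _synth_trials(rng, cal.noise_amp, cfg.trials_per_load, cfg.n_channels, n)
            osc = _synth_trials(rng, cal.osc_amp, cfg.trials_per_load, cfg.n_channels, n)
            x = noise + profile[None, None, :] * osc
            x = np.einsum("ij,tjn->tin", mix, x)
            blocks.append(x)
            labels.extend([load] * cfg.trials_per_load)
        out.append(
            EpochSet(
                data=np.concatenate(blocks, axis=0),
                sampling_rate=cfg.sampling_rate,
                t0=t0,
                sample_onset=cfg.sample_onset,
                condition=np.array(labels),
                subject_id=sid,
                channel_names=layout.channel_names,
            )
        )
    return out


def null_condition_maps(
    n_subjects: int,
    layout: SensorLayout,
    n_freqs: int,
    n_times: int,
    seed: int,
    smooth_sigma: float = 1.5,
    mixing: float = 0.5,
) -> np.ndarray:
    """Exchangeable per-subject condition maps with no condition effect.

    Returns an array (subject, condition=2, channel, frequency, time) of
    smoothed Gaussian noise sharing the spatial and spectro-temporal
    correlation style of real baseline-corrected maps. Used for type-I
    calibration studies of the cluster permutation machinery, which
    operates at exactly this level.
    """
    rng = child_rng(seed, "nullmaps")
    x = rng.standard_normal((n_subjects, 2, layout.n_channels, n_freqs, n_times))
    x = ndimage.gaussian_filter1d(x, smooth_sigma, axis=3, mode="nearest")
    x = ndimage.gaussian_filter1d(x, smooth_sigma, axis=4, mode="nearest")
    mix = _mixing_matrix(layout, mixing)
    return np.einsum("ij,scjft->scift", mix, x)


# ---------------------------------------------------------------------------
# structure


def generate_structure(cfg: SimulationConfig, behavior_power: pd.DataFrame) -> pd.DataFrame:
    """Draw structural scalars conditioned on behavior and power columns.

    ``behavior_power`` must contain ``subject_id`` and the conditioning
    columns (d' and latent mask power for medium and high load). The new
    columns (age, gray matter, connectivity, mask sizes) are appended;
    pre-existing columns are returned untouched.
    """
    missing = [c for c in CONDITIONING_VARIABLES if c not in behavior_power.columns]
    if missing:
        raise ConfigurationError(f"behavior_power lacks conditioning columns {missing}")
    if behavior_power["subject_id"].duplicated().any():
        raise ConfigurationError("duplicated subject_id in behavior_power")
    names = list(cfg.structure_variables)
    existing = [v for v in names if v in CONDITIONING_VARIABLES]
    new = [v for v in names if v not in CONDITIONING_VARIABLES]
    r = cfg.structure_correlations
    ie = [names.index(v) for v in existing]
    inw = [names.index(v) for v in new]
    r_en = r[np.ix_(ie, inw)]
    r_nn = r[np.ix_(inw, inw)]

    x = behavior_power[existing].to_numpy(dtype=float)
    n = len(x)
    sd = x.std(axis=0, ddof=1)
    r_ee_cfg = r[np.ix_(ie, ie)]
    if np.any(sd == 0) or n < 3:
        # degenerate conditioning columns: fall back to the configured block
        z = np.zeros_like(x)
        r_ee = r_ee_cfg
    else:
        z = (x - x.mean(axis=0)) / sd
        # empirical correlation of the realized columns, so that target
        # new-vs-existing correlations are achieved without attenuation
        r_ee = np.corrcoef(z, rowvar=False)

    def conditional(r_ee_used):
        b = np.linalg.pinv(r_ee_used) @ r_en
        resid = r_nn - r_en.T @ b
        evals, evecs = np.linalg.eigh((resid + resid.T) / 2)
        return b, evals, evecs

    b, evals, evecs = conditional(r_ee)
    if evals.min() < -1e-10:
        # the empirical correlation of few subjects can be incompatible with
        # the configured targets; the configured block always yields a PSD
        # Schur complement
        b, evals, evecs = conditional(r_ee_cfg)
    if evals.min() < -1e-8:
        raise ConfigurationError(
            "conditional covariance is not positive semidefinite; "
            "the configured correlation targets are incompatible"
        )
    root = evecs * np.sqrt(np.clip(evals, 0, None))

    rng = child_rng(cfg.seed, "structure")
    u = rng.standard_normal((n, len(new)))
    new_z = z @ b + u @ root.T

    out = behavior_power.copy()
    for j, name in enumerate(new):
        out[name] = cfg.structure_means[name] + cfg.structure_sds[name] * new_z[:, j]
    for name in cfg.masksize_means:
        draw = rng.normal(cfg.masksize_means[name], cfg.masksize_sds[name], n)
        out[name] = np.maximum(np.round(draw), 200).astype(int)
    return out
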