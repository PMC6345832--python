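"""Configuration objects for the simulation and the analysis chain.

Two geometries ship with the package:

* ``scaled_down`` (the default): 12 subjects, 16 channels, 20 trials per
  load, epochs from −1.2 to +3.5 s around retention onset with the sample
  array onset at −0.5 s, a 20-point frequency grid from 4–30 Hz and a
  50 ms time grid. This geometry keeps every stage of the chain — and the
  simulation studies in the test suite — at desk scale.
* ``full_scale``: the study design proper — 31 subjects, 60 channels,
  60 trials per load, epochs −2.975…+4.0 s (725 ms pre-sample baseline
  period, 2250 ms sample array, 4 s retention), 0.5 Hz / 8 ms grids and
  1000 permutations.

The oscillatory effect is a load-dependent power decrease (event-related
desynchronization) in the 5–12 Hz theta-alpha band during retention,
expressed as a relative change from the pre-sample baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "AnalysisConfig",
    "PipelineConfig",
    "default_structure_correlations",
    "DEFAULT_ASSOCIATION_PLAN",
]

STRUCTURE_VARIABLES = (
    "age",
    "dprime_medium",
    "dprime_high",
    "power_medium",
    "power_high",
    "gm_phc",
    "gm_striatum_l",
    "gm_striatum_r",
    "conn_phc_parietal",
    "conn_phc_frontal",
    "conn_frontal_parietal",
)

# Columns that already exist when structural scalars are generated; the
# remaining variables are drawn conditionally on these.
CONDITIONING_VARIABLES = ("dprime_medium", "dprime_high", "power_medium", "power_high")

_DEFAULT_CORR_PAIRS = {
    # age couples negatively with performance and structure, and weakly
    # positively with retention power (less desynchronization with age)
    ("age", "dprime_medium"): -0.35,
    ("age", "dprime_high"): -0.40,
    ("age", "power_medium"): 0.15,
    ("age", "power_high"): 0.20,
    ("age", "gm_phc"): -0.35,
    ("age", "gm_striatum_l"): -0.30,
    ("age", "gm_striatum_r"): -0.30,
    ("age", "conn_phc_parietal"): -0.25,
    ("age", "conn_phc_frontal"): -0.25,
    ("age", "conn_frontal_parietal"): -0.25,
    ("dprime_medium", "dprime_high"): 0.60,
    ("power_medium", "power_high"): 0.60,
    # parahippocampal gray matter tracks accuracy, strongest under high load
    ("gm_phc", "dprime_medium"): 0.45,
    ("gm_phc", "dprime_high"): 0.60,
    ("gm_phc", "gm_striatum_l"): 0.35,
    ("gm_phc", "gm_striatum_r"): 0.35,
    ("gm_phc", "conn_phc_parietal"): 0.25,
    ("gm_phc", "conn_phc_frontal"): 0.25,
    ("gm_phc", "conn_frontal_parietal"): 0.10,
    # dorsal striatum tracks accuracy, strongest under medium load
    ("gm_striatum_l", "dprime_medium"): 0.60,
    ("gm_striatum_l", "dprime_high"): 0.40,
    ("gm_striatum_r", "dprime_medium"): 0.55,
    ("gm_striatum_r", "dprime_high"): 0.35,
    ("gm_striatum_l", "gm_striatum_r"): 0.70,
    ("gm_striatum_l", "conn_phc_parietal"): 0.15,
    ("gm_striatum_l", "conn_phc_frontal"): 0.15,
    ("gm_striatum_l", "conn_frontal_parietal"): 0.15,
    ("gm_striatum_r", "conn_phc_parietal"): 0.15,
    ("gm_striatum_r", "conn_phc_frontal"): 0.15,
    ("gm_striatum_r", "conn_frontal_parietal"): 0.15,
    # temporo-parietal connectivity couples negatively with retention power
    ("conn_phc_parietal", "power_medium"): -0.50,
    ("conn_phc_parietal", "power_high"): -0.30,
    ("conn_phc_frontal", "power_medium"): -0.25,
    ("conn_phc_frontal", "power_high"): -0.15,
    ("conn_phc_parietal", "conn_phc_frontal"): 0.35,
    ("conn_phc_parietal", "conn_frontal_parietal"): 0.35,
    ("conn_phc_frontal", "conn_frontal_parietal"): 0.35,
}

DEFAULT_STRUCTURE_MEANS = {
    "age": 67.3,
    "gm_phc": 0.55,
    "gm_striatum_l": 0.50,
    "gm_striatum_r": 0.50,
    "conn_phc_parietal": 0.35,
    "conn_phc_frontal": 0.30,
    "conn_frontal_parietal": 0.40,
}
DEFAULT_STRUCTURE_SDS = {
    "age": 6.2,
    "gm_phc": 0.08,
    "gm_striatum_l": 0.07,
    "gm_striatum_r": 0.07,
    "conn_phc_parietal": 0.12,
    "conn_phc_frontal": 0.10,
    "conn_frontal_parietal": 0.12,
}

# The study's correlation families: gray matter vs accuracy (two loads,
# alpha/2 per region) and tract connectivity vs power and accuracy
# (medium+high x power/accuracy, alpha/4).
DEFAULT_ASSOCIATION_PLAN = [
    {"x": "gm_phc", "y": "dprime_medium", "covariates": ["age"], "family_size": 2},
    {"x": "gm_phc", "y": "dprime_high", "covariates": ["age"], "family_size": 2},
    {"x": "gm_striatum_l", "y": "dprime_medium", "covariates": ["age"], "family_size": 2},
    {"x": "gm_striatum_l", "y": "dprime_high", "covariates": ["age"], "family_size": 2},
    {
        "x": "conn_phc_parietal",
        "y": "power_medium",
        "covariates": ["age", "masksize_parietal"],
        "family_size": 4,
    },
    {
        "x": "conn_phc_parietal",
        "y": "power_high",
        "covariates": ["age", "masksize_parietal"],
        "family_size": 4,
    },
    {
        "x": "conn_phc_parietal",
        "y": "dprime_medium",
        "covariates": ["age", "masksize_parietal"],
        "family_size": 4,
    },
    {
        "x": "conn_phc_parietal",
        "y": "dprime_high",
        "covariates": ["age", "masksize_parietal"],
        "family_size": 4,
    },
]


def default_structure_correlations() -> np.ndarray:
    """The default target correlation matrix over STRUCTURE_VARIABLES."""
    k = len(STRUCTURE_VARIABLES)
    idx = {v: i for i, v in enumerate(STRUCTURE_VARIABLES)}
    r = np.eye(k)
    for (a, b), v in _DEFAULT_CORR_PAIRS.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    return r


def validate_correlation_matrix(r: np.ndarray, names) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    k = len(names)
    if r.shape != (k, k):
        raise ConfigurationError(f"correlation matrix must be {k}x{k}")
    if not np.allclose(r, r.T, atol=1e-12):
        raise ConfigurationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(r), 1.0, atol=1e-12):
        raise ConfigurationError("correlation matrix must have unit diagonal")
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ConfigurationError("correlations must lie in [-1, 1]")
    eigmin = float(np.linalg.eigvalsh(r).min())
    if eigmin < -1e-10:
        raise ConfigurationError(
            f"correlation matrix is not positive semidefinite (min eig {eigmin:.3g})"
        )
    return r


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the scaled-down geometry; :meth:`full_scale` returns the
    study design proper (31 subjects, 60 channels, 60 trials per load).
    """

    n_subjects: int = 12
    trials_per_load: int = 20
    loads: tuple = ("low", "medium", "high")
    sampling_rate: float = 250.0
    n_channels: int = 16
    epoch_window: tuple = (-1.2, 3.5)  # s relative to retention onset
    sample_onset: float = -0.5  # sample-array onset, same axis
    baseline_window: tuple = (-0.150, -0.050)  # s relative to sample onset
    # behavior
    target_dprime_by_load: dict = field(
        default_factory=lambda: {"low": 3.0, "medium": 2.0, "high": 1.2}
    )
    dprime_subject_sd: float = 0.4
    dprime_shared_frac: float = 0.6  # shared across-load variance fraction
    criterion: float = 0.0
    rt_location_by_load: dict = field(
        default_factory=lambda: {"low": 560.0, "medium": 650.0, "high": 685.0}
    )
    rt_shift_ms: float = 250.0
    rt_sigma: float = 0.30
    rt_subject_sd: float = 0.15
    # EEG
    oscillation_band: tuple = (5.0, 12.0)
    oscillation_relchange_by_load: dict = field(
        default_factory=lambda: {"low": -0.05, "medium": -0.15, "high": -0.25}
    )
    relchange_subject_sd: float = 0.05
    relchange_shared_frac: float = 0.6
    oscillation_snr: float = 1.0  # baseline-band oscillatory/background power
    noise_exponent: float = 1.0  # beta of the 1/f^beta background
    spatial_mixing: float = 0.5  # one smoothing pass over the neighbor graph
    # structure
    structure_variables: tuple = STRUCTURE_VARIABLES
    structure_correlations: np.ndarray = field(default_factory=default_structure_correlations)
    structure_means: dict = field(default_factory=lambda: dict(DEFAULT_STRUCTURE_MEANS))
    structure_sds: dict = field(default_factory=lambda: dict(DEFAULT_STRUCTURE_SDS))
    masksize_means: dict = field(
        default_factory=lambda: {"masksize_parietal": 3000.0, "masksize_frontal": 2400.0}
    )
    masksize_sds: dict = field(
        default_factory=lambda: {"masksize_parietal": 450.0, "masksize_frontal": 360.0}
    )
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_load % 2:
            raise ValueError("trials_per_load must be even (half change / half no-change)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        t_lo, t_hi = self.epoch_window
        b_lo, b_hi = self.baseline_window
        if not b_lo < b_hi <= 0:
            raise ConfigurationError("baseline_window must lie strictly before sample onset")
        if not (t_lo <= self.sample_onset + b_lo and self.sample_onset + b_hi <= t_hi):
            raise ConfigurationError("epoch_window must contain the baseline window")
        if not (t_lo <= 1.0 and 3.0 <= t_hi):
            raise ConfigurationError("epoch_window must contain the 1-3 s analysis window")
        if not self.sample_onset < 0:
            raise ConfigurationError("sample onset must precede retention onset")
        for load in self.loads:
            v = self.oscillation_relchange_by_load[load]
            if not np.isfinite(v):
                raise ValueError(f"oscillation relchange for {load!r} must be finite")
            if v <= -1:
                raise ValueError("relative power change must be > -1")
            if not np.isfinite(self.target_dprime_by_load[load]):
                raise ValueError(f"target d' for {load!r} must be finite")
        lo, hi = self.oscillation_band
        if lo < 4.0 or hi > 30.0:
            warnings.warn(
                "oscillation_band extends outside the 4-30 Hz analysis range",
                stacklevel=2,
            )
        self.structure_correlations = validate_correlation_matrix(
            self.structure_correlations, self.structure_variables
        )

    @classmethod
    def full_scale(cls, **overrides) -> "SimulationConfig":
        kw = dict(
            n_subjects=31,
            trials_per_load=60,
            n_channels=60,
            epoch_window=(-2.975, 4.0),
            sample_onset=-2.25,
        )
        kw.update(overrides)
        return cls(**kw)

    @property
    def epoch_duration(self) -> float:
        return self.epoch_window[1] - self.epoch_window[0]

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_duration * self.sampling_rate)) + 1


@dataclass
class AnalysisConfig:
    """Parameters of the spectral and cluster-statistics stages."""

    freq_min: float = 4.0
    freq_max: float = 30.0
    n_freqs: int = 20
    n_cycles: float = 4.0
    time_step: float = 0.05  # s; full scale uses 0.008
    baseline_window: tuple = (-0.150, -0.050)  # s relative to sample onset
    analysis_window: tuple = (1.0, 3.0)  # s relative to retention onset
    contrast: tuple = ("high", "low")  # (A, B); the test examines A - B
    n_permutations: int = 500
    alpha: float = 0.025  # per direction (0.05 Bonferroni over 2 tails)
    cluster_alpha: float = 0.05  # sample-level cluster-forming threshold
    min_neighbor_channels: int = 3
    neighbor_radius: float = 0.70

    @property
    def freqs(self) -> np.ndarray:
        return np.linspace(self.freq_min, self.freq_max, self.n_freqs)

    @classmethod
    def full_scale(cls, **overrides) -> "AnalysisConfig":
        kw = dict(n_freqs=53, time_step=0.008, n_permutations=1000, neighbor_radius=0.35)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PipelineConfig:
    """One config drives the whole pipeline; a single seed derives every
    stage- and subject-level RNG."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    association_plan: list = field(default_factory=lambda: [dict(p) for p in DEFAULT_ASSOCIATION_PLAN])
    exclude_low_load: bool = True  # low-load d' excluded from correlations

    def __post_init__(self):
        self.simulation.seed = self.seed

    @classmethod
    def full_scale(cls, seed: int = 0) -> "PipelineConfig":
        return cls(
            seed=seed,
            simulation=SimulationConfig.full_scale(),
            analysis=AnalysisConfig.full_scale(),
        )

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "exclude_low_load": self.exclude_low_load,
            "simulation": asdict(self.simulation),
            "analysis": asdict(self.analysis),
            "association_plan": self.association_plan,
        }
        d["simulation"]["structure_correlations"] = self.simulation.structure_correlations.tolist()
        for key in ("loads", "epoch_window", "baseline_window", "oscillation_band", "structure_variables"):
            d["simulation"][key] = list(d["simulation"][key])
        for key in ("baseline_window", "analysis_window", "contrast"):
            d["analysis"][key] = list(d["analysis"][key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            sim = dict(d.get("simulation", {}))
            ana = dict(d.get("analysis", {}))
            for key in ("loads", "epoch_window", "baseline_window", "oscillation_band", "structure_variables"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "structure_correlations" in sim:
                sim["structure_correlations"] = np.asarray(sim["structure_correlations"], dtype=float)
            for key in ("baseline_window", "analysis_window", "contrast"):
                if key in ana:
                    ana[key] = tuple(ana[key])
            return cls(
                seed=int(d.get("seed", 0)),
                simulation=SimulationConfig(**sim),
                analysis=AnalysisConfig(**ana),
                association_plan=[dict(p) for p in d.get("association_plan", DEFAULT_ASSOCIATION_PLAN)],
                exclude_low_load=bool(d.get("exclude_low_load", True)),
            )
        except (TypeError, KeyError, ValueError, ConfigurationError) as e:
            if isinstance(e, ConfigurationError):
                raise
            raise ConfigurationError(f"invalid pipeline configuration: {e}") from e

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(d)
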