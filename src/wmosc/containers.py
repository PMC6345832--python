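"""In-memory containers passed between analysis stages.

Time conventions: all times are in seconds relative to retention onset
(t = 0 when the sample array disappears and maintenance begins). Each
container that needs it also carries ``sample_onset``, the time of sample
array onset on the same axis (negative), so that windows specified
relative to sample onset — the pre-sample baseline — can be resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EpochSet",
    "TrialPower",
    "TimeFrequencyMap",
    "TrialOutcomes",
    "AssociationResult",
]


@dataclass
class EpochSet:
    """Per-subject stack of trial segments (trial x channel x time, µV)."""

    data: np.ndarray
    sampling_rate: float
    t0: float  # time of first sample relative to retention onset (s)
    sample_onset: float  # sample-array onset relative to retention onset (s)
    condition: np.ndarray  # label per trial
    subject_id: str
    channel_names: tuple

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.condition = np.asarray(self.condition)
        if self.data.ndim != 3:
            raise ValueError("data must be (trial, channel, time)")
        if self.data.shape[0] != len(self.condition):
            raise ValueError("one condition label per trial required")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match data")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_times) / self.sampling_rate


def _check_grids(freqs, times):
    freqs = np.asarray(freqs, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly increasing")
    steps = np.diff(times)
    if len(steps) and (np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6)):
        raise ValueError("times must be strictly increasing with uniform step")
    return freqs, times


@dataclass
class TrialPower:
    """Single-trial wavelet power (trial x channel x frequency x time).

    Invalid edge samples (within 3 wavelet SDs of an epoch edge) are NaN.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    sample_onset: float
    condition: np.ndarray  # label per trial
    subject_id: str
    channel_names: tuple

    def __post_init__(self):
        self.freqs, self.times = _check_grids(self.freqs, self.times)
        if self.power.ndim != 4:
            raise ValueError("power must be (trial, channel, frequency, time)")

    def conditions(self):
        seen = []
        for c in self.condition:
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class TimeFrequencyMap:
    """Trial-averaged power (channel x frequency x time) for one subject
    and condition, either raw or expressed as relative change from the
    pre-sample baseline."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    baseline_state: str  # "raw" | "relative-change"
    n_trials: int
    condition: str
    subject_id: str
    channel_names: tuple
    sample_onset: float

    def __post_init__(self):
        self.freqs, self.times = _check_grids(self.freqs, self.times)
        if self.power.ndim != 3:
            raise ValueError("power must be (channel, frequency, time)")
        if self.baseline_state not in ("raw", "relative-change", "ratio"):
            raise ValueError(f"unknown baseline_state {self.baseline_state!r}")
        finite = self.power[np.isfinite(self.power)]
        lo = -1.0 if self.baseline_state == "relative-change" else 0.0
        if finite.size and finite.min() < lo - 1e-9:
            raise ValueError(f"{self.baseline_state} power below {lo}")

    def same_grid(self, other: "TimeFrequencyMap") -> bool:
        return (
            np.array_equal(self.freqs, other.freqs)
            and np.allclose(self.times, other.times)
            and self.channel_names == other.channel_names
        )

    def copy_with(self, **kw) -> "TimeFrequencyMap":
        return replace(self, **kw)


class TrialOutcomes:
    """Signal-detection counts and correct-trial reaction times per
    subject and load.

    ``counts`` is a DataFrame with columns subject_id, load, nh, nm, nfa,
    ncr; ``rt_correct`` maps (subject_id, load) to the reaction times (ms)
    of correct trials. ``trials`` optionally keeps the trial-level table
    (columns subject_id, load, trial_type, response, correct, rt_ms).
    """

    def __init__(self, counts: pd.DataFrame, rt_correct: dict, trials: pd.DataFrame | None = None):
        counts = counts.reset_index(drop=True)
        for col in ("nh", "nm", "nfa", "ncr"):
            if (counts[col] < 0).any():
                raise ValueError(f"negative count in column {col}")
        self.counts = counts
        self.rt_correct = {k: np.asarray(v, dtype=float) for k, v in rt_correct.items()}
        self.trials = trials
        for _, row in counts.iterrows():
            key = (row["subject_id"], row["load"])
            n_corr = int(row["nh"] + row["ncr"])
            if key in self.rt_correct and len(self.rt_correct[key]) != n_corr:
                raise ValueError(
                    f"rt_correct length for {key} is {len(self.rt_correct[key])}, "
                    f"expected NH+NCR={n_corr}"
                )

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "TrialOutcomes":
        """Aggregate a trial-level table into counts and correct-trial RTs."""
        rows = []
        rts = {}
        for (sid, load), g in trials.groupby(["subject_id", "load"], sort=True):
            change = g[g["trial_type"] == "change"]
            stay = g[g["trial_type"] == "no-change"]
            nh = int((change["response"] == "change").sum())
            nfa = int((stay["response"] == "change").sum())
            rows.append(
                {
                    "subject_id": sid,
                    "load": load,
                    "nh": nh,
                    "nm": len(change) - nh,
                    "nfa": nfa,
                    "ncr": len(stay) - nfa,
                }
            )
            rts[(sid, load)] = g.loc[g["correct"].astype(bool), "rt_ms"].to_numpy(dtype=float)
        return cls(pd.DataFrame(rows), rts, trials=trials)

    def subjects(self):
        return list(pd.unique(self.counts["subject_id"]))

    def loads(self):
        return list(pd.unique(self.counts["load"]))


@dataclass
class AssociationResult:
    """One partial-correlation test from the structure-function battery."""

    x_name: str
    y_name: str
    covariate_names: tuple
    r_partial: float
    df: int
    p: float
    n_used: int
    alpha_corrected: float
    significant: bool
    n_excluded: int = 0

    def __post_init__(self):
        if np.isfinite(self.r_partial) and abs(self.r_partial) > 1 + 1e-12:
            raise ValueError("|r_partial| must be <= 1")
        if self.df != self.n_used - 2 - len(self.covariate_names):
            raise ValueError("df must equal n_used - 2 - #covariates")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["covariate_names"] = list(self.covariate_names)
        return d
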