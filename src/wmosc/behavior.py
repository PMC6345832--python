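"""Change-detection scoring and load-effect statistics.

Sensitivity is d' = Phi^-1(HR) - Phi^-1(FAR) with the +0.5/+1 count
correction HR = (NH + 0.5)/(NH + NM + 1), FAR = (NFA + 0.5)/(NFA + NCR + 1),
which keeps both rates strictly inside (0, 1). Reaction time is summarized
as the per-subject median over correct trials only. The load effect is
tested with a classical one-way within-subject ANOVA
(F = MS_load / MS_(load x subject)) followed by planned paired t-tests at
a Bonferroni-corrected threshold, with a single-pass 3-SD outlier rule on
the per-subject scalars.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TrialOutcomes

__all__ = [
    "compute_dprime",
    "summarize_rt",
    "rm_anova",
    "planned_pairwise_tests",
    "sd_outlier_mask",
    "summarize_behavior",
]

log = logging.getLogger(__name__)


def compute_dprime(outcomes: TrialOutcomes) -> pd.DataFrame:
    """Corrected hit/false-alarm rates and d' per subject and load.

    Returns a DataFrame with columns subject_id, load, hr, far, dprime.
    Cells with zero change or zero no-change trials are undefined and
    raise ValueError.
    """
    c = outcomes.counts
    for col in ("nh", "nm", "nfa", "ncr"):
        if (c[col] < 0).any():
            raise ValueError(f"negative counts in {col}")
    n_change = c["nh"] + c["nm"]
    n_stay = c["nfa"] + c["ncr"]
    if (n_change == 0).any() or (n_stay == 0).any():
        raise ValueError("zero change or no-change trials in some cell; d' undefined")
    hr = (c["nh"] + 0.5) / (n_change + 1)
    far = (c["nfa"] + 0.5) / (n_stay + 1)
    return pd.DataFrame(
        {
            "subject_id": c["subject_id"],
            "load": c["load"],
            "hr": hr,
            "far": far,
            "dprime": stats.norm.ppf(hr) - stats.norm.ppf(far),
        }
    )


def summarize_rt(outcomes: TrialOutcomes) -> pd.DataFrame:
    """Median reaction time over correct trials per subject and load.

    Cells without any correct trial get NaN and a logged warning; the
    even-length median is the midpoint of the two central order
    statistics.
    """
    rows = []
    for _, row in outcomes.counts.iterrows():
        key = (row["subject_id"], row["load"])
        rts = outcomes.rt_correct.get(key, np.array([]))
        if len(rts) == 0:
            log.warning("no correct trials for subject %s load %s; cell excluded", *key)
            med = np.nan
        else:
            med = float(np.median(rts))
        rows.append({"subject_id": key[0], "load": key[1], "median_rt": med})
    return pd.DataFrame(rows)


def _wide(values: pd.DataFrame, column: str) -> pd.DataFrame:
    return values.pivot(index="subject_id", columns="load", values=column)


def rm_anova(table: np.ndarray | pd.DataFrame, sphericity_correction: bool = False) -> dict:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    Classical within-subject decomposition: the condition effect is tested
    against the condition-by-subject interaction,
    F = MS_cond / MS_(cond x subject), df = (k-1, (k-1)(n-1)). Sums of
    squares are returned for audit. Missing cells raise (no imputation).

    ``sphericity_correction=True`` additionally applies the
    Greenhouse-Geisser epsilon to the degrees of freedom of the p-value
    (off by default; the uncorrected test is the primary output either
    way, with df reported unscaled and ``epsilon``/``p_gg`` added).
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("table must be subjects x conditions")
    n, k = x.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if np.isnan(x).any():
        raise ValueError("missing cells; repeated-measures ANOVA requires complete data")
    grand = x.mean()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    f = ms_cond / ms_err if ms_err > 0 else (0.0 if ms_cond == 0 else np.inf)
    out = {
        "F": float(f),
        "df1": df1,
        "df2": df2,
        "p": float(stats.f.sf(f, df1, df2)),
        "ss_condition": float(ss_cond),
        "ss_subject": float(ss_subj),
        "ss_error": float(ss_err),
        "n": n,
        "k": k,
    }
    if sphericity_correction:
        # Greenhouse-Geisser epsilon from the double-centered covariance
        s = np.cov(x, rowvar=False, ddof=1)
        sc = s - s.mean(axis=0) - s.mean(axis=1)[:, None] + s.mean()
        eps = float(np.trace(sc) ** 2 / ((k - 1) * np.sum(sc**2)))
        eps = min(max(eps, 1.0 / (k - 1)), 1.0)
        out["epsilon"] = eps
        out["p_gg"] = float(stats.f.sf(f, eps * df1, eps * df2))
    return out


def planned_pairwise_tests(
    table: pd.DataFrame, corrected_alpha: float = 0.05 / 3
) -> list:
    """Paired two-sided t-tests between all condition pairs.

    ``table`` is a subjects x conditions DataFrame (columns are condition
    labels). A zero-variance nonzero difference is degenerate: flagged,
    with p = NaN. Each contrast is significant iff p < corrected_alpha.
    """
    results = []
    cols = list(table.columns)
    x = table.to_numpy(dtype=float)
    n = x.shape[0]
    for i, j in itertools.combinations(range(len(cols)), 2):
        d = x[:, i] - x[:, j]
        sd = d.std(ddof=1)
        degenerate = False
        if sd == 0:
            if np.allclose(d, 0):
                t, p = 0.0, 1.0
            else:
                t, p, degenerate = np.nan, np.nan, True
        else:
            t = d.mean() / (sd / np.sqrt(n))
            p = 2 * stats.t.sf(abs(t), n - 1)
        results.append(
            {
                "pair": (cols[i], cols[j]),
                "t": float(t),
                "df": n - 1,
                "p": float(p),
                "significant_at_corrected_alpha": bool(not degenerate and p < corrected_alpha),
                "degenerate": degenerate,
            }
        )
    return results


def sd_outlier_mask(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Single-pass k-SD inclusion flags (False = excluded).

    Mean and SD are computed once over all values; no re-iteration after
    exclusion. With zero spread everything is included.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for the outlier rule")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.ones(x.shape, dtype=bool)
    include = np.abs(x - x.mean()) <= k * sd
    n_out = int((~include).sum())
    if n_out:
        log.info("3-SD rule excluded %d of %d values", n_out, x.size)
    return include


@dataclass
class BehaviorSummary:
    """Scored task plus the load-effect statistics for one measure."""

    measure: str
    table: pd.DataFrame  # subjects x loads
    anova: dict
    contrasts: list
    outlier_include: pd.Series  # per subject, from the 3-SD rule
    corrected_alpha: float


def _load_ordered(table: pd.DataFrame, loads) -> pd.DataFrame:
    order = [l for l in loads if l in table.columns]
    return table[order]


def summarize_behavior(
    outcomes: TrialOutcomes,
    loads: tuple = ("low", "medium", "high"),
    corrected_alpha: float = 0.05 / 3,
    outlier_k: float = 3.0,
) -> dict:
    """Score d' and median RT and run the load-effect statistics.

    The 3-SD rule is applied per measure to the subject means over loads;
    excluded subjects are dropped from the ANOVA and contrasts of that
    measure (the rule is applied once, not iterated).

    Returns ``{"dprime": BehaviorSummary, "median_rt": BehaviorSummary,
    "scores": tidy per-subject-and-load DataFrame}``.
    """
    dp = compute_dprime(outcomes)
    rt = summarize_rt(outcomes)
    scores = dp.merge(rt, on=["subject_id", "load"])
    out = {"scores": scores}
    for measure, col in (("dprime", "dprime"), ("median_rt", "median_rt")):
        wide = _load_ordered(_wide(scores, col), loads)
        subject_mean = wide.mean(axis=1)
        include = pd.Series(
            sd_outlier_mask(subject_mean.to_numpy(), k=outlier_k), index=wide.index
        )
        kept = wide.loc[include]
        out[measure] = BehaviorSummary(
            measure=measure,
            table=wide,
            anova=rm_anova(kept.to_numpy()),
            contrasts=planned_pairwise_tests(kept, corrected_alpha),
            outlier_include=include,
            corrected_alpha=corrected_alpha,
        )
    return out
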