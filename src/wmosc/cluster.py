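"""Group-level cluster-based Monte Carlo permutation inference on
channel x frequency x time maps.

The test statistic is the cluster mass: the sum of paired-sample t-values
over a connected set of supra-threshold samples. Sample-level t-tests
(two-sided p < 0.05 by default) define candidate samples; a candidate at
channel c survives only if at least ``min_neighbor_channels`` neighbors of
c are simultaneously supra-threshold with the same sign at the same
(frequency, time) point; surviving samples of equal sign are connected
when they differ by one step on the time grid, one step on the frequency
grid, or lie at the same (frequency, time) on neighboring channels.
Condition labels are sign-flipped per subject (paired design) and the
maximum cluster mass per sign is recorded per permutation; the Monte
Carlo p of an observed cluster is (1 + #{permutation max >= observed}) /
(n_permutations + 1) within its sign family, slightly conservative but
strictly positive. Two directions are tested, so clusters count as
significant at the Bonferroni-corrected 0.025 per direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .containers import TimeFrequencyMap
from .layout import SensorLayout
from .seeding import child_rng

__all__ = [
    "TMap",
    "ClusterReport",
    "paired_tmap",
    "form_clusters",
    "permutation_cluster_test",
    "sign_flip_cluster_test",
    "extract_mask_power",
]

log = logging.getLogger(__name__)


@dataclass
class TMap:
    """Sample-wise paired t statistics on a channel x frequency x time grid."""

    t: np.ndarray
    df: int
    significant: np.ndarray  # |t| above the cluster-forming threshold
    cluster_alpha: float
    freqs: np.ndarray
    times: np.ndarray
    channel_names: tuple


@dataclass
class ClusterReport:
    """Observed clusters, their Monte Carlo p-values, and the group mask."""

    clusters: list  # dicts: members (k,3 int array), mass, sign, p_mc
    t_map: TMap
    analysis_window: tuple
    corrected_alpha: float
    n_permutations: int
    seed: int | None
    method: str  # "monte-carlo" | "exhaustive"
    significance_mask: np.ndarray  # bool, channel x frequency x time
    perm_max_pos: np.ndarray = field(repr=False, default=None)
    perm_max_neg: np.ndarray = field(repr=False, default=None)

    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c["p_mc"] < self.corrected_alpha]

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            m = c["members"]
            rows.append(
                {
                    "sign": c["sign"],
                    "mass": c["mass"],
                    "p_mc": c["p_mc"],
                    "n_samples": len(m),
                    "n_channels": len(np.unique(m[:, 0])),
                    "freq_min": float(self.t_map.freqs[m[:, 1].min()]),
                    "freq_max": float(self.t_map.freqs[m[:, 1].max()]),
                    "time_min": float(self.t_map.times[m[:, 2].min()]),
                    "time_max": float(self.t_map.times[m[:, 2].max()]),
                    "significant": bool(c["p_mc"] < self.corrected_alpha),
                }
            )
        return pd.DataFrame(rows)


def _stack_differences(cond_a, cond_b, analysis_window):
    """Per-subject (a - b) difference maps cropped to the analysis window."""
    if len(cond_a) != len(cond_b) or len(cond_a) == 0:
        raise ValueError("both conditions must be present for every subject")
    ref = cond_a[0]
    diffs = []
    for a, b in zip(cond_a, cond_b):
        if a.subject_id != b.subject_id:
            raise ValueError(f"subject mismatch: {a.subject_id} vs {b.subject_id}")
        if not (a.same_grid(ref) and b.same_grid(ref)):
            raise ValueError("all maps must share one grid")
        if a.baseline_state != b.baseline_state:
            raise ValueError("conditions differ in baseline state")
        diffs.append(a.power - b.power)
    sel = (ref.times >= analysis_window[0] - 1e-9) & (ref.times <= analysis_window[1] + 1e-9)
    if not sel.any():
        raise ValueError("analysis window outside the time grid")
    d = np.stack(diffs)[:, :, :, sel]
    if np.isnan(d).any():
        raise ValueError("analysis window contains invalid (edge) samples")
    return d, ref.freqs.copy(), ref.times[sel].copy(), ref.channel_names


def _tvalues(d2: np.ndarray) -> tuple:
    """Paired t over the subject axis; zero-variance samples get t = 0."""
    n = d2.shape[0]
    mean = d2.mean(axis=0)
    var = d2.var(axis=0, ddof=1)
    zero = var <= 0
    if zero.any():
        log.warning("%d samples with zero variance; t set to 0", int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, mean / np.sqrt(var / n))
    return t, n - 1


def paired_tmap(
    cond_a: list,
    cond_b: list,
    analysis_window: tuple = (1.0, 3.0),
    cluster_alpha: float = 0.05,
) -> TMap:
    """Sample-wise paired two-sided t-test of condition A minus B.

    ``cond_a`` and ``cond_b`` are per-subject :class:`TimeFrequencyMap`
    lists in matching subject order. The maps are cropped to the analysis
    window (1-3 s after retention onset by default, where wavelet edge
    effects cannot reach).
    """
    d, freqs, times, chn = _stack_differences(cond_a, cond_b, analysis_window)
    if d.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    t, df = _tvalues(d)
    tcrit = stats.t.ppf(1 - cluster_alpha / 2, df)
    return TMap(
        t=t,
        df=df,
        significant=np.abs(t) > tcrit,
        cluster_alpha=cluster_alpha,
        freqs=freqs,
        times=times,
        channel_names=chn,
    )


def _grid_graph(n_ch: int, n_f: int, n_t: int, adjacency: np.ndarray) -> sparse.csr_matrix:
    """Sparse sample-adjacency graph over the flattened (c, f, t) grid."""
    idx = np.arange(n_ch * n_f * n_t).reshape(n_ch, n_f, n_t)
    rows, cols = [], []
    rows.append(idx[:, :, :-1].ravel())
    cols.append(idx[:, :, 1:].ravel())
    rows.append(idx[:, :-1, :].ravel())
    cols.append(idx[:, 1:, :].ravel())
    for i, j in np.argwhere(np.triu(adjacency, 1)):
        rows.append(idx[i].ravel())
        cols.append(idx[j].ravel())
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    g = sparse.coo_matrix(
        (np.ones(len(r), dtype=np.int8), (r, c)), shape=(idx.size, idx.size)
    )
    g = g + g.T
    return g.tocsr()


def _prune(sig: np.ndarray, adjacency: np.ndarray, min_nb: int) -> np.ndarray:
    """Keep a supra-threshold sample only if >= min_nb neighboring
    channels are supra-threshold (same sign) at the same (f, t)."""
    if min_nb <= 0:
        return sig
    flat = sig.reshape(sig.shape[0], -1)
    counts = adjacency.astype(np.int32) @ flat
    return (flat & (counts >= min_nb)).reshape(sig.shape)


def _components(mask_flat: np.ndarray, graph: sparse.csr_matrix):
    nodes = np.flatnonzero(mask_flat)
    if nodes.size == 0:
        return nodes, np.array([], dtype=int), 0
    sub = graph[nodes][:, nodes]
    n_comp, labels = connected_components(sub, directed=False)
    return nodes, labels, n_comp


def form_clusters(
    sig: np.ndarray,
    t: np.ndarray,
    layout: SensorLayout,
    min_neighbor_channels: int = 3,
    graph: sparse.csr_matrix | None = None,
) -> list:
    """Cluster supra-threshold samples, per sign.

    ``sig`` and ``t`` are channel x frequency x time arrays; channels must
    match the layout. Pruning (the minimum-neighbor-channel rule) is
    applied before connected components are formed. Returns a list of
    ``{"members": (k, 3) int array, "mass": float, "sign": str}`` sorted
    by decreasing |mass|.
    """
    if sig.shape != t.shape or sig.ndim != 3:
        raise ValueError("sig and t must be matching (channel, freq, time) arrays")
    if sig.shape[0] != layout.n_channels:
        raise ValueError("channel count does not match the layout")
    n_ch, n_f, n_t = sig.shape
    if graph is None:
        graph = _grid_graph(n_ch, n_f, n_t, layout.adjacency)
    clusters = []
    tf = t.ravel()
    for sign, name in ((1, "positive"), (-1, "negative")):
        m = sig & ((t > 0) if sign > 0 else (t < 0))
        m = _prune(m, layout.adjacency, min_neighbor_channels)
        nodes, labels, n_comp = _components(m.ravel(), graph)
        for k in range(n_comp):
            members = nodes[labels == k]
            cidx, rem = np.divmod(members, n_f * n_t)
            fidx, tidx = np.divmod(rem, n_t)
            clusters.append(
                {
                    "members": np.column_stack([cidx, fidx, tidx]),
                    "mass": float(tf[members].sum()),
                    "sign": name,
                }
            )
    clusters.sort(key=lambda c: -abs(c["mass"]))
    return clusters


def _perm_max_masses(
    d_flat: np.ndarray,
    signs: np.ndarray,
    shape: tuple,
    adjacency: np.ndarray,
    graph: sparse.csr_matrix,
    tcrit: float,
    min_nb: int,
) -> tuple:
    """Maximum positive mass and maximum |negative mass| per permutation."""
    n = d_flat.shape[0]
    sumsq = (d_flat**2).sum(axis=0)
    max_pos = np.zeros(len(signs))
    max_neg = np.zeros(len(signs))
    batch = 256
    for lo in range(0, len(signs), batch):
        s = signs[lo : lo + batch].astype(float)
        mean = s @ d_flat / n
        var = (sumsq - n * mean**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var <= 0, 0.0, mean / np.sqrt(var / n))
        b = t.shape[0]
        t3 = t.reshape(b, *shape)
        for sign in (1, -1):
            m = (t3 > tcrit) if sign > 0 else (t3 < -tcrit)
            if min_nb > 0:
                flat = m.reshape(b, shape[0], -1)
                counts = np.einsum("cd,pdk->pck", adjacency.astype(np.int32), flat)
                m = (flat & (counts >= min_nb)).reshape(b, *shape)
            for p in range(b):
                nodes, labels, n_comp = _components(m[p].ravel(), graph)
                if n_comp == 0:
                    continue
                masses = np.bincount(labels, weights=t[p][nodes])
                if sign > 0:
                    max_pos[lo + p] = masses.max()
                else:
                    max_neg[lo + p] = -masses.min()
    return max_pos, max_neg


def sign_flip_cluster_test(
    diffs: np.ndarray,
    layout: SensorLayout,
    freqs: np.ndarray,
    times: np.ndarray,
    n_permutations: int = 1000,
    seed: int | None = None,
    alpha: float = 0.025,
    cluster_alpha: float = 0.05,
    min_neighbor_channels: int = 3,
    method: str = "auto",
    analysis_window: tuple = (1.0, 3.0),
) -> ClusterReport:
    """Cluster permutation test on per-subject difference maps.

    ``diffs`` is (subject, channel, frequency, time), already cropped to
    the analysis window. Flipping a subject's condition labels negates
    its difference map, so permutation is implemented as per-subject sign
    flips. ``method`` "exhaustive" enumerates all 2^n sign vectors (used
    automatically, with a warning, when n <= 3 subjects).
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 4:
        raise ValueError("diffs must be (subject, channel, freq, time)")
    n = d.shape[0]
    shape = d.shape[1:]
    if shape[0] != layout.n_channels:
        raise ValueError("channel count does not match the layout")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives poor p-value resolution")
    if method == "auto":
        if n <= 3:
            warnings.warn(
                f"only {n} subjects: using exhaustive 2^{n} sign-flip enumeration"
            )
            method = "exhaustive"
        else:
            method = "monte-carlo"
    if method not in ("monte-carlo", "exhaustive"):
        raise ValueError(f"unknown method {method!r}")

    t_obs, df = _tvalues(d)
    tcrit = stats.t.ppf(1 - cluster_alpha / 2, df)
    graph = _grid_graph(*shape, layout.adjacency)
    sig = np.abs(t_obs) > tcrit
    clusters = form_clusters(sig, t_obs, layout, min_neighbor_channels, graph=graph)

    if method == "exhaustive":
        if n > 20:
            raise ValueError("exhaustive enumeration is limited to 20 subjects")
        bits = np.arange(2**n, dtype=np.int64)
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n)[None, :]) & 1)
        denom_offset = 0  # identity permutation is part of the reference set
        n_eff = 2**n
    else:
        rng = child_rng(seed if seed is not None else 0, "cluster-perm")
        signs = rng.choice([-1, 1], size=(n_permutations, n))
        denom_offset = 1  # (b + 1) / (m + 1): ties count as exceedances
        n_eff = n_permutations

    d_flat = d.reshape(n, -1)
    max_pos, max_neg = _perm_max_masses(
        d_flat, signs, shape, layout.adjacency, graph, tcrit, min_neighbor_channels
    )
    for c in clusters:
        ref = max_pos if c["sign"] == "positive" else max_neg
        exceed = int((ref >= abs(c["mass"]) - 1e-12).sum())
        c["p_mc"] = (exceed + denom_offset) / (n_eff + denom_offset)

    mask = np.zeros(shape, dtype=bool)
    for c in clusters:
        if c["p_mc"] < alpha:
            m = c["members"]
            mask[m[:, 0], m[:, 1], m[:, 2]] = True

    tmap = TMap(
        t=t_obs,
        df=df,
        significant=sig,
        cluster_alpha=cluster_alpha,
        freqs=np.asarray(freqs, dtype=float),
        times=np.asarray(times, dtype=float),
        channel_names=layout.channel_names,
    )
    return ClusterReport(
        clusters=clusters,
        t_map=tmap,
        analysis_window=tuple(analysis_window),
        corrected_alpha=alpha,
        n_permutations=n_eff,
        seed=seed,
        method=method,
        significance_mask=mask,
        perm_max_pos=max_pos,
        perm_max_neg=max_neg,
    )


def permutation_cluster_test(
    cond_a: list,
    cond_b: list,
    layout: SensorLayout,
    analysis_window: tuple = (1.0, 3.0),
    n_permutations: int = 1000,
    seed: int | None = None,
    alpha: float = 0.025,
    cluster_alpha: float = 0.05,
    min_neighbor_channels: int = 3,
    method: str = "auto",
) -> ClusterReport:
    """Cluster permutation test between two conditions (A minus B).

    ``cond_a``/``cond_b`` are per-subject :class:`TimeFrequencyMap` lists
    in matching subject order; the maps are cropped to the analysis
    window before testing.
    """
    d, freqs, times, chn = _stack_differences(cond_a, cond_b, analysis_window)
    if chn != layout.channel_names:
        raise ValueError("map channels do not match the layout")
    return sign_flip_cluster_test(
        d,
        layout,
        freqs,
        times,
        n_permutations=n_permutations,
        seed=seed,
        alpha=alpha,
        cluster_alpha=cluster_alpha,
        min_neighbor_channels=min_neighbor_channels,
        method=method,
        analysis_window=analysis_window,
    )


def extract_mask_power(maps: list, report: ClusterReport) -> pd.DataFrame:
    """Mean power over the significant-cluster mask, per map.

    ``maps`` is a list of per-subject, per-condition
    :class:`TimeFrequencyMap`; each contributes one scalar: the
    arithmetic mean of its (baseline-corrected) power over the masked
    samples. Returns a DataFrame (subject_id, condition, mean_power).
    """
    mask = report.significance_mask
    if not mask.any():
        raise ValueError("significance mask is empty")
    tm = report.t_map
    rows = []
    for m in maps:
        sel = np.isin(m.times, tm.times)
        if (
            not np.array_equal(m.freqs, tm.freqs)
            or sel.sum() != len(tm.times)
            or m.channel_names != tm.channel_names
        ):
            raise ValueError(f"grid mismatch for subject {m.subject_id}")
        cropped = m.power[:, :, sel]
        rows.append(
            {
                "subject_id": m.subject_id,
                "condition": m.condition,
                "mean_power": float(cropped[mask].mean()),
            }
        )
    return pd.DataFrame(rows)
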