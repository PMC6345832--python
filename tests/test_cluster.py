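import numpy as np
import pytest

import wmosc
from wmosc import TimeFrequencyMap
from wmosc.cluster import (
    extract_mask_power,
    form_clusters,
    paired_tmap,
    permutation_cluster_test,
    sign_flip_cluster_test,
)


def tf_map(power, freqs, times, subject="S00", cond="a", state="relative-change", n_ch=None):
    n_ch = power.shape[0]
    return TimeFrequencyMap(
        power=power,
        freqs=freqs,
        times=times,
        baseline_state=state,
        n_trials=10,
        condition=cond,
        subject_id=subject,
        channel_names=tuple(f"C{i:02d}" for i in range(n_ch)),
        sample_onset=-0.5,
    )


def random_condition_pair(rng, n_subj, n_ch, n_f=5, n_t=8, effect=0.0):
    freqs = np.linspace(5, 12, n_f)
    times = np.linspace(1, 3, n_t)
    a_maps, b_maps = [], []
    for s in range(n_subj):
        a = rng.normal(size=(n_ch, n_f, n_t)) * 0.1
        b = rng.normal(size=(n_ch, n_f, n_t)) * 0.1 + effect
        a_maps.append(tf_map(a, freqs, times, subject=f"S{s:02d}", cond="a"))
        b_maps.append(tf_map(b, freqs, times, subject=f"S{s:02d}", cond="b"))
    return a_maps, b_maps, freqs, times


# ---------------------------------------------------------------------------
# t maps


def test_identical_conditions_give_zero_t_everywhere(layout4, caplog):
    rng = np.random.default_rng(0)
    a, _, _, _ = random_condition_pair(rng, 6, 4)
    tm = paired_tmap(a, a)
    assert np.all(tm.t == 0)
    assert not tm.significant.any()


def test_swapping_conditions_negates_t_exactly(layout4):
    rng = np.random.default_rng(1)
    a, b, _, _ = random_condition_pair(rng, 8, 4, effect=0.05)
    t_ab = paired_tmap(a, b).t
    t_ba = paired_tmap(b, a).t
    assert np.array_equal(t_ab, -t_ba)


def test_tmap_spot_checks_match_hand_formula():
    rng = np.random.default_rng(2)
    a, b, _, _ = random_condition_pair(rng, 8, 4)
    tm = paired_tmap(a, b)
    d = np.stack([x.power - y.power for x, y in zip(a, b)])
    for idx in [(0, 0, 0), (2, 3, 4), (1, 4, 7)]:
        v = d[(slice(None),) + idx]
        t_hand = v.mean() / (v.std(ddof=1) / np.sqrt(8))
        assert tm.t[idx] == pytest.approx(t_hand, abs=1e-10)
    assert tm.df == 7


def test_analysis_window_cropping():
    rng = np.random.default_rng(3)
    freqs = np.linspace(5, 12, 4)
    times = np.linspace(0, 4, 41)
    a = [tf_map(rng.normal(size=(4, 4, 41)) * 0.2, freqs, times, subject=f"S{i}") for i in range(5)]
    b = [tf_map(rng.normal(size=(4, 4, 41)) * 0.2, freqs, times, subject=f"S{i}") for i in range(5)]
    tm = paired_tmap(a, b, analysis_window=(1.0, 3.0))
    assert tm.times.min() >= 1.0 and tm.times.max() <= 3.0


# ---------------------------------------------------------------------------
# cluster formation


def test_all_significant_connected_forms_single_cluster(layout16):
    shape = (16, 4, 5)
    t = np.ones(shape)
    sig = np.ones(shape, dtype=bool)
    clusters = form_clusters(sig, t, layout16, min_neighbor_channels=3)
    assert len(clusters) == 1
    assert len(clusters[0]["members"]) == np.prod(shape)
    assert clusters[0]["mass"] == pytest.approx(np.prod(shape))
    assert clusters[0]["sign"] == "positive"


def test_isolated_channel_sample_is_pruned(layout16):
    shape = (16, 4, 5)
    t = np.zeros(shape)
    sig = np.zeros(shape, dtype=bool)
    t[3, 2, 2] = 5.0
    sig[3, 2, 2] = True
    assert form_clusters(sig, t, layout16, min_neighbor_channels=3) == []
    # without pruning the sample forms its own cluster
    solo = form_clusters(sig, t, layout16, min_neighbor_channels=0)
    assert len(solo) == 1 and solo[0]["mass"] == 5.0


def _flood_fill_oracle(sig, t, adjacency, min_nb):
    """Independent implementation: prune by the neighbor rule, then BFS
    over the explicit sample-adjacency relation, per sign."""
    n_ch, n_f, n_t = sig.shape
    retained = {}
    for c in range(n_ch):
        for f in range(n_f):
            for k in range(n_t):
                if not sig[c, f, k]:
                    continue
                s = np.sign(t[c, f, k])
                nb = sum(
                    1
                    for d in range(n_ch)
                    if adjacency[c, d] and sig[d, f, k] and np.sign(t[d, f, k]) == s
                )
                if nb >= min_nb:
                    retained[(c, f, k)] = s

    def neighbors(node):
        c, f, k = node
        out = []
        for dk in (-1, 1):
            out.append((c, f, k + dk))
            out.append((c, f + dk, k))
        for d in range(n_ch):
            if adjacency[c, d]:
                out.append((d, f, k))
        return out

    seen, comps = set(), []
    for start in retained:
        if start in seen:
            continue
        comp, queue = set(), [start]
        seen.add(start)
        while queue:
            node = queue.pop()
            comp.add(node)
            for nb in neighbors(node):
                if nb in retained and nb not in seen and retained[nb] == retained[node]:
                    seen.add(nb)
                    queue.append(nb)
        comps.append((comp, sum(t[n] for n in comp)))
    return comps


def test_planted_blobs_match_flood_fill_oracle(layout4):
    rng = np.random.default_rng(4)
    shape = (4, 5, 5)
    t = rng.normal(size=shape) * 0.1
    sig = np.zeros(shape, dtype=bool)
    # two blobs of opposite sign on all four (fully connected) channels
    t[:, 0:2, 0:2] = 3.0
    sig[:, 0:2, 0:2] = True
    t[:, 3:5, 3:5] = -2.0
    sig[:, 3:5, 3:5] = True
    # plus scattered singletons that the neighbor rule must prune
    t[0, 2, 4] = 4.0
    sig[0, 2, 4] = True
    clusters = form_clusters(sig, t, layout4, min_neighbor_channels=2)
    oracle = _flood_fill_oracle(sig, t, layout4.adjacency, 2)
    assert len(clusters) == len(oracle) == 2
    got = {frozenset(map(tuple, c["members"])): c["mass"] for c in clusters}
    for comp, mass in oracle:
        key = frozenset(comp)
        assert key in got
        assert got[key] == pytest.approx(mass, abs=1e-9)


# ---------------------------------------------------------------------------
# permutation inference


def test_counting_rule_minimum_pvalue(layout4):
    """An observed cluster exceeding every permutation maximum gets
    p = 1 / (n_permutations + 1)."""
    rng = np.random.default_rng(5)
    a, b, freqs, times = random_condition_pair(rng, 8, 4, effect=2.0)
    rep = permutation_cluster_test(
        a, b, layout4, n_permutations=200, seed=0, min_neighbor_channels=2
    )
    assert rep.clusters[0]["p_mc"] == pytest.approx(1 / 201)
    assert rep.significance_mask.any()


def test_condition_exchange_mirrors_clusters(layout4):
    rng = np.random.default_rng(6)
    a, b, _, _ = random_condition_pair(rng, 8, 4, effect=0.08)
    kw = dict(n_permutations=300, seed=3, min_neighbor_channels=2)
    r_ab = permutation_cluster_test(a, b, layout4, **kw)
    r_ba = permutation_cluster_test(b, a, layout4, **kw)
    assert len(r_ab.clusters) == len(r_ba.clusters)
    for ca, cb in zip(r_ab.clusters, r_ba.clusters):
        assert ca["mass"] == pytest.approx(-cb["mass"], abs=1e-9)
        assert ca["p_mc"] == cb["p_mc"]
        assert {ca["sign"], cb["sign"]} == {"positive", "negative"}


def test_identical_condition_sets_yield_no_clusters(layout4):
    rng = np.random.default_rng(7)
    for seed in range(5):
        a, _, _, _ = random_condition_pair(rng, 6, 4)
        rep = permutation_cluster_test(a, a, layout4, n_permutations=150, seed=seed)
        assert rep.clusters == []
        assert not rep.significance_mask.any()


def test_pvalue_monotone_in_effect_amplitude(layout4):
    rng = np.random.default_rng(8)
    noise = rng.normal(size=(8, 4, 5, 8)) * 0.5
    freqs = np.linspace(5, 12, 5)
    times = np.linspace(1, 3, 8)
    pvals = []
    for amp in (0.2, 0.45, 0.9):
        d = noise + amp
        rep = sign_flip_cluster_test(
            d, layout4, freqs, times, n_permutations=400, seed=1, min_neighbor_channels=2
        )
        # absence of any supra-threshold cluster counts as p = 1
        pvals.append(rep.clusters[0]["p_mc"] if rep.clusters else 1.0)
    assert pvals[0] >= pvals[1] >= pvals[2]
    assert pvals[2] < 0.05, "largest amplitude should yield a clear cluster"


def test_small_sample_switches_to_exhaustive_with_warning(layout4):
    rng = np.random.default_rng(9)
    a, b, _, _ = random_condition_pair(rng, 3, 4, effect=0.3)
    with pytest.warns(UserWarning, match="exhaustive"):
        rep = permutation_cluster_test(a, b, layout4, n_permutations=500)
    assert rep.method == "exhaustive"
    assert rep.n_permutations == 8


def test_few_permutations_warns(layout4):
    rng = np.random.default_rng(10)
    a, b, _, _ = random_condition_pair(rng, 6, 4)
    with pytest.warns(UserWarning, match="100 permutations"):
        permutation_cluster_test(a, b, layout4, n_permutations=50, seed=0)


def test_zero_variance_samples_get_zero_t(layout4, caplog):
    rng = np.random.default_rng(11)
    a, b, _, _ = random_condition_pair(rng, 6, 4)
    for x, y in zip(a, b):
        x.power[0, 0, 0] = y.power[0, 0, 0] = 1.0
    with caplog.at_level("WARNING"):
        tm = paired_tmap(a, b)
    assert tm.t[0, 0, 0] == 0.0
    assert "zero variance" in caplog.text


def test_missing_subject_condition_rejected(layout4):
    rng = np.random.default_rng(12)
    a, b, _, _ = random_condition_pair(rng, 6, 4)
    with pytest.raises(ValueError, match="both conditions"):
        paired_tmap(a, b[:-1])
    b[0].subject_id = "S99"
    with pytest.raises(ValueError, match="subject mismatch"):
        paired_tmap(a, b)


# ---------------------------------------------------------------------------
# mask power extraction


def test_extract_mask_power_against_direct_oracle(layout4):
    rng = np.random.default_rng(13)
    a, b, freqs, times = random_condition_pair(rng, 8, 4, effect=2.0)
    rep = permutation_cluster_test(
        a, b, layout4, n_permutations=200, seed=0, min_neighbor_channels=2
    )
    # full mask equals the global mean
    rep.significance_mask[:] = True
    df = extract_mask_power(a[:2], rep)
    for i in range(2):
        assert df["mean_power"].iloc[i] == pytest.approx(a[i].power.mean(), abs=1e-12)
    # single-sample mask picks that sample
    rep.significance_mask[:] = False
    rep.significance_mask[1, 2, 3] = True
    df = extract_mask_power(a[:1], rep)
    assert df["mean_power"].iloc[0] == a[0].power[1, 2, 3]
    # random mask equals the explicit masked mean
    rep.significance_mask = rng.random(rep.significance_mask.shape) < 0.3
    df = extract_mask_power(b[:3], rep)
    for i in range(3):
        oracle = b[i].power[rep.significance_mask].sum() / rep.significance_mask.sum()
        assert df["mean_power"].iloc[i] == pytest.approx(oracle, abs=1e-12)


def test_empty_mask_rejected(layout4):
    rng = np.random.default_rng(14)
    a, b, _, _ = random_condition_pair(rng, 8, 4, effect=2.0)
    rep = permutation_cluster_test(
        a, b, layout4, n_permutations=200, seed=0, min_neighbor_channels=2
    )
    rep.significance_mask[:] = False
    with pytest.raises(ValueError, match="empty"):
        extract_mask_power(a, rep)
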