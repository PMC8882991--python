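"""Diversity statistics against independent oracles.

Kruskal-Wallis, Bray-Curtis, NMDS, ANOSIM and PERMANOVA are implemented
natively in the package; scipy/scikit-bio serve here purely as independent
reference implementations.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_bc, pdist, squareform
from scipy.stats import kruskal as scipy_kruskal, rankdata
from skbio import DistanceMatrix

from farmnet import (
    AsvTable,
    anosim,
    bray_curtis,
    kruskal_wallis,
    nmds,
    observed_richness,
    permanova,
)
from farmnet.diversity import anosim_statistic, permanova_statistics


def random_dm(rng, n):
    x = rng.random((n, 4))
    return DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(n)])


# ---------------------------------------------------------------------------
# richness + Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_observed_richness(tiny_table, rng):
    assert observed_richness(tiny_table).tolist() == [2, 2]
    counts = pd.DataFrame(
        rng.integers(0, 2, size=(8, 20)),
        index=[f"s{i}" for i in range(8)],
        columns=[f"a{j}" for j in range(20)],
    )
    rich = observed_richness(AsvTable(counts))
    assert rich.tolist() == (counts.to_numpy() > 0).sum(axis=1).tolist()


def test_kruskal_maximal_separation():
    """Tie-free full separation of 2x3 observations gives H = 27/7."""
    res = kruskal_wallis({"A": [1, 2, 3], "B": [10, 11, 12]})
    assert res.statistic == pytest.approx(27 / 7, abs=1e-12)


def test_kruskal_all_equal():
    res = kruskal_wallis({"A": [2.0, 2.0], "B": [2.0, 2.0]})
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_kruskal_exchangeable_groups_not_significant():
    res = kruskal_wallis({"A": [1, 2], "B": [1, 2]})
    assert res.p_value > 0.05


def test_kruskal_matches_scipy_on_random_inputs(rng):
    """1000 random datasets (with ties) match scipy to 1e-10."""
    for _ in range(1000):
        g = rng.integers(2, 5)
        groups = {
            str(i): rng.integers(0, 12, size=rng.integers(2, 8)).astype(float)
            for i in range(g)
        }
        mine = kruskal_wallis(groups)
        h, p = scipy_kruskal(*groups.values())
        assert mine.statistic == pytest.approx(h, abs=1e-10)
        assert mine.p_value == pytest.approx(p, abs=1e-10)


def test_kruskal_empty_group_errors():
    with pytest.raises(ValueError):
        kruskal_wallis({"A": [1.0], "B": []})


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def test_bray_curtis_hand_values():
    counts = pd.DataFrame(
        [[2, 0, 1], [1, 1, 0], [2, 0, 1], [0, 5, 0]],
        index=["x", "y", "x2", "z"],
        columns=list("abc"),
    )
    d = bray_curtis(AsvTable(counts))
    assert d["x", "y"] == pytest.approx(0.6)  # 1 - 2*1/5
    assert d["x", "x2"] == 0.0
    assert d["x", "z"] == 1.0  # disjoint supports


def test_bray_curtis_matches_scipy(rng):
    counts = pd.DataFrame(
        rng.integers(0, 30, size=(10, 25)) , index=[f"s{i}" for i in range(10)],
        columns=[f"a{j}" for j in range(25)],
    )
    counts.iloc[:, 0] += 1  # guard against zero-sum rows
    d = bray_curtis(AsvTable(counts))
    x = counts.to_numpy(float)
    for i, j in itertools.combinations(range(10), 2):
        assert d[str(counts.index[i]), str(counts.index[j])] == pytest.approx(
            scipy_bc(x[i], x[j]), abs=1e-12
        )


def test_bray_curtis_scale_invariance(rng):
    """Equal row sums: scaling to relative abundance changes nothing."""
    counts = rng.integers(0, 20, size=(6, 15)).astype(float)
    counts[:, 0] += 1
    counts = counts / counts.sum(axis=1, keepdims=True) * 1000  # equal sums
    df = pd.DataFrame(counts, index=[f"s{i}" for i in range(6)])
    df.columns = [f"a{j}" for j in range(15)]
    d_raw = bray_curtis(df)
    d_rel = bray_curtis(df / 1000.0)
    np.testing.assert_allclose(d_raw.data, d_rel.data, atol=1e-12)


def test_bray_curtis_zero_sum_sample_named(tiny_table):
    counts = tiny_table.counts.copy()
    counts.loc["s1"] = 0
    with pytest.raises(Exception, match="s1"):
        bray_curtis(AsvTable(counts))


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def test_nmds_equilateral_embeds_exactly():
    d = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
    res = nmds(d, k=2, n_starts=5, seed=0)
    assert res.stress < 1e-6


def test_nmds_collinear_in_one_dimension():
    pts = np.array([0.0, 1.0, 3.0, 6.0])
    d = DistanceMatrix(np.abs(pts[:, None] - pts[None, :]), ids=list("abcd"))
    res = nmds(d, k=1, n_starts=5, seed=0)
    assert res.stress < 1e-6


def test_nmds_stress_trace_non_increasing(rng):
    d = random_dm(rng, 6)
    res = nmds(d, k=2, n_starts=3, seed=1)
    trace = np.array(res.stress_trace)
    assert np.all(np.diff(trace) <= 1e-8)


def test_nmds_requires_small_k(rng):
    with pytest.raises(ValueError):
        nmds(random_dm(rng, 4), k=4)


# ---------------------------------------------------------------------------
# ANOSIM / PERMANOVA
# ---------------------------------------------------------------------------

def two_group_labels(n=6):
    return {str(i): ("A" if i < n // 2 else "B") for i in range(n)}


def test_anosim_maximal_separation():
    """All between-distances above all within-distances gives R = 1."""
    d = np.full((6, 6), 0.2)
    d[:3, 3:] = 0.9
    d[3:, :3] = 0.9
    np.fill_diagonal(d, 0)
    dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
    res = anosim(dm, two_group_labels(), n_perm=99, seed=0)
    assert res.statistic == pytest.approx(1.0)


def test_anosim_null_mean_near_zero(rng):
    """Random labels: mean R over simulations within 3 SE of zero."""
    stats = []
    for _ in range(200):
        dm = random_dm(rng, 8)
        labels = rng.permutation(["A"] * 4 + ["B"] * 4)
        stats.append(anosim_statistic(dm, labels))
    se = np.std(stats) / np.sqrt(len(stats))
    assert abs(np.mean(stats)) < 3 * se


def exhaustive_p(dm, stat_fn, labels):
    """Oracle: enumerate all distinct assignments of the label multiset."""
    obs = stat_fn(dm, labels)
    stats = [
        stat_fn(dm, list(perm))
        for perm in sorted(set(itertools.permutations(labels)))
    ]
    return sum(s >= obs - 1e-12 for s in stats) / len(stats)


def test_anosim_exhaustive_matches_enumeration(rng):
    labels = ["A", "A", "A", "B", "B", "B"]
    for _ in range(10):
        dm = random_dm(rng, 6)
        res = anosim(dm, dict(zip(dm.ids, labels)), exhaustive=True)
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(
            exhaustive_p(dm, anosim_statistic, labels)
        )


def test_permanova_exhaustive_matches_enumeration(rng):
    labels = ["A", "A", "A", "B", "B", "B"]
    f_stat = lambda dm, lab: permanova_statistics(dm, lab)[0]
    for _ in range(10):
        dm = random_dm(rng, 6)
        res = permanova(dm, dict(zip(dm.ids, labels)), exhaustive=True)
        assert res.p_value == pytest.approx(exhaustive_p(dm, f_stat, labels))


def test_permanova_all_equal_distances_closed_form():
    """n=4, 2 groups of 2, all d=1: SS_t=1.5, SS_w=1, F=1, R2=1/3."""
    d = np.ones((4, 4)) - np.eye(4)
    dm = DistanceMatrix(d, ids=list("abcd"))
    res = permanova(dm, {"a": "A", "b": "A", "c": "B", "d": "B"}, n_perm=19, seed=0)
    assert res.statistic == pytest.approx(1.0)
    assert res.extras["r_squared"] == pytest.approx(1 / 3)


def test_permanova_zero_within_gives_r2_one():
    d = np.array([
        [0, 0, 1, 1],
        [0, 0, 1, 1],
        [1, 1, 0, 0],
        [1, 1, 0, 0],
    ], dtype=float)
    dm = DistanceMatrix(d, ids=list("abcd"))
    res = permanova(dm, {"a": "A", "b": "A", "c": "B", "d": "B"}, n_perm=19, seed=0)
    assert res.extras["r_squared"] == pytest.approx(1.0)


def test_ss_partition_conserved(rng):
    """SS_between + SS_within = SS_total to 1e-10 (via R2 self-consistency)."""
    for _ in range(20):
        n = int(rng.integers(6, 12))
        dm = random_dm(rng, n)
        labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
        f, r2 = permanova_statistics(dm, labels)
        # recompute the three sums independently
        d2 = dm.data ** 2
        iu = np.triu_indices(n, k=1)
        ss_t = d2[iu].sum() / n
        idx_a = np.arange(n // 2)
        idx_b = np.arange(n // 2, n)
        ss_w = sum(
            d2[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)].sum() / len(idx)
            for idx in (idx_a, idx_b)
        )
        assert (ss_t - ss_w) / ss_t == pytest.approx(r2, abs=1e-10)


def test_group_stats_invariant_to_relabeling(rng):
    dm = random_dm(rng, 8)
    labels = ["A"] * 4 + ["B"] * 4
    swapped = ["X" if l == "B" else "Y" for l in labels]
    assert anosim_statistic(dm, labels) == pytest.approx(
        anosim_statistic(dm, swapped), abs=1e-12
    )
    assert permanova_statistics(dm, labels)[0] == pytest.approx(
        permanova_statistics(dm, swapped)[0], abs=1e-12
    )


def test_anosim_matches_skbio(rng):
    from skbio.stats.distance import anosim as sk_anosim

    dm = random_dm(rng, 10)
    labels = ["A"] * 5 + ["B"] * 5
    mine = anosim_statistic(dm, labels)
    ref = sk_anosim(
        dm, pd.Series(labels, index=dm.ids, name="g"), permutations=0
    )["test statistic"]
    assert mine == pytest.approx(ref, abs=1e-12)


def test_permanova_matches_skbio(rng):
    from skbio.stats.distance import permanova as sk_permanova

    dm = random_dm(rng, 10)
    labels = ["A"] * 5 + ["B"] * 5
    mine = permanova_statistics(dm, labels)[0]
    ref = sk_permanova(
        dm, pd.Series(labels, index=dm.ids, name="g"), permutations=0
    )["test statistic"]
    assert mine == pytest.approx(ref, abs=1e-10)


def test_permutation_p_in_valid_range(rng):
    dm = random_dm(rng, 8)
    labels = dict(zip(dm.ids, ["A"] * 4 + ["B"] * 4))
    for res in (anosim(dm, labels, 99, seed=5), permanova(dm, labels, 99, seed=5)):
        assert 1 / 100 <= res.p_value <= 1.0


def test_singleton_group_rejected(rng):
    dm = random_dm(rng, 5)
    labels = dict(zip(dm.ids, ["A", "A", "A", "A", "B"]))
    with pytest.raises(ValueError):
        anosim(dm, labels)
    with pytest.raises(ValueError):
        permanova(dm, labels)
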