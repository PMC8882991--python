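"""ASV pool selection, Spearman edges, thresholding, graph summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from farmnet import (
    AsvTable,
    build_network,
    layout_force_directed,
    select_asv_pool,
    spearman_matrix,
    summarize_networks,
    threshold_edges,
)
from farmnet.network import EDGE_COLUMNS

from conftest import make_meta_table


def _presence_table(presence, niches=None, treatments=None):
    counts = pd.DataFrame(
        np.asarray(presence) * 5,
        index=[f"s{i}" for i in range(len(presence))],
    )
    counts.columns = [f"a{j}" for j in range(counts.shape[1])]
    if niches is None:
        return AsvTable(counts)
    return make_meta_table(counts, niches, treatments)


# ---------------------------------------------------------------------------
# pool selection
# ---------------------------------------------------------------------------

def test_pool_prevalence_boundary_inclusive():
    """6 of 10 samples meets the 60% criterion; 5 of 10 does not."""
    presence = np.zeros((10, 2), int)
    presence[:6, 0] = 1  # 60% - in
    presence[:5, 1] = 1  # 50% - out even if responsive
    t = _presence_table(presence)
    pool = select_asv_pool(t, n_responsive_set={"a0", "a1"}, top_n=0)
    assert pool.asv_ids == ["a0"]


def test_pool_requires_responsive_or_top():
    presence = np.ones((5, 3), int)
    t = _presence_table(presence)
    pool = select_asv_pool(t, n_responsive_set=set(), top_n=2)
    assert len(pool) == 2  # top-2 only; third prevalent ASV excluded


def test_pool_matches_set_algebra_oracle(rng):
    counts = pd.DataFrame(
        rng.integers(0, 4, size=(15, 40)),
        index=[f"s{i}" for i in range(15)],
        columns=[f"a{j}" for j in range(40)],
    )
    t = AsvTable(counts)
    responsive = {f"a{j}" for j in rng.choice(40, size=8, replace=False)}
    top_n, prevalence = 10, 0.6
    pool = select_asv_pool(t, responsive, top_n=top_n, prevalence=prevalence)
    # oracle: direct set algebra on the criteria
    prev_ok = {
        c for c in counts.columns
        if (counts[c] > 0).sum() >= math.ceil(prevalence * 15)
    }
    top = set(counts.sum(axis=0).sort_values(ascending=False, kind="stable").index[:top_n])
    expect = prev_ok & (responsive | top)
    assert set(pool.asv_ids) == expect


# ---------------------------------------------------------------------------
# Spearman records
# ---------------------------------------------------------------------------

def _pool_of(t):
    return select_asv_pool(t, set(), top_n=t.n_asvs, prevalence=0.01)


def test_spearman_perfect_monotone():
    counts = pd.DataFrame(
        {"up1": [1, 2, 3, 4, 5], "up2": [2, 4, 9, 16, 30], "down": [50, 40, 30, 20, 10]},
        index=[f"s{i}" for i in range(5)],
    )
    t = AsvTable(counts)
    rec = spearman_matrix(t, _pool_of(t), min_n=4).set_index(["asv_i", "asv_j"])
    assert rec.loc[("up1", "up2"), "r"] == pytest.approx(1.0)
    assert rec.loc[("up1", "down"), "r"] == pytest.approx(-1.0)
    assert rec.loc[("up1", "up2"), "p"] == 0.0


def test_spearman_ties_match_scipy(rng):
    for _ in range(100):
        x = rng.integers(0, 5, size=8)
        y = rng.integers(0, 5, size=8)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        counts = pd.DataFrame({"x": x + 1, "y": y + 1})  # +1 avoids zero-sum rows
        counts.index = [f"s{i}" for i in range(8)]
        t = AsvTable(counts)
        rec = spearman_matrix(t, _pool_of(t), min_n=4)
        ref_r, ref_p = spearmanr(x, y)
        assert rec["r"].iloc[0] == pytest.approx(ref_r, abs=1e-12)
        assert rec["p"].iloc[0] == pytest.approx(ref_p, abs=1e-9)


def test_spearman_constant_asv_excluded(caplog):
    counts = pd.DataFrame(
        {"var1": [1, 2, 3, 4], "const": [5, 5, 5, 5], "var2": [4, 3, 2, 1]},
        index=[f"s{i}" for i in range(4)],
    )
    t = AsvTable(counts)
    rec = spearman_matrix(t, _pool_of(t), min_n=4)
    pairs = set(map(tuple, rec[["asv_i", "asv_j"]].to_numpy()))
    assert pairs == {("var1", "var2")}


def test_spearman_too_few_samples_errors():
    counts = pd.DataFrame({"a": [1, 2], "b": [2, 1]}, index=["s0", "s1"])
    t = AsvTable(counts)
    with pytest.raises(ValueError, match="min_n"):
        spearman_matrix(t, _pool_of(t), min_n=4)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def test_threshold_boundaries_inclusive():
    rec = pd.DataFrame(
        {
            "asv_i": ["a", "a", "a", "b"],
            "asv_j": ["b", "c", "d", "c"],
            "r": [0.80, 0.79, -0.85, 0.9],
            "p": [0.05, 0.001, 0.04, 0.051],
            "n": 10,
        }
    )
    kept = threshold_edges(rec)
    pairs = set(map(tuple, kept[["asv_i", "asv_j"]].to_numpy()))
    assert pairs == {("a", "b"), ("a", "d")}


def test_threshold_matches_predicate_scan(rng):
    rec = pd.DataFrame(
        {
            "asv_i": [f"a{i}" for i in range(200)],
            "asv_j": [f"b{i}" for i in range(200)],
            "r": rng.uniform(-1, 1, 200),
            "p": rng.uniform(0, 0.2, 200),
            "n": 10,
        }
    )
    kept = threshold_edges(rec, r_min=0.5, alpha=0.05)
    expect = rec[(rec.r.abs() >= 0.5) & (rec.p <= 0.05)]
    assert len(kept) == len(expect)
    assert set(kept.asv_i) == set(expect.asv_i)


def test_edge_count_monotone_in_r_min(rng):
    rec = pd.DataFrame(
        {
            "asv_i": [f"a{i}" for i in range(300)],
            "asv_j": [f"b{i}" for i in range(300)],
            "r": rng.uniform(-1, 1, 300),
            "p": rng.uniform(0, 0.1, 300),
            "n": 10,
        }
    )
    sizes = [len(threshold_edges(rec, r_min=r)) for r in (0.9, 0.7, 0.5, 0.3)]
    assert sizes == sorted(sizes)


# ---------------------------------------------------------------------------
# graph construction and summaries
# ---------------------------------------------------------------------------

def _edges(pairs_r):
    return pd.DataFrame(
        [
            {"asv_i": i, "asv_j": j, "r": r, "p": 0.01, "n": 5}
            for i, j, r in pairs_r
        ],
        columns=list(EDGE_COLUMNS),
    )


def test_empty_network():
    nw = build_network(pd.DataFrame(columns=EDGE_COLUMNS), context=("BulkSoil", "N150", "16S"))
    assert (nw.n_nodes, nw.n_edges, nw.edges_per_node) == (0, 0, 0.0)
    row = summarize_networks([nw]).iloc[0]
    assert row["n_edges"] == 0 and row["edges_per_node"] == 0.0


def test_triangle_edges_per_node():
    nw = build_network(_edges([("a", "b", 0.9), ("b", "c", 0.85), ("a", "c", -0.95)]))
    assert nw.edges_per_node == pytest.approx(1.0)
    s = nw.summary()
    assert s["n_positive"] == 2 and s["n_negative"] == 1
    assert s["mean_degree"] == pytest.approx(2.0)
    assert s["n_components"] == 1


def test_two_planted_cliques():
    pairs = [
        (f"x{i}", f"x{j}", 0.9) for i, j in itertools.combinations(range(5), 2)
    ] + [
        (f"y{i}", f"y{j}", 0.9) for i, j in itertools.combinations(range(5), 2)
    ]
    nw = build_network(_edges(pairs))
    assert nw.n_edges == 20  # 2 * C(5,2)
    assert nw.summary()["n_components"] == 2


def test_isolated_pool_members_are_not_nodes():
    nw = build_network(_edges([("a", "b", 0.9)]))
    assert set(nw.graph.nodes) == {"a", "b"}


def test_summary_matches_recomputation(rng):
    pairs = []
    names = [f"n{i}" for i in range(12)]
    for i, j in itertools.combinations(range(12), 2):
        if rng.random() < 0.3:
            pairs.append((names[i], names[j], float(rng.uniform(-1, 1))))
    nw = build_network(_edges(pairs))
    row = summarize_networks([nw]).iloc[0]
    # oracle: independent traversal over the edge list
    nodes = {a for p in pairs for a in p[:2]}
    assert row["n_nodes"] == len(nodes)
    assert row["n_edges"] == len(pairs)
    assert row["edges_per_node"] == pytest.approx(len(pairs) / len(nodes))
    assert row["n_positive"] + row["n_negative"] == len(pairs)


def test_node_phylum_annotation():
    tax = pd.DataFrame(
        {"kingdom": ["Bacteria"] * 2, "phylum": ["Firmicutes", "Bacteroidetes"]},
        index=["a", "b"],
    )
    nw = build_network(_edges([("a", "b", 0.9)]), taxonomy=tax)
    assert nw.graph.nodes["a"]["phylum"] == "Firmicutes"


def test_graphml_round_trip(tmp_path):
    import networkx as nx

    from farmnet.network import write_graphml

    nw = build_network(_edges([("a", "b", 0.9), ("b", "c", -0.9)]),
                       context=("Rumen", "N0", "16S"))
    path = tmp_path / "net.graphml"
    write_graphml(nw, path)
    back = nx.read_graphml(path)
    assert set(back.nodes) == {"a", "b", "c"}
    assert back.edges["a", "b"]["sign"] == 1


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def test_layout_single_node_origin():
    nw = build_network(pd.DataFrame(columns=EDGE_COLUMNS))
    nw.graph.add_node("solo")
    assert layout_force_directed(nw) == {"solo": (0.0, 0.0)}


def test_layout_deterministic_and_bounded():
    nw = build_network(_edges([("a", "b", 0.9)]))
    pos1 = layout_force_directed(nw, seed=4)
    pos2 = layout_force_directed(nw, seed=4)
    assert pos1 == pos2
    (x1, y1), (x2, y2) = pos1["a"], pos1["b"]
    dist = math.hypot(x1 - x2, y1 - y2)
    # two connected nodes settle within a sane band of the ideal length
    assert 0.1 <= dist <= 10.0
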