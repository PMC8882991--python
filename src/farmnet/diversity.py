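"""Alpha/beta diversity statistics with native permutation machinery.

Implements observed richness, the tie-corrected Kruskal-Wallis H test,
Bray-Curtis dissimilarity, non-metric multidimensional scaling (NMDS,
Kruskal stress-1 with isotonic regression and Guttman updates), ANOSIM and
one-factor PERMANOVA with label-permutation p-values. The rank, permutation
and majorization machinery is written here rather than delegated so each
statistic has an independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import squareform
from scipy.stats import chi2, rankdata
from skbio import DistanceMatrix

from .table import AsvTable, TableError


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of a group-comparison test (H, ANOSIM R, or PERMANOVA F)."""

    method: str
    statistic: float
    p_value: float
    n_permutations: int = 0
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }
        d.update(self.extras)
        return d


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    n_iterations: int
    converged: bool
    stress_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def observed_richness(table: AsvTable) -> pd.Series:
    """Number of ASVs with count > 0, per sample."""
    return (table.counts > 0).sum(axis=1).rename("observed_richness")


def kruskal_wallis(values: Mapping[str, Sequence[float]]) -> GroupTestResult:
    """Kruskal-Wallis rank-sum test with tie correction.

    H is computed from average ranks of the pooled observations; the
    p-value comes from the chi-square approximation with g-1 degrees of
    freedom. When all observations are identical H = 0 and p = 1.
    """
    groups = list(values)
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires >= 2 groups")
    arrays = [np.asarray(values[g], dtype=float) for g in groups]
    for g, a in zip(groups, arrays):
        if a.size == 0:
            raise ValueError(f"group {g!r} is empty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = rankdata(pooled)
    splits = np.cumsum([a.size for a in arrays])[:-1]
    group_ranks = np.split(ranks, splits)
    rbar = (n + 1) / 2.0
    h = 12.0 / (n * (n + 1)) * sum(
        a.size * (r.mean() - rbar) ** 2 for a, r in zip(arrays, group_ranks)
    )
    # tie correction: divide by 1 - sum(t^3 - t) / (n^3 - n)
    _, t = np.unique(pooled, return_counts=True)
    denom = 1.0 - (t**3 - t).sum() / (n**3 - n)
    if denom <= 0:  # all observations identical
        return GroupTestResult("kruskal_wallis", 0.0, 1.0, extras={"df": len(groups) - 1})
    h /= denom
    p = float(chi2.sf(h, len(groups) - 1))
    return GroupTestResult("kruskal_wallis", float(h), p, extras={"df": len(groups) - 1})


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(table: AsvTable | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d(i,j) = 1 - 2 * sum_k min(x_ik, x_jk) / (sum_k x_ik + sum_k x_jk),
    computed via the L1 identity sum_k min = (s_i + s_j - sum_k |x_i - x_j|)/2.
    """
    counts = table.counts if isinstance(table, AsvTable) else table
    x = counts.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("bray_curtis requires >= 2 samples")
    sums = x.sum(axis=1)
    if np.any(sums == 0):
        bad = counts.index[sums == 0].tolist()
        raise TableError(f"zero-sum samples: {bad}")
    from scipy.spatial.distance import pdist

    l1 = pdist(x, metric="cityblock")
    pair_sums = np.add.outer(sums, sums)[np.triu_indices(len(sums), k=1)]
    d = l1 / pair_sums
    return DistanceMatrix(squareform(d), ids=[str(i) for i in counts.index])


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _kruskal_stress1(dhat: np.ndarray, dstar: np.ndarray) -> float:
    denom = (dhat**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - dstar) ** 2).sum() / denom))


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Alternates isotonic regression of the embedded distances on the
    dissimilarity order (disparities) with a Guttman-transform update of
    the configuration. The first start is the classical-scaling (PCoA)
    configuration; remaining starts are random. Best start by final stress
    wins.
    """
    ids = list(d.ids)
    n = len(ids)
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    diss = squareform(d.data, checks=False)
    order = np.argsort(diss, kind="stable")
    rng = np.random.default_rng(seed)

    def run(x0: np.ndarray):
        x = x0.copy()
        trace: list[float] = []
        prev = np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            dhat = _pdist(x)
            dhat = np.maximum(dhat, 1e-12)
            dstar = np.empty_like(dhat)
            dstar[order] = isotonic_regression(dhat[order]).x
            stress = _kruskal_stress1(dhat, dstar)
            trace.append(stress)
            if prev - stress < tol:
                converged = True
                break
            prev = stress
            # Guttman transform with disparities dstar
            ratio = squareform(dstar / dhat, checks=False)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = b @ x / n
            x -= x.mean(axis=0)
        return x, trace, converged, it

    best = None
    for s in range(n_starts):
        if s == 0:
            x0 = _classical_scaling(d.data, k)
        else:
            x0 = rng.standard_normal((n, k))
        x, trace, conv, it = run(x0)
        if best is None or trace[-1] < best[1][-1]:
            best = (x, trace, conv, it)
    x, trace, conv, it = best
    coords = pd.DataFrame(x, index=ids, columns=[f"NMDS{i+1}" for i in range(k)])
    return OrdinationResult(coords, trace[-1], it, conv, trace)


def _pdist(x: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist as _p

    return _p(x)


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """PCoA configuration used as the deterministic NMDS start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:k]
    w = np.clip(w[idx], 0, None)
    return v[:, idx] * np.sqrt(w)


# ---------------------------------------------------------------------------
# ANOSIM / PERMANOVA
# ---------------------------------------------------------------------------

def _group_vector(d: DistanceMatrix, groups: Mapping[str, str]) -> np.ndarray:
    try:
        return np.asarray([groups[i] for i in d.ids])
    except KeyError as exc:
        raise ValueError(f"sample {exc.args[0]!r} missing from the grouping") from exc


def _check_groups(labels: np.ndarray, min_size: int = 2) -> None:
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    small = uniq[counts < min_size]
    if len(small):
        raise ValueError(f"groups with fewer than {min_size} members: {small.tolist()}")


def anosim_statistic(d: DistanceMatrix, labels: Sequence[str]) -> float:
    """ANOSIM R = (mean between-rank - mean within-rank) / (M/2)."""
    labels = np.asarray(labels)
    condensed = squareform(d.data, checks=False)
    ranks = rankdata(condensed)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    within = labels[iu[0]] == labels[iu[1]]
    m = n * (n - 1) / 2
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def _distinct_label_arrangements(labels: np.ndarray) -> list[np.ndarray]:
    """All distinct arrangements of a small label multiset (n <= 10)."""
    import itertools

    if len(labels) > 10:
        raise ValueError("exhaustive enumeration limited to n <= 10 samples")
    return [np.asarray(p) for p in sorted(set(itertools.permutations(labels)))]


def anosim(
    d: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> GroupTestResult:
    """ANOSIM with a label-permutation p-value, p = (b+1)/(m+1).

    ``exhaustive=True`` enumerates every distinct label arrangement
    instead (small n only); p is then the exact permutation p-value
    #(R_perm >= R_obs) / n_arrangements, the identity included.
    """
    labels = _group_vector(d, groups)
    _check_groups(labels)
    n = len(labels)
    condensed = squareform(d.data, checks=False)
    rank_mat = squareform(rankdata(condensed))  # square matrix of pair ranks
    iu = np.triu_indices(n, k=1)
    m = n * (n - 1) / 2.0

    def stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        r = rank_mat[iu]
        return float((r[~within].mean() - r[within].mean()) / (m / 2.0))

    observed = stat(labels)
    if exhaustive:
        stats = [stat(lab) for lab in _distinct_label_arrangements(labels)]
        p = sum(s >= observed - 1e-12 for s in stats) / len(stats)
        return GroupTestResult("anosim", observed, p, len(stats), None)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        if stat(rng.permutation(labels)) >= observed:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return GroupTestResult("anosim", observed, p, n_perm, seed)


def permanova_statistics(d: DistanceMatrix, labels: Sequence[str]) -> tuple[float, float]:
    """One-factor PERMANOVA (pseudo-F, R^2) from squared dissimilarities."""
    labels = np.asarray(labels)
    n = len(labels)
    d2 = d.data**2
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    uniq, counts = np.unique(labels, return_counts=True)
    for g, ng in zip(uniq, counts):
        idx = np.where(labels == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / ng
    ss_between = ss_total - ss_within
    g = len(uniq)
    if ss_within == 0:  # perfect within-group duplication -> F unbounded
        f = np.inf
    else:
        f = (ss_between / (g - 1)) / (ss_within / (n - g))
    r2 = ss_between / ss_total
    return float(f), float(r2)


def permanova(
    d: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> GroupTestResult:
    """One-factor PERMANOVA with a label-permutation p-value on pseudo-F."""
    labels = _group_vector(d, groups)
    _check_groups(labels)
    f_obs, r2 = permanova_statistics(d, labels)
    if exhaustive:
        stats = [
            permanova_statistics(d, lab)[0]
            for lab in _distinct_label_arrangements(labels)
        ]
        p = sum(s >= f_obs - 1e-12 for s in stats) / len(stats)
        return GroupTestResult("permanova", f_obs, p, len(stats), None,
                               extras={"r_squared": r2})
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        f_perm, _ = permanova_statistics(d, rng.permutation(labels))
        if f_perm >= f_obs:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return GroupTestResult(
        "permanova", f_obs, p, n_perm, seed, extras={"r_squared": r2}
    )


# ---------------------------------------------------------------------------
# serialisation helpers
# ---------------------------------------------------------------------------

def write_distance_matrix(d: DistanceMatrix, path) -> None:
    df = pd.DataFrame(d.data, index=list(d.ids), columns=list(d.ids))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])
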