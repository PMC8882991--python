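"""Thresholded Spearman co-occurrence networks per niche x treatment.

The ASV pool for a niche keeps ASVs that are present in at least 60% of the
niche's samples and are either nitrogen-responsive anywhere in the study or
among the 200 most abundant ASVs study-wide. Within each niche x treatment
context, tie-aware Spearman correlations are computed between all pool
pairs and edges with |r| >= 0.8 and p <= 0.05 (raw, mirroring common
practice for these networks) are kept in a signed undirected graph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .table import AsvTable
from .differential import bh_adjust

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ("asv_i", "asv_j", "r", "p", "n")


@dataclass
class AsvPool:
    """Ordered candidate ASV set for one niche, with provenance flags."""

    asv_ids: list[str]
    provenance: pd.DataFrame  # index asv_id; bool columns n_responsive, top200, prevalence_pass

    def __len__(self) -> int:
        return len(self.asv_ids)


@dataclass
class CoocNetwork:
    """Signed co-occurrence graph for one (niche, treatment, amplicon)."""

    context: tuple[str, str, str]
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges_per_node(self) -> float:
        return self.n_edges / self.n_nodes if self.n_nodes else 0.0

    def summary(self) -> dict:
        signs = [d["sign"] for _, _, d in self.graph.edges(data=True)]
        degrees = [deg for _, deg in self.graph.degree()]
        return {
            "niche": self.context[0],
            "treatment": self.context[1],
            "amplicon": self.context[2],
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "edges_per_node": self.edges_per_node,
            "n_positive": sum(s > 0 for s in signs),
            "n_negative": sum(s < 0 for s in signs),
            "mean_degree": float(np.mean(degrees)) if degrees else 0.0,
            "n_components": nx.number_connected_components(self.graph),
        }


def select_asv_pool(
    niche_table: AsvTable,
    n_responsive_set: Iterable[str],
    study_table: AsvTable | None = None,
    top_n: int = 200,
    prevalence: float = 0.6,
) -> AsvPool:
    """Pool = prevalence-passing ASVs that are N-responsive or top-N abundant.

    Prevalence ("present in at least 60% of samples") is evaluated within
    the niche across all treatments; the top-N abundance ranking uses total
    counts over the whole study table (the niche table itself when no study
    table is given).
    """
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must lie in (0, 1]")
    counts = niche_table.counts
    n = counts.shape[0]
    need = math.ceil(prevalence * n)
    present = (counts > 0).sum(axis=0)
    prevalence_pass = present >= need

    ranking_counts = (study_table or niche_table).counts
    totals = ranking_counts.sum(axis=0).sort_values(ascending=False, kind="stable")
    top_set = set(totals.index[:top_n])
    responsive = set(n_responsive_set)

    prov = pd.DataFrame(
        {
            "prevalence_pass": prevalence_pass,
            "n_responsive": counts.columns.isin(responsive),
            "top200": counts.columns.isin(top_set),
        },
        index=counts.columns,
    )
    member = prov["prevalence_pass"] & (prov["n_responsive"] | prov["top200"])
    pool_ids = list(counts.columns[member])
    if not pool_ids:
        logger.warning("select_asv_pool: empty pool for %d-sample niche table", n)
    return AsvPool(pool_ids, prov.loc[pool_ids])


def spearman_matrix(
    context_table: AsvTable,
    pool: AsvPool,
    min_n: int = 4,
) -> pd.DataFrame:
    """Tie-aware Spearman r and t-approximation p for all pool pairs.

    Returns one row per unordered pair (asv_i < asv_j in pool order),
    unfiltered. Pool ASVs constant across the context's samples have no
    defined rank correlation and are excluded with a log entry. |r| = 1
    yields p = 0.
    """
    counts = context_table.counts
    n = counts.shape[0]
    if n < min_n:
        raise ValueError(f"context has {n} samples, fewer than min_n={min_n}")
    cols = [a for a in pool.asv_ids if a in counts.columns]
    x = counts[cols].to_numpy(dtype=float)
    variable = x.std(axis=0) > 0
    dropped = [c for c, v in zip(cols, variable) if not v]
    if dropped:
        logger.info("spearman_matrix: %d constant ASVs excluded: %s", len(dropped), dropped[:10])
    cols = [c for c, v in zip(cols, variable) if v]
    if len(cols) < 2:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    ranks = np.apply_along_axis(rankdata, 0, x[:, variable])
    r = np.corrcoef(ranks, rowvar=False)
    iu = np.triu_indices(len(cols), k=1)
    rv = np.clip(r[iu], -1.0, 1.0)
    exact = np.abs(rv) >= 1.0 - 1e-12  # snap float noise on perfect monotone pairs
    rv = np.where(exact, np.sign(rv), rv)
    with np.errstate(divide="ignore"):
        tstat = rv * np.sqrt((n - 2) / (1.0 - rv**2))
    p = np.where(np.abs(rv) >= 1.0, 0.0, 2.0 * t_dist.sf(np.abs(tstat), n - 2))
    cols_arr = np.asarray(cols)
    return pd.DataFrame(
        {
            "asv_i": cols_arr[iu[0]],
            "asv_j": cols_arr[iu[1]],
            "r": rv,
            "p": p,
            "n": n,
        }
    )


def threshold_edges(
    records: pd.DataFrame,
    r_min: float = 0.8,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Keep strong significant correlations: |r| >= r_min and p <= alpha.

    Boundaries are inclusive. ``adjust=True`` applies BH to the p-values
    first (off by default; the headline procedure thresholds raw p).
    """
    if records.empty:
        return records.copy()
    p = bh_adjust(records["p"].to_numpy()) if adjust else records["p"].to_numpy()
    keep = (np.abs(records["r"].to_numpy()) >= r_min) & (p <= alpha)
    return records.loc[keep].reset_index(drop=True)


def build_network(
    edges: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    context: tuple[str, str, str] = ("", "", ""),
    provenance: pd.DataFrame | None = None,
    phylum_rank: str = "phylum",
) -> CoocNetwork:
    """Build the signed undirected graph from surviving edges.

    Nodes are exactly the edge endpoints — pool members with no surviving
    edge do not appear. An empty edge list yields an empty network.
    """
    g = nx.Graph()
    if not edges.empty:
        for row in edges.sort_values(["asv_i", "asv_j"], kind="stable").itertuples():
            g.add_edge(
                row.asv_i,
                row.asv_j,
                r=float(row.r),
                p=float(row.p),
                sign=1 if row.r > 0 else -1,
            )
    for node in g.nodes:
        phylum = "unassigned"
        if taxonomy is not None and node in taxonomy.index:
            if phylum_rank in taxonomy.columns:
                phylum = str(taxonomy.loc[node, phylum_rank])
            elif len(taxonomy.columns) > 1:
                phylum = str(taxonomy.loc[node].iloc[1])
        g.nodes[node]["phylum"] = phylum
        if provenance is not None and node in provenance.index:
            for flag in ("n_responsive", "top200", "prevalence_pass"):
                g.nodes[node][flag] = bool(provenance.loc[node, flag])
    return CoocNetwork(context, g)


def summarize_networks(networks: Sequence[CoocNetwork]) -> pd.DataFrame:
    """One summary row per network (niche, treatment, amplicon)."""
    return pd.DataFrame([nw.summary() for nw in networks])


def layout_force_directed(
    network: CoocNetwork,
    iterations: int = 50,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold layout, deterministic for a fixed seed."""
    g = network.graph
    if g.number_of_nodes() == 0:
        return {}
    if g.number_of_nodes() == 1:
        return {next(iter(g.nodes)): (0.0, 0.0)}
    pos = nx.spring_layout(g, iterations=iterations, seed=seed)
    return {node: (float(xy[0]), float(xy[1])) for node, xy in pos.items()}


def write_edge_list(edges: pd.DataFrame, path) -> None:
    out = edges.copy()
    if not out.empty:
        out["sign"] = np.where(out["r"] > 0, 1, -1)
    else:
        out["sign"] = []
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_graphml(network: CoocNetwork, path) -> None:
    g = network.graph.copy()
    g.graph["niche"], g.graph["treatment"], g.graph["amplicon"] = network.context
    nx.write_graphml(g, path)
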