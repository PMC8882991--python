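"""Negative-binomial exact tests for nitrogen-responsive ASV calling.

Per niche, counts of two treatment groups (rarefied to equal depth, so
library sizes are equal) are compared ASV by ASV with a conditional exact
test on negative-binomial group sums: under the null the two group totals
Y_A ~ NB(n_A mu, phi/n_A) and Y_B ~ NB(n_B mu, phi/n_B) are compared
conditionally on their sum, with a probability-mass-ordering two-sided
rule. A common dispersion phi (variance = mu + phi mu^2) is estimated by a
trimmed method-of-moments pool across ASVs. Benjamini-Hochberg adjustment
is applied within each (niche, contrast) family and an ASV is called
N-responsive when |log2 fold change| >= 2 and adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom, nbinom, trim_mean

from .table import AsvTable

CONTRASTS = (("N0", "N150"), ("N0", "N300"))

#: relative tolerance when comparing conditional probability masses, so the
#: observed outcome's own mass is always included despite float rounding
_MASS_TIE_RTOL = 1e-10


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    method: str
    n_asvs_used: int


def estimate_common_dispersion(
    table: AsvTable | pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
) -> DispersionEstimate:
    """Common NB dispersion by pooled method-of-moments with trimming.

    Within each group, phi_k = max(0, (s_k^2 - xbar_k) / xbar_k^2) per ASV
    (undefined when the group mean is 0); per-ASV group estimates are
    averaged, and the common value is the 20%-trimmed mean over ASVs with
    at least one defined estimate.
    """
    counts = table.counts if isinstance(table, AsvTable) else table
    labels = pd.Series(groups).loc[counts.index]
    uniq = labels.unique()
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(uniq)}")
    per_group = []
    for g in uniq:
        sub = counts.loc[labels == g].to_numpy(dtype=float)
        if sub.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        xbar = sub.mean(axis=0)
        s2 = sub.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(xbar > 0, np.maximum(0.0, (s2 - xbar) / xbar**2), np.nan)
        per_group.append(phi)
    stacked = np.vstack(per_group)
    valid = ~np.isnan(stacked)
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        pooled = np.where(n_valid > 0, np.nansum(np.where(valid, stacked, 0.0), axis=0) / np.maximum(n_valid, 1), np.nan)
    usable = pooled[~np.isnan(pooled)]
    if usable.size == 0:
        return DispersionEstimate(0.0, "mom_trimmed", 0)
    phi = float(trim_mean(usable, proportiontocut=0.2)) if usable.size > 2 else float(usable.mean())
    return DispersionEstimate(max(0.0, phi), "mom_trimmed", int(usable.size))


def nb_exact_test(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    phi: float,
    prior_count: float = 0.5,
) -> tuple[float, float]:
    """Conditional NB exact test on group sums; returns (log2FC, p).

    Requires equal per-sample library sizes (guaranteed after rarefaction).
    Two-sided p sums the conditional probability of every split of the
    total no more probable than the observed one. log2FC compares per-sample
    group means with a prior count added to each to avoid infinities.
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    n_a, n_b = a.size, b.size
    y_a, y_b = int(a.sum()), int(b.sum())
    s = y_a + y_b
    logfc = float(np.log2((y_a / n_a + prior_count) / (y_b / n_b + prior_count)))
    if s == 0:
        return 0.0, 1.0
    grid = np.arange(s + 1)
    if phi == 0.0:
        # Poisson limit: conditional distribution is Binomial(s, n_a/(n_a+n_b))
        logp = binom.logpmf(grid, s, n_a / (n_a + n_b))
    else:
        mu = s / (n_a + n_b)  # common per-sample mean under the null
        pp = 1.0 / (1.0 + phi * mu)
        logp = nbinom.logpmf(grid, n_a / phi, pp) + nbinom.logpmf(s - grid, n_b / phi, pp)
        logp -= logsumexp(logp)
    obs = logp[y_a]
    keep = logp <= obs + _MASS_TIE_RTOL
    p = float(np.exp(logsumexp(logp[keep])))
    return logfc, min(1.0, p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def exact_test_table(
    table: AsvTable | pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    phi: float | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Run the exact test for every ASV; BH-adjust within the family.

    ASVs with zero total count in both groups are excluded (logged count in
    the ``n_excluded`` attribute). Returns a DataFrame indexed by asv_id
    with columns logFC, p_value, p_adj.
    """
    counts = table.counts if isinstance(table, AsvTable) else table
    labels = pd.Series(groups).loc[counts.index]
    sub_a = counts.loc[labels == group_a]
    sub_b = counts.loc[labels == group_b]
    if sub_a.shape[0] < 2 or sub_b.shape[0] < 2:
        raise ValueError("each group needs >= 2 samples")
    if phi is None:
        both = pd.concat([sub_a, sub_b])
        phi = estimate_common_dispersion(
            both, labels.loc[both.index]
        ).phi
    totals = sub_a.sum(axis=0) + sub_b.sum(axis=0)
    tested = totals.index[totals > 0]
    rows = []
    a_mat = sub_a[tested].to_numpy()
    b_mat = sub_b[tested].to_numpy()
    for j, asv in enumerate(tested):
        logfc, p = nb_exact_test(a_mat[:, j], b_mat[:, j], phi, prior_count)
        rows.append((asv, logfc, p))
    df = pd.DataFrame(rows, columns=["asv_id", "logFC", "p_value"]).set_index("asv_id")
    df["p_adj"] = bh_adjust(df["p_value"].to_numpy()) if len(df) else []
    df.attrs["phi"] = phi
    df.attrs["n_excluded"] = int((totals == 0).sum())
    return df


def call_n_responsive(
    results: pd.DataFrame,
    logfc_min: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag ASVs with |logFC| >= logfc_min and BH-adjusted p < alpha."""
    out = results.copy()
    out["n_responsive"] = (out["logFC"].abs() >= logfc_min) & (out["p_adj"] < alpha)
    return out


def differential_abundance(
    table: AsvTable,
    niche: str,
    contrasts: Sequence[tuple[str, str]] = CONTRASTS,
    logfc_min: float = 2.0,
    alpha: float = 0.05,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """All contrasts for one niche; one row per (ASV, contrast).

    The treated group is A and the untreated (N0) group is B in each
    contrast, so positive logFC means enrichment under nitrogen.
    """
    from .table import subset

    frames = []
    for base, treated in contrasts:
        sub = subset(table, niche=niche)
        labels = sub.metadata["treatment"]
        sel = labels.isin([base, treated])
        counts = sub.counts.loc[sel]
        labels = labels.loc[sel]
        res = exact_test_table(
            AsvTable(counts), labels, treated, base, prior_count=prior_count
        )
        res = call_n_responsive(res, logfc_min, alpha)
        res["niche"] = niche
        res["contrast"] = f"{base}_vs_{treated}"
        frames.append(res.reset_index())
    return pd.concat(frames, ignore_index=True)


def n_responsive_union(results: pd.DataFrame) -> set[str]:
    """Study-wide N-responsive set: union over niches and contrasts."""
    return set(results.loc[results["n_responsive"], "asv_id"])
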