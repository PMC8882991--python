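"""Synthetic multi-niche ASV tables with known ground truth.

The generator emulates a multi-niche farm study design: seven niches
sampled under three soil-nitrogen treatments with three amplicon-like
subpopulations, niche-specific composition (overlapping per-niche ASV
windows over a global pool), log-normal base abundances with
negative-binomial sampling noise, planted treatment fold-changes, planted
latent correlation blocks imposed through a Gaussian copula (so marginals
stay exactly NB while rank correlation is tunable), and zero-inflated
"satellite" taxa that create core-satellite occupancy structure.

Every planted signal is echoed in a :class:`SyntheticTruth` record so
downstream stages (differential abundance, network inference, occupancy
classification) can be scored against ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import nbinom, poisson

from .table import AMPLICONS, NICHES, TREATMENTS, AsvTable

#: per-niche sample counts mirroring the study design (169 samples total)
STUDY_NICHE_SIZES = {
    "Rumen": 52,
    "Faecal": 62,
    "BulkSoil": 11,
    "P.RyeGrassRoot": 12,
    "P.RyeGrassLeaf": 9,
    "WhiteCloverRoot": 11,
    "WhiteCloverLeaf": 12,
}

_PHYLA = (
    "Proteobacteria", "Bacteroidetes", "Firmicutes", "Actinobacteria",
    "Acidobacteria", "Verrucomicrobia", "Chloroflexi", "Planctomycetes",
)


def _split_three(n: int) -> tuple[int, int, int]:
    base = n // 3
    rem = n - 3 * base
    return (base + (rem > 0), base + (rem > 1), base)


@dataclass(frozen=True)
class PlantedEffect:
    """A planted differential-abundance signal: ``fold_change`` multiplies
    the ASV's mean in ``treatment`` samples of ``niche`` (contrast vs N0)."""

    asv: str
    niche: str
    treatment: str
    fold_change: float

    @property
    def contrast(self) -> str:
        return f"N0_vs_{self.treatment}"


@dataclass(frozen=True)
class CorrelationBlock:
    """Latent equicorrelated ASV block within one niche.

    The latent Gaussian correlation between block members in samples of
    treatment t is ``rho * gamma[t]`` (gamma defaults to 1 everywhere).
    """

    asvs: tuple[str, ...]
    niche: str
    rho: float
    gamma: Mapping[str, float] = field(default_factory=dict)

    def rho_eff(self, treatment: str) -> float:
        return self.rho * float(self.gamma.get(treatment, 1.0))


def expected_spearman(rho: float) -> float:
    """Large-sample Spearman correlation implied by latent Gaussian rho
    (continuous-marginal limit; NB discreteness attenuates it slightly)."""
    return 6.0 / math.pi * math.asin(rho / 2.0)


@dataclass
class SyntheticConfig:
    seed: int = 0
    amplicon: str = "16S"
    niche_samples: dict = field(
        default_factory=lambda: {
            niche: dict(zip(TREATMENTS, _split_three(n)))
            for niche, n in STUDY_NICHE_SIZES.items()
        }
    )
    n_asvs_total: int = 600
    n_asvs_per_niche: int = 250
    mu_log: float = 1.0
    sigma_log: float = 1.5
    phi: float = 0.3
    libsize_sigma: float = 0.3
    da_effects: list = field(default_factory=list)
    blocks: list = field(default_factory=list)
    occupancy_mode: str = "core_satellite"
    satellite_fraction: float = 0.88
    satellite_beta: tuple = (0.3, 6.0)
    # abundance-occupancy coupling: presence probability is floored for
    # abundant taxa (ramp from lo to hi mean), so a high-count taxon is
    # never present in just one or two samples of a niche
    satellite_abundant_lo: float = 6.0
    satellite_abundant_hi: float = 15.0
    satellite_abundant_presence: float = 0.85
    core_fraction: float = 0.05
    core_min_mean: float = 50.0
    mid_presence_lo: float = 0.9
    flat_presence: float = 0.5
    flat_sigma_log: float = 0.5
    block_min_mean: float = 20.0
    da_min_mean: float = 10.0
    n_chloroplast: int = 0
    truth_r_min: float = 0.8

    def validate(self) -> None:
        if self.occupancy_mode not in ("core_satellite", "flat"):
            raise ValueError(f"unknown occupancy_mode {self.occupancy_mode!r}")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        for eff in self.da_effects:
            if eff.fold_change <= 0:
                raise ValueError(f"fold change must be > 0: {eff}")
            if eff.treatment not in TREATMENTS:
                raise ValueError(f"unknown treatment in {eff}")
        seen: dict[str, set] = {}
        for blk in self.blocks:
            if not 0 <= blk.rho < 1:
                raise ValueError(f"block rho must be in [0, 1): {blk.rho}")
            for t, g in blk.gamma.items():
                if not 0 <= g <= 1:
                    raise ValueError(f"gamma must be in [0, 1]: {g}")
            used = seen.setdefault(blk.niche, set())
            overlap = used.intersection(blk.asvs)
            if overlap:
                raise ValueError(
                    f"overlapping blocks in {blk.niche}: {sorted(overlap)}"
                )
            used.update(blk.asvs)
        for niche, per_t in self.niche_samples.items():
            if niche not in NICHES:
                raise ValueError(f"unknown niche {niche!r}")
            if any(n < 0 for n in per_t.values()):
                raise ValueError(f"negative sample count for {niche}")


@dataclass
class SyntheticTruth:
    """Ground truth of planted signals, for recovery scoring."""

    da_truth: list  # of PlantedEffect
    edge_truth: dict  # (niche, treatment) -> set of frozenset({asv_i, asv_j})
    params: dict = field(default_factory=dict)

    def edges_for(self, niche: str, treatment: str) -> set:
        return self.edge_truth.get((niche, treatment), set())

    def to_json(self, path) -> None:
        payload = {
            "da_truth": [asdict(e) for e in self.da_truth],
            "edge_truth": {
                f"{niche}|{treatment}": sorted(sorted(pair) for pair in pairs)
                for (niche, treatment), pairs in self.edge_truth.items()
            },
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            [PlantedEffect(**e) for e in payload["da_truth"]],
            {
                tuple(key.split("|")): {frozenset(p) for p in pairs}
                for key, pairs in payload["edge_truth"].items()
            },
            payload.get("params", {}),
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _asv_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"ASV_{i:0{width}d}" for i in range(n)]


def _niche_window(config: SyntheticConfig, niche_index: int) -> slice:
    """Contiguous, overlapping window of the global pool for one niche."""
    total, per = config.n_asvs_total, config.n_asvs_per_niche
    n_niches = len(config.niche_samples)
    if per > total:
        raise ValueError("n_asvs_per_niche cannot exceed n_asvs_total")
    if n_niches == 1:
        return slice(0, per)
    start = round(niche_index * (total - per) / (n_niches - 1))
    return slice(start, start + per)


def _nb_quantile(u: np.ndarray, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0.0:
        return poisson.ppf(u, mean).astype(np.int64)
    r = 1.0 / phi
    p = r / (r + mean)
    return nbinom.ppf(u, r, p).astype(np.int64)


def generate_counts(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[AsvTable, SyntheticTruth]:
    """Draw one synthetic study table plus its ground-truth record.

    Per niche: base ASV means come from a log-normal; each sample's counts
    are NB quantiles of a Gaussian-copula vector whose within-block latent
    correlation is rho * gamma(treatment); planted fold-changes multiply
    treated-sample means; satellite ASVs are independently zeroed per
    sample. Bitwise reproducible for a fixed config + seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    all_ids = _asv_ids(config.n_asvs_total)
    chl_ids = [f"ASV_chl_{i:03d}" for i in range(config.n_chloroplast)]

    effects_by_niche: dict[str, list[PlantedEffect]] = {}
    for eff in config.da_effects:
        effects_by_niche.setdefault(eff.niche, []).append(eff)
    blocks_by_niche: dict[str, list[CorrelationBlock]] = {}
    for blk in config.blocks:
        blocks_by_niche.setdefault(blk.niche, []).append(blk)

    sample_rows = []
    meta_rows = []
    sample_ids = []

    for niche_index, (niche, per_treatment) in enumerate(config.niche_samples.items()):
        window = _niche_window(config, niche_index)
        active = all_ids[window]
        n_active = len(active)
        idx_of = {a: i for i, a in enumerate(active)}

        flat = config.occupancy_mode == "flat"
        sigma = config.flat_sigma_log if flat else config.sigma_log
        base_means = rng.lognormal(config.mu_log, sigma, size=n_active)

        # enforce detectability floors for planted taxa
        blocked_idx = set()
        for blk in blocks_by_niche.get(niche, []):
            for a in blk.asvs:
                if a not in idx_of:
                    raise ValueError(f"block ASV {a} outside niche window of {niche}")
                base_means[idx_of[a]] = max(base_means[idx_of[a]], config.block_min_mean)
                blocked_idx.add(idx_of[a])
        planted_idx = set()
        for eff in effects_by_niche.get(niche, []):
            if eff.asv not in idx_of:
                raise ValueError(f"planted ASV {eff.asv} outside niche window of {niche}")
            base_means[idx_of[eff.asv]] = max(base_means[idx_of[eff.asv]], config.da_min_mean)
            planted_idx.add(idx_of[eff.asv])

        # occupancy roles by abundance rank: a large satellite class with
        # right-skewed presence probabilities (mode near occupancy 1), a
        # small always-present core, and a middle class in between. Planted
        # block/DA taxa are always core-like so their signals survive.
        presence = np.ones(n_active)
        if flat:
            presence[:] = config.flat_presence
        else:
            order = np.argsort(base_means, kind="stable")
            n_sat = int(round(config.satellite_fraction * n_active))
            n_core = int(round(config.core_fraction * n_active))
            sat_draw = rng.beta(*config.satellite_beta, size=n_sat)
            mid_lo = config.mid_presence_lo
            n_mid = max(0, n_active - n_sat - n_core)
            mid_draw = rng.uniform(mid_lo, 1.0, size=n_mid)
            protected = planted_idx | blocked_idx
            lo, hi = config.satellite_abundant_lo, config.satellite_abundant_hi
            for j, i in enumerate(order[:n_sat]):
                if i not in protected:
                    ramp = np.clip((base_means[i] - lo) / max(hi - lo, 1e-9), 0.0, 1.0)
                    floor = ramp * config.satellite_abundant_presence
                    presence[i] = max(sat_draw[j], floor)
            for j, i in enumerate(order[n_sat:n_sat + n_mid]):
                if i not in protected:
                    presence[i] = mid_draw[j]
            core_idx = order[::-1][:n_core]
            base_means[core_idx] = np.maximum(base_means[core_idx], config.core_min_mean)

        fold = {t: np.ones(n_active) for t in TREATMENTS}
        for eff in effects_by_niche.get(niche, []):
            fold[eff.treatment][idx_of[eff.asv]] *= eff.fold_change

        # Presence/absence is a niche-level property: draw each ASV's total
        # number of occupied samples once, then spread the occupied slots as
        # evenly as possible over treatments (random within a treatment).
        # Independent per-sample zeroing would otherwise fabricate
        # treatment-level abundance differences in 3-4-sample niches.
        treatments_here = [t for t in TREATMENTS if int(per_treatment.get(t, 0)) > 0]
        n_per_t = {t: int(per_treatment[t]) for t in treatments_here}
        n_niche = sum(n_per_t.values())
        absent_mask = {t: np.zeros((n_per_t[t], n_active), dtype=bool) for t in treatments_here}
        inflated = np.where(presence < 1.0)[0]
        for i in inflated:
            k = int(rng.binomial(n_niche, presence[i]))
            quota, rem = divmod(k, len(treatments_here))
            extras = rng.permutation(len(treatments_here))[:rem]
            for ti, t in enumerate(treatments_here):
                k_t = min(quota + (ti in extras), n_per_t[t])
                absent = np.ones(n_per_t[t], dtype=bool)
                if k_t:
                    absent[rng.choice(n_per_t[t], size=k_t, replace=False)] = False
                absent_mask[t][:, i] = absent

        for treatment in treatments_here:
            n_samples = n_per_t[treatment]
            lib = rng.lognormal(0.0, config.libsize_sigma, size=n_samples)
            z = rng.standard_normal((n_samples, n_active))
            for blk in blocks_by_niche.get(niche, []):
                rho_eff = blk.rho_eff(treatment)
                if rho_eff > 0:
                    shared = rng.standard_normal(n_samples)
                    if n_samples > 1:
                        # centre the block factor within the treatment group:
                        # planted co-fluctuation must not double as a planted
                        # group-mean shift
                        shared = shared - shared.mean()
                    cols = [idx_of[a] for a in blk.asvs]
                    z[:, cols] = (
                        math.sqrt(rho_eff) * shared[:, None]
                        + math.sqrt(1.0 - rho_eff) * z[:, cols]
                    )
            u = np.clip(ndtr(z), 1e-12, 1 - 1e-12)
            mean = base_means[None, :] * lib[:, None] * fold[treatment][None, :]
            counts = _nb_quantile(u, np.maximum(mean, 1e-9), config.phi)
            counts[absent_mask[treatment]] = 0
            chl_counts = None
            if chl_ids:
                chl_counts = rng.poisson(5.0, size=(n_samples, len(chl_ids)))
            for i in range(n_samples):
                sid = f"{niche}.{treatment}.{i:03d}"
                sample_ids.append(sid)
                row = np.zeros(config.n_asvs_total, dtype=np.int64)
                row[window] = counts[i]
                if chl_counts is not None:
                    row = np.concatenate([row, chl_counts[i]])
                sample_rows.append(row)
                meta_rows.append((sid, niche, treatment, config.amplicon))

    columns = all_ids + chl_ids
    counts_df = pd.DataFrame(
        np.vstack(sample_rows), index=sample_ids, columns=columns
    )
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "niche", "treatment", "amplicon"]
    ).set_index("sample_id")
    taxonomy = _synthetic_taxonomy(all_ids, chl_ids)
    table = AsvTable(counts_df, metadata, taxonomy)

    edge_truth: dict[tuple[str, str], set] = {}
    for blk in config.blocks:
        for treatment in TREATMENTS:
            if expected_spearman(blk.rho_eff(treatment)) >= config.truth_r_min:
                pairs = edge_truth.setdefault((blk.niche, treatment), set())
                for i, a in enumerate(blk.asvs):
                    for b_ in blk.asvs[i + 1:]:
                        pairs.add(frozenset((a, b_)))
    truth = SyntheticTruth(
        list(config.da_effects),
        edge_truth,
        params={
            "phi": config.phi,
            "mu_log": config.mu_log,
            "sigma_log": config.sigma_log,
            "occupancy_mode": config.occupancy_mode,
            "truth_r_min": config.truth_r_min,
            "n_asvs_total": config.n_asvs_total,
        },
    )
    return table, truth


def _synthetic_taxonomy(asv_ids: Sequence[str], chl_ids: Sequence[str]) -> pd.DataFrame:
    rows = []
    for i, asv in enumerate(asv_ids):
        phylum = _PHYLA[i % len(_PHYLA)]
        rows.append(
            (asv, "Bacteria", phylum, f"Class_{i % 17}", f"Order_{i % 29}",
             f"Family_{i % 41}", f"Genus_{i % 59}")
        )
    for i, asv in enumerate(chl_ids):
        rows.append(
            (asv, "Bacteria", "Cyanobacteria", "Oxyphotobacteria", "Chloroplast",
             "unassigned", "unassigned")
        )
    return pd.DataFrame(
        rows,
        columns=["asv_id", "kingdom", "phylum", "class", "order", "family", "genus"],
    ).set_index("asv_id")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset_study_mimic(
    amplicon: str = "16S",
    n_asvs_total: int = 420,
    n_asvs_per_niche: int = 180,
    seed: int = 0,
) -> SyntheticConfig:
    """Config planting the study's qualitative findings.

    Bulk-soil correlation blocks collapse under nitrogen (gamma = 0 for
    N150/N300), animal-niche blocks vary with treatment (faecal densest
    under medium nitrogen), plant niches carry stable weak blocks below
    the edge threshold, and ~40 differential ASVs are planted in the two
    animal niches only.
    """
    config = SyntheticConfig(
        seed=seed,
        amplicon=amplicon,
        n_asvs_total=n_asvs_total,
        n_asvs_per_niche=n_asvs_per_niche,
        # library sizes ~2500-4000 reads so a 1000-read rarefaction depth
        # subsamples every sample rather than discarding the small niches
        mu_log=1.6,
        libsize_sigma=0.25,
        # block taxa are abundant core members: keeps them inside the
        # study-wide top-200 pool criterion and tie-free at small n even
        # after rarefaction thins each library to the even depth
        block_min_mean=150.0,
        n_chloroplast=5 if amplicon == "16S" else 0,
    )
    ids = _asv_ids(n_asvs_total)
    niche_order = list(config.niche_samples)

    def window_ids(niche: str) -> list[str]:
        return ids[_niche_window(config, niche_order.index(niche))]

    blocks: list[CorrelationBlock] = []
    rumen_ids = window_ids("Rumen")
    faecal_ids = window_ids("Faecal")
    soil_ids = window_ids("BulkSoil")

    blocks.append(CorrelationBlock(
        tuple(rumen_ids[:8]), "Rumen", 0.9, {"N0": 0.4, "N150": 1.0, "N300": 0.7},
    ))
    blocks.append(CorrelationBlock(
        tuple(faecal_ids[40:48]), "Faecal", 0.9, {"N0": 0.3, "N150": 1.0, "N300": 0.6},
    ))
    # the soil-collapse phenomenon: connected under N0, dissolved under N.
    # Soil contexts have only 3-4 samples, where chance-perfect Spearman
    # pairs are common, so the planted blocks are large enough for the N0
    # signal to stand clear of that background.
    collapse = {"N0": 1.0, "N150": 0.0, "N300": 0.0}
    blocks.append(CorrelationBlock(tuple(soil_ids[0:16]), "BulkSoil", 0.96, collapse))
    blocks.append(CorrelationBlock(tuple(soil_ids[20:36]), "BulkSoil", 0.96, collapse))
    blocks.append(CorrelationBlock(tuple(soil_ids[40:56]), "BulkSoil", 0.96, collapse))
    for niche in ("P.RyeGrassRoot", "P.RyeGrassLeaf", "WhiteCloverRoot", "WhiteCloverLeaf"):
        w = window_ids(niche)
        blocks.append(CorrelationBlock(tuple(w[60:66]), niche, 0.5, {}))

    effects: list[PlantedEffect] = []
    for i, asv in enumerate(rumen_ids[80:100]):
        fold = 6.0 if i % 4 else 1 / 6.0
        effects.append(PlantedEffect(asv, "Rumen", "N150" if i % 2 else "N300", fold))
    for i, asv in enumerate(faecal_ids[100:120]):
        fold = 6.0 if i % 3 else 1 / 6.0
        effects.append(PlantedEffect(asv, "Faecal", "N150" if i % 2 else "N300", fold))

    config.blocks = blocks
    config.da_effects = effects
    return config
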