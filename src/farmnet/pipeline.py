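"""Configuration-driven orchestration of the full analysis flow.

Per amplicon: read (or simulate) counts -> rarefy -> filter (chloroplast,
singletons) -> alpha diversity + Kruskal-Wallis -> Bray-Curtis + NMDS +
ANOSIM + PERMANOVA (globally across niches and per niche across
treatments) -> NB exact tests per niche x contrast -> BH -> N-responsive
set -> ASV pool -> Spearman networks per niche x treatment -> summaries ->
occupancy curves + classification. Every stage writes plain-text artifacts
and the run report carries per-stage dimensions, warnings, and a hashed
output manifest; a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, diversity, network, occupancy, synthetic, table as tbl
from .table import AMPLICONS, NICHES, TREATMENTS, AsvTable

logger = logging.getLogger(__name__)

DEFAULT_DEPTHS = {"16S": 10000, "18S": 25000, "ITS": 10000}


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    counts_format: str = "tsv"
    orientation: str = "asv_rows"
    synthetic_preset: str | None = None  # e.g. "study_mimic"
    rarefaction_depths: dict = field(default_factory=lambda: dict(DEFAULT_DEPTHS))
    remove_chloroplast: bool = True
    chloroplast_amplicons: tuple = ("16S",)
    remove_singletons: bool = True
    n_perm: int = 999
    n_starts_nmds: int = 20
    r_min: float = 0.8
    alpha: float = 0.05
    logfc_min: float = 2.0
    top_n: int = 200
    prevalence: float = 0.6
    min_n: int = 4
    output_dir: str = "farmnet_out"
    seed: int = 0
    amplicons: tuple = AMPLICONS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["amplicons"] = list(self.amplicons)
        d["chloroplast_amplicons"] = list(self.chloroplast_amplicons)
        return d


_VALIDATORS = [
    ("r_min", lambda c: 0 < c.r_min <= 1, "r_min must be in (0,1]"),
    ("alpha", lambda c: 0 < c.alpha <= 1, "alpha must be in (0,1]"),
    ("prevalence", lambda c: 0 < c.prevalence <= 1, "prevalence must be in (0,1]"),
    ("logfc_min", lambda c: c.logfc_min >= 0, "logfc_min must be >= 0"),
    ("top_n", lambda c: c.top_n >= 1, "top_n must be >= 1"),
    ("n_perm", lambda c: c.n_perm >= 1, "n_perm must be >= 1"),
    ("min_n", lambda c: c.min_n >= 3, "min_n must be >= 3"),
    (
        "rarefaction_depths",
        lambda c: all(int(v) >= 1 for v in c.rarefaction_depths.values()),
        "rarefaction depths must be >= 1",
    ),
    (
        "inputs",
        lambda c: c.synthetic_preset is not None or c.counts_path is not None,
        "either counts_path or synthetic_preset is required",
    ),
]


def validate_config(config_path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config; raises with ALL violations listed."""
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    errors = [f"unknown config key {k!r}" for k in raw if k not in known]
    config = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    if isinstance(config.amplicons, list):
        config.amplicons = tuple(config.amplicons)
    if isinstance(config.chloroplast_amplicons, list):
        config.chloroplast_amplicons = tuple(config.chloroplast_amplicons)
    for name, check, message in _VALIDATORS:
        try:
            ok = check(config)
        except Exception:
            ok = False
        if not ok:
            errors.append(message)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return config


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one (stage-name hashing)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunReport:
    config: dict
    stages: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def log_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})
        logger.info("stage %s: %s", name, info)

    def add_output(self, path: Path, root: Path) -> None:
        rel = str(path.relative_to(root))
        self.manifest[rel] = hashlib.sha256(path.read_bytes()).hexdigest()

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "stages": self.stages,
                    "manifest": self.manifest,
                    "warnings": self.warnings,
                },
                fh, indent=1, sort_keys=True, default=str,
            )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _load_amplicon_table(config: PipelineConfig, amplicon: str) -> AsvTable:
    if config.synthetic_preset is not None:
        if config.synthetic_preset != "study_mimic":
            raise ValueError(f"unknown synthetic preset {config.synthetic_preset!r}")
        syn = synthetic.preset_study_mimic(
            amplicon=amplicon, seed=stage_seed(config.seed, f"simulate:{amplicon}")
        )
        t, _ = synthetic.generate_counts(syn)
        return t
    t = tbl.read_asv_table(config.counts_path, config.counts_format, config.orientation)
    if config.metadata_path:
        t = tbl.attach_metadata(t, config.metadata_path)
    if config.taxonomy_path:
        t = tbl.attach_taxonomy(t, config.taxonomy_path)
    if t.metadata is not None:
        t = tbl.subset(t, amplicon=amplicon)
    return t


def preprocess(config: PipelineConfig, t: AsvTable, amplicon: str) -> AsvTable:
    depth = int(config.rarefaction_depths.get(amplicon, 10000))
    t = tbl.rarefy(t, depth, stage_seed(config.seed, f"rarefy:{amplicon}"))
    if config.remove_chloroplast and amplicon in config.chloroplast_amplicons and t.taxonomy is not None:
        t = tbl.remove_lineage_match(t, "chloroplast")
    if config.remove_singletons:
        t = tbl.remove_singletons(t)
    return t


def run_pipeline(config: PipelineConfig) -> RunReport:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())
    for amplicon in config.amplicons:
        _run_amplicon(config, amplicon, outdir, report)
    report.to_json(outdir / "run_report.json")
    return report


def _run_amplicon(config: PipelineConfig, amplicon: str, outdir: Path, report: RunReport) -> None:
    adir = outdir / amplicon
    adir.mkdir(parents=True, exist_ok=True)

    def save(df, name, index=True):
        path = adir / name
        _write_tsv(df, path, index=index)
        report.add_output(path, outdir)

    def save_json(obj, name):
        path = adir / name
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True, default=str)
        report.add_output(path, outdir)

    raw = _load_amplicon_table(config, amplicon)
    report.log_stage(f"load:{amplicon}", n_samples=raw.n_samples, n_asvs=raw.n_asvs)
    if raw.n_samples == 0:
        raise tbl.TableError(f"stage load:{amplicon}: no samples for amplicon")

    t = preprocess(config, raw, amplicon)
    report.log_stage(
        f"preprocess:{amplicon}",
        depth=int(config.rarefaction_depths.get(amplicon, 10000)),
        n_samples=t.n_samples, n_asvs=t.n_asvs,
        samples_dropped=raw.n_samples - t.n_samples,
        asvs_removed=raw.n_asvs - t.n_asvs,
    )
    save(t.counts.T.rename_axis("#ASV_ID"), "rarefied_counts.tsv")

    meta = t.metadata
    niches = [n for n in NICHES if n in set(meta["niche"])]

    # ---- alpha diversity ------------------------------------------------
    rich = diversity.observed_richness(t)
    rich_df = pd.DataFrame({"observed_richness": rich}).join(meta)
    save(rich_df.rename_axis("sample_id"), "richness.tsv")
    kw_rows = []
    kw_niche = diversity.kruskal_wallis(
        {n: rich[meta["niche"] == n].tolist() for n in niches}
    )
    kw_rows.append({"comparison": "niche", "scope": "all", **kw_niche.to_dict()})
    for n in niches:
        sub = meta["niche"] == n
        groups = {
            tr: rich[sub & (meta["treatment"] == tr)].tolist()
            for tr in TREATMENTS
            if (sub & (meta["treatment"] == tr)).any()
        }
        if len(groups) >= 2:
            res = diversity.kruskal_wallis(groups)
            kw_rows.append({"comparison": "treatment", "scope": n, **res.to_dict()})
    kw_df = pd.DataFrame(kw_rows)
    kw_df["p_adj"] = differential.bh_adjust(kw_df["p_value"].to_numpy())
    save(kw_df, "kruskal_wallis.tsv", index=False)
    report.log_stage(f"alpha:{amplicon}", n_tests=len(kw_df))

    # ---- beta diversity -------------------------------------------------
    dm = diversity.bray_curtis(t)
    diversity.write_distance_matrix(dm, adir / "bray_curtis.tsv")
    report.add_output(adir / "bray_curtis.tsv", outdir)
    ord_res = diversity.nmds(
        dm, k=2, n_starts=config.n_starts_nmds,
        seed=stage_seed(config.seed, f"nmds:{amplicon}"),
    )
    coords = ord_res.coordinates.copy()
    coords["stress"] = ord_res.stress
    save(coords.rename_axis("sample_id"), "nmds.tsv")

    niche_groups = meta["niche"].to_dict()
    beta_rows = []
    res_a = diversity.anosim(dm, niche_groups, config.n_perm,
                             stage_seed(config.seed, f"anosim:{amplicon}:all"))
    res_p = diversity.permanova(dm, niche_groups, config.n_perm,
                                stage_seed(config.seed, f"permanova:{amplicon}:all"))
    beta_rows.append({
        "scope": "all", "grouping": "niche",
        "anosim_R": res_a.statistic, "anosim_p": res_a.p_value,
        "permanova_F": res_p.statistic, "permanova_R2": res_p.extras["r_squared"],
        "permanova_p": res_p.p_value, "n_perm": config.n_perm,
    })
    for n in niches:
        ids = meta.index[meta["niche"] == n]
        counts = meta.loc[ids, "treatment"].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            report.warnings.append(f"beta:{amplicon}:{n}: too few samples per treatment")
            continue
        sub_dm = dm.filter([str(i) for i in ids])
        tr_groups = meta.loc[ids, "treatment"].to_dict()
        res_a = diversity.anosim(sub_dm, tr_groups, config.n_perm,
                                 stage_seed(config.seed, f"anosim:{amplicon}:{n}"))
        res_p = diversity.permanova(sub_dm, tr_groups, config.n_perm,
                                    stage_seed(config.seed, f"permanova:{amplicon}:{n}"))
        beta_rows.append({
            "scope": n, "grouping": "treatment",
            "anosim_R": res_a.statistic, "anosim_p": res_a.p_value,
            "permanova_F": res_p.statistic, "permanova_R2": res_p.extras["r_squared"],
            "permanova_p": res_p.p_value, "n_perm": config.n_perm,
        })
    save(pd.DataFrame(beta_rows), "beta_stats.tsv", index=False)
    report.log_stage(f"beta:{amplicon}", stress=ord_res.stress, n_rows=len(beta_rows))

    # ---- differential abundance ----------------------------------------
    da_frames = []
    for n in niches:
        sub_meta = meta[meta["niche"] == n]
        counts_ok = all(
            (sub_meta["treatment"] == x).sum() >= 2
            for pair in differential.CONTRASTS for x in pair
        )
        if not counts_ok:
            report.warnings.append(f"da:{amplicon}:{n}: too few samples per treatment")
            continue
        res = differential.differential_abundance(
            t, n, logfc_min=config.logfc_min, alpha=config.alpha
        )
        da_frames.append(res)
    da = (
        pd.concat(da_frames, ignore_index=True)
        if da_frames
        else pd.DataFrame(columns=["asv_id", "logFC", "p_value", "p_adj",
                                   "n_responsive", "niche", "contrast"])
    )
    save(da, "differential_abundance.tsv", index=False)
    responsive = differential.n_responsive_union(da)
    save_json(sorted(responsive), "n_responsive_asvs.json")
    report.log_stage(
        f"da:{amplicon}", n_tests=len(da), n_responsive=len(responsive)
    )

    # ---- co-occurrence networks -----------------------------------------
    networks = []
    for n in niches:
        niche_t = tbl.subset(t, niche=n)
        pool = network.select_asv_pool(
            niche_t, responsive, study_table=t,
            top_n=config.top_n, prevalence=config.prevalence,
        )
        for tr in TREATMENTS:
            ctx = tbl.subset(t, niche=n, treatment=tr)
            context = (n, tr, amplicon)
            if ctx.n_samples < config.min_n or len(pool) < 2:
                report.warnings.append(
                    f"network:{amplicon}:{n}:{tr}: empty network "
                    f"({ctx.n_samples} samples, pool {len(pool)})"
                )
                nw = network.build_network(
                    pd.DataFrame(columns=network.EDGE_COLUMNS), t.taxonomy, context
                )
            else:
                records = network.spearman_matrix(ctx, pool, config.min_n)
                edges = network.threshold_edges(records, config.r_min, config.alpha)
                nw = network.build_network(edges, t.taxonomy, context, pool.provenance)
                path = adir / f"edges_{n}_{tr}.tsv"
                network.write_edge_list(edges, path)
                report.add_output(path, outdir)
                path = adir / f"network_{n}_{tr}.graphml"
                network.write_graphml(nw, path)
                report.add_output(path, outdir)
            networks.append(nw)
    summary = network.summarize_networks(networks)
    save(summary, "network_summary.tsv", index=False)
    report.log_stage(
        f"network:{amplicon}",
        n_networks=len(networks),
        total_edges=int(summary["n_edges"].sum()),
    )

    # ---- occupancy -------------------------------------------------------
    occ_rows = []
    classifications = {}
    for n in niches:
        niche_t = tbl.subset(t, niche=n)
        curve = occupancy.occupancy_frequency(niche_t, n)
        df = curve.to_frame()
        df.insert(0, "niche", n)
        occ_rows.append(df)
        if curve.n_samples >= 3:
            label, trace = occupancy.classify_core_satellite(curve)
            classifications[n] = {"classification": label, "trace": trace}
    save(pd.concat(occ_rows, ignore_index=True), "occupancy.tsv", index=False)
    save_json(classifications, "occupancy_classification.json")
    report.log_stage(f"occupancy:{amplicon}", n_niches=len(occ_rows))
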