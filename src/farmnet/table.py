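"""Core ASV count-table structures and preprocessing.

An :class:`AsvTable` holds a samples x ASVs matrix of non-negative integer
read counts together with optional per-sample metadata (niche, nitrogen
treatment, amplicon) and per-ASV taxonomy.  Preprocessing mirrors the
standard amplicon workflow: rarefy every sample to an even depth by
subsampling reads without replacement, discard singleton ASVs, and remove
unwanted lineages (chloroplast reads in 16S libraries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NICHES = (
    "Rumen",
    "Faecal",
    "BulkSoil",
    "P.RyeGrassRoot",
    "P.RyeGrassLeaf",
    "WhiteCloverRoot",
    "WhiteCloverLeaf",
)
TREATMENTS = ("N0", "N150", "N300")
AMPLICONS = ("16S", "18S", "ITS")

#: accepted spellings for treatment labels in metadata files
_TREATMENT_ALIASES = {
    "N0": "N0", "0": "N0", "N150": "N150", "150": "N150",
    "N300": "N300", "300": "N300",
}

METADATA_COLUMNS = ("niche", "treatment", "amplicon")


class TableError(ValueError):
    """Malformed count table, metadata, or taxonomy input."""


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    niche: str
    treatment: str
    amplicon: str

    def __post_init__(self):
        if self.niche not in NICHES:
            raise TableError(f"unknown niche {self.niche!r} for sample {self.sample_id!r}")
        if self.treatment not in TREATMENTS:
            raise TableError(
                f"unknown treatment {self.treatment!r} for sample {self.sample_id!r}"
            )
        if self.amplicon not in AMPLICONS:
            raise TableError(
                f"unknown amplicon {self.amplicon!r} for sample {self.sample_id!r}"
            )


@dataclass(frozen=True)
class TaxonomyRecord:
    """Ranked lineage for one ASV; unassigned ranks hold the marker string."""

    asv_id: str
    lineage: tuple[str, ...]
    unassigned_marker: str = "unassigned"

    def rank(self, i: int) -> str:
        return self.lineage[i] if i < len(self.lineage) else self.unassigned_marker


@dataclass
class AsvTable:
    """Samples x ASVs integer count matrix with optional metadata/taxonomy.

    ``counts`` is indexed by sample id (rows) and ASV id (columns).
    ``metadata`` (if present) is indexed by sample id with columns
    ``niche``, ``treatment``, ``amplicon``; ``taxonomy`` is indexed by
    ASV id with one column per rank.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample identifiers: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise TableError(f"duplicate ASV identifiers: {dups}")
        vals = c.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.floor(vals)):
                raise TableError("counts must be non-negative integers")
            c = c.astype(np.int64)
            object.__setattr__(self, "counts", c)
            vals = c.to_numpy()
        if vals.size and vals.min() < 0:
            i, j = np.argwhere(vals < 0)[0]
            raise TableError(
                f"negative count at sample {c.index[i]!r}, ASV {c.columns[j]!r}"
            )
        if self.metadata is not None:
            missing = c.index.difference(self.metadata.index)
            if len(missing):
                raise TableError(f"samples missing from metadata: {sorted(missing)}")

    # -- basic accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def sample_record(self, sample_id: str) -> SampleRecord:
        if self.metadata is None:
            raise TableError("no metadata attached")
        row = self.metadata.loc[sample_id]
        return SampleRecord(sample_id, row["niche"], row["treatment"], row["amplicon"])

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def copy(self) -> "AsvTable":
        return AsvTable(
            self.counts.copy(),
            None if self.metadata is None else self.metadata.copy(),
            None if self.taxonomy is None else self.taxonomy.copy(),
        )

    def _with_counts(self, counts: pd.DataFrame) -> "AsvTable":
        meta = None
        if self.metadata is not None:
            meta = self.metadata.loc[counts.index]
        tax = None
        if self.taxonomy is not None:
            tax = self.taxonomy.loc[self.taxonomy.index.intersection(counts.columns)]
        return AsvTable(counts, meta, tax)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_asv_table(
    counts_path: str | Path,
    format: str = "tsv",
    orientation: str = "asv_rows",
) -> AsvTable:
    """Read a counts-only table from TSV or BIOM.

    TSV dialect: first column = ASV id, header = sample ids (QIIME-style,
    ``orientation='asv_rows'``); pass ``orientation='sample_rows'`` for the
    transpose. BIOM accepts v2.1 HDF5 or v1 JSON.
    """
    path = Path(counts_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path, orientation)
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path, orientation: str) -> AsvTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise TableError(f"{path}: empty or header-less file") from exc
    if df.shape[1] == 0:
        raise TableError(f"{path}: no sample columns found")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise TableError(f"{path}: malformed numeric cell at row {row!r}, column {col!r}")
        if df[col].isna().any():
            row = df.index[df[col].isna().to_numpy().nonzero()[0][0]]
            raise TableError(f"{path}: missing value at row {row!r}, column {col!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "asv_rows":
        df = df.T
    elif orientation != "sample_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index.name = None
    df.columns.name = None
    return AsvTable(df)


def _read_biom(path: Path) -> AsvTable:
    import biom

    bt = biom.load_table(str(path))
    df = pd.DataFrame(
        bt.matrix_data.toarray().T,  # biom stores observations x samples
        index=[str(s) for s in bt.ids("sample")],
        columns=[str(o) for o in bt.ids("observation")],
    )
    return AsvTable(df)


def write_asv_table(
    table: AsvTable,
    counts_path: str | Path,
    format: str = "tsv",
    orientation: str = "asv_rows",
) -> None:
    path = Path(counts_path)
    if format == "tsv":
        df = table.counts.T if orientation == "asv_rows" else table.counts
        df = df.rename_axis("#ASV_ID" if orientation == "asv_rows" else "#SampleID")
        df.to_csv(path, sep="\t")
    elif format == "biom":
        import biom
        from biom.util import biom_open

        bt = biom.Table(
            table.counts.to_numpy().T,
            observation_ids=table.asv_ids,
            sample_ids=table.sample_ids,
        )
        if path.suffix == ".json":
            with open(path, "w") as fh:
                fh.write(bt.to_json("farmnet"))
        else:
            with biom_open(str(path), "w") as fh:
                bt.to_hdf5(fh, "farmnet")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_metadata(metadata_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", *METADATA_COLUMNS}
    missing = required.difference(df.columns)
    if missing:
        raise TableError(f"metadata missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise TableError(f"duplicate sample ids in metadata: {dups}")
    df = df.set_index("sample_id")
    df["treatment"] = df["treatment"].map(
        lambda t: _TREATMENT_ALIASES.get(str(t), str(t))
    )
    for sid, row in df.iterrows():
        SampleRecord(str(sid), row["niche"], row["treatment"], row["amplicon"])
    return df[list(METADATA_COLUMNS)]


def attach_metadata(table: AsvTable, metadata_path: str | Path) -> AsvTable:
    """Attach sample metadata; every count-table sample must be covered.

    Metadata rows for samples absent from the count table are ignored with
    a logged warning.
    """
    meta = read_metadata(metadata_path)
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise TableError(f"count-table samples missing from metadata: {missing}")
    extra = meta.index.difference(table.counts.index)
    if len(extra):
        logger.warning(
            "metadata has %d samples not present in the count table: %s",
            len(extra), sorted(extra),
        )
    return AsvTable(table.counts, meta.loc[table.sample_ids], table.taxonomy)


def read_taxonomy(taxonomy_path: str | Path) -> pd.DataFrame:
    """Read an asv_id + one-column-per-rank TSV; empty cells -> 'unassigned'."""
    df = pd.read_csv(taxonomy_path, sep="\t", dtype=str, index_col=0)
    if df.index.has_duplicates:
        raise TableError("duplicate ASV ids in taxonomy")
    return df.fillna("unassigned")


def attach_taxonomy(table: AsvTable, taxonomy_path: str | Path) -> AsvTable:
    tax = read_taxonomy(taxonomy_path)
    return AsvTable(table.counts, table.metadata, tax)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def rarefy(table: AsvTable, depth: int, seed: int) -> AsvTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained row is a multivariate-hypergeometric draw from its read
    pool, so per-ASV counts never exceed the originals and every retained
    row sums to ``depth``. Samples with fewer than ``depth`` reads are
    dropped (logged). Deterministic for a fixed seed.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    sums = table.library_sizes()
    keep = sums >= depth
    dropped = sums.index[~keep].tolist()
    if dropped:
        logger.warning(
            "rarefy: dropping %d samples below depth %d: %s", len(dropped), depth, dropped
        )
    if not keep.any():
        raise TableError(f"all {table.n_samples} samples fall below depth {depth}")
    rng = np.random.default_rng(seed)
    kept = table.counts.loc[keep]
    out = np.empty_like(kept.to_numpy())
    for i, row in enumerate(kept.to_numpy()):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    new = pd.DataFrame(out, index=kept.index, columns=kept.columns)
    return table._with_counts(new)


def remove_singletons(table: AsvTable) -> AsvTable:
    """Drop ASVs whose total count over all samples is <= 1."""
    totals = table.counts.sum(axis=0)
    keep = totals > 1
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("remove_singletons: removed %d ASVs", n_removed)
    return table._with_counts(table.counts.loc[:, keep])


def remove_lineage_match(
    table: AsvTable,
    pattern: str = "chloroplast",
    ranks: Iterable[str] | None = None,
) -> AsvTable:
    """Remove ASVs whose lineage contains ``pattern`` (case-insensitive).

    ``ranks`` restricts matching to named taxonomy columns; default scans
    every rank. Requires attached taxonomy.
    """
    if table.taxonomy is None:
        raise TableError("remove_lineage_match requires attached taxonomy")
    tax = table.taxonomy
    cols = list(tax.columns) if ranks is None else [r for r in ranks if r in tax.columns]
    pat = pattern.lower()
    hit = pd.Series(False, index=tax.index)
    for col in cols:
        hit |= tax[col].astype(str).str.lower().str.contains(pat, regex=False)
    matched = set(tax.index[hit])
    keep = [a for a in table.asv_ids if a not in matched]
    n_removed = table.n_asvs - len(keep)
    if n_removed:
        logger.info("remove_lineage_match(%r): removed %d ASVs", pattern, n_removed)
    return table._with_counts(table.counts.loc[:, keep])


def subset(
    table: AsvTable,
    niche: str | None = None,
    treatment: str | None = None,
    amplicon: str | None = None,
    drop_empty_asvs: bool = False,
    require_nonempty: bool = False,
) -> AsvTable:
    """Filter samples by the conjunction of the given metadata predicates."""
    if niche is None and treatment is None and amplicon is None:
        sel = pd.Series(True, index=table.counts.index)
    else:
        if table.metadata is None:
            raise TableError("subset by metadata requires attached metadata")
        meta = table.metadata
        sel = pd.Series(True, index=table.counts.index)
        if niche is not None:
            sel &= meta["niche"] == niche
        if treatment is not None:
            sel &= meta["treatment"] == treatment
        if amplicon is not None:
            sel &= meta["amplicon"] == amplicon
    counts = table.counts.loc[sel]
    if require_nonempty and counts.shape[0] == 0:
        raise TableError(
            f"subset(niche={niche!r}, treatment={treatment!r}, amplicon={amplicon!r}) is empty"
        )
    if drop_empty_asvs and counts.shape[0]:
        counts = counts.loc[:, counts.sum(axis=0) > 0]
    elif drop_empty_asvs:
        counts = counts.loc[:, []]
    return table._with_counts(counts)
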