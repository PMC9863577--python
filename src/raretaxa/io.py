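"""Reading, writing and basic transformation of OTU tables, metadata and trees.

The canonical in-memory orientation is samples x OTUs: rows are samples,
columns are OTUs.  Tables on disk are UTF-8 TSV with a mandatory header row;
the first column holds OTU IDs (default) or sample IDs, and an optional final
``taxonomy`` column carries semicolon-separated lineage strings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENV_VARS = ["pH", "OM", "TN", "AP", "AK", "NH4", "NO3", "MAT", "MAP"]
METADATA_COLUMNS = ["sample_id", "site_id", "latitude", "longitude"] + ENV_VARS


@dataclass
class OtuTable:
    """Integer count matrix (samples x OTUs) with optional taxonomy strings.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts; index = sample IDs, columns = OTU IDs.
    taxonomy : pandas.Series, optional
        Lineage string per OTU (``kingdom;phylum;...;genus``), indexed by
        OTU ID.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()][0]
            raise ValueError(f"duplicate OTU ID: {dup!r}")
        arr = c.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("counts must be finite")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            bad = np.argwhere(arr != np.round(arr))[0]
            raise ValueError(
                f"non-integer count at sample {c.index[bad[0]]!r}, "
                f"OTU {c.columns[bad[1]]!r}"
            )
        self.counts = c.astype(np.int64)
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(c.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def subset_otus(self, otu_ids) -> "OtuTable":
        """Column-subset keeping all samples; preserves taxonomy."""
        otu_ids = [o for o in self.counts.columns if o in set(otu_ids)]
        tax = self.taxonomy.loc[otu_ids] if self.taxonomy is not None else None
        return OtuTable(self.counts[otu_ids].copy(), tax)


@dataclass
class SampleMetadata:
    """Per-sample site coordinates and environmental variables."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        d = self.data
        missing = [c for c in METADATA_COLUMNS if c not in d.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if d["sample_id"].duplicated().any():
            dup = d.loc[d["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample ID in metadata: {dup!r}")
        lat, lon = d["latitude"], d["longitude"]
        if not lat.between(-90, 90).all():
            raise ValueError("latitude out of [-90, 90]")
        if not lon.between(-180, 180).all():
            raise ValueError("longitude out of [-180, 180]")
        env = d[ENV_VARS].to_numpy(dtype=float)
        if not np.isfinite(env).all():
            raise ValueError("environmental values must be finite")
        self.data = d.set_index(d["sample_id"].astype(str), drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def env(self) -> pd.DataFrame:
        """Raw environmental matrix (samples x 9 variables)."""
        return self.data[ENV_VARS].astype(float)

    def loc(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)].reset_index(drop=True))


def read_otu_table(path, orientation: str = "otus_as_rows") -> OtuTable:
    """Read a TSV OTU table.

    Parameters
    ----------
    path : str or Path
        TSV file; first column = OTU IDs (``otus_as_rows``, the usual export
        layout) or sample IDs (``samples_as_rows``); optional trailing
        ``taxonomy`` column.
    """
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, comment="#")
    df.index = df.index.astype(str)
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df.pop("taxonomy").astype(str)
    if orientation == "otus_as_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate ID in {path}: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate ID in {path}: {dup!r}")
    arr = df.to_numpy()
    nonint = ~np.isclose(arr.astype(float), np.round(arr.astype(float)))
    if nonint.any():
        i, j = np.argwhere(nonint)[0]
        raise ValueError(
            f"non-integer count in {path} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    return OtuTable(df.astype(np.int64), taxonomy)


def write_otu_table(table: OtuTable, path, orientation: str = "otus_as_rows") -> None:
    """Write a TSV OTU table (inverse of :func:`read_otu_table`)."""
    df = table.counts.T if orientation == "otus_as_rows" else table.counts
    df = df.copy()
    if orientation == "otus_as_rows" and table.taxonomy is not None:
        df["taxonomy"] = table.taxonomy
    df.to_csv(path, sep="\t", index_label="OTU_ID" if orientation == "otus_as_rows" else "sample_id")


def read_metadata(path) -> SampleMetadata:
    """Read sample metadata TSV with the standard column set."""
    df = pd.read_csv(path, sep="\t", header=0, comment="#")
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index=False)


def read_tree(path) -> dendropy.Tree:
    """Read a rooted Newick phylogeny with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")
    return tree


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Rarefy every sample to ``depth`` reads by subsampling without
    replacement (vegan ``rrarefy`` semantics, one draw per sample).

    Samples whose total is below ``depth`` are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    dropped = list(table.counts.index[~keep])
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) with total < %d: %s",
            len(dropped), depth, dropped,
        )
        warnings.warn(f"rarefy dropped samples below depth {depth}: {dropped}")
    out = []
    for sid in table.counts.index[keep]:
        row = table.counts.loc[sid].to_numpy()
        if row.sum() == depth:
            out.append(row)
        else:
            out.append(rng.multivariate_hypergeometric(row, depth))
    counts = pd.DataFrame(
        np.asarray(out, dtype=np.int64),
        index=table.counts.index[keep],
        columns=table.counts.columns,
    )
    return OtuTable(counts, table.taxonomy)


def to_relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Row-normalized proportions (samples x OTUs).

    All-zero samples yield all-zero rows with a warning.
    """
    totals = table.counts.sum(axis=1)
    if (totals == 0).all():
        raise ValueError("no sample has positive counts")
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        warnings.warn(f"all-zero sample(s) left as zero rows: {zero}")
    safe = totals.replace(0, 1)
    return table.counts.div(safe, axis=0)


def prevalence_filter(table: OtuTable, min_fraction: float = 0.2) -> OtuTable:
    """Keep OTUs present (count > 0) in at least ``ceil(min_fraction * n)``
    samples — the 'detected in at least one fifth of samples' screen used
    before network construction.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    n_required = int(np.ceil(min_fraction * table.n_samples))
    prevalence = (table.counts > 0).sum(axis=0)
    keep = prevalence[prevalence >= n_required].index
    return table.subset_otus(keep)
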