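"""OTU count tables with sample metadata: reading, validation, filtering, normalization.

The central container is :class:`OTUTable`, a non-negative integer count
matrix (one row per OTU, one column per sample) paired with per-sample
metadata (pH, habitat). Sample depth is always recomputed as the column sum
of the count matrix, never trusted from metadata, so the depth invariant
holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sample",
    "OTUTable",
    "read_otu_table",
    "write_otu_table",
    "filter_samples",
    "filter_otus_by_prevalence",
    "relative_abundance",
]


@dataclass(frozen=True)
class Sample:
    """One soil sample: identifier, measured pH, total reads and habitat class."""

    sample_id: str
    pH: float
    depth: int = 0
    habitat: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.pH):
            raise ValueError(f"sample {self.sample_id!r}: pH must be finite, got {self.pH}")
        if self.depth < 0:
            raise ValueError(f"sample {self.sample_id!r}: depth must be >= 0")


@dataclass
class OTUTable:
    """Integer OTU-by-sample count matrix with aligned sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by OTU id with sample ids as columns; integer,
        non-negative entries.
    metadata
        DataFrame indexed by sample id with at least columns ``pH`` and
        ``habitat``. A ``depth`` column is (re)computed from the matrix.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = counts.to_numpy()
        if arr.size == 0:
            counts = counts.astype(np.int64)
        elif not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0, rtol=0):
                bad = counts.columns[np.where(arr != np.round(arr))[1][0]]
                raise ValueError(f"non-integer counts (e.g. in sample {bad!r})")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        meta = self.metadata
        if meta.index.has_duplicates:
            dups = meta.index[meta.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dups}")
        missing = counts.columns.difference(meta.index)
        if len(missing):
            raise ValueError(f"samples missing from metadata: {missing.tolist()}")
        extra = meta.index.difference(counts.columns)
        if len(extra):
            raise ValueError(f"metadata samples missing from counts: {extra.tolist()}")
        if "pH" not in meta.columns:
            raise ValueError("metadata must have a 'pH' column")
        meta = meta.loc[counts.columns].copy()
        ph = pd.to_numeric(meta["pH"], errors="coerce")
        if ph.isna().any():
            bad = meta.index[ph.isna()].tolist()
            raise ValueError(f"missing or non-numeric pH for samples: {bad}")
        meta["pH"] = ph.astype(float)
        if "habitat" not in meta.columns:
            meta["habitat"] = ""
        meta["depth"] = counts.sum(axis=0).astype(np.int64)
        self.counts = counts
        self.metadata = meta

    # ---- convenience accessors -------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def ph(self) -> pd.Series:
        return self.metadata["pH"]

    @property
    def depths(self) -> pd.Series:
        return self.metadata["depth"]

    @property
    def habitats(self) -> pd.Series:
        return self.metadata["habitat"]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples(self) -> list[Sample]:
        return [
            Sample(sample_id=str(s), pH=float(r["pH"]), depth=int(r["depth"]), habitat=str(r["habitat"]))
            for s, r in self.metadata.iterrows()
        ]


def _samples_to_metadata(samples: Sequence[Sample]) -> pd.DataFrame:
    return pd.DataFrame(
        {"pH": [s.pH for s in samples], "habitat": [s.habitat for s in samples]},
        index=pd.Index([s.sample_id for s in samples], name="sample_id"),
    )


def table_from_arrays(
    counts: np.ndarray, otu_ids: Sequence[str], samples: Sequence[Sample]
) -> OTUTable:
    """Build an :class:`OTUTable` from a raw matrix and sample descriptions."""
    df = pd.DataFrame(
        np.asarray(counts), index=pd.Index(otu_ids, name="otu_id"), columns=[s.sample_id for s in samples]
    )
    return OTUTable(df, _samples_to_metadata(samples))


def read_otu_table(counts_path: str | Path, metadata_path: str | Path) -> OTUTable:
    """Read a TSV count matrix (first column ``otu_id``) and CSV metadata.

    The metadata CSV must have columns ``sample_id``, ``pH`` and ``habitat``;
    extra columns are preserved but ignored. The sample sets of the two files
    must agree exactly; depth is recomputed from the matrix.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.shape[0] == 0:
        raise ValueError(f"no OTUs in {counts_path}")
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    meta = pd.read_csv(metadata_path)
    if "sample_id" not in meta.columns:
        raise ValueError(f"{metadata_path}: metadata must have a 'sample_id' column")
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta = meta.set_index("sample_id")
    return OTUTable(counts, meta)


def write_otu_table(table: OTUTable, counts_path: str | Path, metadata_path: str | Path) -> None:
    """Write the table back out as counts TSV + metadata CSV."""
    out = table.counts.copy()
    out.index.name = "otu_id"
    out.to_csv(counts_path, sep="\t")
    meta = table.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path)


def filter_samples(table: OTUTable, min_reads: int = 5000) -> OTUTable:
    """Keep samples with depth >= ``min_reads`` (inclusive, reading "at least" literally).

    OTU rows are unchanged; all-zero rows may remain until
    :func:`filter_otus_by_prevalence`. May return a table with zero samples.
    """
    keep = table.depths >= min_reads
    cols = table.counts.columns[keep.to_numpy()]
    # bypass __post_init__ "no OTUs" check only applies to rows; zero samples allowed
    return OTUTable(table.counts[cols], table.metadata.loc[cols, ["pH", "habitat"]])


def filter_otus_by_prevalence(table: OTUTable, min_samples: int = 30) -> OTUTable:
    """Keep OTUs with nonzero counts in at least ``min_samples`` samples."""
    prevalence = (table.counts.to_numpy() > 0).sum(axis=1)
    keep = prevalence >= min_samples
    return OTUTable(table.counts.loc[keep], table.metadata[["pH", "habitat"]])


def relative_abundance(table: OTUTable) -> pd.DataFrame:
    """Per-sample relative abundances: count / sample depth; columns sum to 1."""
    depths = table.depths.to_numpy()
    if (depths <= 0).any():
        bad = table.metadata.index[depths <= 0].tolist()
        raise ValueError(f"zero-depth samples: {bad}")
    return table.counts / depths
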