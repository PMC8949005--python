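"""OTU count tables: containers, readers/writers, rarefaction, filtering.

The central exchange object is :class:`OtuTable` — a rectangular table of
non-negative integer read counts (OTUs as rows, samples as columns) with an
optional per-sample metadata sheet (pressure, size fraction, isotope label,
replicate) and per-OTU taxonomy lineage strings.

All downstream stages (diversity, SIP incorporator calling, lifestyle
odds ratios, network inference) consume either raw counts or the
column-normalized :class:`RelativeAbundanceTable` produced by
:func:`to_relative`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateSampleError,
    InfeasibleDepthError,
    TableFormatError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "RelativeAbundanceTable",
    "read_otu_table",
    "write_otu_table",
    "rarefy",
    "to_relative",
    "filter_prevalence",
]


@dataclass
class OtuTable:
    """Integer OTU-by-sample count matrix with optional metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by OTU id with sample ids as columns; values are
        non-negative integers.
    sample_meta
        Optional DataFrame indexed by sample id. Conventional columns:
        ``pressure`` (MPa or ``"ISW"``), ``temperature`` (°C), ``fraction``
        (``"PA"``/``"FL"``), ``label`` (``"13C"``/``"12C"``/``"none"``),
        ``replicate``.
    taxonomy
        Optional Series mapping OTU id to a ranked lineage string
        (``"k__...;p__...;..."``).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate OTU ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample ids: {dups}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.any(frac != 0):
                r, c = np.argwhere(frac != 0)[0]
                raise TableFormatError(
                    f"non-integer count at OTU {counts.index[r]!r}, "
                    f"sample {counts.columns[c]!r}: {arr[r, c]}"
                )
            self.counts = counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            r, c = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative count at OTU {counts.index[r]!r}, "
                f"sample {counts.columns[c]!r}: {arr[r, c]}"
            )

    @property
    def otu_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "OtuTable":
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[list(sample_ids)]
        return OtuTable(self.counts[list(sample_ids)].copy(), meta, self.taxonomy)


@dataclass
class RelativeAbundanceTable:
    """Column-normalized proportions; every sample column sums to 1."""

    proportions: pd.DataFrame
    #: tolerance on column sums, matches the table invariant
    atol: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        sums = self.proportions.sum(axis=0)
        arr = self.proportions.to_numpy()
        if arr.size:
            if arr.min() < 0 or arr.max() > 1 + self.atol:
                raise ValueError("proportions must lie in [0, 1]")
            bad = sums[np.abs(sums - 1.0) > self.atol]
            if len(bad):
                raise ValueError(
                    f"columns do not sum to 1: {bad.index.tolist()}"
                )

    @property
    def otu_ids(self) -> list:
        return list(self.proportions.index)

    @property
    def sample_ids(self) -> list:
        return list(self.proportions.columns)


def read_otu_table(
    path: str | Path,
    meta_path: str | Path | None = None,
    taxonomy_path: str | Path | None = None,
) -> OtuTable:
    """Read a tab-delimited OTU table (first column OTU id, header = samples).

    Raises
    ------
    TableFormatError
        On a missing header, duplicate ids, negative or non-integer counts;
        the message names the offending row/column.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise TableFormatError(f"{path}: missing header with sample columns")
    samples = header[1:]
    dups = sorted({s for s in samples if samples.count(s) > 1})
    if dups:
        raise TableFormatError(f"{path}: duplicate sample ids {dups}")
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    try:
        numeric = raw.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"{path}: non-numeric entry ({exc})") from exc
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", header=0, index_col=0)
    taxonomy = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", header=0, index_col=0)
        taxonomy = tax.iloc[:, 0]
    return OtuTable(numeric, meta, taxonomy)


def write_otu_table(table: OtuTable, path: str | Path,
                    meta_path: str | Path | None = None,
                    taxonomy_path: str | Path | None = None) -> None:
    """Write the counts (and optionally metadata/taxonomy) as TSV."""
    table.counts.to_csv(path, sep="\t", index_label="otu_id")
    if meta_path is not None and table.sample_meta is not None:
        table.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")
    if taxonomy_path is not None and table.taxonomy is not None:
        table.taxonomy.rename("taxonomy").to_csv(
            taxonomy_path, sep="\t", index_label="otu_id"
        )


def rarefy(table: OtuTable, depth: int, seed: int,
           drop_empty: bool = True) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Subsampling is multivariate-hypergeometric per sample (draw ``depth``
    reads from the sample's read pool without replacement), the convention
    used by standard amplicon toolchains.

    Parameters
    ----------
    depth
        Common target depth; must not exceed any sample's total.
    seed
        Seed for the subsampling RNG.
    drop_empty
        Drop OTUs whose counts are zero in every sample after rarefaction
        (logged); pass ``False`` to keep them.
    """
    sums = table.sample_sums()
    short = sums[sums < depth]
    if len(short):
        sid = short.index[0]
        raise InfeasibleDepthError(
            f"sample {sid!r} has only {short.iloc[0]} reads (< depth {depth})"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy()
        if col.sum() == depth:
            out[sid] = col.copy()
        else:
            out[sid] = rng.multivariate_hypergeometric(col, depth)
    rare = pd.DataFrame(out, index=table.counts.index)
    if drop_empty:
        empty = rare.index[(rare == 0).all(axis=1)]
        if len(empty):
            logger.info("rarefy: dropping %d all-zero OTUs: %s",
                        len(empty), list(empty[:10]))
            rare = rare.drop(index=empty)
    tax = table.taxonomy
    if tax is not None:
        tax = tax.reindex(rare.index)
    return OtuTable(rare, table.sample_meta, tax)


def to_relative(table: OtuTable) -> RelativeAbundanceTable:
    """Divide every sample column by its sum.

    Raises
    ------
    DegenerateSampleError
        If any sample has zero total reads.
    """
    sums = table.sample_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise DegenerateSampleError(
            f"all-zero sample(s): {zero.index.tolist()}"
        )
    props = table.counts.div(sums, axis=1)
    return RelativeAbundanceTable(props)


def filter_prevalence(table: OtuTable, min_samples: int = 7) -> OtuTable:
    """Keep OTUs detected (count > 0) in at least ``min_samples`` samples.

    The default of 7 encodes the network-input rule that taxa must occur in
    more than six samples.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    prevalence = (table.counts > 0).sum(axis=1)
    keep = prevalence[prevalence >= min_samples].index
    if len(keep) == 0:
        logger.warning("filter_prevalence: no OTU passes min_samples=%d",
                       min_samples)
    tax = table.taxonomy
    if tax is not None:
        tax = tax.reindex(keep)
    return OtuTable(table.counts.loc[keep].copy(), table.sample_meta, tax)
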