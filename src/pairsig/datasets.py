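"""Expression-matrix containers and I/O.

The unit of data every stage of the pipeline consumes is an
:class:`ExpressionDataset`: a gene × sample matrix of log2 expression values
plus per-sample metadata (tumor/nontumor label, dataset of origin, platform
tag, and — for nontumor samples — the tissue subtype). Values are assumed to
be already normalized and on the log2 scale, as distributed in processed GEO
series matrices; no normalization stage is provided here because the
downstream pair features only depend on within-sample rank order.

Also provided: probe→gene collapsing (arithmetic mean across probes mapping
to one symbol), restriction of a multi-dataset collection to its common gene
universe, and a minimal reader for the table block of GEO Series Matrix
files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LABELS = ("tumor", "nontumor")
NONTUMOR_SUBTYPES = ("adjacent_normal", "adenoma", "healthy")
#: metadata columns written/required by the TSV sidecar, in file order
META_COLUMNS = ("label", "dataset_id", "platform", "nontumor_subtype")


class ExpressionError(ValueError):
    """Structural problem in an expression matrix or its metadata."""


@dataclass
class ExpressionDataset:
    """Log2 expression matrix (genes × samples) with per-sample metadata.

    Parameters
    ----------
    expr
        DataFrame indexed by gene symbol, columns are sample ids, values are
        log2 expression. Gene symbols and sample ids must be unique and all
        values finite.
    meta
        DataFrame indexed by sample id with columns ``label`` (``tumor`` /
        ``nontumor``), ``dataset_id``, ``platform`` and ``nontumor_subtype``
        (one of ``adjacent_normal`` / ``adenoma`` / ``healthy``, or ``NA``
        for tumor samples). Row order is aligned to ``expr`` columns on
        construction; the sample *set* must match exactly.
    """

    expr: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.expr.index.duplicated().any():
            dupes = self.expr.index[self.expr.index.duplicated()].unique().tolist()
            raise ExpressionError(
                f"duplicate gene rows {dupes}: collapse probes explicitly before "
                "building an ExpressionDataset"
            )
        if self.expr.columns.duplicated().any():
            dupes = self.expr.columns[self.expr.columns.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate sample ids: {dupes}")
        expr_samples = set(self.expr.columns)
        meta_samples = set(self.meta.index)
        missing = sorted(expr_samples - meta_samples)
        extra = sorted(meta_samples - expr_samples)
        if missing or extra:
            raise ExpressionError(
                "sample id mismatch between matrix and metadata: "
                f"missing from metadata {missing}, absent from matrix {extra}"
            )
        # align metadata rows to matrix column order; never reorder samples
        self.meta = self.meta.loc[list(self.expr.columns)]
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise ExpressionError(f"metadata lacks required column {col!r}")
        bad = self.meta.loc[~self.meta["label"].isin(LABELS), "label"]
        if len(bad):
            raise ExpressionError(
                f"labels must be one of {LABELS}; offending samples: "
                f"{bad.index.tolist()}"
            )
        values = self.expr.to_numpy()
        if values.size and not np.isfinite(values).all():
            n_bad = int((~np.isfinite(values)).sum())
            raise ExpressionError(f"expression matrix contains {n_bad} non-finite values")
        # normalized axis names so datasets compare equal across TSV round-trips
        self.expr.index.name = "gene"
        self.expr.columns.name = None
        self.meta.index.name = "sample_id"

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.expr.index)

    @property
    def samples(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def labels(self) -> pd.Series:
        """Per-sample label in ('tumor', 'nontumor'), aligned to sample order."""
        return self.meta["label"]

    @property
    def y(self) -> np.ndarray:
        """Binary response vector, tumor coded 1."""
        return (self.meta["label"] == "tumor").to_numpy(dtype=np.int64)

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        """Restrict to ``genes`` in the given order; missing genes are an error."""
        missing = [g for g in genes if g not in self.expr.index]
        if missing:
            raise ExpressionError(f"genes absent from dataset: {missing}")
        return ExpressionDataset(self.expr.loc[list(genes)].copy(), self.meta.copy())

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.expr.copy(), self.meta.copy())


def write_expression(ds: ExpressionDataset, path: str | Path, meta_path: str | Path) -> None:
    """Write matrix and metadata TSVs (shortest-roundtrip float formatting)."""
    expr = ds.expr.copy()
    expr.index.name = "gene"
    expr.to_csv(path, sep="\t")
    meta = ds.meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


def read_expression(path: str | Path, meta_path: str | Path) -> ExpressionDataset:
    """Read an expression TSV plus metadata sidecar written by :func:`write_expression`.

    Round-trips bit-identically with :func:`write_expression` because pandas
    writes shortest-roundtrip float representations by default.
    """
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    meta.index = meta.index.astype(str)
    if "nontumor_subtype" in meta.columns:
        meta["nontumor_subtype"] = meta["nontumor_subtype"].replace({"": "NA"})
    return ExpressionDataset(expr, meta)


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_map: Mapping[str, str],
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame | ExpressionDataset:
    """Collapse a probe × sample matrix to gene level by averaging probes.

    Each retained probe must map to a non-empty gene symbol; probes without a
    mapping are dropped (the count is logged). When several probes map to the
    same symbol the gene's value is the arithmetic mean of its probes' values,
    computed per sample.

    Returns a gene × sample DataFrame, or an :class:`ExpressionDataset` when
    ``meta`` is supplied.
    """
    for probe, symbol in probe_map.items():
        if symbol is not None and symbol == "":
            raise ExpressionError(f"probe {probe!r} maps to an empty gene symbol")
    mapped = [p for p in probe_matrix.index if probe_map.get(p)]
    n_dropped = probe_matrix.shape[0] - len(mapped)
    if n_dropped:
        log.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    if not mapped:
        raise ExpressionError("no probes remain after applying the probe→gene map")
    symbols = pd.Index([probe_map[p] for p in mapped], name="gene")
    collapsed = probe_matrix.loc[mapped].groupby(symbols, sort=True).mean()
    if meta is not None:
        return ExpressionDataset(collapsed, meta)
    return collapsed


def intersect_collection(datasets: Sequence[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict every dataset to the sorted intersection of their gene sets.

    All returned datasets share the same gene order. Idempotent; raises if the
    intersection is empty or no datasets are given.
    """
    if not datasets:
        raise ExpressionError("intersect_collection requires at least one dataset")
    common: set[str] = set(datasets[0].genes)
    for ds in datasets[1:]:
        common &= set(ds.genes)
    if not common:
        raise ExpressionError("gene-set intersection across datasets is empty")
    ordered = sorted(common)
    return [ds.subset_genes(ordered) for ds in datasets]


def merge_collection(datasets: Sequence[ExpressionDataset]) -> ExpressionDataset:
    """Concatenate samples of gene-aligned datasets into one dataset.

    Datasets are first restricted to their common gene universe. Sample ids
    must be globally unique across the collection.
    """
    aligned = intersect_collection(datasets)
    expr = pd.concat([ds.expr for ds in aligned], axis=1)
    meta = pd.concat([ds.meta for ds in aligned], axis=0)
    return ExpressionDataset(expr, meta)


def read_series_matrix(path: str | Path) -> pd.DataFrame:
    """Parse the table block of a GEO Series Matrix file.

    Only the probe × sample block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` is read; all other SOFT dialect handling is
    out of scope. Returns a probe × sample DataFrame of floats.
    """
    lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped == "!series_matrix_table_begin":
                in_table = True
                continue
            if stripped == "!series_matrix_table_end":
                in_table = False
                break
            if in_table:
                lines.append(line)
    if not lines:
        raise ExpressionError(f"no series-matrix table block found in {path}")
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0)
    table.index = table.index.astype(str).str.strip('"')
    table.columns = [str(c).strip('"') for c in table.columns]
    return table
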