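"""Within-sample gene-pair order indicators — the batch-invariant feature space.

A canonical gene pair (a, b) with a < b lexicographically is scored 1 in a
sample iff expression(a) > expression(b) strictly in that sample, else 0
(ties score 0). Because the indicator depends only on the within-sample
order of two values, it is invariant to any strictly increasing per-sample
transform of the expression vector — the property that lets samples from
different platforms and batches be pooled without batch correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset

PAIR_SEP = "__"


@dataclass(frozen=True, order=True)
class GenePair:
    """Canonical unordered gene pair: ``first < second`` lexicographically."""

    first: str
    second: str

    def __post_init__(self) -> None:
        if self.first == self.second:
            raise ValueError(f"a gene cannot be paired with itself: {self.first!r}")
        if not self.first < self.second:
            raise ValueError(
                f"pair ({self.first!r}, {self.second!r}) is not in canonical "
                "lexicographic order"
            )

    @property
    def id(self) -> str:
        return f"{self.first}{PAIR_SEP}{self.second}"

    @classmethod
    def from_id(cls, pair_id: str) -> "GenePair":
        first, second = pair_id.split(PAIR_SEP)
        return cls(first, second)


@dataclass
class PairFeatureMatrix:
    """Binary pair × sample indicator matrix with labels carried through.

    ``values`` is indexed by pair id (``GENE1__GENE2``) with sample columns;
    entries are strictly 0/1 (uint8). ``pairs`` preserves the canonical pair
    order; ``labels`` is the per-sample tumor/nontumor label of the source
    dataset.
    """

    values: pd.DataFrame
    pairs: list[GenePair]
    labels: pd.Series

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("pair feature matrix must be strictly binary")
        if len(self.pairs) != self.values.shape[0]:
            raise ValueError("pair list and matrix row count disagree")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def X(self) -> np.ndarray:
        """Samples × pairs design matrix (float64) for model fitting."""
        return self.values.to_numpy(dtype=np.float64).T

    @property
    def y(self) -> np.ndarray:
        return (self.labels == "tumor").to_numpy(dtype=np.int64)


def enumerate_pairs(genes: Sequence[str]) -> list[GenePair]:
    """All n(n−1)/2 canonical pairs of ``genes``, sorted by (first, second).

    The input order is irrelevant: genes are sorted lexicographically first,
    so repeated runs on shuffled inputs yield identical output. Duplicate
    symbols are an error.
    """
    genes = list(genes)
    if len(set(genes)) != len(genes):
        seen: set[str] = set()
        dupes = sorted({g for g in genes if g in seen or seen.add(g)})
        raise ValueError(f"duplicate gene symbols: {dupes}")
    return [GenePair(a, b) for a, b in combinations(sorted(genes), 2)]


def pair_indicator(expr: Mapping[str, float], pair: GenePair, sample: str = "?") -> int:
    """Indicator for one sample: 1 iff expr[first] > expr[second] strictly."""
    for gene in (pair.first, pair.second):
        if gene not in expr:
            raise KeyError(f"gene {gene!r} missing from sample {sample!r}")
    return int(expr[pair.first] > expr[pair.second])


def build_pair_matrix(ds: ExpressionDataset, pairs: Sequence[GenePair]) -> PairFeatureMatrix:
    """Vectorized pair indicators for every sample of ``ds``.

    All pair genes must be present; the first missing gene is reported with
    the dataset's first sample id for context.
    """
    pairs = list(pairs)
    present = set(ds.expr.index)
    for pair in pairs:
        for gene in (pair.first, pair.second):
            if gene not in present:
                raise KeyError(
                    f"gene {gene!r} (pair {pair.id}) missing from dataset "
                    f"(samples {ds.samples[:1]}...)"
                )
    firsts = [p.first for p in pairs]
    seconds = [p.second for p in pairs]
    a = ds.expr.loc[firsts].to_numpy()
    b = ds.expr.loc[seconds].to_numpy()
    values = pd.DataFrame(
        (a > b).astype(np.uint8),
        index=pd.Index([p.id for p in pairs], name="pair"),
        columns=ds.expr.columns.copy(),
    )
    return PairFeatureMatrix(values=values, pairs=pairs, labels=ds.labels.copy())


def write_pair_matrix(pm: PairFeatureMatrix, path) -> None:
    pm.values.to_csv(path, sep="\t")


def read_pair_matrix(path, labels: pd.Series) -> PairFeatureMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    pairs = [GenePair.from_id(i) for i in values.index]
    return PairFeatureMatrix(values=values.astype(np.uint8), pairs=pairs, labels=labels)
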