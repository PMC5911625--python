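"""Differential-expression screening with empirical-Bayes variance moderation.

Per dataset, tumor vs nontumor differential expression is assessed with a
moderated two-sample t-test: gene-wise pooled variances are shrunk toward a
common prior estimated by the standard closed-form method of moments on log
sample variances (the limma-style empirical-Bayes squeeze), and p-values come
from a t distribution with the augmented degrees of freedom d0 + d_g.
Benjamini–Hochberg adjustment controls the FDR, genes pass a strict
``q < fdr_cut and |log2FC| > lfc_cut`` filter, and a consensus rule keeps
genes flagged in at least ``min_datasets`` of the per-dataset screens.

Conventions: log2FC = mean(tumor) − mean(nontumor) on the log2 scale;
p-values are two-sided; both screening inequalities are strict, so ties at
the printed cutoffs (0.05, 0.585 ≈ log2 1.5) are excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset

log = logging.getLogger(__name__)

#: DegTable column order, written as TSV by the pipeline
DEG_COLUMNS = ("log2fc", "t", "p", "q", "df_total")


@dataclass(frozen=True)
class DegScreenParams:
    """Cutoffs of the screening rule.

    ``fdr_cut`` and ``lfc_cut`` are applied strictly (<, >); ``min_datasets``
    is the consensus frequency threshold; ``moderation`` selects the
    empirical-Bayes moderated t (``ebayes``) or the ordinary pooled-variance
    t-test (``plain_t``).
    """

    fdr_cut: float = 0.05
    lfc_cut: float = 0.585
    min_datasets: int = 4
    moderation: str = "ebayes"

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_cut < 1.0:
            raise ValueError("fdr_cut must lie in (0, 1)")
        if self.lfc_cut < 0:
            raise ValueError("lfc_cut must be ≥ 0")
        if self.min_datasets < 1:
            raise ValueError("min_datasets must be ≥ 1")
        if self.moderation not in ("ebayes", "plain_t"):
            raise ValueError("moderation must be 'ebayes' or 'plain_t'")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton with the standard asymptotic start)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Returns (d0, s0²). Uses the moments of log sample variances: with
    e_g = log s²_g − digamma(d/2) + log(d/2), E[e] = log s0² − digamma(d0/2)
    + log(d0/2) and Var[e] = trigamma(d0/2) + trigamma(d/2). When the excess
    variance is non-positive the solution is d0 = ∞ (full shrinkage to s0²).
    """
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all residual variances are zero; cannot moderate")
    e = np.log(s2[positive]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    if len(e) < 2:
        return np.inf, float(np.exp(e_mean))
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if not np.isfinite(excess):
        raise FloatingPointError("non-finite moment estimate for the variance prior")
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_ttest(
    ds: ExpressionDataset,
    moderation: str = "ebayes",
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Moderated (or plain) two-sample t-test of tumor vs nontumor, per gene.

    Returns a DegTable: a DataFrame indexed by gene with columns ``log2fc``
    (mean(tumor) − mean(nontumor)), ``t`` (moderated statistic), ``p`` (raw
    two-sided), ``q`` (BH-adjusted) and ``df_total`` (residual + prior df).

    With ``moderation='plain_t'`` this reduces exactly to the ordinary
    pooled-variance two-sample t-test. ``d0_override`` forces the prior df
    (useful for exercising the d0 → ∞ limit).

    Raises if either class has fewer than 2 samples, if fewer than 2 genes
    are present (moment estimation needs a spread of variances), or if every
    gene has zero residual variance.
    """
    y = ds.y
    n1 = int(y.sum())  # tumor
    n0 = int(len(y) - n1)
    if n1 < 2 or n0 < 2:
        raise ValueError(
            f"need ≥2 samples per class for a t-test; got {n1} tumor / {n0} nontumor"
        )
    if ds.expr.shape[0] < 2:
        raise ValueError("need ≥2 genes to estimate the variance prior")
    values = ds.expr.to_numpy(dtype=np.float64)
    tumor = values[:, y == 1]
    nontumor = values[:, y == 0]
    mean_diff = tumor.mean(axis=1) - nontumor.mean(axis=1)
    ss1 = ((tumor - tumor.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss0 = ((nontumor - nontumor.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df_resid = n1 + n0 - 2
    s2 = (ss1 + ss0) / df_resid
    if np.all(s2 == 0):
        raise ValueError("zero residual variance for every gene")

    if moderation == "plain_t":
        d0, s0_2 = 0.0, 0.0
        s2_post = s2
    elif moderation == "ebayes":
        if d0_override is not None:
            d0 = float(d0_override)
            _, s0_2 = _fit_variance_prior(s2, df_resid)
        else:
            try:
                d0, s0_2 = _fit_variance_prior(s2, df_resid)
            except FloatingPointError as err:  # degenerate moments: fall back
                warnings.warn(
                    f"variance-prior estimation failed ({err}); "
                    "falling back to the plain pooled t-test",
                    RuntimeWarning,
                    stacklevel=2,
                )
                return moderated_ttest(ds, moderation="plain_t")
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
        else:
            s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
    else:
        raise ValueError("moderation must be 'ebayes' or 'plain_t'")

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean_diff / se, np.where(mean_diff == 0, 0.0, np.inf * np.sign(mean_diff)))
    df_total = df_resid + (d0 if moderation == "ebayes" else 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    table = pd.DataFrame(
        {
            "log2fc": mean_diff,
            "t": t,
            "p": p,
            "q": bh_adjust(p),
            "df_total": df_total,
        },
        index=ds.expr.index.copy(),
    )
    table.index.name = "gene"
    return table


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order, capped at 1."""
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_degs(table: pd.DataFrame, params: DegScreenParams = DegScreenParams()) -> set[str]:
    """Genes with q < fdr_cut AND |log2FC| > lfc_cut (both strict)."""
    keep = (table["q"] < params.fdr_cut) & (table["log2fc"].abs() > params.lfc_cut)
    return set(table.index[keep])


def consensus_degs(per_dataset: Sequence[Iterable[str]], min_datasets: int = 4) -> list[str]:
    """Genes present in at least ``min_datasets`` of the per-dataset DEG sets.

    Returned sorted lexicographically so the downstream pair order is
    deterministic.
    """
    sets = [set(s) for s in per_dataset]
    if len(sets) < min_datasets:
        raise ValueError(
            f"need at least min_datasets={min_datasets} DEG sets, got {len(sets)}"
        )
    counts: dict[str, int] = {}
    for s in sets:
        for gene in s:
            counts[gene] = counts.get(gene, 0) + 1
    return sorted(g for g, c in counts.items() if c >= min_datasets)


def screen_collection(
    datasets: Sequence[ExpressionDataset], params: DegScreenParams = DegScreenParams()
) -> tuple[list[str], list[pd.DataFrame]]:
    """Per-dataset moderated screens followed by the consensus rule.

    Returns (consensus gene list, per-dataset DegTables).
    """
    tables = [moderated_ttest(ds, moderation=params.moderation) for ds in datasets]
    per_dataset = [screen_degs(t, params) for t in tables]
    consensus = consensus_degs(per_dataset, params.min_datasets)
    log.info(
        "screen_collection: %s datasets, per-dataset DEG counts %s, consensus %d",
        len(datasets),
        [len(s) for s in per_dataset],
        len(consensus),
    )
    return consensus, tables
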