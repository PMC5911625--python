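"""ROC/AUC evaluation, subgroup-stratified AUCs, and gene-list baselines.

AUC is computed with the Mann–Whitney rank formulation (midranks for ties):
AUC = P(score_tumor > score_nontumor) + ½·P(tie), tumor being the positive
class throughout. The ROC step curve predicts positive when score ≥
threshold, its trapezoidal area equals the rank statistic, and all curves
start at (0, 0) and end at (1, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .datasets import ExpressionDataset

STRATA_KEYS = ("nontumor_subtype", "platform", "dataset_id")


def _as_binary(labels: Sequence[str] | np.ndarray) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype.kind in "SUO":
        unknown = set(np.unique(lab)) - {"tumor", "nontumor"}
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
        return (lab == "tumor").astype(np.int64)
    y = lab.astype(np.int64)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("numeric labels must be 0/1")
    return y


def auc(scores: Sequence[float], labels: Sequence[str] | np.ndarray) -> float:
    """Rank (Mann–Whitney) AUC with midrank tie handling; tumor = positive."""
    s = np.asarray(scores, dtype=np.float64)
    y = _as_binary(labels)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"AUC needs both classes; got {n_pos} tumor / {n_neg} nontumor"
        )
    ranks = rankdata(s)  # midranks
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass
class RocResult:
    """ROC step curve: descending thresholds with (fpr, tpr) coordinates.

    The leading point is (0, 0) at threshold +inf; the final point (1, 1) is
    reached at the minimum score. ``auc`` is the midrank AUC, which equals
    the trapezoidal integral of the curve.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_curve(scores: Sequence[float], labels: Sequence[str] | np.ndarray) -> RocResult:
    """ROC over the unique score thresholds (positive iff score ≥ threshold)."""
    s = np.asarray(scores, dtype=np.float64)
    y = _as_binary(labels)
    area = auc(s, y)  # validates class presence
    cuts = np.unique(s)[::-1]
    pos = s[y == 1]
    neg = s[y == 0]
    tpr = np.array([(pos >= t).mean() for t in cuts])
    fpr = np.array([(neg >= t).mean() for t in cuts])
    thresholds = np.concatenate(([np.inf], cuts))
    return RocResult(
        thresholds=thresholds,
        fpr=np.concatenate(([0.0], fpr)),
        tpr=np.concatenate(([0.0], tpr)),
        auc=area,
    )


def stratified_auc(
    scores: pd.Series, ds: ExpressionDataset, key: str
) -> pd.DataFrame:
    """Per-stratum AUC table for one metadata grouping key.

    For ``nontumor_subtype`` (defined only on nontumor samples) each subtype's
    nontumor samples are compared against the pooled tumor samples. For
    ``platform`` and ``dataset_id`` — keys every sample carries — each
    stratum's own tumor and nontumor samples are compared. Strata lacking a
    class are reported with AUC = NaN, never dropped.
    """
    if key not in STRATA_KEYS:
        raise ValueError(f"unknown grouping key {key!r}; choose from {STRATA_KEYS}")
    scores = scores.loc[ds.samples]
    labels = ds.labels
    rows = []
    if key == "nontumor_subtype":
        tumor_mask = labels == "tumor"
        strata = sorted(ds.meta.loc[~tumor_mask, key].unique())
        for stratum in strata:
            in_stratum = (~tumor_mask) & (ds.meta[key] == stratum)
            mask = tumor_mask | in_stratum
            rows.append(_stratum_row(stratum, scores[mask], labels[mask]))
    else:
        for stratum in sorted(ds.meta[key].unique()):
            mask = ds.meta[key] == stratum
            rows.append(_stratum_row(stratum, scores[mask], labels[mask]))
    return pd.DataFrame(rows, columns=["stratum", "auc", "n_tumor", "n_nontumor"])


def _stratum_row(stratum: str, scores: pd.Series, labels: pd.Series) -> tuple:
    n_tumor = int((labels == "tumor").sum())
    n_nontumor = int((labels == "nontumor").sum())
    if n_tumor == 0 or n_nontumor == 0:
        return (stratum, np.nan, n_tumor, n_nontumor)
    return (stratum, auc(scores.to_numpy(), labels.to_numpy()), n_tumor, n_nontumor)


def gene_list_baseline(
    genes: Sequence[str],
    train_ds: ExpressionDataset,
    eval_ds: ExpressionDataset | None = None,
    max_iter: int = 1000,
) -> pd.Series:
    """Unpenalized logistic regression on raw expression of a gene list.

    Fits label ~ expression(genes) on ``train_ds`` and returns the linear
    predictor on ``eval_ds`` (default: the training data itself, i.e. the
    resubstitution design used to compare published gene-list signatures).
    Perfect separation is handled by capping iterations with a warning
    rather than diverging.
    """
    if eval_ds is None:
        eval_ds = train_ds
    for name, ds in (("training", train_ds), ("evaluation", eval_ds)):
        missing = sorted(set(genes) - set(ds.expr.index))
        if missing:
            raise KeyError(f"genes missing from {name} dataset: {missing}")
    X_train = train_ds.expr.loc[list(genes)].to_numpy().T
    y_train = train_ds.y
    model = LogisticRegression(C=np.inf, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.filterwarnings("always", category=ConvergenceWarning)
        model.fit(X_train, y_train)
    X_eval = eval_ds.expr.loc[list(genes)].to_numpy().T
    scores = model.decision_function(X_eval)
    return pd.Series(scores, index=eval_ds.expr.columns, name="score")


def evaluation_report(
    scores: pd.Series,
    ds: ExpressionDataset,
    set_name: str = "all",
    strata_keys: Sequence[str] = STRATA_KEYS,
) -> pd.DataFrame:
    """Global plus per-stratum AUC rows: (set, key, stratum, n_tumor, n_nontumor, auc)."""
    labels = ds.labels
    rows = [
        {
            "set": set_name,
            "key": "overall",
            "stratum": "all",
            "n_tumor": int((labels == "tumor").sum()),
            "n_nontumor": int((labels == "nontumor").sum()),
            "auc": auc(scores.loc[ds.samples].to_numpy(), labels.to_numpy()),
        }
    ]
    for key in strata_keys:
        table = stratified_auc(scores, ds, key)
        for _, r in table.iterrows():
            rows.append(
                {
                    "set": set_name,
                    "key": key,
                    "stratum": r["stratum"],
                    "n_tumor": r["n_tumor"],
                    "n_nontumor": r["n_nontumor"],
                    "auc": r["auc"],
                }
            )
    return pd.DataFrame(rows)
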