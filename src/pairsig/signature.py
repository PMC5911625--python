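"""L1-penalized logistic signature selection and scoring.

The diagnostic signature is the sparse solution of

    minimize_{b0, β}  −(1/n) Σ_i [ y_i η_i − log(1 + e^{η_i}) ] + λ‖β‖₁,
    η_i = b0 + x_iᵀβ,  y ∈ {0, 1} (tumor = 1),

fitted over a descending λ grid by cyclic coordinate descent inside an IRLS
outer loop (warm-started along the path; intercept unpenalized; the binary
pair features are deliberately *not* standardized so coefficients stay
interpretable on the 0/1 indicator scale). λ is chosen by stratified k-fold
cross-validation of the binomial deviance at the one-standard-error rule:
the largest λ whose mean CV deviance is within one SE of the minimum.

A sample's diagnostic score is b0 + Σ_k β_k s_k over the selected pairs'
indicators s_k; higher scores are more tumor-like. The published 19-pair
thyroid-cancer signature ships with the package and can be loaded with
:func:`load_default_signature`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from sklearn.model_selection import StratifiedKFold

from .datasets import ExpressionDataset
from .pairs import GenePair, PairFeatureMatrix, build_pair_matrix

log = logging.getLogger(__name__)

DEFAULT_SIGNATURE_RESOURCE = "signature_tc19.tsv"

#: convergence threshold on the max absolute coefficient change
COEF_TOL = 1e-9
MAX_OUTER = 100
MAX_INNER = 1000
#: probability clamp used in deviance evaluation
P_EPS = 1e-10


# --------------------------------------------------------------------------
# coordinate-descent solver
# --------------------------------------------------------------------------


@njit(cache=True)
def _cd_fit(X, y, lam, beta, b0, tol, max_outer, max_inner):  # pragma: no cover
    """Penalized IRLS / cyclic coordinate descent for one λ, warm-started.

    Mutates ``beta`` in place; returns the fitted intercept. Quadratic
    approximation of the binomial log-likelihood at the current solution,
    then coordinate descent to convergence on the weighted lasso problem,
    iterated until the solution stabilizes.
    """
    n, p = X.shape
    eta = b0 + X @ beta
    for _ in range(max_outer):
        beta_old_outer = beta.copy()
        b0_old_outer = b0
        # IRLS weights and working response at the current solution
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        for i in range(n):
            if w[i] < 1e-5:
                w[i] = 1e-5
        z = eta + (y - mu) / w
        wsum = w.sum()
        # per-feature curvature v_j = (1/n) Σ w_i x_ij²
        v = np.zeros(p)
        for j in range(p):
            acc = 0.0
            for i in range(n):
                acc += w[i] * X[i, j] * X[i, j]
            v[j] = acc / n
        r = z - b0 - X @ beta  # working residual, maintained incrementally
        for _ in range(max_inner):
            max_delta = 0.0
            # unpenalized intercept
            delta0 = 0.0
            for i in range(n):
                delta0 += w[i] * r[i]
            delta0 /= wsum
            b0 += delta0
            for i in range(n):
                r[i] -= delta0
            if abs(delta0) > max_delta:
                max_delta = abs(delta0)
            for j in range(p):
                if v[j] <= 0.0:
                    continue
                grad = 0.0
                for i in range(n):
                    grad += w[i] * X[i, j] * r[i]
                grad = grad / n + v[j] * beta[j]
                if grad > lam:
                    new = (grad - lam) / v[j]
                elif grad < -lam:
                    new = (grad + lam) / v[j]
                else:
                    new = 0.0
                delta = new - beta[j]
                if delta != 0.0:
                    beta[j] = new
                    for i in range(n):
                        r[i] -= X[i, j] * delta
                    if abs(delta) > max_delta:
                        max_delta = abs(delta)
            if max_delta < tol:
                break
        eta = z - r
        outer_change = abs(b0 - b0_old_outer)
        for j in range(p):
            diff = abs(beta[j] - beta_old_outer[j])
            if diff > outer_change:
                outer_change = diff
        if outer_change < tol * 10.0:
            break
    return b0


def _lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest λ at which all penalized coefficients are zero (KKT bound)."""
    ybar = y.mean()
    return float(np.max(np.abs(X.T @ (y - ybar))) / len(y))


def _fit_path_arrays(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started fits over a descending λ grid; returns (coefs, intercepts)."""
    n, p = X.shape
    coefs = np.zeros((len(lambdas), p))
    intercepts = np.zeros(len(lambdas))
    beta = np.zeros(p)
    ybar = y.mean()
    b0 = float(np.log(ybar / (1.0 - ybar)))
    Xf = np.ascontiguousarray(X, dtype=np.float64)
    yf = np.ascontiguousarray(y, dtype=np.float64)
    for k, lam in enumerate(lambdas):
        b0 = _cd_fit(Xf, yf, lam, beta, b0, COEF_TOL, MAX_OUTER, MAX_INNER)
        coefs[k] = beta
        intercepts[k] = b0
    return coefs, intercepts


def binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """Mean binomial deviance −(2/n) Σ [y log p + (1−y) log(1−p)]."""
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, P_EPS, 1.0 - P_EPS)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def kkt_violation(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, b0: float, lam: float
) -> float:
    """Maximum KKT stationarity violation of a candidate lasso solution.

    At an exact optimum the negative-log-likelihood gradient g_j =
    (1/n) Σ x_ij (p_i − y_i) satisfies |g_j| ≤ λ where β_j = 0 and
    g_j = −λ·sign(β_j) where β_j ≠ 0, and the intercept gradient is 0.
    """
    eta = b0 + X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    g = X.T @ (p - y) / len(y)
    active = beta != 0
    viol = abs(float(np.mean(p - y)))  # intercept stationarity
    if active.any():
        viol = max(viol, float(np.max(np.abs(g[active] + lam * np.sign(beta[active])))))
    if (~active).any():
        viol = max(viol, float(np.max(np.abs(g[~active])) - lam))
    return viol


# --------------------------------------------------------------------------
# path container, CV, 1-SE selection
# --------------------------------------------------------------------------


@dataclass
class LassoPath:
    """Regularization path with cross-validation summaries.

    ``lambdas`` is stored descending from λ_max; ``coefs`` row k and
    ``intercepts[k]`` are the solution at ``lambdas[k]``; ``cv_mean`` /
    ``cv_se`` are the mean and standard error of the held-out binomial
    deviance across the stratified folds recorded in ``fold_ids``.
    """

    lambdas: np.ndarray  # descending
    coefs: np.ndarray  # n_lambda × n_features
    intercepts: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    feature_names: list[str]
    fold_ids: np.ndarray
    nfolds: int
    seed: int

    def n_nonzero(self) -> np.ndarray:
        return (self.coefs != 0).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Path summary for TSV inspection dumps."""
        return pd.DataFrame(
            {
                "lambda": self.lambdas,
                "n_nonzero": self.n_nonzero(),
                "intercept": self.intercepts,
                "cv_mean_deviance": self.cv_mean,
                "cv_se": self.cv_se,
            }
        )


def fit_lasso_logistic(
    features: PairFeatureMatrix | np.ndarray,
    labels: Sequence[str] | np.ndarray | None = None,
    nfolds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    feature_names: Sequence[str] | None = None,
) -> LassoPath:
    """Fit the full L1 logistic path with stratified k-fold CV deviance.

    ``features`` is a :class:`PairFeatureMatrix` (labels taken from it) or a
    samples × features binary array with ``labels`` given separately as
    tumor/nontumor strings or a 0/1 vector. The λ grid is ``n_lambda``
    log-spaced values from λ_max (the KKT bound at which every penalized
    coefficient is zero) down to ``lambda_min_ratio·λ_max``. Folds are
    stratified by class and seeded; each class must contribute at least
    ``nfolds`` samples so no fold can lose a class.
    """
    if isinstance(features, PairFeatureMatrix):
        X = features.X
        y = features.y
        names = [p.id for p in features.pairs]
    else:
        X = np.asarray(features, dtype=np.float64)
        if labels is None:
            raise ValueError("labels are required when passing a plain array")
        lab = np.asarray(labels)
        if lab.dtype.kind in "SU":
            unknown = set(np.unique(lab)) - {"tumor", "nontumor"}
            if unknown:
                raise ValueError(f"non-binary labels: {sorted(unknown)}")
            y = (lab == "tumor").astype(np.int64)
        else:
            uniq = set(np.unique(lab).tolist())
            if not uniq <= {0, 1}:
                raise ValueError(f"labels must be binary 0/1; got {sorted(uniq)}")
            y = lab.astype(np.int64)
        names = list(feature_names) if feature_names is not None else [
            f"f{j}" for j in range(X.shape[1])
        ]
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("pair features must be binary")
    n1, n0 = int(y.sum()), int(len(y) - y.sum())
    if min(n1, n0) < nfolds:
        raise ValueError(
            f"need ≥{nfolds} samples per class for {nfolds}-fold stratified CV; "
            f"got {n1} tumor / {n0} nontumor"
        )

    lam_max = _lambda_max(X, y)
    if lam_max <= 0:
        raise ValueError("degenerate design: λ_max is zero")
    lambdas = np.logspace(
        np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambda
    )
    coefs, intercepts = _fit_path_arrays(X, y, lambdas)

    skf = StratifiedKFold(n_splits=nfolds, shuffle=True, random_state=seed)
    fold_ids = np.empty(len(y), dtype=np.int64)
    fold_dev = np.zeros((nfolds, len(lambdas)))
    for f, (train_idx, val_idx) in enumerate(skf.split(X, y)):
        fold_ids[val_idx] = f
        if len(set(y[val_idx])) < 2 or len(set(y[train_idx])) < 2:
            raise ValueError(f"CV fold {f} lacks both classes")
        c_f, b_f = _fit_path_arrays(X[train_idx], y[train_idx], lambdas)
        eta_val = b_f[:, None] + c_f @ X[val_idx].T  # n_lambda × n_val
        for k in range(len(lambdas)):
            fold_dev[f, k] = binomial_deviance(y[val_idx], eta_val[k])
    cv_mean = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(nfolds)

    return LassoPath(
        lambdas=lambdas,
        coefs=coefs,
        intercepts=intercepts,
        cv_mean=cv_mean,
        cv_se=cv_se,
        feature_names=names,
        fold_ids=fold_ids,
        nfolds=nfolds,
        seed=seed,
    )


def select_lambda_1se(path: LassoPath) -> float:
    """Largest λ with mean CV deviance ≤ min deviance + SE at the minimum."""
    k_min = int(np.argmin(path.cv_mean))
    bound = path.cv_mean[k_min] + path.cv_se[k_min]
    qualifying = np.where(path.cv_mean <= bound)[0]
    # grid is descending, so the smallest index among qualifiers is largest λ
    return float(path.lambdas[qualifying.min()])


def select_lambda_min(path: LassoPath) -> float:
    return float(path.lambdas[int(np.argmin(path.cv_mean))])


# --------------------------------------------------------------------------
# signature model
# --------------------------------------------------------------------------


@dataclass
class SignatureModel:
    """Sparse gene-pair diagnostic model: score = β0 + Σ_k β_k s_k.

    ``entries`` holds (canonical pair, nonzero coefficient) in canonical pair
    order; ``intercept`` may be zero; ``provenance`` records where the fit
    came from.
    """

    entries: list[tuple[GenePair, float]]
    intercept: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pair, coef in self.entries:
            if coef == 0:
                raise ValueError(f"zero coefficient stored for pair {pair.id}")
            if pair.id in seen:
                raise ValueError(f"duplicate pair {pair.id}")
            seen.add(pair.id)

    @property
    def pairs(self) -> list[GenePair]:
        return [p for p, _ in self.entries]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, c in self.entries])

    @property
    def genes(self) -> list[str]:
        """Distinct genes covered by the signature, sorted."""
        out: set[str] = set()
        for pair, _ in self.entries:
            out.update((pair.first, pair.second))
        return sorted(out)

    def __len__(self) -> int:
        return len(self.entries)


def extract_signature(path: LassoPath, lam: float, provenance: str = "") -> SignatureModel:
    """Nonzero-coefficient pairs at grid value ``lam`` (must be on the grid)."""
    matches = np.isclose(path.lambdas, lam, rtol=1e-10, atol=0.0)
    if not matches.any():
        raise ValueError(f"λ={lam} is not on the fitted grid")
    k = int(np.argmax(matches))
    beta = path.coefs[k]
    entries = [
        (GenePair.from_id(path.feature_names[j]), float(beta[j]))
        for j in np.nonzero(beta)[0]
    ]
    if not entries:
        warnings.warn(
            f"all coefficients are zero at λ={lam:g}; returning an empty signature",
            RuntimeWarning,
            stacklevel=2,
        )
    return SignatureModel(
        entries=entries, intercept=float(path.intercepts[k]), provenance=provenance
    )


def score_samples(
    sig: SignatureModel, ds: ExpressionDataset, include_intercept: bool = True
) -> pd.Series:
    """Per-sample diagnostic score β0 + Σ_k β_k s_k; higher = more tumor-like.

    All signature genes must be present in ``ds``; missing genes raise with
    the full missing list. The score depends on expression only through
    within-sample pair order, so it is invariant to strictly increasing
    per-sample transforms.
    """
    missing = sorted(set(g for g in sig.genes) - set(ds.expr.index))
    if missing:
        raise KeyError(f"signature genes missing from dataset: {missing}")
    if not sig.entries:
        base = sig.intercept if include_intercept else 0.0
        return pd.Series(base, index=ds.expr.columns, name="score", dtype=float)
    pm = build_pair_matrix(ds, sig.pairs)
    # fixed-order, fixed-layout reduction so identical indicators give
    # bit-identical scores regardless of how the matrix was materialized
    indicators = np.ascontiguousarray(pm.values.to_numpy(dtype=np.float64))
    scores = (indicators * sig.coefficients[:, None]).sum(axis=0)
    if include_intercept:
        scores = scores + sig.intercept
    return pd.Series(scores, index=ds.expr.columns, name="score")


# --------------------------------------------------------------------------
# signature persistence
# --------------------------------------------------------------------------


def save_signature(sig: SignatureModel, path: str | Path) -> None:
    """Write a signature TSV: commented provenance/intercept lines + 3 columns."""
    with open(path, "w") as fh:
        if sig.provenance:
            fh.write(f"# provenance: {sig.provenance}\n")
        fh.write(f"# intercept: {sig.intercept!r}\n")
        fh.write("gene_first\tgene_second\tcoefficient\n")
        for pair, coef in sig.entries:
            fh.write(f"{pair.first}\t{pair.second}\t{coef!r}\n")


def load_signature(path: str | Path) -> SignatureModel:
    """Read a signature TSV; rejects non-canonical or duplicate pairs."""
    intercept = 0.0
    provenance = ""
    entries: list[tuple[GenePair, float]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("intercept:"):
                    intercept = float(body.split(":", 1)[1])
                elif body.startswith("provenance:"):
                    provenance = body.split(":", 1)[1].strip()
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != ["gene_first", "gene_second", "coefficient"]:
                    raise ValueError(
                        f"{path}:{lineno}: malformed header {fields!r}"
                    )
                header_seen = True
                continue
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            first, second, coef = fields
            try:
                pair = GenePair(first, second)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from err
            entries.append((pair, float(coef)))
    if not header_seen:
        raise ValueError(f"{path}: missing signature header")
    return SignatureModel(entries=entries, intercept=intercept, provenance=provenance)


def load_default_signature() -> SignatureModel:
    """The packaged 19-pair thyroid-cancer diagnostic signature (26 genes)."""
    ref = resources.files("pairsig").joinpath("data", DEFAULT_SIGNATURE_RESOURCE)
    with resources.as_file(ref) as p:
        return load_signature(p)
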