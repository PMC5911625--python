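"""End-to-end orchestration: simulate → screen → pair → fit → score → evaluate.

`run_train` drives the full training pipeline on a collection of expression
datasets (synthetic by default, or any datasets read from TSV): per-dataset
moderated differential screening, the cross-dataset consensus rule, pair
enumeration over the consensus genes, the cross-validated L1 logistic fit at
the 1-SE penalty, and ROC evaluation of the resulting signature. Every
artifact is written as TSV next to a JSON run manifest recording the seeds
and parameters that produced it, so a rerun with the same config reproduces
the signature file bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import degs, evaluate, pairs, signature, simulate
from .datasets import ExpressionDataset, merge_collection, read_expression, write_expression

log = logging.getLogger(__name__)

COHORT_RESOURCE = "cohorts_tc.tsv"


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters for one training run."""

    synthetic: simulate.SyntheticConfig = field(default_factory=simulate.SyntheticConfig)
    deg: degs.DegScreenParams = field(default_factory=degs.DegScreenParams)
    nfolds: int = 10
    seed: int = 0
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3

    def to_manifest(self) -> dict:
        out = dataclasses.asdict(self)
        return out


@dataclass
class TrainResult:
    consensus_genes: list[str]
    deg_tables: list[pd.DataFrame]
    path: signature.LassoPath | None
    lambda_1se: float | None
    signature: signature.SignatureModel
    train_scores: pd.Series
    report: pd.DataFrame | None
    manifest: dict


def _stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, str(err)) from err


def run_train(
    config: PipelineConfig = PipelineConfig(),
    datasets: Sequence[ExpressionDataset] | None = None,
    outdir: str | Path | None = None,
) -> TrainResult:
    """Run the full training pipeline; optionally persist all artifacts.

    When ``datasets`` is None a synthetic collection is generated from
    ``config.synthetic``. If the consensus DEG list has fewer than two genes
    (e.g. a null run with no planted signal) the result carries an empty
    signature instead of failing.
    """
    if datasets is None:
        datasets, _truth = _stage("simulate", simulate.generate_collection, config.synthetic)
        log.info("simulate: %d datasets × %d genes", len(datasets), len(datasets[0].genes))
    if len(datasets) < config.deg.min_datasets:
        raise PipelineError(
            "deg_screen",
            f"need ≥{config.deg.min_datasets} datasets, got {len(datasets)}",
        )

    consensus, tables = _stage("deg_screen", degs.screen_collection, datasets, config.deg)
    merged = _stage("merge", merge_collection, datasets)
    manifest: dict = {
        "config": config.to_manifest(),
        "stages": {
            "deg_screen": {
                "per_dataset_deg_counts": [
                    int(len(degs.screen_degs(t, config.deg))) for t in tables
                ],
                "n_consensus": len(consensus),
            }
        },
    }

    if len(consensus) < 2:
        log.warning("consensus list has %d genes; returning empty signature", len(consensus))
        sig = signature.SignatureModel(entries=[], intercept=0.0, provenance="empty (no consensus genes)")
        scores = signature.score_samples(sig, merged)
        result = TrainResult(
            consensus_genes=consensus,
            deg_tables=tables,
            path=None,
            lambda_1se=None,
            signature=sig,
            train_scores=scores,
            report=None,
            manifest=manifest,
        )
        if outdir is not None:
            _write_artifacts(result, datasets, merged, config, Path(outdir))
        return result

    pair_list = _stage("pair_features", pairs.enumerate_pairs, consensus)
    pm = _stage("pair_features", pairs.build_pair_matrix, merged, pair_list)
    log.info("pair_features: %d genes → %d pairs", len(consensus), len(pair_list))

    path = _stage(
        "signature_model",
        signature.fit_lasso_logistic,
        pm,
        nfolds=config.nfolds,
        seed=config.seed,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    lam = signature.select_lambda_1se(path)
    sig = signature.extract_signature(
        path, lam, provenance=f"trained on {len(datasets)} datasets (seed={config.seed}, λ_1SE={lam:.6g})"
    )
    log.info("signature_model: λ_1SE=%.5g, %d nonzero pairs", lam, len(sig))

    scores = _stage("evaluation", signature.score_samples, sig, merged)
    report = (
        _stage("evaluation", evaluate.evaluation_report, scores, merged, "training")
        if len(sig)
        else None
    )
    manifest["stages"]["signature_model"] = {
        "n_pairs": len(pair_list),
        "lambda_1se": lam,
        "n_selected_pairs": len(sig),
        "n_signature_genes": len(sig.genes),
    }

    result = TrainResult(
        consensus_genes=consensus,
        deg_tables=tables,
        path=path,
        lambda_1se=lam,
        signature=sig,
        train_scores=scores,
        report=report,
        manifest=manifest,
    )
    if outdir is not None:
        _write_artifacts(result, datasets, merged, config, Path(outdir))
    return result


def _write_artifacts(
    result: TrainResult,
    datasets: Sequence[ExpressionDataset],
    merged: ExpressionDataset,
    config: PipelineConfig,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    for i, table in enumerate(result.deg_tables):
        name = f"deg_table_{i + 1}.tsv"
        table.to_csv(outdir / name, sep="\t")
        artifacts[name] = "per-dataset DEG table"
    (outdir / "consensus_genes.txt").write_text(
        "".join(f"{g}\n" for g in result.consensus_genes)
    )
    artifacts["consensus_genes.txt"] = "consensus DEG list (one symbol per line)"
    if result.path is not None:
        result.path.to_frame().to_csv(outdir / "lasso_path.tsv", sep="\t", index=False)
        artifacts["lasso_path.tsv"] = "λ grid with CV deviance"
    signature.save_signature(result.signature, outdir / "signature.tsv")
    artifacts["signature.tsv"] = "fitted gene-pair signature"
    result.train_scores.to_csv(outdir / "train_scores.tsv", sep="\t")
    artifacts["train_scores.tsv"] = "per-sample diagnostic scores (training)"
    if result.report is not None:
        result.report.to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
        artifacts["evaluation.tsv"] = "overall and stratified AUCs"
    result.manifest["artifacts"] = artifacts
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))


def run_score(
    signature_path: str | Path | None,
    expr_path: str | Path,
    meta_path: str | Path,
    out: str | Path | None = None,
    include_intercept: bool = True,
) -> pd.Series:
    """Apply a saved signature (default: the packaged one) to a dataset TSV."""
    sig = (
        signature.load_default_signature()
        if signature_path is None
        else signature.load_signature(signature_path)
    )
    ds = _stage("expression_io", read_expression, expr_path, meta_path)
    scores = _stage("evaluation", signature.score_samples, sig, ds, include_intercept)
    if out is not None:
        scores.to_csv(out, sep="\t")
    return scores


# --------------------------------------------------------------------------
# cohort fixture
# --------------------------------------------------------------------------


def load_cohort_table() -> pd.DataFrame:
    """The packaged study-cohort table (accession, platform, class counts, set)."""
    ref = resources.files("pairsig").joinpath("data", COHORT_RESOURCE)
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def validate_cohort_table(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check per-row count consistency and summarize totals by set.

    Every row must satisfy total = tumor + nontumor. Returns a summary frame
    with one row per set plus an ``overall`` row (columns: total, tumor,
    nontumor, n_datasets).
    """
    if table is None:
        table = load_cohort_table()
    bad = table[table["total"] != table["tumor"] + table["nontumor"]]
    if len(bad):
        rows = bad["accession"].tolist()
        raise ValueError(f"cohort rows with total ≠ tumor + nontumor: {rows}")
    by_set = (
        table.groupby("set")[["total", "tumor", "nontumor"]].sum().astype(int)
    )
    by_set["n_datasets"] = table.groupby("set").size()
    overall = pd.DataFrame(
        {
            "total": [int(table["total"].sum())],
            "tumor": [int(table["tumor"].sum())],
            "nontumor": [int(table["nontumor"].sum())],
            "n_datasets": [len(table)],
        },
        index=pd.Index(["overall"], name="set"),
    )
    return pd.concat([by_set, overall])
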