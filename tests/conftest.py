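"""Shared fixtures: tiny hand-built datasets and the seeded recovery runs.

Expensive seeded pipeline runs are session-scoped so the acceptance tests
and unit tests share one computation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import pairsig as ps


def make_dataset(
    values: np.ndarray,
    genes: list[str],
    samples: list[str],
    labels: list[str],
    dataset_id: str = "DS1",
    platform: str = "PLAT1",
) -> ps.ExpressionDataset:
    """Small helper to assemble an ExpressionDataset from raw pieces."""
    subtypes = [
        "NA" if lab == "tumor" else "adjacent_normal" for lab in labels
    ]
    meta = pd.DataFrame(
        {
            "label": labels,
            "dataset_id": dataset_id,
            "platform": platform,
            "nontumor_subtype": subtypes,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ps.ExpressionDataset(
        pd.DataFrame(values, index=genes, columns=samples), meta
    )


@pytest.fixture
def toy_dataset() -> ps.ExpressionDataset:
    """3 genes × 4 samples with known values."""
    values = np.array(
        [
            [5.0, 1.0, 3.0, 2.0],  # GA
            [4.0, 2.0, 3.0, 8.0],  # GB
            [1.0, 9.0, 3.0, 4.0],  # GC
        ]
    )
    return make_dataset(
        values,
        ["GA", "GB", "GC"],
        ["s1", "s2", "s3", "s4"],
        ["tumor", "tumor", "nontumor", "nontumor"],
    )


@pytest.fixture(scope="session")
def recovery_config() -> ps.SyntheticConfig:
    """The seeded parameter-recovery study conditions."""
    return ps.SyntheticConfig(
        n_datasets=5,
        samples_per_dataset=(53, 34),
        n_genes=1000,
        n_informative=20,
        effect_lfc=1.0,
        informative_in_fraction=0.8,
        seed=0,
    )


@pytest.fixture(scope="session")
def recovery_run(recovery_config):
    """Full pipeline on the recovery conditions plus the generator truth."""
    datasets, truth = ps.generate_collection(recovery_config)
    config = ps.PipelineConfig(synthetic=recovery_config, seed=recovery_config.seed)
    result = ps.run_train(config, datasets=datasets)
    return {
        "config": config,
        "datasets": datasets,
        "truth": truth,
        "result": result,
    }


@pytest.fixture(scope="session")
def heldout_datasets(recovery_config):
    """Two unseen datasets drawn from the same gene universe and process."""
    extended = dataclasses.replace(recovery_config, n_datasets=7)
    return [ps.generate_dataset(extended, d)[0] for d in (5, 6)]


@pytest.fixture(scope="session")
def signature_demo_dataset():
    """Synthetic dataset containing the 26 packaged-signature symbols.

    Random log2 values (no planted class structure): enough to exercise
    scoring, totality and invariance of the packaged signature.
    """
    sig = ps.load_default_signature()
    genes = sig.genes + [f"G{i:04d}" for i in range(10)]
    rng = np.random.default_rng(11)
    n = 30
    values = rng.uniform(4.0, 12.0, size=(len(genes), n))
    labels = ["tumor"] * 15 + ["nontumor"] * 15
    return make_dataset(values, genes, [f"s{i:02d}" for i in range(n)], labels)
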