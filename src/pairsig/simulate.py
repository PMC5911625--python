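"""Synthetic multi-dataset two-class expression generator.

Emulates the structure of a multi-cohort microarray compendium: several
datasets ("batches") of tumor and nontumor samples drawn over one shared gene
universe, a configurable subset of truly differential genes with a stated
log2 effect size, per-gene-per-batch additive shifts, and optional per-sample
strictly monotone distortions — the batch effects that within-sample
gene-pair features are designed to neutralize.

Every quantity has known ground truth, so each downstream stage (differential
screening, consensus selection, pair binarization, penalized fitting) has a
parameter-recovery test surface.

Random streams are split hierarchically (collection seed → per-dataset →
per-sample) with :class:`numpy.random.SeedSequence` spawn keys, so adding a
dataset or a sample never perturbs previously generated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import NONTUMOR_SUBTYPES, ExpressionDataset

DISTORTION_KINDS = ("none", "affine", "power")


class ConfigurationError(ValueError):
    """Invalid synthetic-generator configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic multi-dataset collection.

    Defaults mirror a five-cohort training compendium: per-dataset class
    sizes (53 tumor, 34 nontumor) match the mean cohort composition of the
    thyroid training sets (263 tumor / 172 nontumor over five datasets),
    baseline means span typical log2 array intensities, and gene-level SDs
    span the usual 0.3–0.8 log2 range.

    Attributes
    ----------
    n_datasets : number of datasets (batches) in the collection.
    samples_per_dataset : (n_tumor, n_nontumor) per dataset.
    n_genes : size of the shared gene universe.
    n_informative : number of genes carrying a true class effect.
    effect_lfc : log2-fold-change magnitude of informative genes (≥ 0); the
        sign is fixed per gene, deterministically from the seed.
    baseline_mean_range : (lo, hi) of per-gene baseline means, log2 units.
    baseline_sd_range : (lo, hi) of per-gene residual SDs, log2 units.
    batch_shift_sd : SD of the per-gene-per-batch additive shift, log2 units.
    sample_distortion : 'none', 'affine' or 'power' per-sample monotone map.
    affine_slope_range / affine_offset_range / power_exponent_range :
        parameter ranges for the distortions (slopes and exponents must stay
        positive to keep the maps strictly increasing).
    informative_in_fraction : probability that an informative gene carries
        its effect in any given dataset (models cross-dataset DEG frequency).
    seed : master seed; identical (config, seed) reproduces byte-identical
        output.
    """

    n_datasets: int = 5
    samples_per_dataset: tuple[int, int] = (53, 34)
    n_genes: int = 1000
    n_informative: int = 20
    effect_lfc: float = 1.0
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    baseline_sd_range: tuple[float, float] = (0.3, 0.8)
    batch_shift_sd: float = 0.3
    sample_distortion: str = "none"
    affine_slope_range: tuple[float, float] = (0.8, 1.25)
    affine_offset_range: tuple[float, float] = (-2.0, 2.0)
    power_exponent_range: tuple[float, float] = (0.8, 1.25)
    informative_in_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        n_tumor, n_nontumor = self.samples_per_dataset
        for name, value in [
            ("n_datasets", self.n_datasets),
            ("n_tumor", n_tumor),
            ("n_nontumor", n_nontumor),
            ("n_genes", self.n_genes),
        ]:
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ConfigurationError(
                f"n_informative must lie in [0, n_genes]; got {self.n_informative}"
            )
        if self.effect_lfc < 0:
            raise ConfigurationError("effect_lfc must be ≥ 0")
        if self.batch_shift_sd < 0:
            raise ConfigurationError("batch_shift_sd must be ≥ 0")
        if not 0.0 <= self.informative_in_fraction <= 1.0:
            raise ConfigurationError("informative_in_fraction must lie in [0, 1]")
        if self.sample_distortion not in DISTORTION_KINDS:
            raise ConfigurationError(
                f"sample_distortion must be one of {DISTORTION_KINDS}"
            )
        if self.affine_slope_range[0] <= 0:
            raise ConfigurationError("affine slopes must be positive (monotone map)")
        if self.power_exponent_range[0] <= 0:
            raise ConfigurationError("power exponents must be positive (monotone map)")
        if self.baseline_sd_range[0] <= 0:
            raise ConfigurationError("baseline SDs must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: informative genes and where their effects are.

    ``effect_indicator`` is an informative-genes × datasets boolean frame;
    entry (g, d) is True when gene g carries its class effect in dataset d.
    ``effect_sign`` maps each informative gene to ±1 (direction of the tumor
    shift).
    """

    informative_genes: frozenset[str]
    effect_indicator: pd.DataFrame
    effect_sign: pd.Series


def _gene_universe(config: SyntheticConfig):
    """Per-gene parameters drawn from the collection-level stream (spawn key 0)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    genes = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    mu = rng.uniform(*config.baseline_mean_range, size=config.n_genes)
    sigma = rng.uniform(*config.baseline_sd_range, size=config.n_genes)
    informative_idx = np.sort(
        rng.choice(config.n_genes, size=config.n_informative, replace=False)
    )
    signs = rng.choice([-1.0, 1.0], size=config.n_informative)
    return genes, mu, sigma, informative_idx, signs


def _dataset_effect_indicator(config: SyntheticConfig, dataset_index: int) -> np.ndarray:
    """Which informative genes carry their effect in this dataset (Bernoulli)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1, dataset_index, 0))
    )
    return rng.random(config.n_informative) < config.informative_in_fraction


def generate_dataset(
    config: SyntheticConfig, dataset_index: int
) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate one dataset of the collection.

    Expression is drawn gene-wise Normal(μ_g + batch_gd + class effect, σ_g)
    on the log2 scale; tumor samples of informative genes active in this
    dataset are shifted by ``sign_g · effect_lfc``. Labels, a synthetic
    platform tag (alternating by dataset index) and a round-robin nontumor
    subtype are populated in the metadata.
    """
    if dataset_index < 0 or dataset_index >= config.n_datasets:
        raise ConfigurationError(
            f"dataset_index {dataset_index} outside [0, {config.n_datasets})"
        )
    genes, mu, sigma, informative_idx, signs = _gene_universe(config)
    n_tumor, n_nontumor = config.samples_per_dataset
    n_samples = n_tumor + n_nontumor

    ds_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1, dataset_index, 1))
    )
    batch_shift = ds_rng.normal(0.0, config.batch_shift_sd, size=config.n_genes)
    active = _dataset_effect_indicator(config, dataset_index)

    effect = np.zeros(config.n_genes)
    effect[informative_idx[active]] = signs[active] * config.effect_lfc

    values = np.empty((config.n_genes, n_samples))
    labels = ["tumor"] * n_tumor + ["nontumor"] * n_nontumor
    for s in range(n_samples):
        s_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1, dataset_index, 2, s))
        )
        center = mu + batch_shift + (effect if labels[s] == "tumor" else 0.0)
        values[:, s] = center + s_rng.normal(0.0, 1.0, size=config.n_genes) * sigma

    dataset_id = f"SYN{dataset_index + 1:02d}"
    sample_ids = [f"{dataset_id}_S{s + 1:03d}" for s in range(n_samples)]
    subtypes = ["NA"] * n_tumor + [
        NONTUMOR_SUBTYPES[i % len(NONTUMOR_SUBTYPES)] for i in range(n_nontumor)
    ]
    meta = pd.DataFrame(
        {
            "label": labels,
            "dataset_id": dataset_id,
            "platform": f"SYNPLAT{dataset_index % 2 + 1}",
            "nontumor_subtype": subtypes,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    ds = ExpressionDataset(pd.DataFrame(values, index=genes, columns=sample_ids), meta)
    if config.sample_distortion != "none":
        ds = apply_sample_distortion(
            ds,
            config.sample_distortion,
            config=config,
            seed=np.random.SeedSequence(
                config.seed, spawn_key=(1, dataset_index, 3)
            ).generate_state(1)[0] % (2**31),
        )

    informative_genes = [genes[i] for i in informative_idx]
    truth = GroundTruth(
        informative_genes=frozenset(informative_genes),
        effect_indicator=pd.DataFrame(
            {dataset_id: active}, index=pd.Index(informative_genes, name="gene")
        ),
        effect_sign=pd.Series(signs, index=informative_genes, name="sign"),
    )
    return ds, truth


def generate_collection(
    config: SyntheticConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate all ``n_datasets`` datasets over one shared gene universe."""
    datasets: list[ExpressionDataset] = []
    indicators = []
    truth: GroundTruth | None = None
    for d in range(config.n_datasets):
        ds, t = generate_dataset(config, d)
        datasets.append(ds)
        indicators.append(t.effect_indicator)
        truth = t
    assert truth is not None
    combined = GroundTruth(
        informative_genes=truth.informative_genes,
        effect_indicator=pd.concat(indicators, axis=1),
        effect_sign=truth.effect_sign,
    )
    return datasets, combined


def apply_sample_distortion(
    ds: ExpressionDataset,
    kind: str,
    config: SyntheticConfig | None = None,
    seed: int = 0,
    slope_range: tuple[float, float] | None = None,
    offset_range: tuple[float, float] | None = None,
    exponent_range: tuple[float, float] | None = None,
) -> ExpressionDataset:
    """Apply an independent strictly increasing distortion to every sample.

    ``affine`` maps each sample's log2 vector x → a·x + b with a > 0.
    ``power`` anti-logs, raises to a positive exponent γ, rescales and
    re-logs — on the log2 scale this is x → γ·x + log2(c), again strictly
    increasing; it changes the spacing of values but never their order, so
    per-sample gene ranks are invariant (the property the pair features
    exploit).

    Parameter ranges default to those in ``config`` (or
    :class:`SyntheticConfig`'s defaults). Non-positive slopes or exponents
    are rejected: they would break monotonicity.
    """
    if kind == "none":
        return ds.copy()
    if kind not in DISTORTION_KINDS:
        raise ConfigurationError(f"unknown distortion kind {kind!r}")
    base = config or SyntheticConfig()
    slope_range = slope_range or base.affine_slope_range
    offset_range = offset_range or base.affine_offset_range
    exponent_range = exponent_range or base.power_exponent_range
    if slope_range[0] <= 0:
        raise ConfigurationError("affine slope must be positive")
    if exponent_range[0] <= 0:
        raise ConfigurationError("power exponent must be positive")

    rng = np.random.default_rng(seed)
    values = ds.expr.to_numpy().copy()
    n_samples = values.shape[1]
    if kind == "affine":
        slopes = rng.uniform(*slope_range, size=n_samples)
        offsets = rng.uniform(*offset_range, size=n_samples)
        values = values * slopes + offsets
    else:  # power, applied on the anti-logged (linear) scale then re-logged
        exponents = rng.uniform(*exponent_range, size=n_samples)
        scales = 2.0 ** rng.uniform(*offset_range, size=n_samples)
        linear = np.exp2(values)
        values = np.log2(scales * linear**exponents)
    distorted = pd.DataFrame(values, index=ds.expr.index, columns=ds.expr.columns)
    return ExpressionDataset(distorted, ds.meta.copy())


def write_config(config: SyntheticConfig, path) -> None:
    """Persist a config as a flat ``key\\tvalue`` file."""
    with open(path, "w") as fh:
        for key, value in vars(config).items():
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            fh.write(f"{key}\t{value}\n")


def read_config(path) -> SyntheticConfig:
    """Read a config written by :func:`write_config`."""
    raw: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            key, value = line.rstrip("\n").split("\t", 1)
            raw[key] = value
    kwargs: dict = {}
    for f in SyntheticConfig.__dataclass_fields__.values():
        if f.name not in raw:
            continue
        text = raw[f.name]
        if f.name == "sample_distortion":
            kwargs[f.name] = text
        elif "," in text:
            parts = [float(p) for p in text.split(",")]
            if f.name == "samples_per_dataset":
                parts = [int(p) for p in parts]
            kwargs[f.name] = tuple(parts)
        elif f.name in ("n_datasets", "n_genes", "n_informative", "seed"):
            kwargs[f.name] = int(text)
        else:
            kwargs[f.name] = float(text)
    return SyntheticConfig(**kwargs)
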