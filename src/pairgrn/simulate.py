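"""Paired bulk + single-cell expression simulator with planted regulation.

The generator emulates the statistical structure that joint-expression
featurization relies on: a TF and its targets co-vary across bulk samples
and across single cells because they share a latent per-sample/per-cell TF
activity, while decoy genes fluctuate independently. Bulk values are
log-normal TPM-like intensities; single-cell values are negative-binomial
counts thinned by Bernoulli dropout, reproducing the sparse, zero-inflated
character of UMI data.

Generative model, per TF ``i`` and sample/cell ``s``::

    a_is   ~ Normal(mu0, sigma0)                      # latent TF activity
    tf:     log-mean = a_is
    target: log-mean = mu0 + slope * (a_is - mu0)
    bulk    value = exp(log-mean + Normal(0, bulk_noise_sd))
    sc      value = NB(mean=exp(log-mean), size=sc_dispersion), then
            zeroed with probability dropout_rate

Decoys draw their own independent latent activity. Every (TF, own-target)
pair is a positive; an equal number of (TF, decoy) pairs, sampled without
replacement, are the negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .matrix import ExpressionMatrix
from .pairs import GenePairLabelSet, PairSetError


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the paired-dataset simulator.

    Defaults are the strong-signal setting used throughout the package's
    own evaluation: 40 TFs x 5 targets plus 200 decoys (400 labeled pairs),
    200 bulk samples, 500 cells, regulatory slope 2 on the log scale.
    """

    n_tfs: int = 40
    targets_per_tf: int = 5
    n_decoys: int = 200
    n_bulk_samples: int = 200
    n_cells: int = 500
    effect_slope: float = 2.0
    bulk_noise_sd: float = 0.2
    sc_dispersion: float = 2.0
    dropout_rate: float = 0.3
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs < 1 or self.targets_per_tf < 1:
            raise ValueError("need at least one TF and one target per TF")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be non-negative")
        if self.n_bulk_samples < 1 or self.n_cells < 1:
            raise ValueError("need at least one bulk sample and one cell")
        if self.bulk_noise_sd < 0 or self.baseline_log_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.sc_dispersion <= 0:
            raise ValueError("sc_dispersion must be positive")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.n_tfs * (1 + self.targets_per_tf) + self.n_decoys


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial draws via the gamma-Poisson mixture."""
    lam = rng.gamma(shape=size_param, scale=mean / size_param)
    return rng.poisson(lam).astype(np.float64)


def simulate_paired_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GenePairLabelSet]:
    """Generate (bulk, sc, labeled pairs) under ``config``.

    Deterministic: identical config (including seed) gives bit-identical
    matrices and labels.
    """
    n_pos = config.n_tfs * config.targets_per_tf
    if config.n_decoys * config.n_tfs < n_pos:
        raise PairSetError(
            f"{config.n_decoys} decoys cannot supply {n_pos} negative pairs"
        )
    rng = np.random.default_rng(config.seed)
    mu0, s0 = config.baseline_log_mean, config.baseline_log_sd

    tf_ids = [f"TF{i:04d}" for i in range(config.n_tfs)]
    target_ids = [
        f"TF{i:04d}_T{j:02d}"
        for i in range(config.n_tfs)
        for j in range(config.targets_per_tf)
    ]
    decoy_ids = [f"DEC{i:04d}" for i in range(config.n_decoys)]
    gene_ids = tf_ids + target_ids + decoy_ids

    n_genes = config.n_genes
    log_mean_bulk = np.empty((n_genes, config.n_bulk_samples))
    log_mean_sc = np.empty((n_genes, config.n_cells))

    # latent TF activities, one per sample/cell, shared with all own targets
    act_bulk = rng.normal(mu0, s0, size=(config.n_tfs, config.n_bulk_samples))
    act_sc = rng.normal(mu0, s0, size=(config.n_tfs, config.n_cells))
    log_mean_bulk[: config.n_tfs] = act_bulk
    log_mean_sc[: config.n_tfs] = act_sc
    for i in range(config.n_tfs):
        lo = config.n_tfs + i * config.targets_per_tf
        hi = lo + config.targets_per_tf
        log_mean_bulk[lo:hi] = mu0 + config.effect_slope * (act_bulk[i] - mu0)
        log_mean_sc[lo:hi] = mu0 + config.effect_slope * (act_sc[i] - mu0)
    n_core = config.n_tfs * (1 + config.targets_per_tf)
    log_mean_bulk[n_core:] = rng.normal(
        mu0, s0, size=(config.n_decoys, config.n_bulk_samples)
    )
    log_mean_sc[n_core:] = rng.normal(mu0, s0, size=(config.n_decoys, config.n_cells))

    bulk_values = np.exp(
        log_mean_bulk + rng.normal(0, config.bulk_noise_sd, size=log_mean_bulk.shape)
    )
    sc_values = _nb_counts(rng, np.exp(log_mean_sc), config.sc_dispersion)
    if config.dropout_rate > 0:
        keep = rng.random(sc_values.shape) >= config.dropout_rate
        sc_values = sc_values * keep

    bulk = ExpressionMatrix(
        gene_ids,
        [f"S{j:04d}" for j in range(config.n_bulk_samples)],
        bulk_values,
        modality="bulk",
    )
    sc = ExpressionMatrix(
        gene_ids,
        [f"C{j:05d}" for j in range(config.n_cells)],
        sc_values,
        modality="single_cell",
    )

    positives = [
        (tf_ids[i], target_ids[i * config.targets_per_tf + j], 1)
        for i in range(config.n_tfs)
        for j in range(config.targets_per_tf)
    ]
    candidates = [(tf, d) for tf in tf_ids for d in decoy_ids]
    chosen = rng.choice(len(candidates), size=n_pos, replace=False)
    negatives = [(candidates[i][0], candidates[i][1], 0) for i in np.sort(chosen)]
    pairs = GenePairLabelSet.from_tuples(positives + negatives, provenance="simulated")
    return bulk, sc, pairs


def summarize_simulation(
    bulk: ExpressionMatrix,
    sc: ExpressionMatrix,
    pairs: GenePairLabelSet,
) -> pd.DataFrame:
    """Per-pair Spearman rank correlations in each modality, split by label.

    Returns one row per pair with columns ``tf_id, target_id, label,
    rho_bulk, rho_sc``; group means are available via
    ``df.groupby("label")[["rho_bulk", "rho_sc"]].mean()``.
    """
    rows = []
    for tf, target, label in pairs:
        rho_b = spearmanr(bulk.gene_vector(tf), bulk.gene_vector(target)).statistic
        rho_s = spearmanr(sc.gene_vector(tf), sc.gene_vector(target)).statistic
        rows.append((tf, target, label, rho_b, rho_s))
    return pd.DataFrame(
        rows, columns=["tf_id", "target_id", "label", "rho_bulk", "rho_sc"]
    )


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-dict form of a config, e.g. for YAML serialization."""
    return asdict(config)
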