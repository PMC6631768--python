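"""Synthetic paired expression genomes with known truth and outlier masks.

Emulates a two-condition paired microarray-style experiment on the log
scale: every gene's expressions are Gaussian with variance ``sigma2`` around
condition means drawn uniformly from ``mu_range``.  Equally expressed genes
(EEGs) share one mean across conditions; differentially expressed genes
(DEGs) draw the two condition means independently (redrawing the pair if
exactly equal), which yields a triangular spectrum of effect sizes
``|mu1 - mu2|`` on ``(0, mu_range width)`` rather than a single fixed effect.
A ``de_means="fixed"`` mode with a constant effect is available.

Contamination replaces randomly chosen entries by the one-sided rule

    x* = d + 2 * max(x_gik over replicates k of that gene and condition),

with ``d`` drawn uniformly from ``d_range`` (or fixed), so an outlier always
exceeds the per-condition maximum.  Either every gene is contaminated
(``all_genes``, one or two entries each) or a random fraction of genes is
(``per_gene_fraction``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .experiment import PairedExperiment

__all__ = ["SimulationConfig", "SimulatedDataset", "generate", "contaminate"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings for a data-type-1 style genome.

    Defaults follow the simulation protocol the package reproduces: 10,000
    genes, 3% DEGs, condition means in (3, 5), per-observation variance
    0.05, outlier shifts in (5, 10).
    """

    n_genes: int = 10000
    prop_de: float = 0.03
    n: int = 3
    mu_range: tuple[float, float] = (3.0, 5.0)
    sigma2: float = 0.05
    contamination: str = "none"  # none | per_gene_fraction | all_genes
    outlier_genes_fraction: float = 0.05
    outliers_per_gene: object = 1  # 1, 2 or "one_or_two"
    d_range: tuple[float, float] = (5.0, 10.0)
    d_fixed: Optional[float] = None
    de_means: str = "independent"  # independent | fixed
    fixed_effect: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n < 2:
            raise ValueError("need n_genes >= 1 and n >= 2")
        if not 0 < self.prop_de < 1:
            raise ValueError("prop_de must lie in (0, 1)")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if not self.mu_range[0] < self.mu_range[1]:
            raise ValueError("mu_range must be a non-empty interval")
        if not self.d_range[0] < self.d_range[1]:
            raise ValueError("d_range must be a non-empty interval")
        if self.contamination not in ("none", "per_gene_fraction", "all_genes"):
            raise ValueError(f"unknown contamination mode {self.contamination!r}")
        if self.outliers_per_gene not in (1, 2, "one_or_two"):
            raise ValueError("outliers_per_gene must be 1, 2 or 'one_or_two'")
        if not 0 < self.outlier_genes_fraction <= 1:
            raise ValueError("outlier_genes_fraction must lie in (0, 1]")
        if self.de_means not in ("independent", "fixed"):
            raise ValueError("de_means must be 'independent' or 'fixed'")

    @property
    def n_de(self) -> int:
        return round(self.prop_de * self.n_genes)


@dataclass(frozen=True)
class SimulatedDataset:
    """Expression matrix plus ground truth, outlier mask and originals."""

    experiment: PairedExperiment
    is_de: np.ndarray
    outlier_mask: np.ndarray
    config: SimulationConfig
    originals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.originals is None:
            object.__setattr__(self, "originals", np.zeros(0))

    @property
    def contaminated(self) -> bool:
        return bool(self.outlier_mask.any())


def generate(config: SimulationConfig) -> SimulatedDataset:
    """Draw a clean genome; fully reproducible from ``config.seed``.

    Columns are laid out condition 1 first (pair ``k`` is columns
    ``(k, n + k)``); DEG positions are randomized by a seeded shuffle.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5A4D]))
    G, n, nde = config.n_genes, config.n, config.n_de
    lo, hi = config.mu_range
    mu1 = rng.uniform(lo, hi, G)
    mu2 = mu1.copy()
    if config.de_means == "independent":
        draw = rng.uniform(lo, hi, nde)
        redo = draw == mu1[:nde]
        while redo.any():  # measure-zero, but the contract excludes equality
            draw[redo] = rng.uniform(lo, hi, redo.sum())
            redo = draw == mu1[:nde]
        mu2[:nde] = draw
    else:
        mu2[:nde] = mu1[:nde] + config.fixed_effect * rng.choice([1, -1], nde)
    is_de = np.zeros(G, dtype=bool)
    is_de[:nde] = True
    perm = rng.permutation(G)
    mu1, mu2, is_de = mu1[perm], mu2[perm], is_de[perm]
    sd = np.sqrt(config.sigma2)
    x1 = rng.normal(mu1[:, None], sd, (G, n))
    x2 = rng.normal(mu2[:, None], sd, (G, n))
    values = np.hstack([x1, x2])
    gene_ids = tuple(f"g{i:0{len(str(G))}d}" for i in range(G))
    pairing = tuple((k, n + k) for k in range(n))
    exp = PairedExperiment(gene_ids, values, pairing)
    return SimulatedDataset(exp, is_de, np.zeros((G, 2 * n), dtype=bool), config)


def contaminate(
    dataset: SimulatedDataset, config: Optional[SimulationConfig] = None
) -> SimulatedDataset:
    """Inject outlying expressions by ``x* = d + 2 * max(condition values)``.

    Returns a new dataset; replaced values are recorded in ``originals``
    (aligned with the True entries of ``outlier_mask`` in row-major order).
    """
    config = dataset.config if config is None else config
    if config.contamination == "none":
        return dataset
    if dataset.contaminated:
        raise ValueError("dataset is already contaminated")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC047]))
    exp = dataset.experiment
    G, n = exp.n_genes, exp.n
    values = exp.values.copy()
    mask = np.zeros_like(values, dtype=bool)
    cols = {1: [a for a, _ in exp.pairing], 2: [b for _, b in exp.pairing]}
    if config.contamination == "all_genes":
        targets = np.arange(G)
    else:
        k = round(config.outlier_genes_fraction * G)
        targets = rng.choice(G, size=k, replace=False)
    original = exp.values
    for g in targets:
        if config.outliers_per_gene == "one_or_two":
            n_out = int(rng.integers(1, 3))
        else:
            n_out = int(config.outliers_per_gene)
        # distinct entries; the max is taken over the pre-contamination values
        for flat in rng.choice(2 * n, size=n_out, replace=False):
            cond = 1 if flat < n else 2
            col = cols[cond][int(flat % n)]
            d = (
                config.d_fixed
                if config.d_fixed is not None
                else float(rng.uniform(*config.d_range))
            )
            values[g, col] = d + 2.0 * original[g, cols[cond]].max()
            mask[g, col] = True
    originals = exp.values[mask]
    new_exp = PairedExperiment(exp.gene_ids, values, exp.pairing)
    return SimulatedDataset(
        new_exp, dataset.is_de, mask, config, originals=originals
    )
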