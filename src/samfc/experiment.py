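"""Paired two-condition expression data and classical per-gene estimates.

A paired design measures every subject once under each condition, so the
analysis operates on the within-pair difference vector of each gene,
``d_gk = x_g1k - x_g2k``.  For log-scale expression these differences are the
per-pair log fold changes, and under a Gaussian model they are i.i.d.
``N(mu_g, sigma_g^2)`` with ``mu_g`` the log fold change of gene ``g``.
This module holds the data container, the classical (maximum-likelihood style)
location/scale estimates and the one-sample paired t statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedExperiment",
    "DifferenceVector",
    "LocationScaleEstimate",
    "compute_differences",
    "difference_matrix",
    "mle_estimate",
    "paired_t_statistic",
    "paired_t_pvalue",
]


@dataclass(frozen=True)
class PairedExperiment:
    """Genes x samples log-expression matrix with an explicit pairing map.

    Parameters
    ----------
    gene_ids
        One identifier per row of ``values``.
    values
        Array of shape ``(n_genes, 2 * n)``; assumed already normalized and on
        the analysis (typically log2) scale.
    pairing
        ``n`` pairs ``(condition1_column, condition2_column)`` of column
        indices.  Defaults to the first half of the columns versus the second
        half, in order.
    """

    gene_ids: tuple
    values: np.ndarray
    pairing: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        if len(self.gene_ids) != values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {values.shape[0]} rows"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene row {bad[0]}, column {bad[1]}"
            )
        pairing = self.pairing
        if pairing is None:
            m = values.shape[1]
            if m % 2:
                raise ValueError(
                    "odd number of sample columns; declare an explicit pairing"
                )
            pairing = tuple((k, m // 2 + k) for k in range(m // 2))
        else:
            pairing = tuple((int(a), int(b)) for a, b in pairing)
        used = [c for pair in pairing for c in pair]
        if len(set(used)) != len(used):
            dup = next(c for c in used if used.count(c) > 1)
            raise ValueError(f"column {dup} appears in more than one pair slot")
        if any(c < 0 or c >= values.shape[1] for c in used):
            bad_pair = next(
                p for p in pairing if any(c < 0 or c >= values.shape[1] for c in p)
            )
            raise ValueError(f"pairing {bad_pair} references a missing column")
        if len(pairing) < 2:
            raise ValueError("need n >= 2 pairs for the scale to be estimable")
        object.__setattr__(self, "pairing", pairing)

    @property
    def n(self) -> int:
        """Replicate (pair) count per condition."""
        return len(self.pairing)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DifferenceVector:
    """Per-gene vector of paired differences (per-pair log fold changes)."""

    gene_id: object
    d: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))


@dataclass(frozen=True)
class LocationScaleEstimate:
    """Location/scale estimate for one gene's difference vector.

    ``kind`` is ``"classical"`` for the plain mean / sample standard deviation
    and ``"robust"`` for the minimum beta-divergence fit.  ``weights`` are the
    per-replicate beta-weights (identically 1 for a classical estimate).
    """

    mu: float
    sigma: float
    kind: str
    weights: np.ndarray
    is_outlying_gene: bool = False
    converged: bool = True
    iterations: int = 0

    def __post_init__(self):
        if self.kind not in ("classical", "robust"):
            raise ValueError(f"unknown estimate kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        w = np.asarray(self.weights, dtype=float)
        if np.any((w < 0) | (w > 1)):
            raise ValueError("weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)


def difference_matrix(experiment: PairedExperiment) -> np.ndarray:
    """Matrix of paired differences, shape ``(n_genes, n)``.

    Column ``k`` is condition-1 minus condition-2 of pair ``k``.
    """
    c1 = [a for a, _ in experiment.pairing]
    c2 = [b for _, b in experiment.pairing]
    return experiment.values[:, c1] - experiment.values[:, c2]


def compute_differences(experiment: PairedExperiment) -> list[DifferenceVector]:
    """One :class:`DifferenceVector` per gene, in input row order."""
    D = difference_matrix(experiment)
    return [DifferenceVector(g, row) for g, row in zip(experiment.gene_ids, D)]


def mle_estimate(d: DifferenceVector) -> LocationScaleEstimate:
    """Classical estimate: arithmetic mean and (n-1)-denominator standard deviation."""
    x = d.d
    if x.size < 2:
        raise ValueError("need n >= 2 paired differences to estimate a scale")
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=1))
    return LocationScaleEstimate(mu, sigma, "classical", np.ones(x.size))


def paired_t_statistic(d: DifferenceVector) -> float:
    """One-sample t statistic ``mean / (sd / sqrt(n))`` of the differences.

    A zero sample standard deviation with a nonzero mean yields a signed
    infinity (the gene sorts above every finite statistic) with a warning.
    """
    est = mle_estimate(d)
    n = d.d.size
    if est.sigma == 0.0:
        if est.mu == 0.0:
            return 0.0
        warnings.warn(
            f"gene {d.gene_id}: zero variance with nonzero mean; "
            "t statistic is infinite",
            stacklevel=2,
        )
        return math.copysign(math.inf, est.mu)
    return est.mu / (est.sigma / math.sqrt(n))


def paired_t_pvalue(d: DifferenceVector) -> float:
    """Two-sided Student-t p-value with n-1 degrees of freedom."""
    t = paired_t_statistic(d)
    if math.isinf(t):
        return 0.0
    return float(2.0 * stats.t.sf(abs(t), d.d.size - 1))
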