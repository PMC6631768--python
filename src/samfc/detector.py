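"""Scikit-learn estimator running the hybrid robust SAM-FC pipeline end to end.

``SAMFCDetector`` is a feature (gene) selector: ``fit`` consumes a
samples x genes expression matrix for a paired design, computes robust
fold changes, beta-SAM statistics, permutation p-values and the fused
FC/SAM ranking, and exposes the genes selected by the leading-run rule as
the support mask, so it composes with scikit-learn pipelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .divergence import BetaConfig, delta_cutoff, fit_genome
from .scoring import bh_adjust, compute_pvalues, select_s0

__all__ = ["SAMFCDetector"]


class SAMFCDetector(SelectorMixin, BaseEstimator):
    """Hybrid robust SAM-FC differential expression detector for paired data.

    The pipeline per gene g with paired differences ``d_gk``:

    1. classical mean/sd and a robust minimum beta-divergence fit;
    2. beta-weights of every replicate at the robust fit, pooled genome-wide
       into the adaptive cutoff ``delta``; genes with any weight <= delta are
       flagged outlying;
    3. unified estimates (robust where flagged, classical elsewhere) feed the
       beta-FC and, with the CV-minimizing fudge factor ``s0``, the beta-SAM
       statistic;
    4. two-sided p-values (pooled sign-flip permutation null by default),
       BH adjustment;
    5. genes ranked by the average of the |beta-FC| and |beta-SAM| ranks;
       the leading run with p-value below ``p_cutoff`` is selected.

    Parameters
    ----------
    beta : float, default=0.2
        Divergence tuning parameter; 0 gives the classical SAM-FC pipeline.
    alpha : float, default=0.1
        Interpolation fraction of the adaptive weight cutoff.
    delta_cap : float, default=0.2
        Cap of the adaptive cutoff.
    tol, max_iter
        Fixed-point stopping rule of the robust fit.
    start : {"pooled", "per_gene"}
        Scale initialization of the genome-wide robust fit.
    delta_pool : {"all", "per_gene_min"}
        Which weights feed the adaptive cutoff.
    s0_method : {"windowed", "simple"}
        Coefficient-of-variation flavour used to choose the fudge factor.
    pvalue_method : {"sign_permutation", "t_reference", None}
        ``None`` skips p-values (and selection) for rank-only use.
    n_perm : int
        Random sign patterns when ``2^n`` exhaustive flips are infeasible.
    p_cutoff : float, default=0.1
        Raw-p threshold of the leading-run selection rule.
    selection : {"raw_p", "bh"}
        ``"bh"`` selects on BH-adjusted p-values at ``bh_cutoff`` instead.
    bh_cutoff : float, default=0.05
    pairing : sequence of (int, int) column pairs or None
        Which sample rows pair up; default first half vs second half.
    random_state : int or None
        Seed of the permutation null.

    Attributes
    ----------
    fold_change_ : ndarray, (n_genes,) — beta-FC per gene.
    statistic_ : ndarray — beta-SAM statistic per gene.
    pvalues_, pvalues_adjusted_ : ndarray — raw and BH-adjusted p-values.
    location_, scale_ : ndarray — classical estimates.
    robust_location_, robust_scale_ : ndarray — minimum beta-divergence fits.
    weights_ : ndarray, (n_genes, n) — beta-weights.
    delta_ : float — adaptive outlier cutoff.
    outlying_ : boolean ndarray — genes flagged as contaminated.
    s0_ : float — fudge factor.
    fc_rank_, sam_rank_, avg_rank_ : ndarray — fused ranking.
    order_ : ndarray — gene indices by ascending average rank.
    support_ : boolean ndarray — genes selected by the leading-run rule.

    Examples
    --------
    >>> from samfc.simulation import SimulationConfig, generate
    >>> ds = generate(SimulationConfig(n_genes=200, n=3, seed=1))
    >>> det = SAMFCDetector(random_state=0).fit(ds.experiment.values.T)
    >>> det.statistic_.shape
    (200,)
    """

    def __init__(
        self,
        beta: float = 0.2,
        alpha: float = 0.1,
        delta_cap: float = 0.2,
        tol: float = 1e-8,
        max_iter: int = 100,
        start: str = "pooled",
        delta_pool: str = "all",
        s0_method: str = "windowed",
        s0_grid_step: int = 5,
        pvalue_method: str | None = "sign_permutation",
        n_perm: int = 100,
        p_cutoff: float = 0.1,
        selection: str = "raw_p",
        bh_cutoff: float = 0.05,
        pairing=None,
        random_state: int | None = None,
    ):
        self.beta = beta
        self.alpha = alpha
        self.delta_cap = delta_cap
        self.tol = tol
        self.max_iter = max_iter
        self.start = start
        self.delta_pool = delta_pool
        self.s0_method = s0_method
        self.s0_grid_step = s0_grid_step
        self.pvalue_method = pvalue_method
        self.n_perm = n_perm
        self.p_cutoff = p_cutoff
        self.selection = selection
        self.bh_cutoff = bh_cutoff
        self.pairing = pairing
        self.random_state = random_state

    def _beta_config(self) -> BetaConfig:
        return BetaConfig(
            beta=self.beta,
            alpha=self.alpha,
            delta_cap=self.delta_cap,
            tol=self.tol,
            max_iter=self.max_iter,
            delta_pool=self.delta_pool,
            start=self.start,
        )

    def _differences(self, X: np.ndarray) -> np.ndarray:
        m = X.shape[0]
        pairing = self.pairing
        if pairing is None:
            if m % 2:
                raise ValueError(
                    "odd number of samples; declare an explicit pairing"
                )
            pairing = [(k, m // 2 + k) for k in range(m // 2)]
        used = [c for p in pairing for c in p]
        if len(set(used)) != len(used) or any(c < 0 or c >= m for c in used):
            raise ValueError("each sample must appear in exactly one pair slot")
        if len(pairing) < 2:
            raise ValueError("need n >= 2 pairs")
        c1 = [a for a, _ in pairing]
        c2 = [b for _, b in pairing]
        return (X[c1] - X[c2]).T  # genes x n

    def fit(self, X, y=None):
        """Run the pipeline.

        Parameters
        ----------
        X : array-like of shape (2 * n_pairs, n_genes)
            Paired log-scale expression, samples in rows.  ``y`` is ignored.
        """
        X = check_array(X, ensure_min_samples=4, ensure_all_finite=True)
        self.n_features_in_ = X.shape[1]
        D = self._differences(X)
        return self._fit_differences(D)

    def fit_differences(self, D):
        """Fit directly from a genes x n_pairs matrix of paired differences."""
        D = check_array(D, ensure_all_finite=True)
        if D.shape[1] < 2:
            raise ValueError("need n >= 2 paired differences per gene")
        self.n_features_in_ = D.shape[0]
        return self._fit_differences(np.asarray(D, dtype=float))

    def _fit_differences(self, D: np.ndarray):
        from scipy import stats as sps

        config = self._beta_config()
        G, n = D.shape
        self.n_ = n
        self.location_ = D.mean(axis=1)
        self.scale_ = D.std(axis=1, ddof=1)
        if self.beta == 0.0:
            self.robust_location_ = self.location_.copy()
            self.robust_scale_ = self.scale_.copy()
            self.weights_ = np.ones_like(D)
            self.delta_ = 0.0
            self.outlying_ = np.zeros(G, dtype=bool)
        else:
            mu_r, sd_r, w, conv = fit_genome(D, config)
            self.robust_location_, self.robust_scale_ = mu_r, sd_r
            self.weights_ = w
            valid = sd_r > 0
            if valid.any():
                pool = w[valid] if self.delta_pool == "all" else w[valid].min(axis=1)
                self.delta_ = delta_cutoff(pool, config)
            else:
                self.delta_ = 0.0
            self.outlying_ = (w <= self.delta_).any(axis=1) & valid
        mu_u = np.where(self.outlying_, self.robust_location_, self.location_)
        sd_u = np.where(self.outlying_, self.robust_scale_, self.scale_)
        self.fold_change_ = mu_u
        scaled_sd = sd_u / np.sqrt(n)
        sel = select_s0(
            mu_u, scaled_sd, method=self.s0_method, grid_step=self.s0_grid_step
        )
        self.s0_ = sel.s0
        self.s0_selection_ = sel
        denom = scaled_sd + self.s0_
        if np.any(denom == 0.0):
            raise ValueError(
                "zero beta-SAM denominator: s0 = 0 with a zero-scale gene"
            )
        self.statistic_ = mu_u / denom

        self.fc_rank_ = sps.rankdata(-np.abs(self.fold_change_), method="average")
        self.sam_rank_ = sps.rankdata(-np.abs(self.statistic_), method="average")
        self.avg_rank_ = (self.fc_rank_ + self.sam_rank_) / 2.0
        tie = self.sam_rank_ / (10.0 * G)  # favour statistical evidence on ties
        self.order_ = np.lexsort((np.arange(G), self.avg_rank_ + tie))

        if self.pvalue_method is not None:
            self.pvalues_ = compute_pvalues(
                self.statistic_,
                D,
                method=self.pvalue_method,
                n_perm=self.n_perm,
                seed=self.random_state,
                s0=self.s0_,
                config=config,
                delta=self.delta_,
            )
            self.pvalues_adjusted_ = bh_adjust(self.pvalues_)
            p = (
                self.pvalues_adjusted_
                if self.selection == "bh"
                else self.pvalues_
            )
            cutoff = self.bh_cutoff if self.selection == "bh" else self.p_cutoff
            below = p[self.order_] < cutoff
            run = int(np.argmin(below)) if not below.all() else below.size
            support = np.zeros(G, dtype=bool)
            support[self.order_[:run]] = True
            self.support_ = support
        else:
            self.pvalues_ = np.full(G, np.nan)
            self.pvalues_adjusted_ = np.full(G, np.nan)
            self.support_ = np.zeros(G, dtype=bool)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def ranking_score(self) -> np.ndarray:
        """Score where larger means stronger DE evidence (negated avg rank)."""
        check_is_fitted(self, "avg_rank_")
        return -self.avg_rank_

    def results(self, gene_ids=None) -> pd.DataFrame:
        """Per-gene results table in input gene order."""
        check_is_fitted(self, "statistic_")
        G = self.statistic_.size
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(G)]
        return pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "beta_fc": self.fold_change_,
                "beta_sam": self.statistic_,
                "p_value": self.pvalues_,
                "p_adjusted": self.pvalues_adjusted_,
                "fc_rank": self.fc_rank_,
                "sam_rank": self.sam_rank_,
                "avg_rank": self.avg_rank_,
                "is_outlying_gene": self.outlying_,
                "selected": self.support_,
            }
        )

    def _more_tags(self):  # pragma: no cover - sklearn compat shim
        return {"requires_y": False, "allow_nan": False}
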