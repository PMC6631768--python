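"""Performance measures, ROC/AUC/pAUC and simple comparator baselines.

Implements the confusion-count measures used throughout the package's
simulation study (TPR, TNR, FPR, FNR, FDR, FOR, MER), ROC analysis with an
unnormalized partial AUC capped at a false-positive-rate ceiling, paired
t-test and Wilcoxon signed-rank baseline rankings, and the multi-dataset
experiment runner that averages top-N metrics across seeded replicates.

Under top-N calling with N equal to the number of true DEGs, TP+FP = TP+FN,
so precision equals recall and FDR equals FNR; the standard definitions are
implemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .detector import SAMFCDetector
from .simulation import SimulationConfig, SimulatedDataset, contaminate, generate

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "top_n_confusion",
    "compute_metrics",
    "roc_auc",
    "baseline_rankings",
    "run_experiment",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class MetricsReport:
    """Fractional measures; undefined ratios are NaN, never a silent 0."""

    tpr: float = np.nan
    tnr: float = np.nan
    fpr: float = np.nan
    fnr: float = np.nan
    fdr: float = np.nan
    for_: float = np.nan
    mer: float = np.nan
    auc: float = np.nan
    pauc: float = np.nan
    fpr_cap: float = 0.2


def top_n_confusion(ranking, truth, n_top: int) -> ConfusionCounts:
    """Call the first ``n_top`` genes of ``ranking`` DE and count outcomes.

    ``ranking`` holds gene indices ordered best first; ``truth`` is the
    boolean DE label vector.
    """
    truth = np.asarray(truth, dtype=bool)
    ranking = np.asarray(ranking, dtype=int)
    if n_top > truth.size:
        raise ValueError("n_top exceeds the number of genes")
    called = np.zeros(truth.size, dtype=bool)
    called[ranking[:n_top]] = True
    tp = int(np.sum(called & truth))
    fp = int(np.sum(called & ~truth))
    fn = int(np.sum(~called & truth))
    tn = int(np.sum(~called & ~truth))
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return np.nan
    return num / den


def compute_metrics(counts: ConfusionCounts, fpr_cap: float = 0.2) -> MetricsReport:
    """Standard confusion-matrix rates from the counts."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = tp + fp + tn + fn
    return MetricsReport(
        tpr=_ratio(tp, tp + fn, "TPR"),
        tnr=_ratio(tn, tn + fp, "TNR"),
        fpr=_ratio(fp, tn + fp, "FPR"),
        fnr=_ratio(fn, tp + fn, "FNR"),
        fdr=_ratio(fp, tp + fp, "FDR"),
        for_=_ratio(fn, tn + fn, "FOR"),
        mer=_ratio(fp + fn, total, "MER"),
        fpr_cap=fpr_cap,
    )


def roc_auc(score, truth, fpr_cap: float = 0.2):
    """ROC points, trapezoid AUC and unnormalized partial AUC.

    ``score`` must be oriented so larger means more likely DE.  The partial
    AUC integrates TPR over FPR in ``[0, fpr_cap]`` without normalization,
    so a perfect classifier attains ``pauc = fpr_cap``.
    """
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(truth, np.asarray(score, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    inside = fpr <= fpr_cap
    f = np.concatenate([fpr[inside], [fpr_cap]])
    t = np.concatenate([tpr[inside], [np.interp(fpr_cap, fpr, tpr)]])
    pauc = float(np.trapezoid(t, f))
    return np.column_stack([fpr, tpr]), auc, pauc


def _signed_rank_pvalues(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized exact two-sided one-sample Wilcoxon signed-rank test.

    Zeros are dropped (Wilcoxon's convention); the exact null is used when
    the within-gene |d| are tie-free, otherwise scipy handles that gene.
    """
    G, n = D.shape
    R = stats.rankdata(np.abs(D), axis=1)
    W = np.where(D > 0, R, 0.0).sum(axis=1)
    has_zero = (D == 0.0).any(axis=1)
    has_tie = np.array(
        [np.unique(np.abs(row)).size < n for row in D]
    )
    clean = ~(has_zero | has_tie)
    p = np.ones(G)
    if clean.any():
        pmf = np.array([1.0])
        for k in range(1, n + 1):
            nxt = np.zeros(pmf.size + k)
            nxt[: pmf.size] += pmf
            nxt[k:] += pmf
            pmf = nxt / 2.0
        cdf = np.cumsum(pmf)
        sf = 1.0 - np.concatenate([[0.0], cdf])  # P(W >= w)
        Wi = W[clean].astype(int)
        p[clean] = np.minimum(1.0, 2.0 * np.minimum(cdf[Wi], sf[Wi]))
    for g in np.nonzero(~clean)[0]:
        row = D[g][D[g] != 0.0]
        if row.size == 0:
            p[g] = 1.0
            W[g] = 0.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(row, method="auto")
        p[g] = float(res.pvalue)
    return p, W


def baseline_rankings(diffs, method: str):
    """Paired t-test or Wilcoxon signed-rank baseline.

    Parameters
    ----------
    diffs : array (n_genes, n) or list of DifferenceVector
    method : {"t_test", "wilcoxon"}

    Returns
    -------
    ranking : ndarray of gene indices, best first (smallest p, ties broken by
        larger centred statistic magnitude, then input order)
    pvalues : ndarray
    statistic : ndarray (t, or the signed-rank sum W)
    """
    if isinstance(diffs, list):
        D = np.vstack([dv.d for dv in diffs])
    else:
        D = np.asarray(diffs, dtype=float)
    G, n = D.shape
    if method == "t_test":
        sd = D.std(axis=1, ddof=1)
        with np.errstate(divide="ignore"):
            t = np.where(
                sd > 0,
                D.mean(axis=1) / np.where(sd > 0, sd / np.sqrt(n), 1.0),
                np.sign(D.mean(axis=1)) * np.inf,
            )
        p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), n - 1))
        magnitude = np.abs(t)
        stat = t
    elif method == "wilcoxon":
        p, W = _signed_rank_pvalues(D)
        magnitude = np.abs(W - n * (n + 1) / 4.0)  # distance from the null mean
        stat = W
    else:
        raise ValueError(f"unknown baseline {method!r}")
    finite_mag = np.where(np.isfinite(magnitude), magnitude, np.finfo(float).max)
    ranking = np.lexsort((np.arange(G), -finite_mag, p))
    return ranking, p, stat


def _method_ranking(
    method: str, ds: SimulatedDataset, seed: Optional[int]
) -> tuple[np.ndarray, np.ndarray]:
    """(ranking best-first, score higher-is-more-DE) for one dataset."""
    from .experiment import difference_matrix

    D = difference_matrix(ds.experiment)
    if method in ("proposed", "sam"):
        det = SAMFCDetector(
            beta=0.2 if method == "proposed" else 0.0,
            pvalue_method=None,
            random_state=seed,
        )
        det.fit_differences(D)
        return det.order_, det.ranking_score()
    ranking, p, stat = baseline_rankings(D, method)
    score = np.empty(len(p))
    score[ranking] = -np.arange(len(p), dtype=float)  # rank-based score
    return ranking, score


def run_experiment(
    config: SimulationConfig,
    n_datasets: int,
    methods: Sequence[str] = ("proposed", "sam", "t_test", "wilcoxon"),
    seed: int = 0,
    fpr_cap: float = 0.2,
    n_top: Optional[int] = None,
) -> pd.DataFrame:
    """Average top-N performance of each method over seeded replicate genomes.

    Each replicate re-generates (and, when the config asks, contaminates) a
    genome with a sub-seed derived from ``seed``, ranks genes with every
    method, calls the top N (default: the true DEG count) and averages the
    metrics.  Returns one row per method with per-metric means and
    Monte-Carlo standard errors (columns ``<metric>_se``).
    """
    rows: dict[str, list[MetricsReport]] = {m: [] for m in methods}
    child_seeds = np.random.SeedSequence(seed).generate_state(n_datasets) % (2**31)
    for r in range(n_datasets):
        cfg = replace(config, seed=int(child_seeds[r]))
        ds = generate(cfg)
        if cfg.contamination != "none":
            ds = contaminate(ds)
        N = int(ds.is_de.sum()) if n_top is None else n_top
        for m in methods:
            ranking, score = _method_ranking(m, ds, int(child_seeds[r]))
            rep = compute_metrics(top_n_confusion(ranking, ds.is_de, N), fpr_cap)
            _, auc, pauc = roc_auc(score, ds.is_de, fpr_cap)
            rows[m].append(replace(rep, auc=auc, pauc=pauc))
    out = []
    metric_names = ["tpr", "tnr", "fpr", "fnr", "fdr", "for_", "mer", "auc", "pauc"]
    for m in methods:
        rec: dict[str, object] = {"method": m}
        for name in metric_names:
            vals = np.array([getattr(rep, name) for rep in rows[m]], dtype=float)
            rec[name] = float(np.nanmean(vals))
            rec[name + "_se"] = float(
                np.nanstd(vals, ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            )
        out.append(rec)
    return pd.DataFrame(out)
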