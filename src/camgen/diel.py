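"""Diel transcriptome analysis: rhythmicity, clustering, CAM classification.

Samples cover one 24-h light/dark cycle at 3-h resolution (nine clock
times, the start time repeated at the end) with replicated FPKM values.
Rhythmicity is tested per gene by ordinary least squares of
log2(FPKM + 1) on a cubic polynomial in time against an intercept-only
null (F-test), with BH adjustment across genes. Mean profiles of
rhythmic genes are clustered hierarchically on correlation distance.
Cross-species profile correlations classify genes as conserved,
divergent, or strong CAM candidates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .expansion import bh_adjust
from .io import ExpressionMatrix

log = logging.getLogger("camgen")


def prefilter_expressed(matrix: ExpressionMatrix,
                        min_mean_fpkm: float = 1.0) -> list[str]:
    """Genes whose replicate-mean FPKM strictly exceeds the cutoff at
    >= 1 timepoint."""
    means = matrix.replicate_means()
    keep = means.max(axis=1) > min_mean_fpkm
    return [g for g, k in zip(matrix.gene_ids, keep) if k]


def _design(timepoints: np.ndarray, n_rep: int, degree: int) -> np.ndarray:
    t = np.repeat(timepoints, n_rep)
    t = (t - t.mean()) / (t.std() if t.std() > 0 else 1.0)  # conditioning
    return np.column_stack([t ** d for d in range(degree + 1)])


def fit_rhythmicity(matrix: ExpressionMatrix, degree: int = 3,
                    alpha: float = 0.05, log_transform: bool = True
                    ) -> pd.DataFrame:
    """Per-gene polynomial-regression F-test of diel expression change.

    All replicate points enter the fit. Returns a DataFrame indexed by
    gene with ``F``, ``p``, ``q`` (BH across genes), ``rhythmic``
    (q < alpha) and ``degenerate`` (zero variance, p forced to 1).
    """
    y = matrix.values
    if log_transform:
        y = np.log2(y + 1.0)
    tps = np.asarray(matrix.timepoints, dtype=float)
    X = _design(tps, matrix.n_replicates, degree)
    n_obs, k = X.shape
    if n_obs <= k:
        raise ValueError("not enough samples for the polynomial degree")
    # shared hat matrix: one pinv for every gene
    beta = np.linalg.pinv(X) @ y.T               # (k, n_genes)
    resid = y.T - X @ beta
    rss = (resid ** 2).sum(axis=0)
    tss = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df1, df2 = k - 1, n_obs - k
    degenerate = tss <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((tss - rss) / df1) / (rss / df2)
    p = np.where(degenerate, 1.0, stats.f.sf(F, df1, df2))
    p = np.where(np.isnan(p) & ~degenerate, 1.0, p)
    F = np.where(degenerate, 0.0, F)
    q = bh_adjust(p)
    return pd.DataFrame({
        "F": F, "p": p, "q": q,
        "rhythmic": q < alpha, "degenerate": degenerate,
    }, index=pd.Index(matrix.gene_ids, name="gene"))


def cluster_profiles(mean_profiles: pd.DataFrame, k: int = 9,
                     method: str = "average") -> pd.Series:
    """Hierarchical clustering of z-scored mean profiles.

    Distance is 1 - Pearson correlation between per-gene z-scored
    profiles; the tree is cut at ``k`` clusters. Rows are genes, columns
    timepoints. Gene order does not affect the partition (labels are
    renumbered by first appearance in the input order).
    """
    n = mean_profiles.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} genes")
    vals = mean_profiles.to_numpy(dtype=float)
    sd = vals.std(axis=1, keepdims=True)
    z = (vals - vals.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    corr = np.corrcoef(z)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    iu = np.triu_indices(n, 1)
    cond = np.maximum(dist[iu], 0.0)
    labels = fcluster(linkage(cond, method=method), t=k, criterion="maxclust")
    # canonical renumbering for order-invariance of the partition
    remap: dict[int, int] = {}
    out = []
    for lab in labels:
        remap.setdefault(lab, len(remap) + 1)
        out.append(remap[lab])
    return pd.Series(out, index=mean_profiles.index, name="cluster")


def diel_correlation(profile_x, profile_y) -> dict:
    """Pearson and Spearman correlation of two mean profiles.

    Zero variance in either profile makes both coefficients undefined
    (NaN) and the pair degenerate.
    """
    x = np.asarray(profile_x, dtype=float)
    y = np.asarray(profile_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must share the timepoint grid")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"pearson": float("nan"), "spearman": float("nan"),
                "degenerate": True}
    return {"pearson": float(stats.pearsonr(x, y)[0]),
            "spearman": float(stats.spearmanr(x, y)[0]),
            "degenerate": False}


def classify_cam(r_c3_pearson: float, r_c3_spearman: float,
                 r_cam_pearson: float, r_cam_spearman: float,
                 t_low: float = 0.5, t_high: float = 0.8,
                 rule: str = "both") -> str:
    """Label a gene by its diel correlation with C3 and CAM references.

    Divergent: correlation with the C3 reference below ``t_low``
    (both Pearson and Spearman under rule="both", Pearson alone under
    rule="pearson"). Strong CAM candidate: divergent AND correlation with
    the CAM reference above ``t_high`` (same coefficient rule). Otherwise
    conserved; any NaN coefficient gives "degenerate".
    """
    vals = (r_c3_pearson, r_c3_spearman, r_cam_pearson, r_cam_spearman)
    if any(np.isnan(v) for v in vals):
        return "degenerate"
    if rule == "both":
        divergent = r_c3_pearson < t_low and r_c3_spearman < t_low
        cam_high = r_cam_pearson > t_high and r_cam_spearman > t_high
    elif rule == "pearson":
        divergent = r_c3_pearson < t_low
        cam_high = r_cam_pearson > t_high
    else:
        raise ValueError("rule must be 'both' or 'pearson'")
    if divergent and cam_high:
        return "strong_CAM_candidate"
    if divergent:
        return "divergent"
    return "conserved"
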