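"""Group-specific orthogroup expansion and contraction testing.

Two species groups are compared on a gene-count matrix: a focal group A
(e.g. five succulent plants) against a background group B (e.g. thirteen
other angiosperms). Under the null that each gene of an orthogroup falls
into group A independently with probability p = |A|/(|A|+|B|), the total
group-A count S_An of an orthogroup with n genes is Binomial(n, p). The
upper tail P(X >= S_An) tests expansion in A, the lower tail P(X <= S_An)
tests contraction, both computed exactly. Calls additionally require a
minimum number of contributing species per group and a per-species
gene-rate ratio (S_An/|A|)/(S_Bn/|B|) on the correct side of 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneCountMatrix


@dataclass(frozen=True)
class GroupPartition:
    """Disjoint focal (A) / background (B) species groups."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        a, b = set(self.group_a), set(self.group_b)
        if not a or not b:
            raise ValueError("both groups must be non-empty")
        if a & b:
            raise ValueError(f"groups overlap: {sorted(a & b)}")

    @property
    def p_success(self) -> float:
        return len(self.group_a) / (len(self.group_a) + len(self.group_b))


def binomial_group_test(matrix: GeneCountMatrix,
                        partition: GroupPartition) -> pd.DataFrame:
    """Exact one-sided binomial tails per orthogroup.

    Returns a DataFrame indexed by orthogroup with columns ``S_An``,
    ``S_Bn``, ``n``, ``k_contrib_A``, ``k_contrib_B``, ``ratio``,
    ``p_expand``, ``p_contract``. Orthogroups with n = 0 across the
    partition are excluded (untestable). Species named in the partition
    but absent from the matrix raise a KeyError naming them.
    """
    ia = matrix.species_index(partition.group_a)
    ib = matrix.species_index(partition.group_b)
    counts_a = matrix.counts[:, ia]
    counts_b = matrix.counts[:, ib]
    s_an = counts_a.sum(axis=1)
    s_bn = counts_b.sum(axis=1)
    n = s_an + s_bn
    keep = n > 0
    s_an, s_bn, n = s_an[keep], s_bn[keep], n[keep]
    ids = [og for og, k in zip(matrix.orthogroup_ids, keep) if k]

    p = partition.p_success
    # exact tails via the regularized incomplete beta inside scipy.binom
    p_expand = stats.binom.sf(s_an - 1, n, p)     # P(X >= S_An)
    p_contract = stats.binom.cdf(s_an, n, p)      # P(X <= S_An)

    na, nb = len(partition.group_a), len(partition.group_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (s_an / na) / (s_bn / nb)
    ratio = np.where(s_bn == 0, np.inf, ratio)

    return pd.DataFrame({
        "S_An": s_an, "S_Bn": s_bn, "n": n,
        "k_contrib_A": (counts_a[keep] > 0).sum(axis=1),
        "k_contrib_B": (counts_b[keep] > 0).sum(axis=1),
        "ratio": ratio,
        "p_expand": np.clip(p_expand, 0.0, 1.0),
        "p_contract": np.clip(p_contract, 0.0, 1.0),
    }, index=pd.Index(ids, name="orthogroup"))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not adjustable")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_orthogroups(stats_df: pd.DataFrame,
                         q_alpha: float = 0.05,
                         min_contrib_a: int = 3,
                         min_contrib_b: int = 7) -> pd.DataFrame:
    """Apply the three-part expansion/contraction criteria.

    Expanded: q_expand < alpha AND k_contrib_A >= min_contrib_a AND
    ratio > 1 (an orthogroup absent from group B counts as ratio = +inf).
    Contracted: q_contract < alpha AND k_contrib_B >= min_contrib_b AND
    ratio < 1. BH adjustment is applied separately within each direction's
    p-value family. The two call sets are disjoint by construction.
    """
    out = stats_df.copy()
    out["q_expand"] = bh_adjust(out["p_expand"].to_numpy())
    out["q_contract"] = bh_adjust(out["p_contract"].to_numpy())
    out["expanded"] = ((out["q_expand"] < q_alpha)
                       & (out["k_contrib_A"] >= min_contrib_a)
                       & (out["ratio"] > 1))
    out["contracted"] = ((out["q_contract"] < q_alpha)
                         & (out["k_contrib_B"] >= min_contrib_b)
                         & (out["ratio"] < 1))
    return out


def two_species_expansion(matrix: GeneCountMatrix,
                          pvalues: pd.Series,
                          species: str,
                          alpha: float = 0.05) -> list[str]:
    """Simple per-species expansion rule on a multi-species matrix.

    An orthogroup is expanded in ``species`` iff its companion p-value is
    below ``alpha`` and its count in that species strictly exceeds the mean
    count across all matrix species. P-values indexed by orthogroup must
    cover every orthogroup in the matrix.
    """
    missing = [og for og in matrix.orthogroup_ids if og not in pvalues.index]
    if missing:
        raise KeyError(f"missing p-values for {len(missing)} orthogroups "
                       f"(first: {missing[0]})")
    j = matrix.species_index([species])[0]
    means = matrix.counts.mean(axis=1)
    out = []
    for i, og in enumerate(matrix.orthogroup_ids):
        if pvalues.loc[og] < alpha and matrix.counts[i, j] > means[i]:
            out.append(og)
    return out
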