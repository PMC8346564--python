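"""Group-comparison statistics for myelination data.

Distributions of percent length myelinated are heavily non-normal (many
zeros, a long tail), so the primary omnibus test is the rank-based
Kruskal–Wallis one-way ANOVA, followed by Dunn's pairwise z tests on pooled
rank means with Šidák correction for the number of comparisons in the
family.  A two-sample Kolmogorov–Smirnov test, a paired t test and one-way
ANOVA cover the remaining comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairwiseComparison",
    "DegenerateDataError",
    "kruskal_wallis",
    "dunn_sidak",
    "dunn_posthoc",
    "comparisons_to_frame",
    "ks_two_sample",
    "paired_t",
    "one_way_anova",
]


class DegenerateDataError(ValueError):
    """Data carries no variance where the test requires some."""


@dataclass(frozen=True)
class PairwiseComparison:
    """One row of a Dunn–Šidák multiple-comparison table.

    The estimate and confidence bounds are on the pooled rank-mean
    difference scale (the scale on which Dunn's z statistic lives).
    """

    sample_1: str
    sample_2: str
    ci_lower: float
    estimate: float
    ci_upper: float
    corrected_p: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction and chi-squared p (k−1 df).

    All-identical pooled data carries no rank information: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least 1 observation")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def dunn_sidak(p_raw: float, m: int) -> float:
    """Šidák correction for m comparisons: 1 − (1 − p)^m, clipped to [0, 1]."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p_raw must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, 1.0 - (1.0 - p_raw) ** m))


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[PairwiseComparison]:
    """Dunn's pairwise z tests on pooled rank means with Šidák correction.

    All observations are ranked together; for each pair of groups the rank-
    mean difference is compared against its tie-corrected standard error.
    The per-pair p value is corrected for the m = k(k−1)/2 comparisons in
    the family, and confidence bounds use the Šidák-adjusted per-comparison
    level so a bound excluding 0 agrees with corrected p < alpha.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels must be parallel to groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    split = np.cumsum([a.size for a in arrays])[:-1]
    group_ranks = np.split(ranks, split)
    mean_ranks = [float(r.mean()) for r in group_ranks]
    sizes = [a.size for a in arrays]

    tie = _tie_term(pooled)
    base_var = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    m = k * (k - 1) // 2
    # Šidák-adjusted per-comparison level for the confidence bounds
    alpha_pc = 1.0 - (1.0 - alpha) ** (1.0 / m)
    zcrit = sps.norm.ppf(1.0 - alpha_pc / 2.0)

    out: list[PairwiseComparison] = []
    for i, j in combinations(range(k), 2):
        diff = mean_ranks[i] - mean_ranks[j]
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            p_raw = 1.0
            half = 0.0
        else:
            z = diff / se
            p_raw = 2.0 * (1.0 - sps.norm.cdf(abs(z)))
            half = zcrit * se
        out.append(
            PairwiseComparison(
                sample_1=labels[i],
                sample_2=labels[j],
                ci_lower=diff - half,
                estimate=diff,
                ci_upper=diff + half,
                corrected_p=dunn_sidak(min(1.0, p_raw), m),
            )
        )
    return out


def comparisons_to_frame(comparisons: Sequence[PairwiseComparison]) -> pd.DataFrame:
    """Tabulate comparisons with the standard multiple-comparison columns."""
    return pd.DataFrame(
        {
            "sample_1": [c.sample_1 for c in comparisons],
            "sample_2": [c.sample_2 for c in comparisons],
            "ci_lower_95": [c.ci_lower for c in comparisons],
            "estimate": [c.estimate for c in comparisons],
            "ci_upper_95": [c.ci_upper for c in comparisons],
            "corrected_p": [c.corrected_p for c in comparisons],
        }
    )


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test (asymptotic p value)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def paired_t(
    a: Sequence[float], b: Sequence[float], two_tailed: bool = True
) -> tuple[float, float]:
    """Paired t test on the differences a − b.

    Identical samples return (0, 1) by convention; non-zero constant
    differences have zero variance and no defined t statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("samples must have equal length >= 2")
    diffs = a - b
    if np.all(diffs == 0):
        return 0.0, 1.0
    if np.var(diffs, ddof=1) == 0:
        raise DegenerateDataError("differences have zero variance")
    res = sps.ttest_rel(a, b, alternative="two-sided" if two_tailed else "greater")
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Ordinary one-way ANOVA F test across groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    res = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)
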