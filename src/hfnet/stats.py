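"""Two-group comparisons and correlations for network centrality analyses.

Wraps the classical tests used to relate biomarker status to network
position: Student/Welch two-sample t tests, Pearson and Spearman
correlation, and the biomarkers-vs-rest contrast on degree and traffic.
All P values are two-sided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "two_sample_t",
    "pearson",
    "spearman",
    "biomarker_centrality_contrast",
]


@dataclass(frozen=True)
class StatResult:
    statistic: str  # "t", "r_pearson" or "r_spearman"
    value: float
    p: float
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p out of range: {self.p}")


def two_sample_t(
    x: Sequence[float], y: Sequence[float], variance_rule: str = "pooled"
) -> StatResult:
    """Two-sample t test; positive t means mean(x) > mean(y).

    ``pooled`` is the classical Student test (equal variances assumed),
    ``welch`` drops that assumption. Two identical constant samples give
    t = 0, p = 1 with a warning rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if variance_rule not in ("pooled", "welch"):
        raise ValueError(f"unknown variance rule: {variance_rule!r}")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            logger.warning("both samples constant and equal: t = 0, p = 1")
            return StatResult("t", 0.0, 1.0, (len(x), len(y)))
        return StatResult("t", np.inf if x.mean() > y.mean() else -np.inf, 0.0,
                          (len(x), len(y)))
    res = sps.ttest_ind(x, y, equal_var=(variance_rule == "pooled"))
    return StatResult("t", float(res.statistic), float(res.pvalue), (len(x), len(y)))


def pearson(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Product-moment correlation with two-sided P (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    if len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance sample")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = sps.pearsonr(x, y)
    return StatResult("r_pearson", float(r), float(p), (len(x),))


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson correlation on mid-ranks (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    if len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    r, p = sps.spearmanr(x, y)
    return StatResult("r_spearman", float(r), float(p), (len(x),))


def biomarker_centrality_contrast(
    centrality: pd.DataFrame, biomarkers: Iterable[str], variance_rule: str = "pooled"
) -> tuple[StatResult, StatResult]:
    """Biomarkers vs all other nodes on degree and on traffic.

    Sign convention: positive t means the biomarker group has the larger
    mean. Requires at least 2 biomarkers and 2 non-biomarkers present in
    the centrality table.
    """
    marks = frozenset(biomarkers)
    present = marks & set(centrality.index)
    if not present:
        raise ValueError("biomarker set disjoint from the network")
    rest = set(centrality.index) - present
    if len(present) < 2 or len(rest) < 2:
        raise ValueError("need >= 2 nodes in both biomarker and non-biomarker groups")
    bio = centrality.loc[sorted(present)]
    other = centrality.loc[sorted(rest)]
    t_degree = two_sample_t(bio["degree"], other["degree"], variance_rule)
    t_traffic = two_sample_t(bio["traffic"], other["traffic"], variance_rule)
    return t_degree, t_traffic
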