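"""Rank aggregation across evidence sources by order statistics.

Each evidence source (annotation similarity, sequence similarity,
co-expression, ...) supplies a ranked candidate list. A gene's rank in a
source is converted to a rank ratio r = rank / (genes ranked by that
source), and the ratios are combined into a single score

    RS = P( U(1) <= r(1), ..., U(N) <= r(N) )

— the probability that N independent uniforms on (0,1) have each order
statistic below the corresponding sorted observed ratio. Small RS means
the gene sits improbably high across sources. RS is computed exactly by
the alternating recursion

    V_0 = 1,   V_k = sum_{i=1..k} (-1)^(i-1) V_{k-i} r_(N-k+1)^i / i!
    RS = N! * V_N

with ratios sorted ascending, which for N = 1 reduces to RS = r. The
omnibus combination of independent P values (X = -2 sum ln p against a
chi-square with 2N df) is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.stats import chi2

__all__ = [
    "SourceRanking",
    "order_statistic_score",
    "fisher_omnibus",
    "combine_rankings",
    "load_source_ranking",
]


@dataclass(frozen=True)
class SourceRanking:
    """One source's ranked genes with rank ratios in (0, 1]."""

    source: str
    ratios: dict[str, float]  # gene -> rank / n_ranked

    @classmethod
    def from_ranked_genes(cls, source: str, genes: Sequence[str]) -> "SourceRanking":
        n = len(genes)
        if n == 0:
            raise ValueError("empty ranking")
        if len(set(genes)) != n:
            raise ValueError("duplicate genes in ranking")
        return cls(source, {g: (i + 1) / n for i, g in enumerate(genes)})

    @classmethod
    def from_scores(cls, source: str, scores: dict[str, float]) -> "SourceRanking":
        """Scores are converted to ranks descending (high score = rank 1)."""
        ordered = sorted(scores, key=lambda g: (-scores[g], g))
        return cls.from_ranked_genes(source, ordered)


def order_statistic_score(rank_ratios: Sequence[float]) -> float:
    """Joint order-statistic probability for the observed rank ratios."""
    n = len(rank_ratios)
    if n == 0:
        raise ValueError("need at least one rank ratio")
    if any(r <= 0 or r > 1 for r in rank_ratios):
        raise ValueError("rank ratios must lie in (0, 1]")
    r = sorted(rank_ratios)
    v = [1.0] + [0.0] * n
    for k in range(1, n + 1):
        s = 0.0
        x = r[n - k]
        for i in range(1, k + 1):
            s += (-1) ** (i - 1) * v[k - i] * x**i / math.factorial(i)
        v[k] = s
    rs = math.factorial(n) * v[n]
    # exact arithmetic guarantees rs in [0,1]; clamp float round-off only
    return min(max(rs, 0.0), 1.0)


def fisher_omnibus(p_values: Sequence[float]) -> tuple[float, float]:
    """Combine independent P values: X = -2 sum ln p vs chi-square(2N).

    Returns (statistic, combined P). For N = 1 the combined P equals the
    input. p = 0 is rejected (floor upstream if needed).
    """
    if len(p_values) == 0:
        raise ValueError("need at least one p value")
    if any(p <= 0 or p > 1 for p in p_values):
        raise ValueError("p values must lie in (0, 1]; floor zeros upstream")
    x = -2.0 * sum(math.log(p) for p in p_values)
    return x, float(chi2.sf(x, df=2 * len(p_values)))


def combine_rankings(
    rankings: Sequence[SourceRanking], top_n: int = 100
) -> pd.DataFrame:
    """Combined candidate ranking over all sources.

    Genes missing from a source get the worst-case ratio 1. Output is
    sorted ascending by RS (ties: lexicographic by gene), truncated to
    ``top_n`` rows, with one ratio column per source.
    """
    if not rankings:
        raise ValueError("no source rankings given")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    genes = sorted(set().union(*(r.ratios for r in rankings)))
    rows = []
    for g in genes:
        ratios = [r.ratios.get(g, 1.0) for r in rankings]
        row = {"gene": g, "rs": order_statistic_score(ratios)}
        row.update({f"ratio_{r.source}": x for r, x in zip(rankings, ratios)})
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(["rs", "gene"], kind="mergesort")
    df = df.head(top_n).reset_index(drop=True)
    df.insert(1, "rank", range(1, len(df) + 1))
    return df


def load_source_ranking(path: str | Path, source: str | None = None) -> SourceRanking:
    """TSV of (gene, rank-or-score). Integer second column = explicit ranks;
    otherwise values are treated as scores and ranked descending."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "value"], comment="#")
    name = source or path.stem
    values = dict(zip(df["gene"].astype(str).str.strip().str.upper(), df["value"].astype(float)))
    if all(float(v).is_integer() for v in values.values()):
        ordered = sorted(values, key=lambda g: (values[g], g))
        return SourceRanking.from_ranked_genes(name, ordered)
    return SourceRanking.from_scores(name, values)
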