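"""Degree statistics, power-law exponent fitting and traffic (betweenness).

"Traffic" follows the bottleneck literature: the betweenness centrality of
a node x is its share of shortest paths between all other node pairs —
counted over unordered pairs, endpoints excluded, with fractional
allocation across equally short paths. Hubs are high-degree nodes;
high-traffic nodes are communication bottlenecks. The degree distribution
D(k) of disease interactomes is typically heavy-tailed, D(k) ~ k^-gamma,
and gamma is estimated here as minus the slope of the ordinary
least-squares line through (ln k, ln D(k)).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DegreeDistribution",
    "PowerLawFit",
    "degree_distribution",
    "fit_power_law",
    "traffic",
    "top_k",
    "write_centrality_table",
]


@dataclass(frozen=True)
class DegreeDistribution:
    """Observed frequency D(k) of each degree k >= 1; isolated nodes counted apart."""

    k: np.ndarray
    freq: np.ndarray
    n_isolated: int = 0

    def __post_init__(self) -> None:
        if np.any(self.k < 1):
            raise ValueError("degree values must be >= 1 (isolated nodes tracked separately)")


@dataclass(frozen=True)
class PowerLawFit:
    gamma: float
    intercept: float
    fit_quality: float  # squared correlation of the ln-ln regression
    n_points: int


def degree_distribution(network: nx.Graph) -> DegreeDistribution:
    """Exact histogram of node degrees >= 1."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    degs = [d for _, d in network.degree()]
    n_isolated = sum(1 for d in degs if d == 0)
    counts = Counter(d for d in degs if d >= 1)
    k = np.array(sorted(counts))
    freq = np.array([counts[i] for i in k])
    return DegreeDistribution(k=k, freq=freq, n_isolated=n_isolated)


def fit_power_law(dist: DegreeDistribution) -> PowerLawFit:
    """OLS line through (ln k, ln D(k)); gamma = -slope.

    Requires at least 3 distinct degree values with positive frequency.
    fit_quality is the squared Pearson correlation of the transformed
    points (1.0 for an exact power law, 0 for a flat histogram).
    """
    mask = dist.freq > 0
    k, freq = dist.k[mask], dist.freq[mask]
    if len(k) < 3:
        raise ValueError(f"power-law fit needs >=3 degree values, got {len(k)}")
    x, y = np.log(k.astype(float)), np.log(freq.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    if np.allclose(y, y[0]):
        quality = 1.0 if np.allclose(slope, 0) else 0.0
    else:
        quality = float(np.corrcoef(x, y)[0, 1] ** 2)
    return PowerLawFit(gamma=float(-slope), intercept=float(intercept),
                       fit_quality=quality, n_points=int(len(k)))


def traffic(network: nx.Graph, scale: float = 1.0) -> pd.DataFrame:
    """Per-node degree and traffic (betweenness centrality).

    Betweenness over unordered node pairs with endpoints excluded and
    fractional split across tied shortest paths. Disconnected inputs are
    allowed; paths exist only within components. ``scale`` multiplies the
    raw counts (published tables sometimes use an unspecified scaling).

    Returns a DataFrame indexed by symbol with columns ``degree`` and
    ``traffic``, sorted by symbol for deterministic output.
    """
    bc = nx.betweenness_centrality(network, normalized=False)
    df = pd.DataFrame(
        {
            "degree": [network.degree(n) for n in network.nodes],
            "traffic": [bc[n] * scale for n in network.nodes],
        },
        index=pd.Index(network.nodes, name="symbol"),
    )
    return df.sort_index()


def top_k(table: pd.DataFrame, metric: str, k: int) -> pd.DataFrame:
    """Top-k rows by ``metric`` (descending), ties broken by symbol.

    k larger than the table truncates (with no error) — the full ranking
    is returned.
    """
    if metric not in table.columns:
        raise KeyError(metric)
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = (table.reset_index()
              .sort_values([metric, "symbol"], ascending=[False, True], kind="mergesort")
              .set_index("symbol"))
    return ranked.head(min(k, len(ranked)))


def write_centrality_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
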