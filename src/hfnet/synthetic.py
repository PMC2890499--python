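"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis is exercisable offline: planted-partition
networks whose designated "biomarker" nodes are boosted into hubs and
bottlenecks, configuration-model graphs with power-law degrees, term maps
aligned to planted modules, per-source candidate rankings with a planted
top gene, and two-class expression matrices with planted differentially
expressed genes. All generators are pure functions of their parameters
plus an integer seed (one seeded generator per call, no global state).

Default parameter values mirror the study conditions the pipeline
emulates: a 16 + 16 two-class expression design, and module-recovery
networks of 4 planted modules x 15 nodes at p_in = 0.4, p_out = 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .classify import ExpressionMatrix
from .enrichment import TermMap
from .modules import ModulePartition
from .prioritize import SourceRanking

import pandas as pd

__all__ = [
    "SyntheticNetworkSpec",
    "SyntheticExpressionSpec",
    "planted_partition_network",
    "powerlaw_network",
    "module_aligned_term_map",
    "two_class_expression",
    "per_source_rankings",
]


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Planted-partition network with biomarker hub boosting.

    ``biomarker_degree_boost`` is the number of extra cross-module edges
    attached to each designated biomarker node (drawn uniformly over the
    other modules), which makes biomarkers both hubs and shortest-path
    bottlenecks.
    """

    module_sizes: tuple[int, ...] = (15, 15, 15, 15)
    p_in: float = 0.4
    p_out: float = 0.02
    n_biomarkers: int = 8
    biomarker_degree_boost: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        if self.n_biomarkers > sum(self.module_sizes):
            raise ValueError("more biomarkers than nodes")


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Two-class Gaussian expression design with planted effect sizes.

    ``de_genes`` maps gene index -> effect size (shift of the first
    class, in units of the unit within-class standard deviation).
    """

    n_genes: int = 200
    n_per_class: tuple[int, int] = (16, 16)
    de_genes: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_class) < 2:
            raise ValueError("need >= 2 samples per class")
        if any(not np.isfinite(d) for d in self.de_genes.values()):
            raise ValueError("effect sizes must be finite")


def _node_name(i: int) -> str:
    return f"G{i:04d}"


def planted_partition_network(
    spec: SyntheticNetworkSpec,
) -> tuple[nx.Graph, ModulePartition, frozenset[str]]:
    """Draw a planted-partition graph and boost biomarker connectivity.

    Returns (network, ground-truth partition, biomarker set). Biomarkers
    are spread round-robin across modules so the boost creates
    inter-module bottlenecks rather than one dense region. Edges carry a
    ``sources`` attribute ("sim") so the graph round-trips through the
    assembly writers.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = spec.module_sizes
    n = sum(sizes)
    names = [_node_name(i) for i in range(n)]
    module_of = {}
    start = 0
    blocks: list[list[str]] = []
    for m, size in enumerate(sizes, start=1):
        block = names[start:start + size]
        blocks.append(block)
        for v in block:
            module_of[v] = m
        start += size
    g = nx.Graph()
    g.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            p = spec.p_in if module_of[names[i]] == module_of[names[j]] else spec.p_out
            if rng.random() < p:
                g.add_edge(names[i], names[j], sources=frozenset({"sim"}))
    # round-robin biomarker designation across modules
    biomarkers = []
    idx = [0] * len(blocks)
    b = 0
    while len(biomarkers) < spec.n_biomarkers:
        block = blocks[b % len(blocks)]
        if idx[b % len(blocks)] < len(block):
            biomarkers.append(block[idx[b % len(blocks)]])
            idx[b % len(blocks)] += 1
        b += 1
    for v in biomarkers:
        others = [u for u in names if module_of[u] != module_of[v] and not g.has_edge(u, v)]
        k = min(spec.biomarker_degree_boost, len(others))
        for u in rng.choice(others, size=k, replace=False):
            g.add_edge(v, str(u), sources=frozenset({"sim"}))
    partition = ModulePartition(dict(module_of), q=float("nan"))
    return g, partition, frozenset(biomarkers)


def powerlaw_network(
    n: int, target_gamma: float, seed: int, kmax: int | None = None, max_tries: int = 50
) -> nx.Graph:
    """Configuration-model graph from a truncated power-law degree sequence.

    Degrees are drawn from P(k) proportional to k^-gamma on 1..kmax; the
    default truncation kmax = round(n^(1/gamma)) is where the expected
    count of a degree value falls to order one, which keeps the sparse
    tail from flattening a frequency-based ln-ln fit. Multi-edges and
    self-loops from the pairing are discarded, leaving a simple graph.
    """
    if target_gamma <= 1:
        raise ValueError("target_gamma must exceed 1")
    if n < 100:
        raise ValueError("need n >= 100")
    if kmax is None:
        kmax = max(10, round(n ** (1.0 / target_gamma)))
    rng = np.random.default_rng(seed)
    ks = np.arange(1, kmax + 1)
    p = ks.astype(float) ** (-target_gamma)
    p /= p.sum()
    for _ in range(max_tries):
        seq = rng.choice(ks, size=n, p=p)
        if seq.sum() % 2 == 1:
            continue
        multi = nx.configuration_model(seq, seed=int(rng.integers(2**31)))
        g = nx.Graph()
        g.add_nodes_from(_node_name(i) for i in range(n))
        for u, v in multi.edges():
            if u != v:
                g.add_edge(_node_name(u), _node_name(v), sources=frozenset({"sim"}))
        return g
    raise RuntimeError("could not realize an even-sum degree sequence")


def module_aligned_term_map(
    partition: ModulePartition,
    purity: float = 0.8,
    n_noise_terms: int = 0,
    seed: int = 0,
    category: str = "BP",
) -> TermMap:
    """One signature term per module plus uniform noise terms.

    A module's signature term contains a ``purity`` fraction of its
    members plus an equal number of random genes from other modules.
    Noise terms are uniform random subsets of all genes (size drawn
    between 5 and 20), carrying no module signal.
    """
    if not (0 < purity <= 1):
        raise ValueError("purity must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    mem = partition.members()
    all_genes = sorted(partition.assignment)
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    for m in sorted(mem):
        members = mem[m]
        k = max(1, round(purity * len(members)))
        inside = list(rng.choice(members, size=k, replace=False))
        outside_pool = [g for g in all_genes if partition.assignment[g] != m]
        n_out = 0 if purity >= 1 else min(len(outside_pool), max(0, round((1 - purity) * k)))
        outside = list(rng.choice(outside_pool, size=n_out, replace=False)) if n_out else []
        terms[f"SIG_M{m}"] = (f"signature of module {m}", category,
                              frozenset(map(str, inside + outside)))
    for t in range(n_noise_terms):
        size = int(rng.integers(5, 21))
        genes = frozenset(map(str, rng.choice(all_genes, size=min(size, len(all_genes)),
                                              replace=False)))
        terms[f"NOISE_{t:03d}"] = (f"noise term {t}", category, genes)
    return TermMap(terms)


def two_class_expression(spec: SyntheticExpressionSpec) -> ExpressionMatrix:
    """Unit-variance Gaussian matrix with planted class-mean shifts.

    Class "HF" (the first ``n_per_class`` samples) is shifted by the
    per-gene effect size; class "nonHF" stays at baseline.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_per_class
    genes = [f"GENE{i:04d}" for i in range(spec.n_genes)]
    samples = [f"S{i:03d}" for i in range(n1 + n2)]
    values = rng.normal(size=(spec.n_genes, n1 + n2))
    for gi, delta in spec.de_genes.items():
        values[gi, :n1] += delta
    labels = {s: ("HF" if i < n1 else "nonHF") for i, s in enumerate(samples)}
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(values=df, labels=labels)


def per_source_rankings(
    n_genes: int, n_sources: int, planted_gene: str | None = None, seed: int = 0
) -> list[SourceRanking]:
    """Random permutation rankings; the planted gene is forced into the
    top decile of every source."""
    if n_sources < 1:
        raise ValueError("need >= 1 source")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    if planted_gene is None:
        planted_gene = genes[0]
    if planted_gene not in genes:
        genes = [planted_gene] + genes[:-1]
    rankings = []
    decile = max(1, n_genes // 10)
    for s in range(n_sources):
        order = list(rng.permutation(genes))
        order.remove(planted_gene)
        pos = int(rng.integers(0, decile))
        order.insert(pos, planted_gene)
        rankings.append(SourceRanking.from_ranked_genes(f"source{s}", order))
    return rankings
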