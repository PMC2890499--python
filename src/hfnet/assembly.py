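"""Assembly of a seed-centered protein-interaction network.

Interaction tables exported from curated repositories (HPRD/BioGRID/MINT
style) are merged into one simple undirected graph, restricted to a set of
seed proteins (known disease biomarkers plus prioritized candidates) and
their first-level interaction partners, and finally decomposed into the
largest connected component (the "core network") and smaller "islands".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Interaction",
    "SeedSet",
    "ComponentDecomposition",
    "normalize_symbol",
    "load_interaction_table",
    "load_seed_list",
    "merge_union",
    "seed_subnetwork",
    "decompose_components",
    "write_edge_list",
    "write_components_report",
]


def normalize_symbol(symbol: str, aliases: dict[str, str] | None = None) -> str:
    """Canonical gene/protein symbol: stripped, uppercased, optionally aliased.

    Idempotent: ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``
    (alias targets are themselves normalized before lookup stops).
    """
    s = symbol.strip().upper()
    if aliases:
        s = aliases.get(s, s)
        s = s.strip().upper()
    return s


@dataclass(frozen=True)
class Interaction:
    """An unordered protein pair with database provenance."""

    a: str
    b: str
    sources: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.a or not self.b:
            raise ValueError("interaction endpoints must be non-empty symbols")
        if self.a == self.b:
            raise ValueError(f"self-interaction not allowed: {self.a}")
        # canonical endpoint order so (a,b) == (b,a)
        if self.a > self.b:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


@dataclass(frozen=True)
class SeedSet:
    """Known biomarkers plus candidate genes; seeds are their union."""

    biomarkers: frozenset[str]
    candidates: frozenset[str]

    @property
    def seeds(self) -> frozenset[str]:
        return self.biomarkers | self.candidates

    @classmethod
    def from_iterables(
        cls, biomarkers: Iterable[str], candidates: Iterable[str] = ()
    ) -> "SeedSet":
        return cls(
            frozenset(normalize_symbol(s) for s in biomarkers),
            frozenset(normalize_symbol(s) for s in candidates),
        )


@dataclass
class ComponentDecomposition:
    """Connected components of a network: core, islands and singletons.

    The core is the component with the most nodes; ties broken by edge
    count, then by lexicographically smallest member. Islands are the
    remaining components with at least 2 nodes, sorted by the same key
    descending. Isolated nodes are recorded separately.
    """

    core: nx.Graph
    islands: list[nx.Graph] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)


class InteractionTableError(ValueError):
    """Malformed interaction table row."""


def _looks_like_header(fields: Sequence[str]) -> bool:
    lowered = [f.strip().lower() for f in fields[:2]]
    header_words = {"protein", "gene", "symbol", "interactor", "interactor_a",
                    "interactor_b", "protein_a", "protein_b", "source",
                    "node1", "node2"}
    return any(w in header_words for w in lowered)


def load_interaction_table(
    path: str | Path,
    normalizer=normalize_symbol,
    default_source: str | None = None,
) -> list[Interaction]:
    """Read a tab-separated edge list (colA, colB, [source]).

    An optional header row is detected by non-identifier-looking first
    fields. Self-pairs are dropped and logged; rows with fewer than two
    fields or empty symbols raise :class:`InteractionTableError` naming
    the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if default_source is None:
        default_source = path.stem
    interactions: list[Interaction] = []
    n_self = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InteractionTableError(
                    f"{path}:{lineno}: expected >=2 tab-separated columns"
                )
            if lineno == 1 and _looks_like_header(fields):
                continue
            a, b = normalizer(fields[0]), normalizer(fields[1])
            if not a or not b:
                raise InteractionTableError(f"{path}:{lineno}: empty symbol")
            source = fields[2].strip() if len(fields) > 2 and fields[2].strip() else default_source
            if a == b:
                n_self += 1
                logger.info("%s:%d: dropped self-pair %s", path, lineno, a)
                continue
            interactions.append(Interaction(a, b, frozenset({source})))
    if n_self:
        logger.warning("%s: dropped %d self-pair(s)", path, n_self)
    return interactions


def load_seed_list(path: str | Path, normalizer=normalize_symbol) -> frozenset[str]:
    """One symbol per line; blank lines and ``#`` comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(normalizer(line))
    return frozenset(out)


def merge_union(tables: Sequence[Sequence[Interaction]]) -> nx.Graph:
    """Union of interaction tables as one simple graph.

    Duplicate unordered pairs collapse into a single edge whose
    ``sources`` attribute is the union of the provenance labels.
    Idempotent: merging a table with itself equals merging it once.
    """
    if not tables:
        raise ValueError("merge_union requires at least one table")
    g = nx.Graph()
    for table in tables:
        for it in table:
            if g.has_edge(it.a, it.b):
                g[it.a][it.b]["sources"] = g[it.a][it.b]["sources"] | it.sources
            else:
                g.add_edge(it.a, it.b, sources=frozenset(it.sources))
    if g.number_of_edges() == 0:
        raise ValueError("union of interaction tables is empty")
    return g


def seed_subnetwork(
    network: nx.Graph,
    seeds: SeedSet | Iterable[str],
    mode: Literal["induced", "seed-incident"] = "induced",
) -> nx.Graph:
    """Subnetwork of the seeds and their first-level interaction partners.

    ``induced`` keeps every edge among seeds and their neighbors;
    ``seed-incident`` keeps only edges touching at least one seed (the
    seed-incident edge set is always a subset of the induced one).
    Seeds absent from the network are logged, not fatal; it is an error
    if none is present.
    """
    seed_nodes = seeds.seeds if isinstance(seeds, SeedSet) else frozenset(seeds)
    if not seed_nodes:
        raise ValueError("empty seed set")
    present = seed_nodes & set(network.nodes)
    missing = seed_nodes - present
    if missing:
        logger.warning("%d seed(s) absent from network: %s", len(missing),
                       ", ".join(sorted(missing)[:10]))
    if not present:
        raise ValueError("no seed protein present in the network")
    nodes = set(present)
    for s in present:
        nodes.update(network.neighbors(s))
    if mode == "induced":
        sub = network.subgraph(nodes).copy()
    elif mode == "seed-incident":
        sub = nx.Graph()
        sub.add_nodes_from((n, network.nodes[n]) for n in nodes)
        for s in present:
            for nbr in network.neighbors(s):
                sub.add_edge(s, nbr, **network[s][nbr])
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    isolated = [n for n in sub.nodes if sub.degree(n) == 0]
    if isolated:
        logger.warning("seed(s) with no partner kept as isolated nodes: %s",
                       ", ".join(sorted(isolated)))
    return sub


def _component_key(network: nx.Graph, comp: frozenset[str]) -> tuple:
    # most nodes first, then most edges, then lexicographically smallest member
    return (-len(comp), -network.subgraph(comp).number_of_edges(), min(comp))


def decompose_components(network: nx.Graph) -> ComponentDecomposition:
    """Split a network into core (largest component), islands and singletons."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = [frozenset(c) for c in nx.connected_components(network)]
    comps.sort(key=lambda c: _component_key(network, c))
    core = network.subgraph(comps[0]).copy()
    islands = [network.subgraph(c).copy() for c in comps[1:] if len(c) >= 2]
    singletons = sorted(n for c in comps[1:] if len(c) == 1 for n in c)
    if singletons:
        logger.info("%d isolated node(s) excluded from islands", len(singletons))
    return ComponentDecomposition(core=core, islands=islands, singletons=singletons)


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Canonical TSV edge list: sorted endpoints, sorted rows, comma-joined sources."""
    rows = []
    for a, b, data in network.edges(data=True):
        a, b = sorted((a, b))
        rows.append((a, b, ",".join(sorted(data.get("sources", ())))))
    rows.sort()
    with Path(path).open("w") as fh:
        for r in rows:
            fh.write("\t".join(r) + "\n")


def write_components_report(decomp: ComponentDecomposition, path: str | Path) -> None:
    comps = [("core", decomp.core)] + [
        (f"island_{i}", g) for i, g in enumerate(decomp.islands, start=1)
    ]
    with Path(path).open("w") as fh:
        fh.write("component\tn_nodes\tn_edges\tmembers\n")
        for name, g in comps:
            fh.write(f"{name}\t{g.number_of_nodes()}\t{g.number_of_edges()}\t"
                     + ",".join(sorted(g.nodes)) + "\n")
        for s in decomp.singletons:
            fh.write(f"singleton\t1\t0\t{s}\n")
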