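"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (exhaustive enumeration, direct
formulas) and shares no code with the package under test.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def brute_force_betweenness(edges: list[tuple], nodes: list) -> dict:
    """Betweenness by explicit enumeration of ALL shortest paths per pair.

    Unordered pairs, endpoints excluded, fractional credit 1/(number of
    tied shortest paths) to every interior vertex of every tied path.
    """
    adj: dict = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    bc = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        w = 1.0 / len(paths)
        for p in paths:
            for v in p[1:-1]:
                bc[v] += w
    return bc


def _all_shortest_paths(adj: dict, s, t) -> list[list]:
    # BFS distances from s, then DFS back-tracking along decreasing levels
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    if t not in dist:
        return []
    paths: list[list] = []

    def backtrack(v, path):
        if v == s:
            paths.append([s] + path)
            return
        for u in adj[v]:
            if u in dist and dist[u] == dist[v] - 1:
                backtrack(u, [v] + path)

    backtrack(t, [])
    return paths


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def modularity_direct(edges: list[tuple], blocks: list[list]) -> float:
    """Q from its definition, per-module, with explicit degree sums."""
    num_e = len(edges)
    deg: dict = {}
    for a, b in edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    q = 0.0
    for block in blocks:
        bs = set(block)
        l_c = sum(1 for a, b in edges if a in bs and b in bs)
        d_c = sum(deg.get(n, 0) for n in bs)
        q += l_c / num_e - (d_c / (2.0 * num_e)) ** 2
    return q


def fisher_two_tailed_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher P by integer-exact enumeration over all tables
    with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    observed = math.comb(r1, a) * math.comb(r2, c)
    # sum of P(table) over tables no more probable than the observed one
    total = sum(w for w in weights if w <= observed)
    return total / denom


def bh_step_up(p: list[float]) -> list[float]:
    """BH adjusted values by the textbook step-up formula, input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, m * p[i] / rank))
        adj[i] = running
    return adj


def spearman_midrank(x: list[float], y: list[float]) -> float:
    """Spearman r as Pearson on mid-ranks, everything written out."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def pearson_textbook(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def count_components_union_find(nodes: list, edges: list[tuple]) -> int:
    parent = {n: n for n in nodes}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(n) for n in nodes})
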