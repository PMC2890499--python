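"""Term overrepresentation for network modules.

Each module is tested against flat gene sets (GO biological process and
cellular component terms, transcription-factor target sets, miRNA target
sets) with a two-tailed Fisher exact test on the 2x2 table

                      in term   not in term
        in module        a          b
        out of module    c          d

over a configurable background universe (default: the core-network gene
set). P values are Benjamini-Hochberg adjusted within each
(module, category) family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from statsmodels.stats.multitest import multipletests

from .modules import ModulePartition

logger = logging.getLogger(__name__)

__all__ = [
    "TermMap",
    "load_gene_sets",
    "write_gene_sets",
    "fisher_two_tailed",
    "bh_adjust",
    "enrich_modules",
]

CATEGORIES = ("BP", "CC", "TF", "miRNA")


@dataclass
class TermMap:
    """Flat gene-set collection: term id -> (name, category, genes)."""

    terms: dict[str, tuple[str, str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.terms)

    def genes(self, term: str) -> frozenset[str]:
        return self.terms[term][2]

    def by_category(self, category: str) -> dict[str, frozenset[str]]:
        return {t: g for t, (_, c, g) in self.terms.items() if c == category}

    @property
    def categories(self) -> list[str]:
        return sorted({c for _, c, _ in self.terms.values()})


def load_gene_sets(path: str | Path, category: str = "BP") -> TermMap:
    """Read a GMT file: term, description, then member genes, tab-separated.

    Duplicate term ids are merged (set union) with a warning. Lines with
    fewer than 3 fields are an error naming the line.
    """
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields")
            term, desc = fields[0].strip(), fields[1].strip()
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no genes")
            if term in terms:
                logger.warning("%s:%d: duplicate term %r merged", path, lineno, term)
                prev = terms[term]
                terms[term] = (prev[0], prev[1], prev[2] | genes)
            else:
                terms[term] = (desc, category, genes)
    return TermMap(terms)


def write_gene_sets(term_map: TermMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term in sorted(term_map.terms):
            desc, _, genes = term_map.terms[term]
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact P for a 2x2 table.

    Sum of probabilities, with margins fixed, of every table whose point
    hypergeometric probability is <= that of the observed one. Degenerate
    tables (a zero margin) give P = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided").pvalue)


def bh_adjust(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted P values, in input order."""
    p = list(p_values)
    if not p:
        return []
    if any(x < 0 or x > 1 for x in p):
        raise ValueError("p values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich_modules(
    partition: ModulePartition | Mapping[str, int],
    term_map: TermMap,
    background: Iterable[str],
    alpha: float = 0.05,
    family: str = "per-module-category",
) -> pd.DataFrame:
    """Fisher-exact overrepresentation of every term in every module.

    Only (module, term) pairs with at least one annotated module gene
    (a > 0) are reported, and BH adjustment runs within each
    (module, category) family by default (``family="global"`` pools all
    records into one family). A record is ``significant`` when
    p_adj <= alpha.
    """
    assignment = partition.assignment if isinstance(partition, ModulePartition) else dict(partition)
    bg = frozenset(g for g in background)
    if not bg:
        raise ValueError("empty background universe")
    outside = set(assignment) - bg
    if outside:
        raise ValueError(
            f"background must contain all module genes; missing {sorted(outside)[:5]}"
        )
    modules: dict[int, frozenset[str]] = {}
    for gene, mod in assignment.items():
        modules.setdefault(mod, set()).add(gene)  # type: ignore[arg-type]
    modules = {m: frozenset(g) for m, g in modules.items()}

    rows = []
    for m in sorted(modules):
        mod_genes = modules[m] & bg
        annotated_any = False
        for term in sorted(term_map.terms):
            name, category, genes = term_map.terms[term]
            term_genes = genes & bg
            a = len(mod_genes & term_genes)
            if a == 0:
                continue
            annotated_any = True
            b = len(mod_genes) - a
            c = len(term_genes) - a
            d = len(bg) - a - b - c
            rows.append(
                {"module": m, "category": category, "term": term, "name": name,
                 "a": a, "b": b, "c": c, "d": d,
                 "p_raw": fisher_two_tailed(a, b, c, d)}
            )
        if not annotated_any:
            logger.info("module %d has no annotated genes; no records", m)
    if not rows:
        return pd.DataFrame(
            columns=["module", "category", "term", "name", "a", "b", "c", "d",
                     "p_raw", "p_adj", "significant"]
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = 1.0
    if family == "global":
        df["p_adj"] = bh_adjust(df["p_raw"])
    else:
        for _, idx in df.groupby(["module", "category"]).groups.items():
            df.loc[idx, "p_adj"] = bh_adjust(df.loc[idx, "p_raw"])
    df["significant"] = df["p_adj"] <= alpha
    return df.sort_values(["module", "category", "p_adj", "term"]).reset_index(drop=True)


def top_terms(enrichment: pd.DataFrame, category: str) -> pd.DataFrame:
    """Best term of ``category`` per module (smallest adjusted P)."""
    sub = enrichment[enrichment["category"] == category]
    if sub.empty:
        return sub
    return sub.loc[sub.groupby("module")["p_adj"].idxmin()].reset_index(drop=True)
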