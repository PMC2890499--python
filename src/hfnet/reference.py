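"""Published reference numbers for the heart-failure core network.

The original study assembled a 772-protein interaction network around 105
seed proteins (37 known heart-failure biomarkers plus the top-100
prioritized candidates, 32 of which encode known biomarkers), whose
746-protein core network decomposes into 17 modules. The per-module
overview table (sizes, intra-module interaction counts, median traffic,
inter-module interaction counts) is shipped here so the pipeline's
internal arithmetic can be checked against the printed values without the
unreleased database retrievals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import StatResult, pearson

__all__ = [
    "N_KNOWN_BIOMARKERS",
    "N_TOP_CANDIDATES",
    "N_CANDIDATES_ENCODING_KNOWN",
    "CORE_NETWORK_SIZE",
    "module_overview",
    "seed_set_size",
    "module_size_total",
    "imi_traffic_correlation",
    "self_check",
]

N_KNOWN_BIOMARKERS = 37
N_TOP_CANDIDATES = 100
N_CANDIDATES_ENCODING_KNOWN = 32
CORE_NETWORK_SIZE = 746


def module_overview() -> pd.DataFrame:
    """The published 17-module overview table."""
    with resources.files("hfnet.data").joinpath("module_overview.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def seed_set_size() -> int:
    """|biomarkers ∪ candidates| from the published counts (inclusion-exclusion)."""
    return N_KNOWN_BIOMARKERS + N_TOP_CANDIDATES - N_CANDIDATES_ENCODING_KNOWN


def module_size_total() -> int:
    """Sum of module sizes; the modules partition the core network."""
    return int(module_overview()["n_proteins"].sum())


def imi_traffic_correlation() -> StatResult:
    """Pearson correlation of inter-module interaction counts vs median traffic."""
    t = module_overview()
    return pearson(t["n_imi"], t["median_traffic"])


def self_check() -> dict[str, float]:
    """The three built-in verification numbers for a run report."""
    r = imi_traffic_correlation()
    return {
        "seed_set_size": float(seed_set_size()),
        "module_size_total": float(module_size_total()),
        "imi_traffic_pearson_r": float(r.value),
        "imi_traffic_pearson_p": float(r.p),
    }
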