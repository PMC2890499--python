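"""End-to-end orchestration: assemble -> topology -> modules -> enrich ->
stats -> classify, from one declarative config.

Each stage writes its artifact files before the next stage starts, so any
stage can be re-run from the preceding artifacts (``from_stage``), and a
failure names the failing stage while retaining partial outputs. The
machine-readable report deliberately contains no wall-clock timestamps:
re-running the same config and seed is byte-identical (timing goes to the
log instead).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import pandas as pd
import yaml

from . import __version__, assembly, classify, enrichment, modules, reference, stats, topology

logger = logging.getLogger(__name__)

STAGES = ("assemble", "topology", "modules", "enrich", "stats", "classify", "report")

__all__ = ["RunConfig", "run_pipeline", "STAGES"]


@dataclass
class RunConfig:
    edges: list[str]
    biomarkers: str
    out_dir: str
    candidates: str | None = None
    gmt: dict[str, str] = field(default_factory=dict)  # category -> path
    expression: str | None = None
    expression_labels: str | None = None
    panel: str | None = None
    mode: str = "induced"
    variance_rule: str = "pooled"
    bh_family: str = "per-module-category"
    background: str = "network"  # "network" or a path to a symbol list
    alpha: float = 0.05
    top_k: int = 20
    traffic_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        paths = list(self.edges) + [self.biomarkers]
        paths += [p for p in (self.candidates, self.expression,
                              self.expression_labels, self.panel) if p]
        paths += list(self.gmt.values())
        if self.background != "network":
            paths.append(self.background)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing files: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_core(out: Path) -> nx.Graph:
    g = nx.Graph()
    for line in (out / "core_edges.tsv").read_text().splitlines():
        a, b, src = line.split("\t")
        g.add_edge(a, b, sources=frozenset(src.split(",")))
    return g


def _stage_assemble(cfg: RunConfig, out: Path) -> nx.Graph:
    tables = [assembly.load_interaction_table(p) for p in cfg.edges]
    network = assembly.merge_union(tables)
    biomarkers = assembly.load_seed_list(cfg.biomarkers)
    candidates = assembly.load_seed_list(cfg.candidates) if cfg.candidates else frozenset()
    seeds = assembly.SeedSet(frozenset(biomarkers), frozenset(candidates))
    sub = assembly.seed_subnetwork(network, seeds, mode=cfg.mode)  # type: ignore[arg-type]
    decomp = assembly.decompose_components(sub)
    assembly.write_edge_list(sub, out / "network_edges.tsv")
    assembly.write_edge_list(decomp.core, out / "core_edges.tsv")
    assembly.write_components_report(decomp, out / "components.tsv")
    summary = {
        "n_nodes": sub.number_of_nodes(),
        "n_edges": sub.number_of_edges(),
        "core_nodes": decomp.core.number_of_nodes(),
        "core_edges": decomp.core.number_of_edges(),
        "n_islands": len(decomp.islands),
        "island_sizes": [g.number_of_nodes() for g in decomp.islands],
        "n_singletons": len(decomp.singletons),
        "n_seeds": len(seeds.seeds),
    }
    (out / "network_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return decomp.core


def _stage_topology(cfg: RunConfig, out: Path, core: nx.Graph) -> pd.DataFrame:
    cent = topology.traffic(core, scale=cfg.traffic_scale)
    topology.write_centrality_table(cent, out / "centrality.tsv")
    dist = topology.degree_distribution(core)
    pd.DataFrame({"k": dist.k, "freq": dist.freq}).to_csv(
        out / "degree_distribution.tsv", sep="\t", index=False)
    fit: dict[str, Any]
    try:
        f = topology.fit_power_law(dist)
        fit = {"gamma": f.gamma, "intercept": f.intercept,
               "fit_quality": f.fit_quality, "n_points": f.n_points}
    except ValueError as exc:
        logger.warning("power-law fit skipped: %s", exc)
        fit = {"gamma": None, "reason": str(exc)}
    (out / "powerlaw_fit.json").write_text(json.dumps(fit, indent=2) + "\n")
    topology.top_k(cent, "traffic", cfg.top_k).to_csv(out / "top_traffic.tsv", sep="\t")
    return cent


def _stage_modules(cfg: RunConfig, out: Path, core: nx.Graph,
                   cent: pd.DataFrame) -> modules.ModulePartition:
    part = modules.greedy_partition(core)
    modules.write_partition(part, out / "partition.tsv")
    profs = modules.profile_modules(core, part, cent)
    modules.write_profiles(profs, out / "module_profiles.tsv")
    with (out / "merge_history.tsv").open("w") as fh:
        fh.write("kept\tabsorbed\tdelta_q\n")
        for i, j, dq in part.history:
            fh.write(f"{i}\t{j}\t{dq:.10g}\n")
    return part


def _stage_enrich(cfg: RunConfig, out: Path, core: nx.Graph,
                  part: modules.ModulePartition) -> pd.DataFrame | None:
    if not cfg.gmt:
        logger.info("no gene-set files configured; enrichment skipped")
        return None
    if cfg.background == "network":
        background = frozenset(core.nodes)
    else:
        background = assembly.load_seed_list(cfg.background) | frozenset(core.nodes)
    frames = []
    for category, path in sorted(cfg.gmt.items()):
        tm = enrichment.load_gene_sets(path, category=category)
        frames.append(enrichment.enrich_modules(part, tm, background,
                                                alpha=cfg.alpha, family=cfg.bh_family))
    enr = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return enr


def _stage_stats(cfg: RunConfig, out: Path, cent: pd.DataFrame) -> dict[str, Any]:
    biomarkers = assembly.load_seed_list(cfg.biomarkers)
    res: dict[str, Any] = {}
    deg_traf = stats.pearson(cent["degree"], cent["traffic"])
    res["degree_traffic_pearson"] = {"r": deg_traf.value, "p": deg_traf.p, "n": deg_traf.n}
    try:
        t_deg, t_traf = stats.biomarker_centrality_contrast(
            cent, biomarkers, cfg.variance_rule)
        res["biomarker_degree_t"] = {"t": t_deg.value, "p": t_deg.p, "n": t_deg.n}
        res["biomarker_traffic_t"] = {"t": t_traf.value, "p": t_traf.p, "n": t_traf.n}
    except ValueError as exc:
        logger.warning("biomarker contrast skipped: %s", exc)
        res["biomarker_contrast_skipped"] = str(exc)
    profiles_path = out / "module_profiles.tsv"
    if profiles_path.exists():
        prof = pd.read_csv(profiles_path, sep="\t")
        if len(prof) >= 3:
            imi = stats.pearson(prof["n_imi"], prof["median_traffic"])
            res["imi_traffic_pearson"] = {"r": imi.value, "p": imi.p, "n": imi.n}
    (out / "stats.json").write_text(json.dumps(res, indent=2) + "\n")
    return res


def _stage_classify(cfg: RunConfig, out: Path) -> dict[str, Any] | None:
    if not (cfg.expression and cfg.expression_labels and cfg.panel):
        logger.info("expression inputs not configured; classification skipped")
        return None
    matrix = classify.load_expression(cfg.expression, cfg.expression_labels)
    panel = sorted(assembly.load_seed_list(cfg.panel))
    de = classify.differential_expression(matrix, panel, alpha=cfg.alpha,
                                          variance_rule=cfg.variance_rule)
    de.to_csv(out / "differential_expression.tsv", sep="\t", index=False)
    result = classify.loo_linear_classify(matrix, panel)
    result.predictions.to_csv(out / "loo_predictions.tsv", sep="\t", index=False)
    summary = {"accuracy": result.accuracy, "auc": result.auc,
               "panel": result.panel}
    (out / "classification.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def run_pipeline(cfg: RunConfig, from_stage: str = "assemble") -> dict[str, Any]:
    """Execute the pipeline stages in order, returning the run report.

    ``from_stage`` restarts at a later stage, reloading the earlier
    artifacts from the output directory.
    """
    if from_stage not in STAGES:
        raise ValueError(f"unknown stage {from_stage!r}; choose from {STAGES}")
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    start = STAGES.index(from_stage)
    stage = "assemble"
    try:
        if start <= STAGES.index("assemble"):
            core = _stage_assemble(cfg, out)
        else:
            core = _load_core(out)
        stage = "topology"
        if start <= STAGES.index("topology"):
            cent = _stage_topology(cfg, out, core)
        else:
            cent = pd.read_csv(out / "centrality.tsv", sep="\t", index_col="symbol")
        stage = "modules"
        if start <= STAGES.index("modules"):
            part = _stage_modules(cfg, out, core, cent)
        else:
            pt = pd.read_csv(out / "partition.tsv", sep="\t")
            part = modules.ModulePartition(dict(zip(pt["symbol"], pt["module"])),
                                           q=float("nan"))
            part.q = modules.modularity(core, part.assignment)
        stage = "enrich"
        enr = _stage_enrich(cfg, out, core, part)
        stage = "stats"
        stat_res = _stage_stats(cfg, out, cent)
        stage = "classify"
        cls_res = _stage_classify(cfg, out)
        stage = "report"
        report = _build_report(cfg, out, core, part, enr, stat_res, cls_res)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    _write_text_report(report, out / "report.txt")
    return report


def _build_report(cfg, out, core, part, enr, stat_res, cls_res) -> dict[str, Any]:
    summary = json.loads((out / "network_summary.json").read_text())
    fit = json.loads((out / "powerlaw_fit.json").read_text())
    prof = pd.read_csv(out / "module_profiles.tsv", sep="\t")
    report: dict[str, Any] = {
        "provenance": {"config_sha256": cfg.digest(), "hfnet_version": __version__,
                       "seed": cfg.seed,
                       "settings": {"mode": cfg.mode, "variance_rule": cfg.variance_rule,
                                    "bh_family": cfg.bh_family, "background": cfg.background,
                                    "alpha": cfg.alpha, "top_k": cfg.top_k,
                                    "traffic_scale": cfg.traffic_scale}},
        "network": summary,
        "powerlaw_fit": fit,
        "partition": {"n_modules": part.n_modules, "q": part.q,
                      "module_sizes": sorted(
                          (prof["n_proteins"].tolist()), reverse=True)},
        "module_profiles": prof.to_dict(orient="records"),
        "stats": stat_res,
        "self_check": reference.self_check(),
    }
    if enr is not None and len(enr):
        top = enr[enr["significant"]]
        report["enrichment"] = {
            "n_records": int(len(enr)),
            "n_significant": int(len(top)),
            "top_per_module": [
                {"module": int(r["module"]), "term": r["term"],
                 "category": r["category"], "p_adj": float(r["p_adj"])}
                for _, r in enr.loc[enr.groupby(["module", "category"])["p_adj"].idxmin()]
                .iterrows()
            ],
        }
    if cls_res is not None:
        report["classification"] = cls_res
    return report


def _write_text_report(report: dict[str, Any], path: Path) -> None:
    lines = ["hfnet run report", "================", ""]
    net = report["network"]
    lines.append(f"network: {net['n_nodes']} nodes / {net['n_edges']} edges; "
                 f"core {net['core_nodes']}/{net['core_edges']}; "
                 f"{net['n_islands']} island(s) {net['island_sizes']}")
    if report["powerlaw_fit"].get("gamma") is not None:
        f = report["powerlaw_fit"]
        lines.append(f"degree distribution: gamma = {f['gamma']:.2f} "
                     f"(R^2 = {f['fit_quality']:.2f}, {f['n_points']} points)")
    p = report["partition"]
    lines.append(f"modules: {p['n_modules']} (Q = {p['q']:.3f}); sizes {p['module_sizes']}")
    for key, val in report["stats"].items():
        if isinstance(val, dict) and "r" in val:
            lines.append(f"{key}: r = {val['r']:.2f} (p = {val['p']:.2g})")
        elif isinstance(val, dict) and "t" in val:
            lines.append(f"{key}: t = {val['t']:.2f} (p = {val['p']:.2g})")
    if "enrichment" in report:
        e = report["enrichment"]
        lines.append(f"enrichment: {e['n_significant']}/{e['n_records']} significant records")
    if "classification" in report:
        c = report["classification"]
        lines.append(f"classification: LOO accuracy = {c['accuracy']:.2f}, AUC = {c['auc']:.2f}")
    sc = report["self_check"]
    lines.append(f"self-check: seeds {sc['seed_set_size']:.0f}, module-size total "
                 f"{sc['module_size_total']:.0f}, IMI-traffic r {sc['imi_traffic_pearson_r']:.2f}")
    Path(path).write_text("\n".join(lines) + "\n")
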