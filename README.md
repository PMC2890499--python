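# hfnet

Biomarker-seeded protein–protein interaction (PPI) network analysis, as
used in disease systems biology: starting from a set of seed proteins —
known disease biomarkers plus candidates prioritized by rank aggregation
— `hfnet` assembles an interaction network from curated-database edge
lists, splits it into a core network and islands, profiles its modular
and communication structure, annotates modules functionally, and
evaluates gene panels as expression-based classifiers. It was built
around the heart-failure (HF) use case but every stage is generic.

The pipeline stages, each usable as a library module or CLI subcommand:

1. **Assembly** — union-merge of edge-list tables with provenance,
   first-neighbor seed subnetwork, core/island decomposition.
2. **Topology** — degree distribution, power-law exponent γ from the OLS
   line through (ln k, ln D(k)), and *traffic* (betweenness centrality:
   a node's share of shortest paths, the bottleneck measure).
3. **Modules** — greedy agglomerative maximization of modularity
   Q = Σ_c [L_c/numE − (d_c/2·numE)²], with per-module profiles
   (size, intra-module edges, median traffic, inter-module interactions).
4. **Enrichment** — two-tailed Fisher exact overrepresentation of GO/TF/
   miRNA gene sets (GMT) per module, Benjamini–Hochberg adjusted.
5. **Prioritization** — combination of per-source candidate rankings into
   one order-statistics score RS = P(U(i) ≤ r(i) ∀i) via the exact
   N!·V_N recursion, plus Fisher's omnibus −2Σln p.
6. **Statistics** — biomarker-vs-rest t contrasts on degree/traffic,
   degree–traffic and IMI–traffic correlations.
7. **Classification** — per-gene differential-expression t tests and
   leak-free leave-one-out evaluation of a linear SVM on gene panels.
8. **Synthetic data** — seeded generators (planted-partition networks
   with biomarker hub boosting, power-law graphs, module-aligned term
   maps, two-class expression matrices, planted rankings) so the whole
   pipeline runs and is tested offline.

## Worked example

Simulate a 4-module network with 8 planted biomarker hubs and run the
full pipeline:

```bash
hfnet simulate network --seed 7 --out sim
# 60 nodes / 244 edges
cat > run.yaml <<EOF
edges: [sim/edges.tsv]
biomarkers: sim/biomarkers.txt
out_dir: out
seed: 7
EOF
hfnet run --config run.yaml
```

which prints:

```
hfnet run report
================

network: 56 nodes / 222 edges; core 56/222; 0 island(s) []
degree distribution: gamma = 0.60 (R^2 = 0.13, 14 points)
modules: 4 (Q = 0.443); sizes [15, 14, 14, 13]
degree_traffic_pearson: r = 0.89 (p = 2e-20)
biomarker_degree_t: t = 9.03 (p = 2.2e-12)
biomarker_traffic_t: t = 12.97 (p = 3.2e-18)
imi_traffic_pearson: r = -0.82 (p = 0.18)
self-check: seeds 105, module-size total 746, IMI-traffic r 0.81
```

Reading the numbers: the seed subnetwork keeps the 56 of 60 simulated
proteins reachable from a biomarker; greedy clustering recovers the 4
planted modules at modularity Q = 0.443; degree and traffic are strongly
correlated (r = 0.89) and the planted biomarkers are both hubs
(t = 9.03) and high-traffic bottlenecks (t = 12.97), positive t meaning
the biomarker group is larger. The poor power-law fit (R² = 0.13) is
expected here — a planted-partition graph has Poisson-like degrees, not
a heavy tail; use `hfnet simulate`'s power-law generator or real
interactome exports for γ estimation. The 4-module IMI–traffic
correlation is uninformative at n = 4 (p = 0.18). The self-check line
recomputes the package's built-in reference arithmetic: the 105-protein
seed union (37 biomarkers + 100 candidates − 32 shared), the 746-protein
module-size total, and the r = 0.81 IMI–traffic correlation of the
published 17-module overview shipped in `hfnet.reference`.

Per-stage subcommands (`hfnet assemble|topology|modules|enrich|
prioritize|stats|classify|simulate`) expose the same functionality on
individual artifact files; `hfnet run --from modules` restarts a run
from intermediate artifacts.

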