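# Methods

`hfnet` implements a biomarker-seeded protein–protein interaction (PPI)
network analysis for heart failure (HF) and similar disease settings: a
network is assembled around seed proteins (known biomarkers plus
prioritized candidates), its modular and communication structure is
profiled, modules are functionally annotated by overrepresentation tests,
candidate genes are prioritized by rank aggregation, and gene panels are
evaluated as expression-based classifiers. This note records the models,
the defaults and why, and the design choices made where the design was
genuinely open.

## Network assembly

Interaction tables (tab-separated edge lists with an optional
source-database column, in the style of HPRD/BioGRID/MINT exports) are
merged as a set union of unordered protein pairs. Duplicate pairs collapse
into one edge carrying the union of provenance labels; self-interactions
are dropped (and logged) because every downstream topology metric assumes
a simple undirected graph. Symbols are normalized by strip + uppercase,
with an optional alias map, and normalization is idempotent.

The seed subnetwork contains the seeds plus their first-level interaction
partners. Two edge rules are provided because the first-neighbor
construction is ambiguous in the field's usage:

- `induced` (default): all edges among seeds ∪ neighbors. Chosen as
  default because observed "islands" in seed-centered disease networks
  carry more edges than a star around a seed could, implying
  neighbor–neighbor edges were retained.
- `seed-incident`: only edges touching at least one seed. Always a subset
  of the induced edge set (a tested invariant).

The network decomposes into connected components: the largest is the
*core network*, components of ≥2 nodes are *islands*, and isolated nodes
are logged separately (islands are defined as interconnected, so a
singleton is not one). Core ties are broken deterministically by node
count, then edge count, then lexicographically smallest member — real
data never faces this tie, but tests do.

## Topology: degree, power-law fit, traffic

The degree distribution D(k) is the exact histogram of degrees ≥ 1
(isolated nodes tracked separately because ln 0 is undefined). The
power-law exponent γ of D(k) ~ k^−γ is estimated as minus the slope of
the ordinary least-squares line through (ln k, ln D(k)), with fit quality
the squared correlation of the transformed points. OLS on raw
frequencies is used — it is the estimator implied by "slope of the
fitted line" in the degree-distribution literature this package serves —
rather than a maximum-likelihood fit; MLE is noted as future work. The
fit requires ≥3 distinct degree values and recovers exponents exactly on
noiseless histograms (tested to 1e−9).

*Traffic* is betweenness centrality: a node's share of shortest paths
over unordered node pairs, endpoints excluded, with fractional credit
split across equally short paths (the standard convention; computed with
networkx's Brandes implementation and validated against an exhaustive
all-shortest-paths enumeration on every connected graph of ≤7 nodes plus
random 8-node graphs). Published traffic tables sometimes carry an
unspecified scaling, so a `scale` factor (default 1) multiplies the raw
counts; the relation "median module traffic ≈ 2·(module size − 1)"
sometimes visible in printed tables is not treated as a contract.
Disconnected inputs are allowed; paths exist only within components.

## Module detection

Modularity of a partition is the closed form

    Q = Σ_c [ L_c / numE − (d_c / (2·numE))² ]

with L_c the intra-module edge count of module c, d_c the total degree of
its members, and numE the network's edge count: observed intra-module
edge fraction minus its expectation under degree-preserving random
rewiring. Detection is agglomerative greedy maximization
(Clauset–Newman–Moore): start from singleton modules, repeatedly merge
the *connected* module pair with the largest ΔQ (merging unconnected
pairs can only lower Q), stop when the best ΔQ ≤ 0. Ties on ΔQ are
broken by the lexicographically smallest module-label pair, purely so
results are reproducible; the published tooling documents no rule.
Incremental ΔQ bookkeeping is tested to equal from-scratch recomputation
after every merge, and the final Q is recomputed exactly.

Greedy agglomeration is a heuristic. Exhaustive Bell-number enumeration
(B(6) = 203 partitions) over every connected 6-node graph shows it
attains the global optimum on 102 of 112 graphs and misses it on
paths/cycles (6-path: greedy Q = 0.26 vs optimum 0.30), because merges
cannot be undone. This is an inherent property of the algorithm, kept
as-is and pinned in tests; on modular (clique-like and planted-partition)
structure the optimum is attained, and planted partitions at 4 modules ×
15 nodes, p_in = 0.4, p_out = 0.02 are recovered with adjusted Rand ≥
0.9.

Module profiles report member count, intra-module edge count, median
member traffic, and the inter-module interaction (IMI) count — edges with
exactly one endpoint in the module — plus partner modules recorded once
per pair regardless of edge multiplicity. Published per-module
"interaction" columns whose totals match neither numE nor 2·numE are not
emulated; the profile reports the well-defined intra-module count.

## Enrichment

Each (module, term) pair is tested with a two-tailed Fisher exact test on
the 2×2 table of module membership × term membership over a background
universe. The two-tailed P is the sum of probabilities of all tables with
the observed margins whose point probability is ≤ the observed one (the
common convention; validated against integer-exact hypergeometric
enumeration for all 164,176 tables with margins ≤ 30). Default background
is the core-network gene set; a whole-annotation universe is
configurable, since genome-wide TF/miRNA associations motivate the larger
universe while GO profiling of network modules motivates the smaller.
Records with zero annotated module genes are suppressed so BH families
stay meaningful, and Benjamini–Hochberg step-up adjustment runs within
each (module, category) family by default (`global` pools everything).
Under a random term map the raw-P rejection rate at α = 0.05 is at or
slightly below α (Fisher on discrete tables is conservative) — tested by
simulation.

## Prioritization

Each evidence source contributes a ranked gene list; ranks become rank
ratios r = rank / n_ranked ∈ (0,1]. The combined score is the joint
order-statistic probability RS = P(U(1) ≤ r(1), …, U(N) ≤ r(N)) that N
independent uniforms would dominate the sorted observed ratios, computed
exactly by the alternating recursion RS = N!·V_N,
V_k = Σ_i (−1)^(i−1) V_{k−i} r_(N−k+1)^i / i!. For N = 1 this is the
uniform CDF; it is permutation-invariant and monotone in each ratio
(property-tested), and matches a 10⁶-draw Monte Carlo oracle at N = 3.
RS is reported as this raw joint probability without any recalibration
(commercial prioritization systems apply an undocumented
post-transformation, so published RS thresholds are illustrative here,
not reproduced). Genes missing from a source are imputed the worst-case
ratio 1 — a conservative, documented default. Fisher's omnibus
combination (X = −2Σln p against χ² with 2N df) is provided for
combining independent P values; at N = 1 it is the identity.

## Association statistics

Two-group comparisons default to the pooled-variance Student t test
(matching the "Student's t" naming convention in the analyses this
package reproduces), with Welch available by flag since expression data
are often heteroscedastic. All P values are two-sided. The
biomarker-vs-rest contrast tests biomarkers against all remaining network
nodes on degree and on traffic, with the sign convention that positive t
means biomarkers larger — so the published direction (biomarkers are
hubs and bottlenecks) is reproducible in sign. Pearson and Spearman
(mid-rank) correlations use the standard t-transform P values.

The shipped 17-module reference overview reproduces its internal
arithmetic as a pinned regression: module sizes sum to the 746-protein
core, and IMI counts correlate with median traffic at r = 0.81 (2 dp).
(The t-transform two-sided P for r = 0.8126 at n = 17 is 7.4e−05;
published alongside that r is P = 0.0007, which does not match any
standard transform we know — only r is asserted.)

## Expression classification

Differential expression screens a gene panel with per-gene two-sample t
tests across the two clinical classes; absent panel genes yield NA rows
and the screen continues (mirroring panels containing genes a platform
did not measure). The classifier protocol is leave-one-out: for each
sample, a linear maximum-margin classifier (linear-kernel SVM, C = 1 —
no kernel or regularization details are published for the protocol this
emulates, so fixed simple defaults are used) is trained on all other
samples, with features z-scored using training-fold statistics only; the
held-out sample is then predicted. Accuracy is the fraction of correct
held-out predictions; AUC comes from the held-out decision values. The
contract is the leak-free LOO protocol, not the solver brand.

A known subtlety documented here because tests rely on it: under label
permutation, LOO accuracy on a balanced design centers slightly *below*
chance (each training fold is tilted one sample against the held-out
class). At the 16+16 design the permutation mean is ≈0.43; at smaller n
the bias grows. Tests therefore run the 16+16 design, which is also the
design the synthetic generator emulates.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (parameters, integer seed) —
bit-reproducible, one seeded RNG per call, no global state.

- **Planted-partition networks** (default 4 modules × 15 nodes,
  p_in = 0.4, p_out = 0.02): independent within/between edge draws.
  Designated "biomarker" nodes (default 8, spread round-robin over
  modules) receive extra *cross-module* edges (default 6 each), making
  them simultaneously hubs and shortest-path bottlenecks — the joint
  property the biomarker contrast is designed to detect. Boosted nodes
  genuinely bridge modules, so module-recovery checks use boost = 0.
- **Power-law graphs**: configuration model on degrees drawn from
  P(k) ∝ k^−γ truncated at kmax = round(n^(1/γ)) — the degree at which
  the expected count of a degree value falls to order one. The
  truncation is what keeps a frequency-based ln–ln OLS fit identifiable:
  with a longer tail the many D(k) = 1 points flatten the regression
  (Monte Carlo at n = 2000, γ = 2.5: kmax ≈ 21 gives fitted γ ∈
  [2.25, 2.66] over 25 seeds; kmax = 30 already drifts out of a ±0.4
  band). Multi-edges/self-loops from the pairing are discarded.
- **Module-aligned term maps**: one signature term per module holding a
  `purity` fraction of its members plus proportional outsiders, and
  uniform noise terms of size 5–20.
- **Two-class expression** (default 16 + 16, emulating the post-MI HF vs
  non-HF design): independent unit Gaussians per gene/sample, with
  planted genes shifted by Δ (in σ units) in the HF class. Gaussian
  noise is a modeling choice — no noise model is published — so effect
  sizes stay interpretable in σ units.
- **Per-source rankings**: random permutations with one planted gene
  forced into the top decile of every source.

What passing tests on these data do **not** show: real interactomes are
not planted-partition graphs (no degree heterogeneity within modules
beyond Bernoulli noise, no study bias toward well-known proteins), real
expression matrices are not i.i.d. Gaussian (correlated genes, batch and
platform effects, non-normal tails), and real annotation databases are
not module-pure. The tests validate the *machinery* — that each stage
recovers structure it is designed to detect at stated parameter regimes
— not claims about any particular biological dataset.

## Numerical and procedural choices

- Greedy merge stop tolerance: ΔQ ≤ 1e−12 treated as non-positive; final
  Q recomputed from scratch to shed accumulated float error.
- Degenerate Fisher tables (a zero margin) return P = 1.
- Two constant equal samples give t = 0, P = 1 with a warning instead of
  NaN propagation.
- `top_k` ranking breaks ties lexicographically by symbol and truncates
  silently past the table size; all writers sort rows so repeated runs
  are byte-identical.
- The machine-readable pipeline report contains no timestamps, so a rerun
  of the same config is byte-identical; timing goes to the log. Provenance
  is a config hash, package version and seed.
- Pipeline problem sizes in tests and in `scripts/acceptance.py` (60-node
  planted networks, 2000-node power-law graphs, 10–50 simulation
  replicates) were chosen as the smallest designs at which the expected
  effects are comfortably detectable by the package's own power
  calculations.

## Known limitations

- Greedy modularity misses global optima on path/cycle-like structure
  (documented above) and inherits the resolution limit of modularity.
- The ln–ln OLS γ estimator is biased on heavy-tailed samples without
  truncation; it is provided because it is the estimator the
  seed-network literature reports, not because it is statistically
  optimal.
- RS values are raw joint probabilities, not calibrated significance
  scores.
- GO structure is ignored: term maps are flat gene sets, with no
  ancestor propagation.
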