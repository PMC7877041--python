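# Methods

This note documents the model implemented by `betweennet`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not establish.

## Model and assumptions

The method assumes that a driver mutation dysregulates the *network
neighborhood* of the mutated gene, and that this dysregulation is visible
as a change in network topology between a patient's paired normal and
tumor samples. Its signal is therefore structural, not expression-level:
a gene can be called dysregulated because other genes around it dropped out
of the tumor network, even if its own expression barely moved. This is the
core difference from coverage-style approaches that define dysregulation by
differential expression alone.

Key assumptions:

- **Paired samples.** Every patient contributes a normal and a tumor
  expression profile. Patients missing either profile, or absent from the
  mutation table, are dropped (with a warning) before any computation;
  mutation frequencies are computed over the retained cohort.
- **Binary expression gating.** A gene is "expressed" when its normalized
  count is ≥ 5 (strictly-less-than-5 is removed; the boundary value
  counts as expressed). The threshold is a parameter because the value 5
  is only meaningful for RSEM-style normalized counts.
- **Unweighted, undirected interactions.** The PPI is a simple graph;
  self-loops and duplicate/reversed edges in the input are dropped at read
  time. Genes absent from an expression matrix are treated as not measured,
  hence not expressed.

## Betweenness with a path-length bound

Long shortest paths through an interaction network rarely correspond to a
functional relation, so centrality only counts geodesics of length ≤ `k`
edges (default `k = 3`). The implementation is Brandes' dependency
accumulation with each source's BFS truncated at depth `k`; vertices within
distance `k` of the source are exactly the admissible targets, so the
truncation is exact, not approximate. Complexity is one truncated BFS per
source per network, O(|P|·|V|·δ^(2k+2)) over the cohort for maximum degree δ.

**Pair convention.** The defining sum runs over ordered source/target
pairs, so every unordered pair contributes twice and no normalization is
applied. The downstream outlier step is scale-sensitive only through the
fitted distribution, so any consistent convention yields identical outlier
sets; `ordered=False` halves values for parity with unordered-pair
implementations (e.g. networkx's undirected convention). Sources iterate in
sorted order so floating-point accumulation is reproducible.

`B_diff(p,i) = |B^N − B^T|` is defined only for genes present in both of a
patient's networks; a gene missing from either side has no difference value
and can never be an outlier in that patient.

## Outlier calls

Across patients, a gene's `B_diff` values are nonnegative and unimodal
with a long right tail; they are modeled as a normal truncated to
[0, ∞). The location/scale MLE is obtained by bounded L-BFGS-B on the
truncated-normal negative log-likelihood, initialized at the sample mean
and standard deviation with tolerance 1e-8 — deterministic by
construction. Genes with fewer than `min_obs = 5` defined values, or zero
variance, are "unfittable" and never flagged. A patient is flagged for a
gene when `B_diff > μ̂ + t·σ̂` with strict inequality (default `t = 0.5`).

The fit scope is per gene — each gene gets its own (μ̂, σ̂) across
patients — because the outlier definition is applied gene by gene. A pooled
`global` scope (one distribution for all genes) is provided as an option;
it trades per-gene adaptivity for stability when cohorts are tiny. With
`t = 0.5` a substantial upper-tail fraction of patients is flagged per
fittable gene; the threshold buys sensitivity to rare drivers at the cost
of many occurrence nodes, and raising `t` is the first knob to turn for
sparser bipartite graphs.

## Influence graph and random walk

Mutated genes absent from the PPI cannot carry edges or a degree, so they
are excluded from the mutations partition and appended after all ranked
genes, ordered by mutation frequency then name and flagged `no-network`.
Isolated nodes of either partition are retained.

The transition matrix is exactly `T_ij = 1/deg(u_j)` on edges; the column
of a zero-degree node is all zeros rather than an artificial self-loop, so
an isolated node's heat decays to its restart fraction `β·MF` (documented
heat leakage, verified against the closed form). The propagation
`F_{t+1} = (1−β)TF_t + βF0` starts at `F_1 = F0` and stops when the largest
entrywise change drops below `tol = 1e-6` (default `max_iter = 1000`);
non-convergence raises an error carrying the residual — reachable at
`β = 0`, where the walk on a bipartite graph oscillates. Because `F0` is
diagonal, columns belonging to zero-heat nodes are identically zero; the
iteration is carried out only on nonzero-heat columns, which is an exact
restriction, and the transition matrix switches to a sparse representation
above 3000 nodes with identical results. `w_in` sums each full row of the
converged `F`, diagonal included.

## Ranking loop

`S_i` mixes the current bipartite degree (recomputed after every removal,
normalized by the current maximum) with the fixed `w_in` (normalized by the
maximum over the *original* partition, frozen once). Ties are broken by
higher current degree, then higher mutation frequency, then gene symbol,
making the output deterministic. Genes whose degree drops to zero remain
eligible through their diffusion term; if the current maximum degree (or
frozen maximum `w_in`) is zero, that term is zero for everyone. Scores of
successive selections are not monotone — the invariant is per-step argmax
correctness, which the tests replay against a brute-force
re-implementation.

## Evaluation conventions

- AUROC walks the ranked list top-down to a cutoff; TPR/FPR denominators
  are the reference and non-reference genes *within the ranked universe*
  (the method only ranks mutated genes, so using all genes would reward
  list length); the curve is integrated by trapezoid and not extrapolated
  past the cutoff.
- Rare drivers are reference genes with cohort MF ≤ 2%; never-mutated
  genes count as MF 0. An empty rare subset yields a warning and no
  stratified metric rather than an error.
- Enrichment uses the one-sided hypergeometric upper tail (the standard
  Fisher-test direction for enrichment) with Benjamini–Hochberg FDR across
  terms; significance defaults to q < 0.05. The annotation input is a
  pre-flattened gene→term table — ontology traversal is out of scope.
- Consistency of two enriched-term sets is |A∩B|/|A∪B|, defined as 0 with
  a warning when both are empty; the raw intersection size is exposed for
  the pathway-count variant.

## Synthetic cohorts

The generator emulates the *structure* the method exploits, at desk scale:
a Barabási–Albert PPI (200 genes, attachment 2), 30 paired patients, and 5
planted drivers drawn from mid-to-high-degree nodes (50th–95th degree
percentile — hubs enough to have neighborhoods, not the global hub).
Baseline expression is log-normal (log-mean 5, log-sd 0.5, floored just
above the expression threshold so normal networks are complete); tumor
expression adds mild log-normal noise (log-sd 0.05) that produces a
realistic false-positive floor of spurious outliers. Each driver is mutated
in a patient with probability 0.5; passengers are sprinkled at rate 0.02
per gene per patient; 10% of mutation records are Silent to exercise the
MAF filter. In a patient carrying a driver mutation, each gene within one
network hop of the driver is knocked down by a factor of 1e-3 with
probability 0.7 — removing it from the tumor network, perturbing the
betweenness of its surviving neighbors, and thereby creating outliers
adjacent to the driver that caused them. Knockdown probability below 1
matters: it leaves some driver neighbors in the tumor network to become
the outliers the influence graph needs.

What passing on this benchmark shows: the pipeline recovers topologically
planted signal through all seven stages, at effect sizes a recurrently
mutated driver would produce. What it does not show: performance under
realistic RSEM count dispersion, copy-number confounding, correlated
passenger mutations, or PPI false edges — none of which the generator
models.

## Problem sizes and defaults

Defaults throughout are `k = 3`, `t = 0.5`, `β = 0.4`, `α = 0.5`,
expression threshold 5, `max_rank = 1000`. The acceptance script runs ten
200-gene/30-patient cohorts plus ten matched no-driver nulls (a few
minutes on one CPU); the test suite checks the centrality, walk, fit and
ranking kernels against independent oracles on hundreds of small random
instances. Per-patient betweenness jobs are independent and can be
dispatched to parallel workers (`n_jobs`), with results identical to serial
execution by construction.

## Known limitations

- The per-gene truncated-normal fit is unstable for genes observed in few
  patients; such genes are silently unfittable below `min_obs`, which can
  hide genuinely dysregulated but rarely co-measured genes.
- Expression gating is binary; a gene hovering around the threshold can
  flip networks under small noise and contribute spurious `B_diff`.
- Mutated genes outside the PPI receive no score beyond their mutation
  frequency (flagged tail of the output).
- The walk treats all occurrence nodes of a gene independently; evidence
  does not accumulate across patients except through the bipartite degree
  and the shared heat value.
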