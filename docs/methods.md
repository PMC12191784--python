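# Methods

## Model

`sigmanet` detects communities by greedily maximizing a generalized
modularity measure. A generalized modularity matrix is
`M = A + W − σ k̃ k̃ᵀ` with `A` the symmetric nonnegative adjacency
matrix of a connected graph, `W` diagonal, `k̃ ≥ 0` nonzero, and
`σ > 0`. A partition P scores

Q(P) = Σ_{u,v} M_uv δ(c_u, c_v) = Σ_{i∈P} (e_ii − a_i²),

where `e_ij` is the total (A+W) weight between communities i and j and
`a_i = √σ Σ_{u∈i} k̃_u`.

**The √σ convention.** Some presentations write `a_i = σ Σ k_u`, but
that normalization is inconsistent with the double-sum form of Q and
with the merge identities below; only `a_i = √σ Σ k̃_u` makes
`Σ_i (e_ii − a_i²)` equal `Σ_{u,v} M_uv δ(c_u,c_v)` while keeping
`a_(ij) = a_i + a_j` exact. We adopt the √σ form throughout; the form
equivalence is enforced by a 200-instance randomized test.

**Null-model instantiations.**

- NG: `W = 0`, `k̃ = k`, `σ = 1/(2m)` — the standard Newman–Girvan
  matrix, no free parameter. Reported NG scores are additionally
  normalized by 2m so they lie in [−1, 1]; the generalized measure is
  reported unnormalized. The algorithm's decisions depend only on signs
  and ratios of gains, so this is purely a reporting convention.
- RB: `W = 0`, `k̃ = k`, `σ = σ_user/(2m)`. σ_user < 1 favours fewer,
  larger communities; σ_user > 1 favours more, smaller ones. RB with
  σ_user = 1 is identically NG (a tested identity).
- AFG: `W = σ_user·I`, `k̃ = k + σ_user·1`, `σ = 1/(σ_user·n + 2m)`;
  continuous in σ_user with AFG(0) = NG. The constructor also accepts
  an explicit `(w_diag, k_tilde, sigma_gen)` triple so other members of
  the family can be plugged in.

Degrees are weighted row sums; "number of edges m" generalizes to
total edge weight. A self-loop of input weight w is stored as 2w on
the adjacency diagonal, so degrees are plain row sums, self-loops count
twice toward 2m, and the storage convention is closed under coarsening
(`R A Rᵀ` turns an internal edge into exactly such a doubled diagonal
entry).

## Algorithm

One coarsening level, starting from the current supernode graph:

1. build the variant's parameters on the current graph (in stochastic
   mode, first draw σ_user ~ Uniform(low, high));
2. merge gains ΔQ(ij) = 2(e_ij − a_i a_j) for adjacent pairs —
   non-adjacent pairs have ΔQ = −2 a_i a_j ≤ 0 when W is diagonal, so
   restricting the search to edges is exact and a level costs O(edges);
3. pointer vector: node i points at the j maximizing ΔQ(ij) if that
   maximum is positive (lowest index on ties), else −1; rows are
   independent, so this step parallelizes trivially (not exploited
   here);
4. pairs that point at each other merge; everyone else stays;
5. coarsen `Aᶜ = R A Rᵀ`, `kᶜ = R k` (total weight and degree mass are
   conserved; verified invariants).

The loop ends when no gain is positive or one supernode remains. Since
only positive-gain disjoint pairs merge, the coarse Q strictly
increases at every level under a fixed measure, and the supernode count
strictly decreases, so at most n levels run.

**Gain bookkeeping across levels.** For a fixed measure the coarse gain
matrix equals the restriction `R ΔQ Rᵀ` of the fine one (diagonal
reset); the implementation recomputes gains from the coarse graph each
level, which is identical for fixed-σ W = 0 runs (tested to 1e−12 over
random coarsenings) and remains correct when σ is redrawn or when the
AFG parameters are rebuilt at the new size. `dq_mode="restrict"`
selects the restriction path; it is refused for stochastic or AFG runs,
where the measure changes between levels and Theorem-style reuse would
be invalid.

**AFG at coarse levels** rebuilds `W = σI` at the coarse size and
`k̃ = kᶜ + σ1` with denominator `σ·nᶜ + 2m` — supernodes are treated as
nodes of the coarse graph, rather than restricting the fine-level W.
This follows the recursion "replace A, k by Aᶜ, kᶜ"; the alternative
(coarsening W as RWRᵀ) would accumulate self-loop mass differently and
is not implemented.

**σ granularity.** "Randomized at each step" is read as one fresh draw
per coarsening level, the level being the algorithm's step;
`sigma_per="run"` gives the one-draw-per-run alternative. The full σ
trace is recorded in every result for reproducibility.

**Stall guard.** With a symmetric gain matrix and lowest-index
tie-breaking, the globally maximal positive pair always points
mutually, so a merge-free round with positive gains is impossible in
exact arithmetic. A defensive fallback merges the single global
best pair (lexicographic ties) and logs a warning if floating-point
asymmetry ever produces that state; it has not been observed in the
test suite.

**Spectral check.** For validation on small graphs (n ≤ 5000, dense
eigensolver), the relaxed two-community optimum is n·λ/2 with λ the
largest eigenvalue of M; the sign pattern of the leading eigenvector
(zeros mapped to +1) gives the approximate bipartition. This is a
diagnostic, not the production path.

## Experiments and stability

`run_experiment` executes `runs` independent replicas. Sub-seeds come
from `numpy.random.SeedSequence(master_seed).spawn(runs)`, so any
replica can be replayed in isolation and the whole summary is
bit-reproducible. Every final partition is scored by Newman–Girvan
modularity *of the original graph*, regardless of the variant that
produced it, so RB and AFG ensembles are comparable on one scale.
Reported statistics: mean/min/max and sample (n−1) standard deviation
of Q; mean/min/max/modal community count; and the NVI quadruplet
(mean, population variance, min, max) over all C(runs, 2) unordered
partition pairs. Runtimes are recorded but never part of any check
(hardware-dependent).

`stability_analysis` repeats the experiment per σ interval (defaults
(0, 0.5), (0.5, 1.5), (1.5, 2.5); overlapping intervals are allowed and
passed through as given). Low intervals under-resolve (runs collapse
into few communities), high intervals over-partition; the quadruplet
and community-count statistics quantify both effects.

**NVI.** VI(P₁,P₂) = H(P₁|P₂) + H(P₂|P₁) from the contingency table,
natural logs, normalized by log n (n ≤ 1 defined as 0). This
normalization makes the extreme pair — all singletons vs one block —
score exactly 1 and identical partitions 0; VI/log n is one of the two
common normalizations (the other divides by the joint entropy) and was
chosen for those exact endpoints. The base of the logarithm cancels.

## Synthetic data

The planted-partition generator samples equal-size Erdős–Rényi blocks:
within-community edges with probability p_in, cross edges with
p_out < p_in. Defaults (4 communities × 25 nodes, p_in = 0.3,
p_out = 0.02) give expected within-degree ≈ 7.2 against cross-degree
≈ 1.5 — clear but not trivial structure, recoverable by the NG
algorithm in nearly all seeds (NVI to truth < 0.2). If a sample is
disconnected the largest component is returned with the planted labels
restricted to it. The generator emulates block structure only: it has
no degree heterogeneity, no community-size spread, no weights and no
overlapping membership, so passing tests demonstrate correctness of
the machinery and recovery of clean planted structure, not performance
on heavy-tailed or hierarchical real networks. Small named graphs
(triangle, K₂, a 6-node barbell of two triangles, two K₄'s joined by a
bridge) host the closed-form worked examples; the barbell optimum
Q = 5/14 is confirmed by exhaustive enumeration of all 203 partitions.

## Numerical choices and edge cases

- Node indexing is 0-based contiguous internally; Matrix Market input
  is 1-based and converted on read, with original labels restored on
  output. Edge-list node labels may be arbitrary strings.
- Duplicate input edges accumulate weight; each undirected edge may be
  listed once (the mirror entry is added) or consistently twice.
- Disconnected graphs are a hard error by default — the modularity
  null model assumes a connected graph — with an explicit
  largest-component opt-in (ties broken toward the smallest original
  node id).
- Gains are compared to 0 exactly (a zero gain never triggers a
  merge); identity tests use 1e−12 absolute or 1e−9 relative
  tolerances depending on whether the quantity is algebraically exact
  or accumulates rounding.
- Experiment problem sizes in the acceptance script (100-node planted
  graphs, 100 replicas, 50 replicas per stability interval) were
  chosen to exercise every code path at statistically meaningful but
  quickly reproducible scale.

## Limitations

- The agglomeration is greedy pair-merging without local refinement
  (no Louvain-style node moves); on non-separable graphs it can stop
  below the global optimum — the exhaustive-enumeration test asserts
  only the upper-bound direction on such instances.
- Merging is pairwise per level, so deep hierarchies cost more levels
  than multi-way merging would.
- Directed, bipartite and overlapping-community structures are out of
  scope; streaming/out-of-core graphs are not supported.
- The dense spectral check is limited to n ≤ 5000.
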