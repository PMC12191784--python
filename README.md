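# sigmanet

Stochastic generalized-modularity community detection for undirected
(optionally weighted) networks — biological interaction graphs,
collaboration networks, meshes — via hierarchical agglomeration with a
randomized resolution parameter.

## The method

A *generalized modularity matrix* is

    M = A + W − σ k̃ k̃ᵀ

where `A` is the adjacency matrix of a connected weighted graph, `W` is
diagonal, `k̃` is a nonnegative vector and `σ > 0`. The quality of a
partition P is the generalized modularity

    Q = Σ_{u,v} (A_uv + W_uv − σ k̃_u k̃_v) δ(c_u, c_v)
      = Σ_{i∈P} (e_ii − a_i²),

with `e_ij` the (A+W)-mass between communities i and j and
`a_i = √σ · Σ_{u∈i} k̃_u`. Three standard null models are built in:

| variant | W | k̃ | σ |
|---|---|---|---|
| NG (Newman–Girvan) | 0 | k | 1/(2m) |
| RB (Reichardt–Bornholdt) | 0 | k | σ_user/(2m) |
| AFG (Arenas–Fernández–Gómez) | σ_user·I | k + σ_user·1 | 1/(σ_user·n + 2m) |

Detection maximizes Q greedily: every supernode points at the
neighbour with the largest positive merge gain ΔQ(ij) = 2(e_ij − a_i a_j)
(lowest index on ties, −1 if none is positive); mutually pointing pairs
merge; the graph is coarsened as `Aᶜ = R A Rᵀ`, `kᶜ = R k`; repeat until
no positive gain remains. The *stochastic* algorithm redraws
σ_user ~ Uniform(low, high) at every coarsening level, which lets the
resolution scale vary during the hierarchy and can escape local optima
of any single fixed-σ objective. Partitions from different null models
are compared on a common scale by their standard (Newman–Girvan)
modularity, and run-to-run consistency by the normalized variation of
information (NVI ∈ [0, 1]; 0 = identical partitions).

## Worked example

```python
import sigmanet as sn
from sigmanet import GeneralizedModularity, PlantedSpec, SigmaSampler

g, truth = sn.planted_partition(PlantedSpec(4, 25, 0.3, 0.02, seed=0))
model = GeneralizedModularity(g, variant="rb",
                              sigma=SigmaSampler.uniform(0.5, 1.5),
                              name="planted-4x25")
res = model.fit(seed=0)
print(res.summary())
print("NVI to planted labels:", round(res.compare(truth), 4))
ens = model.fit_ensemble(runs=100, seed=0)
print(ens.summary())
```

prints

```
Generalized modularity agglomeration
============================================
dataset:            planted-4x25
variant:            RB
nodes, edge mass:   100, 450
communities:        4
Q (Newman-Girvan):  0.5098
coarsening levels:  16
sigma trace:        1.137, 0.770, 0.541, 0.517, 1.313, ...
NVI to planted labels: 0.1333

Stochastic generalized modularity ensemble
============================================
dataset:          planted-4x25
variant:          RB  (100 runs)
sigma:            {'mode': 'uniform', 'low': 0.5, 'high': 1.5, ...}
Q mean (min,max): 0.5095  (0.5087, 0.5098)
Q sd:             0.0005
communities:      mean 4.25, range (4, 5), modal 4
NVI quadruplet:   (0.0057, 0.0001, 0.0000, 0.0151)
total runtime:    1.10 s
```

The single run recovers the four planted blocks (NVI 0.13 to the
ground truth; four communities at Q = 0.51). The 100-run ensemble is
highly stable here: the modal community count is the planted 4 and the
pairwise NVI mean is below 0.01.

## Command line

```sh
sigmanet detect --input graph.mtx --variant rb --sigma 1 --out-partition p.tsv
sigmanet experiment --input graph.mtx --variant afg --runs 100 --seed 1 --out report.json
sigmanet stability --input graph.mtx --runs 100 --seed 1     # σ in (0,.5),(.5,1.5),(1.5,2.5)
sigmanet score --input graph.mtx --partition p.tsv
sigmanet synth --communities 4 --size 25 --seed 1 --out-graph g.mtx --out-partition truth.tsv
```

Inputs are Matrix Market files or plain edge lists (`u v [w]`,
whitespace or comma separated, `#`/`%` comments); partitions are TSV
with a `node<TAB>community` header. Disconnected inputs are rejected
unless `--largest-component` is passed.

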