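# Methods

## Model

Given a two-layer multiplex network over `n` nodes with symmetric weight
matrices `W^(1)`, `W^(2)` (weights in [0, 1], zero diagonal), the method
asks, per node `v`, whether the composition of `v`'s weighted neighborhood
differs between the layers more than chance would allow.

### Representation learning

Each (layer, node) instance is described by its `n`-dimensional weight
vector `W^(ℓ)(v, ·)`. All instances — both real layers, plus every permuted
layer in scenario I, plus all individuals in scenario II — are stacked into
one training matrix for a fully connected encoder-decoder

    n  →  h (ReLU)  →  k (tanh | identity | relu)  →  h (ReLU)  →  n (logistic)

with `h = max(64, 4k)` unless overridden. The decoder target is either the
input weight vector itself ("adjacency" mode, the default) or the exact
`L`-step random-walk distribution `P^L` with `P = row-normalized W`
("random_walk" mode, default `L = 3`; isolated nodes receive a self-loop so
probability is conserved). Targets lie in [0, 1], so the output units are
logistic and the loss is mean binary cross-entropy. Training uses Adam
(lr 1e-3), mini-batches reshuffled each epoch, and early stopping when the
epoch loss has improved by less than 1e-6 for 20 consecutive epochs.

The network is implemented directly on NumPy arrays. This makes every run a
pure function of the integer seed: weight initialization and batch order
come from one `numpy.random.Generator`, so two runs with the same seed
produce bit-identical embeddings, tables and output files.

A deliberate consequence of the shared network: two identical input rows map
to identical bottleneck vectors, so on duplicated layers every between-layer
distance is *exactly* zero — no training noise enters — and every p-value is
exactly 1. Identical vectors are also short-circuited in the cosine distance
(`d = 0` without floating-point cancellation); a zero-norm vector (possible
with a ReLU bottleneck) yields distance 1 with a warning rather than NaN.

### Distances and nulls

The node statistic is the cosine distance (default; Euclidean available)
between the node's two layer embeddings. Cosine distances are invariant to
positive rescaling of one layer's embeddings, which removes one trivial
degree of freedom of the learned space.

Scenario I nulls: each permuted pair is obtained by permuting both layers
independently with either

* `weight_shuffle` — the upper-triangle weight multiset is permuted over all
  node pairs, destroying all structure while preserving the weight
  distribution exactly; or
* `degree_preserving` — 10·|E| double-edge swaps carrying weights, preserving
  every node's binarized degree exactly. Swap starvation (dense or complete
  graphs admit no legal swap) is detected and reported with a pointer to
  `weight_shuffle`, which is the meaningful null for dense co-expression
  networks.

All `n_perm × n` distances of the permuted pairs form one pooled null
(per-node nulls are available via `null_scope="per_node"`); the observed
distance gets the one-sided add-one p-value `(1 + #{null ≥ d}) / (1 + m)`,
which is never 0, so Fisher's combination is always defined.

Per-repeat p-values are combined with Fisher's method (`χ²` with `2R`
degrees of freedom) and BH-adjusted across nodes by default. Repeat
p-values are computed from the same data and are positively dependent;
Fisher's method assumes independence, so combined p-values are
anti-conservative. The procedure is implemented as stated; the type-I
calibration below shows the practical inflation stays modest at `R = 3`
(rejection fraction ≈ 0.05 at nominal 0.05 under an exchangeable null).

Scenario II embeds *all* individuals' layers jointly (one training run per
repeat) so each per-individual distance `d_i(v)` is measured in a single
shared space — a prerequisite for rank tests across individuals to be
meaningful. Per-individual embedding is available behind `joint=False`.
Binary phenotypes use the two-sided Wilcoxon rank-sum test (exact when the
smaller group has ≤ 10 members and there are no ties; otherwise normal
approximation with tie and continuity corrections); continuous phenotypes
use Kendall's τ-b (exact for n ≤ 8 without ties). Constant distance vectors
carry no association and are assigned p = 1; a constant phenotype is an
error.

### Network construction

Co-expression edges are `|corr|` (Pearson default, Spearman optional) across
samples; the absolute value maps weights into [0, 1] as required by the
logistic decoder, at the cost of losing the correlation sign (signed
networks are out of scope). Zero-variance genes produce undefined
correlations; these edges are set to 0 with a warning so matrices stay
total. LIONESS individual-specific networks use the standard linear
interpolation `ISN_q = N·agg − (N−1)·agg_minus_q`; raw values can exceed
[0, 1] and are preserved on request (`clip=False`), while the
embedding-facing default clips into [0, 1]. The mean pre-clip ISN tracks the
aggregate well when gene pairs are substantially correlated; near zero
correlation the absolute value has a kink and the linear approximation
degrades — a property of |corr|-LIONESS, not of the implementation.

## Synthetic data

`generate_multiplex` draws layer 1 as an Erdős–Rényi-style weighted graph
(pair present with probability `edge_density`, weight i.i.d. uniform(0,1) or
Beta), copies it to layer 2, and for each planted node deletes a fraction
`perturbation_strength` of its incident edges while creating the same number
of new incident edges with fresh weights. The planted node's degree is
preserved exactly and its expected weighted degree is unchanged, so
centrality-comparison baselines see (in expectation) nothing — the planted
signal lives purely in *which* nodes form the neighborhood, the regime this
method targets. Defaults (`n=100`, `n_planted=10`, `edge_density=0.2`,
uniform weights) keep a full scenario-I run under a minute on one CPU.

What the generator does **not** emulate: correlation-induced edge dependence
of real GCNs (edges sharing a gene are dependent), heavy-tailed weight
distributions, modular/scale-free topology, and measurement noise shared
between layers. Passing tests therefore demonstrate correctness of the
machinery and calibration under exchangeable weights, not performance on
real transcriptomes.

`generate_cohort` reuses one planted node set across individuals: designated
individuals carry the perturbation between their layers, the rest get
identical layers, giving scenario II a phenotype-linked ground truth.

## Choices for the bundled study conditions

* `k = 2` is the package default (bottleneck dimension). The simulation
  study uses `k = 8` for `n = 100` nodes: a 2-dimensional bottleneck cannot
  reconstruct 100-dimensional neighborhoods and tends to collapse toward a
  saturated corner, making cosine distances noisy; `k ≈ n/12` gives stable,
  near-perfect recovery (AUC ≈ 0.99–1.0 at strength 0.8) at negligible cost.
* Simulation runs use `epochs = 40–80` with batch size 256–512 instead of
  the 200/32 defaults; calibration and ranking are insensitive to the
  longer schedule, which matters for interactive turnaround.
* Test reductions `R = 3–5`, `n_perm = 20–50` (defaults 50/100) follow the
  same reasoning: the pooled null has `m = n_perm·n ≥ 2000` values, ample
  resolution for the 0.05 level.
* The type-I calibration condition is "layer 2 = an independent weight
  shuffle of layer 1" — the exchangeable null in which observed and permuted
  pairs are identically distributed. A strength-0 simulation is *not* a
  useful calibration condition: its layers are bit-identical, every distance
  is exactly 0 and every p-value exactly 1, so the rejection rate is 0 by
  construction (that case is tested as the exact null identity instead).

## Known limitations

* The pooled permutation null is harsh for localized alternatives: a fully
  shuffled layer pair differs everywhere, so its distances stochastically
  dominate those of a node whose neighborhood merely rewired. Rankings are
  sharp (planted nodes fill the top of the table) while absolute power at
  conventional α can be 0; per-node nulls (`null_scope="per_node"`) trade
  resolution for a less dominated reference.
* Fisher combination over dependent repeats is anti-conservative in
  principle (see above); R = 50 combined p-values should be read as scores,
  with the BH adjustment applied on top as stated.
* MLP embeddings scale as O(n²) input size per node; networks beyond a few
  thousand nodes need either feature restriction (top-variance genes) or a
  different encoder.
* Only two designated layers are compared; additional stored layers are
  carried but not analyzed. Directed and bipartite networks are out of
  scope, as are signed edge weights.
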