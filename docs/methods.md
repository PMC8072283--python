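# Methods

## Network model and indexing

A heterogeneous network holds four node populations — drug, protein,
disease, side effect — and one matrix per edge type. Global node indices
are block-contiguous in that fixed order; every embedding matrix in the
package uses this layout, so row `space.offset("protein") + i` is always
protein *i*. Six edge types are binary ({0,1}; values within 1e-9 of 0/1
are snapped on input, anything else is an error naming the cell); the two
similarity edge types are real-valued in [0,1] with unit diagonal and are
validated for symmetry to 1e-9. Matrix files are dense whitespace-delimited
text, one row per source node, tied together by a JSON manifest declaring
counts and per-edge-type metadata.

## Encoder

Initialization is a learnable projection of one-hot node codes, i.e. a
free (count × d) matrix per node type whose rows are the initial embeddings
H⁰.

Aggregation runs once per *directed* edge type: cross-type edge types get
separate (W, b) in each direction (e.g. drug→disease and disease→drug),
same-type edge types one shared pair — 12 weight matrices for the 8
benchmark edge types. For binary edge types the aggregate is the plain mean
of ReLU(W h⁰ + b) over neighbors; for similarity edge types neighbor terms
are weighted by the similarity value and normalized by the weight sum
(config switch `similarity_weighting="binary"` restores the unweighted
mean over positive-similarity neighbors). A node is never its own
similarity neighbor: the unit diagonal is excluded, the self term enters
only through the mean update. Edge types with an empty neighborhood at a
node contribute neither a term nor a denominator count to that node's
element-wise mean.

Propagation is a random walk with restart on the similarity-free
subnetwork. The transition matrix is the row-normalized union of all
walk-eligible binary edges with unit weight per (pair, edge type); a node
with no walk edges keeps a unit self-loop so the restart semantics preserve
its own features. Row normalization (rather than column) makes every row of
the propagated embedding a convex combination of rows of H*, which is both
a testable invariant and the reason the iteration cannot blow up. The
iterative form Z^{k+1} = (1−α)AZ^k + αZ⁰ is the default; the dense closed
form α(I−(1−α)A)⁻¹H* is available below a configurable node cap (default
5000) and agrees with the 200-step iteration to 1e-8 on random
row-stochastic matrices. Gradients are propagated through however many
iterations actually ran (the backward pass applies the transposed
recursion), so the encoder trains end-to-end.

Defaults: α = 0.1, K = 10 iterations, tolerance 1e-6 on the max absolute
update. α = 1 disables propagation exactly (H¹ = H*), which is also the
ablation arm of the experiments.

## Decoder and loss

DistMult with one length-d diagonal per edge type; cross-type score
matrices are V_src diag(M_r) V_dstᵀ, same-type ones are explicitly
symmetrized against float rounding (the bilinear-diagonal form is
symmetric by construction). Scores are raw — no sigmoid — because the loss
is squared reconstruction against the 0/1 (or similarity) targets and both
evaluation metrics are rank-based.

The loss masks the DTI network to the training pairs of the active split
(positives + sampled negatives); the other seven networks are fully
observed. Masked-out target entries contribute exactly zero to the loss
and all gradients (bitwise — the residual is multiplied by the binary mask
before squaring). The L2 term covers every trainable entry: projections,
aggregation weights/biases, decoder diagonals.

Gradients are derived analytically (numpy has no autodiff): residual →
decoder blocks → transposed propagation → per-node mean denominators →
ReLU gates → weights/biases/projections. The test suite checks them
against central finite differences to relative error 1e-4; measured
agreement is ~1e-5.

## Protocols

Negative sampling draws `ratio × #positives` zero cells of the DTI matrix
uniformly without replacement (capped with a warning; `ratio="all"` is the
all-unknowns-negative scenario B). Folds stratify positives and negatives
separately: each class is cut into k test chunks that partition the sampled
dataset, and validation is carved from the non-test portion so final
class-wise proportions are 0.855/0.045/0.1 up to rounding. Training strips
the test-fold positive edges from the adjacency as well as from the mask,
so the encoder and the walk never see test labels; validation positives
stay in the graph (they are masked from the loss and only steer model
selection, never the reported metric). Scenario C removes a positive (d,t)
when another positive (d′,t) exists with drug similarity > 0.6 or another
positive (d,t′) with protein similarity > 0.4.

Optimization is full-batch Adam (lr 0.001, d = 1000 by default, matching
the reference protocol). Early stopping keeps the best-validation snapshot
and stops after `patience` non-improving evaluations; with a constant
validation metric it stops after exactly the first evaluation plus
`patience` more. All randomness flows from integer seeds (one master seed
expands into per-purpose seeds), and identical seeds give byte-identical
metrics files.

AUROC is the Mann–Whitney statistic (ties ½); AUPRC is average precision —
stepwise precision integration at each retrieved positive — with ties
broken by descending score then ascending index. Average precision was
chosen over trapezoidal PR integration because it is the standard,
monotone-safe estimator for imbalanced link prediction; comparisons against
other implementations should state the estimator. Metrics are computed per
fold on test pairs only and macro-averaged; per-fold rows are always
emitted so pooled aggregations can be recomputed. The case-study procedure
builds, per score table and per drug, the m′ highest-scoring targets not
already known (ties: higher score, then lower index), ranks candidates per
drug by occurrence count across tables (ties: mean within-table rank, then
index), keeps the top m, and counts hits against a newly-confirmed
interaction set.

## Synthetic generator

The generator emulates the benchmark's structure at a scale one CPU trains
in minutes: 100 drugs, 150 proteins, 80 diseases, 60 side effects, latent
dimension 16. Latents are spherical Gaussians scaled by 1/√d_true; each
binary edge type takes the top-k cells of its planted bilinear-diagonal
score matrix, with k matching the target density exactly (DTI 0.02, other
associations 0.02–0.03) — quantile thresholding removes density variance
from tests. Noise then corrupts ~2% of the edge set: each edge is deleted
with probability 0.02 and non-edges are switched on at the rate that
preserves expected density. The noise level is a rate on edges, not on
cells; flipping every cell independently at these sparse densities would
create as many spurious edges as planted ones and bury the signal the
generator exists to plant. Similarity matrices are cosine similarities of
the latents min–max rescaled onto [0,1] with unit diagonal; the min–max
map (rather than a fixed (c+1)/2 shift) matters because cosines of
independent 16-dimensional latents concentrate near zero, and a
near-constant similarity matrix would make the similarity-weighted
aggregation an uninformative uniform average — unlike real
chemical/sequence similarity matrices, whose values spread over the unit
interval.

What the generator does not emulate: realistic degree distributions,
biological module structure, or the benchmark's scale (708/1512/5603/4192
nodes). Recovery results on it demonstrate that the pipeline extracts a
planted relational signal end-to-end, not that it matches published
performance on the real benchmark.

## Synthetic experiments

The recovery experiment removes 10% of the planted DTI positives, trains on
the rest (5% of training pairs carved out for validation), and ranks the
held-out positives against ten times as many sampled never-edges, with a
label-shuffled control (averaged over 20 permutations). Experiment-scale
training uses d = 64 (planted rank is 16), Adam at lr 0.02 cosine-decayed
over 3000 full-batch epochs, λ = 1e-5, validation evaluated every 25
epochs with patience equal to the budget — at this scale the ~30-positive
validation set is too noisy for patience-based truncation, so the
best-validation snapshot does the model selection — and K = 30 propagation
iterations, which brings the truncated iteration within (0.9)³⁰ ≈ 4% of
its closed-form fixed point.

Measured behavior: the planted-score oracle ranks held-out positives at
AUROC ≈ 0.985; the trained full model typically lands at 0.85–0.95
depending on the instance (mean ≈ 0.89 over several instances), with AUPRC
0.45–0.75 against a 0.09 prevalence baseline; a decoder-only
factorization of the same data reaches only ≈ 0.78 and overfits, and the
aggregation-only ablation (α = 1) averages a few points below the full
model — the propagation acts as a stabilizer against the free embeddings
memorizing training pairs. The residual gap to the oracle is a
generalization limit at this small scale: held-out interactions must be
inferred almost entirely from the dense similarity matrices, while the
masked squared loss lets memorization leak into the per-node free
embeddings.

## Known limitations

- Transductive only: a new drug or target requires retraining, and fully
  isolated nodes are only reachable through their similarity edges.
- Full-batch optimization assumes the network fits in memory; the dense
  per-edge-type reconstructions are O(n_src × n_dst) per epoch.
- The closed-form propagation is refused above the node cap; use the
  iterative mode (the default) on large networks.
- Early stopping semantics count evaluations, so `val_every > 1` changes
  the effective patience in epochs.
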