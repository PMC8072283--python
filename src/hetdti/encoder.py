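"""Node-embedding encoder: initialization projection, one round of
per-edge-type neighborhood aggregation, then random-walk-with-restart
(personalized PageRank) propagation.

Stage names follow the usual graph-autoencoder notation: H0 is the initial
embedding (a learnable projection of one-hot node codes), H* the embedding
after the single aggregation layer, H1 the final embedding after propagation

    Z_0 = H*,   Z_{k+1} = (1 - alpha) A Z_k + alpha Z_0,

whose fixed point is the closed form alpha (I - (1 - alpha) A)^{-1} H*.

Aggregation, per directed edge type r with neighbor set N_r(v):

    a_v^r = (1 / c_rv) sum_{u in N_r(v)} relu(W_r h_u^0 + b_r),

with c_rv = |N_r(v)| for binary edge types and the sum of similarity weights
for the real-valued ones (each neighbor term weighted by its similarity).
The update is the element-wise mean of h_v^0 together with the a_v^r of every
edge type whose neighborhood of v is nonempty.

Cross-node-type edge types carry separate (W, b) per direction, same-type
edge types one shared pair: with the eight benchmark edge types this yields
the twelve aggregation weight matrices of the model, alongside the four
per-node-type initialization projections and the eight decoder diagonals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .hetnet import EdgeTypeSpec, HeteroNetwork, NodeSpace

# directions of a directed aggregation: "sym" for same-type edge types,
# "fwd" (into dst_type nodes) and "rev" (into src_type nodes) for cross-type
DirectedKey = tuple[str, str]


def directed_edge_keys(edge_types: dict[str, EdgeTypeSpec]) -> list[DirectedKey]:
    """(name, direction) keys of every directed aggregation, in a fixed order."""
    keys: list[DirectedKey] = []
    for name in sorted(edge_types):
        spec = edge_types[name]
        if spec.src_type == spec.dst_type:
            keys.append((name, "sym"))
        else:
            keys.append((name, "fwd"))
            keys.append((name, "rev"))
    return keys


@dataclass
class RwrConfig:
    """Configuration of the propagation stage (and encoder switches).

    alpha is the restart probability in (0, 1]; alpha = 1 disables
    propagation (H1 = H*).  ``mode`` selects the power iteration or the dense
    closed form; the closed form is refused above ``closed_form_cap`` nodes.
    """

    alpha: float = 0.1
    max_iters: int = 10
    tol: float = 1e-6
    mode: str = "iterative"
    closed_form_cap: int = 5000
    similarity_weighting: str = "weighted"  # or "binary"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.max_iters < 1:
            raise ValueError("max_iters must be positive")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")
        if self.mode not in ("iterative", "closed_form"):
            raise ValueError(f"unknown rwr mode {self.mode!r}")
        if self.similarity_weighting not in ("weighted", "binary"):
            raise ValueError(f"unknown similarity_weighting {self.similarity_weighting!r}")


@dataclass
class ModelParams:
    """The three trainable parameter groups.

    * ``init_proj[t]`` — (count[t] x d) initial-embedding rows per node type
      (the projection applied to one-hot node codes);
    * ``agg_weight[(r, dir)]`` / ``agg_bias[(r, dir)]`` — (d x d) matrix and
      length-d bias of each directed edge-type aggregation;
    * ``decoder_diag[r]`` — length-d diagonal of the DistMult relation matrix.
    """

    dim: int
    init_proj: dict[str, np.ndarray]
    agg_weight: dict[DirectedKey, np.ndarray]
    agg_bias: dict[DirectedKey, np.ndarray]
    decoder_diag: dict[str, np.ndarray]

    @classmethod
    def initialize(cls, space: NodeSpace, edge_types: dict[str, EdgeTypeSpec],
                   dim: int, seed: int) -> "ModelParams":
        """Symmetric-uniform fan-in/fan-out init for projections and weights,
        zero biases, small-variance normal noise for the decoder diagonals."""
        rng = np.random.default_rng(seed)
        init_proj = {}
        for t in space.node_types:
            n = space.counts[t]
            a = np.sqrt(6.0 / (n + dim))
            init_proj[t] = rng.uniform(-a, a, size=(n, dim))
        agg_weight, agg_bias = {}, {}
        a_w = np.sqrt(6.0 / (2 * dim))
        for key in directed_edge_keys(edge_types):
            agg_weight[key] = rng.uniform(-a_w, a_w, size=(dim, dim))
            agg_bias[key] = np.zeros(dim)
        decoder_diag = {name: 0.1 * rng.standard_normal(dim) for name in sorted(edge_types)}
        return cls(dim=dim, init_proj=init_proj, agg_weight=agg_weight,
                   agg_bias=agg_bias, decoder_diag=decoder_diag)

    def leaves(self) -> list[tuple[str, np.ndarray]]:
        """Ordered flat view of every trainable array (stable across calls)."""
        out: list[tuple[str, np.ndarray]] = []
        for t in sorted(self.init_proj):
            out.append((f"init_proj/{t}", self.init_proj[t]))
        for key in sorted(self.agg_weight):
            out.append((f"agg_weight/{key[0]}/{key[1]}", self.agg_weight[key]))
            out.append((f"agg_bias/{key[0]}/{key[1]}", self.agg_bias[key]))
        for name in sorted(self.decoder_diag):
            out.append((f"decoder_diag/{name}", self.decoder_diag[name]))
        return out

    def copy(self) -> "ModelParams":
        return ModelParams(
            dim=self.dim,
            init_proj={k: v.copy() for k, v in self.init_proj.items()},
            agg_weight={k: v.copy() for k, v in self.agg_weight.items()},
            agg_bias={k: v.copy() for k, v in self.agg_bias.items()},
            decoder_diag={k: v.copy() for k, v in self.decoder_diag.items()},
        )

    def sq_norm(self) -> float:
        return float(sum(np.sum(arr * arr) for _, arr in self.leaves()))


def init_embeddings(params: ModelParams, space: NodeSpace) -> np.ndarray:
    """H0: vertical concatenation of the per-type projection blocks in the
    global node order (drugs, proteins, diseases, side effects)."""
    blocks = []
    for t in space.node_types:
        blk = params.init_proj[t]
        if blk.shape != (space.counts[t], params.dim):
            raise ValueError(
                f"init_proj[{t!r}] shape {blk.shape} != ({space.counts[t]}, {params.dim})")
        blocks.append(blk)
    return np.vstack(blocks)


def _directed_weights(net: HeteroNetwork, key: DirectedKey,
                      similarity_weighting: str) -> np.ndarray:
    """Neighbor-weight matrix of one directed aggregation, rows = destination
    nodes, columns = source (neighbor) nodes.  The self-similarity diagonal is
    excluded (a node is not its own neighbor)."""
    name, direction = key
    spec = net.edge_types[name]
    mat = net.matrices[name]
    if direction == "sym":
        w = mat.copy()
        if spec.is_similarity:
            np.fill_diagonal(w, 0.0)
    elif direction == "fwd":
        w = mat.T.copy()
    else:  # "rev"
        w = mat.copy()
    if not spec.is_similarity or similarity_weighting == "binary":
        w = (w > 0).astype(float)
    return w


def aggregate_edge_type(H_src: np.ndarray, weights: np.ndarray,
                        W: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate transformed neighbor embeddings for one directed edge type.

    ``weights`` has one row per destination node and one column per potential
    neighbor; entries are the (similarity or 0/1) neighbor weights.  Returns
    the per-destination aggregated vectors (zero where the neighborhood is
    empty) together with the boolean nonempty-neighborhood mask.
    """
    if not (np.isfinite(W).all() and np.isfinite(b).all()):
        raise ValueError("non-finite aggregation parameters")
    Z = np.maximum(H_src @ W.T + b, 0.0)
    rowsum = weights.sum(axis=1)
    mask = rowsum > 0
    norm = np.where(mask, rowsum, 1.0)
    agg = (weights @ Z) / norm[:, None]
    agg[~mask] = 0.0
    return agg, mask


def update_embeddings(H0: np.ndarray,
                      contributions: list[tuple[slice, np.ndarray, np.ndarray]]
                      ) -> np.ndarray:
    """Element-wise mean of h_v^0 with every nonempty-neighborhood aggregate.

    ``contributions`` holds (destination block slice, aggregate block,
    nonempty mask) triples; edge types with an empty neighborhood at v do not
    enter v's denominator.
    """
    num = H0.copy()
    denom = np.ones(H0.shape[0])
    for dst, agg, mask in contributions:
        num[dst] += agg
        denom[dst] += mask.astype(float)
    return num / denom[:, None]


def rwr_propagate(Hstar: np.ndarray, A: sp.spmatrix, cfg: RwrConfig,
                  return_iters: bool = False):
    """Propagate embeddings by random walk with restart.

    Iterative mode runs Z_{k+1} = (1-alpha) A Z_k + alpha Z_0 from Z_0 = H*
    until ``max_iters`` or until the max absolute update falls below ``tol``;
    closed-form mode solves alpha (I - (1-alpha) A)^{-1} H* densely.
    """
    n = Hstar.shape[0]
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    if not np.allclose(rowsum, 1.0, atol=1e-9, rtol=0):
        raise ValueError("transition matrix is not row-stochastic")
    if cfg.mode == "closed_form":
        if n > cfg.closed_form_cap:
            raise ValueError(
                f"closed-form propagation refused for {n} > {cfg.closed_form_cap} nodes")
        M = np.eye(n) - (1.0 - cfg.alpha) * np.asarray(A.todense())
        H1 = cfg.alpha * np.linalg.solve(M, Hstar)
        return (H1, 0) if return_iters else H1
    Z = Hstar
    iters = 0
    for _ in range(cfg.max_iters):
        Z_new = (1.0 - cfg.alpha) * (A @ Z) + cfg.alpha * Hstar
        iters += 1
        delta = np.max(np.abs(Z_new - Z))
        Z = Z_new
        if delta <= cfg.tol:
            break
    return (Z, iters) if return_iters else Z


def encode_with_cache(net: HeteroNetwork, params: ModelParams, cfg: RwrConfig,
                      A: sp.spmatrix | None = None) -> tuple[np.ndarray, dict]:
    """Full encoder forward pass, keeping the intermediates needed for the
    analytic backward pass (see :mod:`hetdti.training`)."""
    from .hetnet import build_transition_matrix

    space = net.space
    H0 = init_embeddings(params, space)
    cache: dict = {"H0": H0, "per_edge": {}}
    contributions = []
    for key in directed_edge_keys(net.edge_types):
        name, direction = key
        spec = net.edge_types[name]
        src_t = spec.src_type if direction != "rev" else spec.dst_type
        dst_t = spec.dst_type if direction == "fwd" else spec.src_type
        if direction == "sym":
            src_t = dst_t = spec.src_type
        src_sl, dst_sl = space.block(src_t), space.block(dst_t)
        weights = _directed_weights(net, key, cfg.similarity_weighting)
        Xs = H0[src_sl]
        pre = Xs @ params.agg_weight[key].T + params.agg_bias[key]
        Z = np.maximum(pre, 0.0)
        rowsum = weights.sum(axis=1)
        mask = rowsum > 0
        norm_w = weights / np.where(mask, rowsum, 1.0)[:, None]
        norm_w[~mask] = 0.0
        agg = norm_w @ Z
        contributions.append((dst_sl, agg, mask))
        cache["per_edge"][key] = {
            "src_sl": src_sl, "dst_sl": dst_sl, "pre_pos": pre > 0,
            "norm_w": norm_w,
        }
    num = H0.copy()
    denom = np.ones(space.n_total)
    for dst_sl, agg, mask in contributions:
        num[dst_sl] += agg
        denom[dst_sl] += mask.astype(float)
    Hstar = num / denom[:, None]
    cache["denom"] = denom
    if A is None:
        A = build_transition_matrix(net)
    cache["A"] = A
    H1, iters = rwr_propagate(Hstar, A, cfg, return_iters=True)
    cache["rwr_iters"] = iters
    cache["Hstar"] = Hstar
    return H1, cache


def encode(net: HeteroNetwork, params: ModelParams, cfg: RwrConfig,
           A: sp.spmatrix | None = None) -> np.ndarray:
    """Compose initialization, aggregation, mean update and propagation into
    the final embedding matrix H1 (deterministic given params and cfg)."""
    H1, _ = encode_with_cache(net, params, cfg, A=A)
    return H1
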