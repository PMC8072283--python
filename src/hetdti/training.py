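"""Negative sampling, stratified fold construction, the masked regularized
reconstruction loss with its exact gradients, and the Adam training loop
with early stopping.

Loss.  With P_r the binary mask of edge type r (training drug-target pairs
for the DTI network, all-ones for the other seven networks),

    L = sum_r || P_r o (X_r - S_r) ||_F^2  +  lambda * sum_w w^2,

where S_r is the DistMult reconstruction from the propagated embeddings and
the weight-square sum runs over every trainable parameter entry.  Masked-out
entries contribute exactly zero to both the loss and its gradients.

Gradients are reverse-mode and exact: the residual gradient is pushed back
through the decoder blocks, transposed through the recorded number of
propagation iterations (Z_{k+1} = (1-a) A Z_k + a Z_0 backpropagates as
g_0 += a g, g <- (1-a) A^T g), divided by the per-node mean denominators,
and finally through the ReLU aggregations into the weights, biases and
initial projections.  Finite-difference agreement is enforced in the test
suite.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .encoder import (
    ModelParams,
    RwrConfig,
    directed_edge_keys,
    encode_with_cache,
)
from .decoder import reconstruct_scores
from .evaluation import auprc, auroc
from .hetnet import HeteroNetwork, build_transition_matrix


class TrainingDivergence(RuntimeError):
    """Raised when the loss becomes non-finite during optimization."""


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the reference protocol: embedding dimension 1000,
    learning rate 0.001 (Adam), ten negatives per positive, restart
    probability 0.1.  ``lam`` is the L2 coefficient on all trainable weights.
    """

    dim: int = 1000
    lr: float = 0.001
    lam: float = 1e-4
    negative_ratio: int | str = 10
    alpha: float = 0.1
    rwr_iters: int = 10
    rwr_tol: float = 1e-6
    similarity_weighting: str = "weighted"
    patience: int = 20
    max_epochs: int = 200
    init_seed: int = 0
    early_stop_metric: str = "auprc"  # or "auroc"
    lr_schedule: str = "constant"  # or "cosine" (decay to 0 over max_epochs)
    val_every: int = 1  # epochs between validation evaluations

    def rwr_config(self) -> RwrConfig:
        return RwrConfig(alpha=self.alpha, max_iters=self.rwr_iters,
                         tol=self.rwr_tol, mode="iterative",
                         similarity_weighting=self.similarity_weighting)


@dataclass
class SplitSpec:
    """Fold assignment of positive and sampled negative drug-target pairs.

    Each of train/val/test is an integer array of shape (m, 3) with columns
    (drug index, protein index, label); the three lists are disjoint and
    jointly cover the sampled DTI dataset of the fold.
    """

    fold_id: int
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    negative_ratio: int | str = 10
    seed: int = 0


def sample_negatives(dti_matrix: np.ndarray, ratio: int | str, seed: int) -> np.ndarray:
    """Uniform sample (without replacement) of zero entries of the DTI matrix.

    Requests ratio x (#positives) pairs, capped at the number of zero entries
    (a warning is emitted when capped).  ``ratio="all"`` returns every zero
    entry, for the all-unknowns-negative scenario.  Returns an (m, 2) array
    of (drug, protein) indices.
    """
    zeros = np.argwhere(dti_matrix == 0)
    n_pos = int(dti_matrix.sum())
    if ratio == "all":
        return zeros
    ratio = int(ratio)
    if ratio < 1:
        raise ValueError("negative ratio must be >= 1")
    want = ratio * n_pos
    if want > len(zeros):
        warnings.warn(
            f"requested {want} negatives but only {len(zeros)} zero entries exist; capping")
        want = len(zeros)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(zeros), size=want, replace=False)
    return zeros[np.sort(idx)]


def _three_way_split(items: np.ndarray, test_chunks: list[np.ndarray], fold: int,
                     val_frac: float, rng: np.random.Generator):
    test = test_chunks[fold]
    rest = np.concatenate([c for f, c in enumerate(test_chunks) if f != fold]) \
        if len(test_chunks) > 1 else np.empty((0,), dtype=int)
    rest = rng.permutation(rest)
    n_val = int(round(val_frac * len(items)))
    return rest[n_val:], rest[:n_val], test


def make_folds(positives: np.ndarray, negatives: np.ndarray, k: int,
               ratios: tuple[float, float, float] = (0.855, 0.045, 0.1),
               seed: int = 0) -> list[SplitSpec]:
    """k stratified train/validation/test splits whose test sets partition
    the sampled DTI dataset.

    Positives and negatives are stratified separately: each class is shuffled
    once and cut into k test chunks; per fold, the validation set is carved
    from the non-test portion so the final class-wise proportions match
    ``ratios`` up to rounding.  Deterministic under ``seed``.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if len(positives) < k or len(negatives) < k:
        raise ValueError("too few samples to stratify across folds")
    rng = np.random.default_rng(seed)
    folds: list[SplitSpec] = []
    pos_chunks = np.array_split(rng.permutation(len(positives)), k)
    neg_chunks = np.array_split(rng.permutation(len(negatives)), k)
    val_frac = ratios[1]
    for f in range(k):
        p_tr, p_va, p_te = _three_way_split(positives, pos_chunks, f, val_frac, rng)
        n_tr, n_va, n_te = _three_way_split(negatives, neg_chunks, f, val_frac, rng)

        def rows(pool, idx, label):
            out = np.empty((len(idx), 3), dtype=int)
            out[:, :2] = pool[idx]
            out[:, 2] = label
            return out

        folds.append(SplitSpec(
            fold_id=f,
            train=np.concatenate([rows(positives, p_tr, 1), rows(negatives, n_tr, 0)]),
            val=np.concatenate([rows(positives, p_va, 1), rows(negatives, n_va, 0)]),
            test=np.concatenate([rows(positives, p_te, 1), rows(negatives, n_te, 0)]),
            seed=seed,
        ))
    return folds


def build_masks(net: HeteroNetwork, train_pairs: np.ndarray | None) -> dict[str, np.ndarray | None]:
    """Mask matrices P per edge type: the DTI network is masked to the given
    training pairs (positives and sampled negatives); the other seven
    networks are fully observed.

    ``None`` stands for an all-ones mask (kept implicit for speed).
    """
    masks: dict[str, np.ndarray | None] = {name: None for name in net.edge_types}
    if train_pairs is not None:
        P = np.zeros_like(net.matrices[net.dti_name])
        P[train_pairs[:, 0], train_pairs[:, 1]] = 1.0
        masks[net.dti_name] = P
    return masks


def masked_loss(reconstructions: dict[str, np.ndarray],
                originals: dict[str, np.ndarray],
                masks: dict[str, np.ndarray | None],
                params: ModelParams | None = None,
                lam: float = 0.0) -> float:
    """Masked squared reconstruction error plus L2 penalty on all weights."""
    total = 0.0
    for name, recon in reconstructions.items():
        resid = originals[name] - recon
        P = masks.get(name)
        if P is not None:
            resid = P * resid
        total += float(np.sum(resid * resid))
    if lam and params is not None:
        total += lam * params.sq_norm()
    return total


def _rwr_backward(gH1: np.ndarray, A: sp.spmatrix, alpha: float, iters: int) -> np.ndarray:
    """Transpose of the truncated propagation: gradient w.r.t. Z_0 = H*."""
    AT = A.T.tocsr()
    g0 = np.zeros_like(gH1)
    gc = gH1
    for _ in range(iters):
        g0 += alpha * gc
        gc = (1.0 - alpha) * (AT @ gc)
    return g0 + gc


def loss_and_grads(net: HeteroNetwork, params: ModelParams, cfg: RwrConfig,
                   masks: dict[str, np.ndarray | None], lam: float,
                   A: sp.spmatrix | None = None,
                   targets: dict[str, np.ndarray] | None = None
                   ) -> tuple[float, dict[str, np.ndarray], dict]:
    """One full forward/backward pass.

    Returns (loss, gradients keyed like ``params.leaves()``, extras).  The
    extras dict carries the DTI reconstruction so the caller can score
    validation pairs without a second forward pass.  ``targets`` are the
    reconstruction targets of Q = P o (target - reconstruction); they default
    to the network matrices themselves (the graph the encoder runs on), but
    masked-out target entries never touch the loss or the gradients.
    """
    space = net.space
    if targets is None:
        targets = net.matrices
    H1, cache = encode_with_cache(net, params, cfg, A=A)

    loss = 0.0
    gH1 = np.zeros_like(H1)
    g_diag: dict[str, np.ndarray] = {}
    extras: dict = {}
    for name in sorted(net.edge_types):
        spec = net.edge_types[name]
        S = reconstruct_scores(H1, params, spec, space)
        if name == net.dti_name:
            extras["dti_scores"] = S
        resid = targets[name] - S
        P = masks.get(name)
        if P is not None:
            resid = P * resid
        loss += float(np.sum(resid * resid))
        G = -2.0 * resid  # dL/dS (mask already folded in; P binary)
        m = params.decoder_diag[name]
        E_src = H1[space.block(spec.src_type)]
        E_dst = H1[space.block(spec.dst_type)]
        GE_d = G @ E_dst
        gH1[space.block(spec.src_type)] += GE_d * m
        gH1[space.block(spec.dst_type)] += (G.T @ E_src) * m
        g_diag[name] = np.sum(GE_d * E_src, axis=0)

    gHstar = _rwr_backward(gH1, cache["A"], cfg.alpha, cache["rwr_iters"])
    gnum = gHstar / cache["denom"][:, None]

    gH0 = gnum.copy()
    H0 = cache["H0"]
    g_w: dict = {}
    g_b: dict = {}
    for key in directed_edge_keys(net.edge_types):
        ec = cache["per_edge"][key]
        dagg = gnum[ec["dst_sl"]]
        dZ = ec["norm_w"].T @ dagg
        dpre = dZ * ec["pre_pos"]
        Xs = H0[ec["src_sl"]]
        g_w[key] = dpre.T @ Xs
        g_b[key] = dpre.sum(axis=0)
        gH0[ec["src_sl"]] += dpre @ params.agg_weight[key]

    grads: dict[str, np.ndarray] = {}
    for t in space.node_types:
        grads[f"init_proj/{t}"] = gH0[space.block(t)]
    for key in g_w:
        grads[f"agg_weight/{key[0]}/{key[1]}"] = g_w[key]
        grads[f"agg_bias/{key[0]}/{key[1]}"] = g_b[key]
    for name, g in g_diag.items():
        grads[f"decoder_diag/{name}"] = g

    if lam:
        loss += lam * params.sq_norm()
        for pname, arr in params.leaves():
            grads[pname] = grads[pname] + 2.0 * lam * arr

    return loss, grads, extras


class Adam:
    """Standard Adam over the flat parameter leaves (in-place updates)."""

    def __init__(self, params: ModelParams, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(arr) for name, arr in params.leaves()}
        self.v = {name: np.zeros_like(arr) for name, arr in params.leaves()}

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, arr in params.leaves():
            g = grads[name]
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1 ** self.t)
            vhat = self.v[name] / (1 - b2 ** self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _pair_scores(score_matrix: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    return score_matrix[pairs[:, 0], pairs[:, 1]]


def _strip_heldout_edges(net: HeteroNetwork, split: SplitSpec) -> HeteroNetwork:
    """Training copy of the network with the test-set positive DTI edges
    removed, so the encoder and the walk never see test labels.  Validation
    positives stay in the adjacency (they are excluded from the loss by the
    mask; they only steer model selection, not the reported metric)."""
    out = net.copy()
    dti = out.matrices[net.dti_name]
    pos = split.test[split.test[:, 2] == 1]
    dti[pos[:, 0], pos[:, 1]] = 0.0
    return out


def train(net: HeteroNetwork, split: SplitSpec, cfg: TrainConfig,
          params: ModelParams | None = None
          ) -> tuple[ModelParams, list[dict]]:
    """Full-batch Adam minimization of the masked loss with early stopping.

    After each epoch the early-stop metric (validation AUPRC by default) is
    evaluated on the validation pairs; the best-validation parameter snapshot
    is kept and training stops after ``patience`` non-improving epochs or at
    ``max_epochs``.  Fully reproducible under the config seeds.
    """
    train_net = _strip_heldout_edges(net, split)
    masks = build_masks(train_net, split.train)
    rwr = cfg.rwr_config()
    A = build_transition_matrix(train_net)
    if params is None:
        params = ModelParams.initialize(train_net.space, train_net.edge_types,
                                        cfg.dim, cfg.init_seed)
    else:
        params = params.copy()
    metric_fn = auprc if cfg.early_stop_metric == "auprc" else auroc

    best = params.copy()
    best_metric = -np.inf
    stale = 0
    opt = Adam(params, cfg.lr)
    history: list[dict] = []
    for epoch in range(cfg.max_epochs):
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / cfg.max_epochs))
        loss, grads, extras = loss_and_grads(train_net, params, rwr, masks,
                                             cfg.lam, A=A)
        if not np.isfinite(loss):
            raise TrainingDivergence(f"non-finite loss at epoch {epoch}: {loss}")
        opt.step(params, grads)

        rec = {"epoch": epoch, "loss": loss}
        evaluate_now = (epoch % cfg.val_every == cfg.val_every - 1) or cfg.val_every == 1
        if not evaluate_now:
            history.append(rec)
            continue
        if len(split.val) and len(np.unique(split.val[:, 2])) == 2:
            H1, _ = encode_with_cache(train_net, params, rwr, A=A)
            S = reconstruct_scores(H1, params, train_net.edge_types[train_net.dti_name],
                                   train_net.space)
            val_metric = metric_fn(_pair_scores(S, split.val), split.val[:, 2])
            rec[f"val_{cfg.early_stop_metric}"] = val_metric
            if val_metric > best_metric:
                best_metric = val_metric
                best = params.copy()
                stale = 0
            else:
                stale += 1
            history.append(rec)
            if stale >= cfg.patience:
                break
        else:
            best = params.copy()
            history.append(rec)
    return best, history


def filter_homologous_positives(net: HeteroNetwork,
                                drug_sim_name: str = "drug_similarity",
                                protein_sim_name: str = "protein_similarity",
                                drug_threshold: float = 0.6,
                                protein_threshold: float = 0.4) -> np.ndarray:
    """Positive DTI pairs surviving the homology filter.

    A positive (d, t) is removed when another positive (d', t) exists with
    drug similarity sim(d, d') > 0.6, or another positive (d, t') exists with
    protein similarity sim(t, t') > 0.4 — the easy cases that structurally
    similar drugs / homologous proteins would give away.
    """
    dti = net.matrices[net.dti_name]
    Sd = net.matrices[drug_sim_name] > drug_threshold
    St = net.matrices[protein_sim_name] > protein_threshold
    np.fill_diagonal(Sd, False)
    np.fill_diagonal(St, False)
    # counts of similar-partner positives per (d, t)
    drug_partner = Sd.astype(float) @ dti      # (d,t): # of d' ~ d with (d',t) positive
    prot_partner = dti @ St.astype(float).T    # (d,t): # of t' ~ t with (d,t') positive
    keep = (dti > 0) & (drug_partner == 0) & (prot_partner == 0)
    return np.argwhere(keep)
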