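"""DistMult decoder: bilinear-diagonal scoring and per-edge-type network
reconstruction from node embeddings.

The score of a candidate edge (u, r, v) is s = e_u^T M_r e_v with a diagonal
relation matrix M_r, so a whole edge-type matrix is reconstructed at once as
V_src diag(M_r) V_dst^T.  Scores are raw (no sigmoid): the training loss is
squared reconstruction error against the 0/1 (or similarity) targets, and
the evaluation metrics are rank-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import ModelParams, RwrConfig, encode
from .hetnet import EdgeTypeSpec, HeteroNetwork, NodeSpace


@dataclass
class ScoreTable:
    """Predicted score matrix for one edge type, with optional evaluation
    labels/mask of identical shape."""

    edge_type: EdgeTypeSpec
    scores: np.ndarray
    labels: np.ndarray | None = None
    mask: np.ndarray | None = None


def distmult_score(e_u: np.ndarray, diag_r: np.ndarray, e_v: np.ndarray) -> float:
    """sum_i e_u[i] * diag_r[i] * e_v[i]  (= e_u^T M_r e_v)."""
    e_u, diag_r, e_v = (np.asarray(x, dtype=float) for x in (e_u, diag_r, e_v))
    if not (e_u.shape == diag_r.shape == e_v.shape):
        raise ValueError("embedding/diagonal length mismatch")
    return float(np.sum(e_u * diag_r * e_v))


def reconstruct_scores(H1: np.ndarray, params: ModelParams, spec: EdgeTypeSpec,
                       space: NodeSpace) -> np.ndarray:
    """Score matrix V_src diag(M_r) V_dst^T from the node-type blocks of H1."""
    if spec.name not in params.decoder_diag:
        raise KeyError(f"no decoder diagonal for edge type {spec.name!r}")
    E_src = H1[space.block(spec.src_type)]
    E_dst = H1[space.block(spec.dst_type)]
    S = (E_src * params.decoder_diag[spec.name]) @ E_dst.T
    if spec.symmetric:
        # the bilinear-diagonal form is symmetric; enforce it exactly
        # against float rounding so same-type tables equal their transpose
        S = 0.5 * (S + S.T)
    return S


def reconstruct_network(H1: np.ndarray, params: ModelParams, spec: EdgeTypeSpec,
                        space: NodeSpace) -> ScoreTable:
    """Reconstruct one edge-type network as a ScoreTable."""
    return ScoreTable(edge_type=spec, scores=reconstruct_scores(H1, params, spec, space))


def predict_dti(net: HeteroNetwork, params: ModelParams, cfg: RwrConfig) -> ScoreTable:
    """Encode the network and reconstruct the drug-target edge type.

    Deterministic given inputs; the returned score matrix has one row per
    drug and one column per protein.
    """
    H1 = encode(net, params, cfg)
    spec = net.edge_types[net.dti_name]
    table = reconstruct_network(H1, params, spec, net.space)
    table.labels = net.matrices[net.dti_name].copy()
    return table
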