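"""Synthetic heterogeneous networks with a planted low-rank relational
signal, so every stage — and end-to-end held-out recovery — is testable
without any external dataset.

Each node carries a latent vector drawn from a fixed spherical Gaussian;
every binary edge type is obtained by thresholding the planted
bilinear-diagonal (DistMult) scores at the quantile matching its target
density (exact top-k selection, so densities are deterministic), then
flipping edges with a small noise probability; the two similarity networks
are the cosine similarities of the latents affinely mapped into [0, 1] with
a unit diagonal.  Because the similarity networks are dense deterministic
functions of the latents, held-out drug-target interactions are recoverable
in principle — the planted signal survives the masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hetnet import (
    EdgeTypeSpec,
    HeteroNetwork,
    NodeSpace,
    default_edge_types,
)

#: default network scale: large enough to carry a rank-16 signal, small
#: enough that end-to-end training completes in minutes on one CPU
DEFAULT_COUNTS = {"drug": 100, "protein": 150, "disease": 80, "side_effect": 60}
DEFAULT_DENSITIES = {
    "drug_target": 0.02,
    "drug_drug": 0.03,
    "protein_protein": 0.03,
    "drug_disease": 0.02,
    "drug_sideeffect": 0.02,
    "protein_disease": 0.02,
}


@dataclass
class SynthConfig:
    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    d_true: int = 16
    densities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    flip_prob: float = 0.02
    diag_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_true < 1:
            raise ValueError("d_true must be >= 1")
        if not 0.0 <= self.flip_prob < 0.5:
            raise ValueError("flip_prob must lie in [0, 0.5)")
        for name, rho in self.densities.items():
            if not 0.0 < rho < 1.0:
                raise ValueError(f"density for {name!r} must lie in (0, 1)")


@dataclass
class PlantedTruth:
    """Ground truth behind a synthetic network: latents, relation diagonals,
    pre-noise planted score matrices, and (after hold-out) the removed
    positive DTI pairs."""

    latents: dict[str, np.ndarray]
    rel_diags: dict[str, np.ndarray]
    scores: dict[str, np.ndarray]
    held_out: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))


def _threshold_top_k(scores: np.ndarray, density: float, symmetric: bool) -> np.ndarray:
    """Binary matrix with exactly round(density * n_eligible) edges: the
    top-scoring cells (off-diagonal upper triangle for symmetric types)."""
    n, m = scores.shape
    if symmetric:
        iu, ju = np.triu_indices(n, k=1)
        vals = scores[iu, ju]
    else:
        vals = scores.ravel()
    k = int(round(density * len(vals)))
    if k < 1 or k >= len(vals):
        raise ValueError(f"target density {density} unattainable for {len(vals)} cells")
    order = np.argsort(vals)[::-1]
    # degenerate scores (all equal) cannot realize a quantile threshold
    if vals[order[0]] == vals[order[-1]]:
        raise ValueError("degenerate planted scores: all equal")
    chosen = order[:k]
    out = np.zeros_like(scores)
    if symmetric:
        out[iu[chosen], ju[chosen]] = 1.0
        out[ju[chosen], iu[chosen]] = 1.0
    else:
        out.ravel()[chosen] = 1.0
    return out


def _flip_noise(mat: np.ndarray, p: float, symmetric: bool,
                rng: np.random.Generator) -> np.ndarray:
    """Corrupt a fraction ~p of the edge set: each edge is deleted with
    probability p, and absent cells are switched on with the matching rate
    p * k / (N - k) so the expected spurious-edge count equals the expected
    deletion count (density preserved in expectation).

    The noise level is a rate on edges, not on cells: at the sparse densities
    used here, flipping every cell independently would bury the planted
    signal under spurious edges, defeating the generator's purpose.
    """
    if p == 0.0:
        return mat
    out = mat.copy()
    if symmetric:
        n = mat.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        vals = out[iu, ju]
    else:
        vals = out.ravel()
    k = vals.sum()
    q = p * k / max(1.0, len(vals) - k)
    r = rng.random(len(vals))
    flip = np.where(vals > 0, r < p, r < q)
    vals = np.where(flip, 1.0 - vals, vals)
    if symmetric:
        out[iu, ju] = vals
        out[ju, iu] = vals
    else:
        out = vals.reshape(mat.shape)
    return out


def _unit_cosine(U: np.ndarray) -> np.ndarray:
    """Cosine similarity of the latents, min-max rescaled onto [0, 1].

    The affine rescaling maps the observed off-diagonal range onto the full
    unit interval: cosines of independent high-dimensional latents
    concentrate near zero, and a shift-only map would leave every pair with
    a near-constant similarity weight, unlike real chemical-structure or
    sequence similarity matrices whose values spread over [0, 1].
    """
    norms = np.linalg.norm(U, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    C = (U / norms[:, None]) @ (U / norms[:, None]).T
    off = ~np.eye(C.shape[0], dtype=bool)
    lo, hi = C[off].min(), C[off].max()
    S = np.clip((C - lo) / (hi - lo), 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate_network(cfg: SynthConfig) -> tuple[HeteroNetwork, PlantedTruth]:
    """Draw a synthetic network with a planted DistMult signal.

    Reproducible under ``cfg.seed``; the output passes ``validate_network``.
    """
    rng = np.random.default_rng(cfg.seed)
    space = NodeSpace(counts=dict(cfg.counts))
    specs = {s.name: s for s in default_edge_types()}
    latents = {
        t: rng.standard_normal((space.counts[t], cfg.d_true)) / np.sqrt(cfg.d_true)
        for t in space.node_types
    }
    rel_diags: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray] = {}
    matrices: dict[str, np.ndarray] = {}
    for name, spec in specs.items():
        U, V = latents[spec.src_type], latents[spec.dst_type]
        if spec.is_similarity:
            matrices[name] = _unit_cosine(U)
            continue
        m = cfg.diag_scale * rng.standard_normal(cfg.d_true)
        rel_diags[name] = m
        S = (U * m) @ V.T
        if spec.symmetric:
            S = 0.5 * (S + S.T)
        scores[name] = S
        mat = _threshold_top_k(S, cfg.densities[name], spec.symmetric)
        matrices[name] = _flip_noise(mat, cfg.flip_prob, spec.symmetric, rng)
    net = HeteroNetwork(space=space, edge_types=specs, matrices=matrices)
    return net, PlantedTruth(latents=latents, rel_diags=rel_diags, scores=scores)


def hold_out_dti(net: HeteroNetwork, truth: PlantedTruth, fraction: float,
                 seed: int) -> tuple[HeteroNetwork, np.ndarray]:
    """Remove a seeded random fraction of positive DTI edges from a copy of
    the network; the removed (drug, protein) pairs are the held-out positives
    for the recovery experiment (also recorded on the returned truth)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    pos = np.argwhere(net.matrices[net.dti_name] > 0)
    n_out = int(round(fraction * len(pos)))
    if n_out >= len(pos):
        raise ValueError("hold-out would remove every positive")
    if n_out < 1:
        raise ValueError("hold-out removes no positives at this fraction")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pos), size=n_out, replace=False)
    held = pos[np.sort(idx)]
    out = net.copy()
    out.matrices[net.dti_name][held[:, 0], held[:, 1]] = 0.0
    truth.held_out = held
    return out, held
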