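"""Heterogeneous-network data model, matrix-file I/O, validation, and
transition-matrix construction for the random walk.

The network holds four node populations (drugs, proteins/targets, diseases,
side effects) and one matrix per edge type.  Six edge types are binary
association/interaction networks; the two similarity networks (drug chemical
structure, protein sequence) are real-valued in [0, 1] with a unit diagonal.
The random walk runs on the similarity-free subnetwork only.

Node indexing is global and block-contiguous: drugs first, then proteins,
diseases, side effects.  Every embedding matrix in the package uses this
order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp

NODE_TYPES = ("drug", "protein", "disease", "side_effect")

#: values within this distance of 0 or 1 are snapped when parsing binary files
BINARY_SNAP_TOL = 1e-9
SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class EdgeTypeSpec:
    """Metadata for one edge type of the heterogeneous network.

    ``value_kind`` is ``"binary"`` for association/interaction networks and
    ``"real_unit_interval"`` for the two similarity networks.  ``in_walk``
    marks edge types that participate in the random walk (the similarity
    edges are deleted before the walk).
    """

    name: str
    src_type: str
    dst_type: str
    value_kind: str = "binary"
    symmetric: bool = False
    in_walk: bool = True

    def __post_init__(self) -> None:
        if self.src_type not in NODE_TYPES or self.dst_type not in NODE_TYPES:
            raise ValueError(f"unknown node type in edge type {self.name!r}")
        if self.value_kind not in ("binary", "real_unit_interval"):
            raise ValueError(f"bad value_kind {self.value_kind!r}")
        if self.symmetric and self.src_type != self.dst_type:
            raise ValueError(f"symmetric edge type {self.name!r} must join one node type")

    @property
    def is_similarity(self) -> bool:
        return self.value_kind == "real_unit_interval"


def default_edge_types() -> tuple[EdgeTypeSpec, ...]:
    """The eight edge types of the benchmark heterogeneous network."""
    return (
        EdgeTypeSpec("drug_target", "drug", "protein"),
        EdgeTypeSpec("drug_drug", "drug", "drug", symmetric=True),
        EdgeTypeSpec("protein_protein", "protein", "protein", symmetric=True),
        EdgeTypeSpec("drug_disease", "drug", "disease"),
        EdgeTypeSpec("drug_sideeffect", "drug", "side_effect"),
        EdgeTypeSpec("protein_disease", "protein", "disease"),
        EdgeTypeSpec(
            "drug_similarity", "drug", "drug",
            value_kind="real_unit_interval", symmetric=True, in_walk=False,
        ),
        EdgeTypeSpec(
            "protein_similarity", "protein", "protein",
            value_kind="real_unit_interval", symmetric=True, in_walk=False,
        ),
    )


@dataclass(frozen=True)
class NodeSpace:
    """Node-type inventory with the global block-contiguous index layout."""

    counts: dict[str, int]
    node_types: tuple[str, ...] = NODE_TYPES

    def __post_init__(self) -> None:
        for t in self.node_types:
            if t not in self.counts:
                raise ValueError(f"missing count for node type {t!r}")
            if int(self.counts[t]) < 1:
                raise ValueError(f"count for {t!r} must be >= 1")

    @property
    def n_total(self) -> int:
        return sum(self.counts[t] for t in self.node_types)

    def offset(self, node_type: str) -> int:
        off = 0
        for t in self.node_types:
            if t == node_type:
                return off
            off += self.counts[t]
        raise KeyError(node_type)

    def block(self, node_type: str) -> slice:
        """Global-index slice covering all nodes of ``node_type``."""
        off = self.offset(node_type)
        return slice(off, off + self.counts[node_type])


@dataclass
class HeteroNetwork:
    """A node space plus one matrix per edge type.

    ``matrices[name]`` has shape ``(counts[src_type], counts[dst_type])`` for
    the edge type of that name; entries are all nonnegative.
    """

    space: NodeSpace
    edge_types: dict[str, EdgeTypeSpec]
    matrices: dict[str, np.ndarray]

    def copy(self) -> "HeteroNetwork":
        return HeteroNetwork(
            space=self.space,
            edge_types=dict(self.edge_types),
            matrices={k: v.copy() for k, v in self.matrices.items()},
        )

    @property
    def dti_name(self) -> str:
        """Name of the drug->protein binary edge type (the prediction target)."""
        for name, spec in self.edge_types.items():
            if spec.src_type == "drug" and spec.dst_type == "protein" and not spec.is_similarity:
                return name
        raise KeyError("network has no drug-target edge type")


@dataclass(frozen=True)
class Violation:
    """One violated network invariant; ``indices`` locates the offending cell."""

    edge_type: str
    kind: str
    message: str
    indices: tuple[int, int] | None = None

    def as_row(self) -> str:
        i, j = self.indices if self.indices is not None else ("", "")
        return f"{self.edge_type}\t{self.kind}\t{i}\t{j}\t{self.message}"


class NetworkFormatError(ValueError):
    """Raised when a manifest or matrix file violates the declared layout."""


def _coerce_binary(mat: np.ndarray, name: str) -> np.ndarray:
    snapped = np.where(np.abs(mat) <= BINARY_SNAP_TOL, 0.0, mat)
    snapped = np.where(np.abs(snapped - 1.0) <= BINARY_SNAP_TOL, 1.0, snapped)
    bad = (snapped != 0.0) & (snapped != 1.0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise NetworkFormatError(
            f"edge type {name!r}: non-binary value {mat[i, j]!r} at cell ({i}, {j})"
        )
    return snapped


def load_network(manifest_path: str | Path) -> HeteroNetwork:
    """Load a heterogeneous network from a JSON manifest.

    The manifest declares node counts and, per edge type, its metadata and the
    path (relative to the manifest) of a dense whitespace-delimited matrix
    file with one row per source node::

        {"counts": {"drug": 708, "protein": 1512, ...},
         "edge_types": [{"name": "drug_target", "src_type": "drug",
                         "dst_type": "protein", "value_kind": "binary",
                         "symmetric": false, "in_walk": true,
                         "file": "mat_drug_protein.txt"}, ...]}
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    space = NodeSpace(counts={t: int(c) for t, c in manifest["counts"].items()})
    edge_types: dict[str, EdgeTypeSpec] = {}
    matrices: dict[str, np.ndarray] = {}
    for entry in manifest["edge_types"]:
        spec = EdgeTypeSpec(
            name=entry["name"],
            src_type=entry["src_type"],
            dst_type=entry["dst_type"],
            value_kind=entry.get("value_kind", "binary"),
            symmetric=bool(entry.get("symmetric", False)),
            in_walk=bool(entry.get("in_walk", not entry.get("value_kind") == "real_unit_interval")),
        )
        path = manifest_path.parent / entry["file"]
        try:
            mat = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:
            raise NetworkFormatError(f"edge type {spec.name!r}: cannot parse {path}: {exc}") from exc
        expect = (space.counts[spec.src_type], space.counts[spec.dst_type])
        if mat.shape != expect:
            raise NetworkFormatError(
                f"edge type {spec.name!r}: matrix shape {mat.shape} != declared {expect}"
            )
        if (mat < 0).any():
            i, j = map(int, np.argwhere(mat < 0)[0])
            raise NetworkFormatError(
                f"edge type {spec.name!r}: negative value at cell ({i}, {j})"
            )
        if spec.value_kind == "binary":
            mat = _coerce_binary(mat, spec.name)
        if spec.symmetric and not np.allclose(mat, mat.T, atol=SYMMETRY_TOL, rtol=0):
            diff = np.abs(mat - mat.T)
            i, j = map(int, np.argwhere(diff > SYMMETRY_TOL)[0])
            raise NetworkFormatError(
                f"edge type {spec.name!r}: asymmetric at cell ({i}, {j})"
            )
        edge_types[spec.name] = spec
        matrices[spec.name] = mat
    return HeteroNetwork(space=space, edge_types=edge_types, matrices=matrices)


def write_network(net: HeteroNetwork, out_dir: str | Path,
                  manifest_name: str = "manifest.json") -> Path:
    """Write manifest + dense matrix text files; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, spec in net.edge_types.items():
        fname = f"{name}.txt"
        fmt = "%d" if spec.value_kind == "binary" else "%.17g"
        np.savetxt(out_dir / fname, net.matrices[name], fmt=fmt)
        entries.append({
            "name": spec.name, "src_type": spec.src_type, "dst_type": spec.dst_type,
            "value_kind": spec.value_kind, "symmetric": spec.symmetric,
            "in_walk": spec.in_walk, "file": fname,
        })
    manifest = {"counts": dict(net.space.counts), "edge_types": entries}
    path = out_dir / manifest_name
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def validate_network(net: HeteroNetwork) -> list[Violation]:
    """Check every network invariant; an empty report means the network is valid."""
    report: list[Violation] = []

    def first_bad(mask: np.ndarray) -> tuple[int, int]:
        return tuple(map(int, np.argwhere(mask)[0]))  # type: ignore[return-value]

    for name, spec in net.edge_types.items():
        mat = net.matrices[name]
        expect = (net.space.counts[spec.src_type], net.space.counts[spec.dst_type])
        if mat.shape != expect:
            report.append(Violation(name, "shape", f"shape {mat.shape} != {expect}"))
            continue
        if (mat < 0).any():
            report.append(Violation(name, "negative", "negative entry", first_bad(mat < 0)))
        if spec.value_kind == "binary":
            bad = (mat != 0.0) & (mat != 1.0)
            if bad.any():
                i, j = first_bad(bad)
                report.append(Violation(
                    name, "non_binary", f"non-binary value {mat[i, j]!r}", (i, j)))
        else:
            bad = (mat < 0.0) | (mat > 1.0)
            if bad.any():
                report.append(Violation(name, "range", "value outside [0, 1]", first_bad(bad)))
            if not np.allclose(np.diag(mat), 1.0, atol=SYMMETRY_TOL, rtol=0):
                i = int(np.argmax(np.abs(np.diag(mat) - 1.0)))
                report.append(Violation(name, "diagonal", "similarity diagonal != 1", (i, i)))
        if spec.symmetric:
            diff = np.abs(mat - mat.T)
            if (diff > SYMMETRY_TOL).any():
                report.append(Violation(name, "asymmetric", "matrix != transpose",
                                        first_bad(diff > SYMMETRY_TOL)))
    return report


def report_to_tsv(report: list[Violation]) -> str:
    header = "edge_type\tkind\trow\tcol\tmessage"
    return "\n".join([header] + [v.as_row() for v in report]) + "\n"


def build_transition_matrix(net: HeteroNetwork) -> sp.csr_matrix:
    """Row-stochastic transition matrix of the walk-eligible subnetwork.

    All edge types with ``in_walk=True`` (i.e. everything except the two
    similarity networks) are unioned into one global symmetric adjacency with
    unit edge weights, cross-type blocks placed in both orientations; each
    row is divided by its sum.  A node with no walk-eligible edge keeps its
    own features via a unit self-loop row.
    """
    n = net.space.n_total
    adj = sp.lil_matrix((n, n))
    for name, spec in net.edge_types.items():
        if not spec.in_walk:
            continue
        block = sp.csr_matrix((net.matrices[name] > 0).astype(float))
        rs, cs = net.space.block(spec.src_type), net.space.block(spec.dst_type)
        adj[rs, cs] += block
        if spec.src_type != spec.dst_type:
            adj[cs, rs] += block.T
        elif not spec.symmetric:  # same-type directed edges contribute both ways
            adj[rs, cs] += block.T
    adj = sp.csr_matrix(adj)
    rowsum = np.asarray(adj.sum(axis=1)).ravel()
    dangling = rowsum == 0
    inv = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, rowsum))
    A = sp.diags(inv) @ adj
    if dangling.any():
        A = A + sp.diags(dangling.astype(float))
    return sp.csr_matrix(A)
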