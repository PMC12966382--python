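"""Protein featurization: sequence to residue graphs.

The main architecture encodes the target as a linear chain graph — one node
per residue, edges between sequence neighbours, preserving biological order.
An optional distance-threshold contact graph built from user-supplied 3D
coordinates (one representative atom per residue, conventionally the
C-alpha) is available for ablation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = [
    "ProteinRecord",
    "ResidueNode",
    "ProteinGraph",
    "build_sequence_graph",
    "build_contact_graph",
    "featurize_residues",
    "RESIDUE_FEATURE_SCHEMES",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(AMINO_ACIDS) | {"X"}

# Kyte-Doolittle hydropathy index.
_KD_HYDROPATHY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
    "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3, "X": 0.0,
}

# Side-chain charge class at physiological pH.
_CHARGE_CLASS = {"D": -1, "E": -1, "K": 1, "R": 1, "H": 1}


@dataclass(frozen=True)
class ProteinRecord:
    """A named one-letter amino-acid sequence (20 canonical letters plus X)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise InputError(f"protein {self.id!r}: sequence must be non-empty")
        for pos, ch in enumerate(self.sequence):
            if ch not in _VALID:
                raise InputError(
                    f"protein {self.id!r}: illegal residue {ch!r} at position {pos}"
                )


@dataclass
class ResidueNode:
    index: int
    aa: str
    features: np.ndarray | None = None


@dataclass
class ProteinGraph:
    record: ProteinRecord
    residues: list[ResidueNode]
    chain_edges: list[tuple[int, int]]
    contact_edges: list[tuple[int, int]] | None = None
    feature_scheme: str | None = None

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def edges(self) -> list[tuple[int, int]]:
        return list(self.chain_edges) + list(self.contact_edges or [])

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_residues, self.n_residues))
        for i, j in self.edges():
            a[i, j] = a[j, i] = 1.0
        return a

    def residue_feature_matrix(self) -> np.ndarray:
        if any(r.features is None for r in self.residues):
            raise InputError(
                f"protein {self.record.id!r}: residues are not featurized; "
                "call featurize_residues first"
            )
        return np.stack([r.features for r in self.residues])


def build_sequence_graph(record: ProteinRecord) -> ProteinGraph:
    """Linear residue graph: N nodes, N-1 consecutive chain edges."""
    residues = [ResidueNode(index=i, aa=aa) for i, aa in enumerate(record.sequence)]
    chain_edges = [(i, i + 1) for i in range(len(residues) - 1)]
    return ProteinGraph(record=record, residues=residues, chain_edges=chain_edges)


def build_contact_graph(
    record: ProteinRecord, coords: np.ndarray, threshold: float = 8.0
) -> ProteinGraph:
    """Chain graph plus contact edges for non-adjacent residue pairs.

    ``coords`` holds one representative-atom (C-alpha) position per residue in
    angstrom; pairs (i, j) with j > i+1 and distance <= ``threshold`` become
    contact edges.
    """
    coords = np.asarray(coords, dtype=float)
    if threshold <= 0:
        raise InputError("contact threshold must be positive")
    n = len(record.sequence)
    if coords.shape != (n, 3):
        raise InputError(
            f"protein {record.id!r}: expected coordinates of shape ({n}, 3), "
            f"got {coords.shape}"
        )
    graph = build_sequence_graph(record)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    ii, jj = np.triu_indices(n, k=2)
    within = dist[ii, jj] <= threshold
    graph.contact_edges = [(int(i), int(j)) for i, j in zip(ii[within], jj[within])]
    return graph


def _default_residue_features(aa: str) -> np.ndarray:
    onehot = np.zeros(len(AMINO_ACIDS))
    if aa in AMINO_ACIDS:
        onehot[AMINO_ACIDS.index(aa)] = 1.0
    return np.concatenate(
        [onehot, [_KD_HYDROPATHY[aa], float(_CHARGE_CLASS.get(aa, 0))]]
    )


RESIDUE_FEATURE_SCHEMES = {"default": _default_residue_features}


def featurize_residues(graph: ProteinGraph, scheme: str = "default") -> ProteinGraph:
    """Fill residue feature vectors: one-hot(20) + hydropathy + charge class.

    The unknown residue X gets an all-zero one-hot block.
    """
    if scheme not in RESIDUE_FEATURE_SCHEMES:
        raise InputError(
            f"unknown feature scheme {scheme!r}; available: "
            f"{sorted(RESIDUE_FEATURE_SCHEMES)}"
        )
    fn = RESIDUE_FEATURE_SCHEMES[scheme]
    for res in graph.residues:
        res.features = fn(res.aa)
    graph.feature_scheme = scheme
    return graph


def prepare_protein(record: ProteinRecord, scheme: str = "default") -> ProteinGraph:
    """Sequence graph + default featurization in one call."""
    return featurize_residues(build_sequence_graph(record), scheme=scheme)
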