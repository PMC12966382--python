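"""The physics-informed dual-branch GCN regressor.

Architecture: a drug branch of two graph-convolution layers over the
ligand's heavy-atom graph, a protein branch of graph convolutions over the
linear residue graph, mean-pooled readouts from both, concatenation with
min-max-normalized physical energy features (Coulomb and Lennard-Jones),
and a dense head emitting one scalar — the predicted binding energy in
kcal/mol (more negative = stronger predicted binding).

Graph convolutions use the symmetric normalisation
D^-1/2 (A + I) D^-1/2, which together with mean pooling makes every
prediction invariant to node ordering.

Forward and backward passes are written directly in NumPy; parameters live
in a flat name -> array dict so optimizers and checkpoints stay trivial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .errors import InputError
from .ligand import LigandGraph
from .protein import ProteinGraph

__all__ = ["ModelConfig", "AffinityPrediction", "PhysDualGCN", "normalized_adjacency"]


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(z):
    return (z > 0).astype(float)


def _tanh(x):
    return np.tanh(x)


def _tanh_grad(z):
    return 1.0 - np.tanh(z) ** 2


_ACTIVATIONS = {"relu": (_relu, _relu_grad), "tanh": (_tanh, _tanh_grad)}


@dataclass(frozen=True)
class ModelConfig:
    drug_feature_dim: int = 19
    protein_feature_dim: int = 22
    drug_hidden_dims: tuple[int, int] = (128, 128)
    protein_hidden_dims: tuple[int, ...] = (64,)
    fusion_dims: tuple[int, ...] = (512, 256)
    dropout: float = 0.2
    activation: str = "relu"
    physics_feature_count: int = 2

    def __post_init__(self):
        if len(self.drug_hidden_dims) != 2:
            raise InputError("the drug branch uses exactly two GCN layers")
        dims = (*self.drug_hidden_dims, *self.protein_hidden_dims, *self.fusion_dims)
        if any(d < 1 for d in dims):
            raise InputError("all hidden dimensions must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise InputError("dropout must lie in [0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise InputError(f"unknown activation {self.activation!r}")
        if self.physics_feature_count < 0:
            raise InputError("physics_feature_count must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("drug_hidden_dims", "protein_hidden_dims", "fusion_dims"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class AffinityPrediction:
    ligand_id: str
    predicted_energy: float  # kcal/mol


def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric GCN normalisation with self-loops: D^-1/2 (A+I) D^-1/2."""
    a_hat = np.asarray(adjacency, dtype=float) + np.eye(len(adjacency))
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _graph_inputs(graph, features: np.ndarray):
    """(A_norm, X) for a graph; A_norm is memoised on the graph object.

    The normalisation depends only on connectivity, which is immutable for a
    built graph, so caching it is safe and saves the dominant matmul when
    the same (large) protein graph is reused across training steps.
    """
    a_norm = getattr(graph, "_gcn_a_norm", None)
    if a_norm is None or a_norm.shape[0] != features.shape[0]:
        a_norm = normalized_adjacency(graph.adjacency())
        graph._gcn_a_norm = a_norm
    return a_norm, features


class PhysDualGCN:
    """Dual-branch GCN + physics fusion; one (ligand, protein) pair per pass."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self._act, self._act_grad = _ACTIVATIONS[config.activation]
        self._init_params(np.random.default_rng(seed))

    # -- parameters ---------------------------------------------------------

    def _glorot(self, rng, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    def _init_params(self, rng):
        cfg = self.config
        dims = [cfg.drug_feature_dim, *cfg.drug_hidden_dims]
        for l in range(2):
            self.params[f"drug_W{l}"] = self._glorot(rng, dims[l], dims[l + 1])
            self.params[f"drug_b{l}"] = np.zeros(dims[l + 1])
        dims = [cfg.protein_feature_dim, *cfg.protein_hidden_dims]
        for l in range(len(cfg.protein_hidden_dims)):
            self.params[f"prot_W{l}"] = self._glorot(rng, dims[l], dims[l + 1])
            self.params[f"prot_b{l}"] = np.zeros(dims[l + 1])
        fusion_in = (
            cfg.drug_hidden_dims[-1]
            + cfg.protein_hidden_dims[-1]
            + cfg.physics_feature_count
        )
        dims = [fusion_in, *cfg.fusion_dims, 1]
        for l in range(len(dims) - 1):
            self.params[f"head_W{l}"] = self._glorot(rng, dims[l], dims[l + 1])
            self.params[f"head_b{l}"] = np.zeros(dims[l + 1])
        self._n_head = len(dims) - 1

    # -- branch forward/backward -------------------------------------------

    def _gcn_forward(self, prefix: str, n_layers: int, a_norm, x):
        cache = {"AH": [], "Z": [], "H": [x]}
        h = x
        for l in range(n_layers):
            ah = a_norm @ h
            z = ah @ self.params[f"{prefix}_W{l}"] + self.params[f"{prefix}_b{l}"]
            h = self._act(z)
            cache["AH"].append(ah)
            cache["Z"].append(z)
            cache["H"].append(h)
        emb = h.mean(axis=0)
        cache["a_norm"] = a_norm
        cache["n_nodes"] = h.shape[0]
        return emb, cache

    def _gcn_backward(self, prefix: str, n_layers: int, cache, d_emb, grads):
        n = cache["n_nodes"]
        dh = np.tile(d_emb / n, (n, 1))
        for l in reversed(range(n_layers)):
            dz = dh * self._act_grad(cache["Z"][l])
            grads[f"{prefix}_W{l}"] = cache["AH"][l].T @ dz
            grads[f"{prefix}_b{l}"] = dz.sum(axis=0)
            if l > 0:
                dh = cache["a_norm"] @ (dz @ self.params[f"{prefix}_W{l}"].T)

    # -- public encoders ----------------------------------------------------

    def encode_drug(self, graph: LigandGraph) -> np.ndarray:
        """Fixed-length ligand embedding (mean-pooled two-layer GCN)."""
        x = graph.atom_feature_matrix()
        if x.shape[1] != self.config.drug_feature_dim:
            raise InputError(
                f"ligand feature length {x.shape[1]} does not match the "
                f"configured drug_feature_dim {self.config.drug_feature_dim}"
            )
        a_norm, x = _graph_inputs(graph, x)
        return self._gcn_forward("drug", 2, a_norm, x)[0]

    def encode_protein(self, graph: ProteinGraph) -> np.ndarray:
        """Fixed-length protein embedding (mean-pooled GCN over the chain)."""
        x = graph.residue_feature_matrix()
        if x.shape[1] != self.config.protein_feature_dim:
            raise InputError(
                f"residue feature length {x.shape[1]} does not match the "
                f"configured protein_feature_dim {self.config.protein_feature_dim}"
            )
        a_norm, x = _graph_inputs(graph, x)
        return self._gcn_forward(
            "prot", len(self.config.protein_hidden_dims), a_norm, x
        )[0]

    def _check_physics(self, physics_features):
        phys = np.atleast_1d(np.asarray(physics_features, dtype=float))
        if phys.shape != (self.config.physics_feature_count,):
            raise InputError(
                f"expected {self.config.physics_feature_count} physics features, "
                f"got shape {phys.shape}"
            )
        if phys.size and (phys.min() < 0.0 or phys.max() > 1.0):
            raise InputError(
                "physics features must be min-max normalized to [0,1]; "
                f"got {phys.tolist()}"
            )
        return phys

    def _head_forward(self, x, training=False, rng=None):
        cache = {"X": [x], "Z": [], "mask": []}
        p = self.config.dropout
        h = x
        for l in range(self._n_head - 1):
            z = h @ self.params[f"head_W{l}"] + self.params[f"head_b{l}"]
            h = self._act(z)
            if training and p > 0:
                mask = (rng.random(h.shape) >= p) / (1.0 - p)
                h = h * mask
            else:
                mask = None
            cache["Z"].append(z)
            cache["mask"].append(mask)
            cache["X"].append(h)
        l = self._n_head - 1
        y = h @ self.params[f"head_W{l}"] + self.params[f"head_b{l}"]
        cache["y"] = float(y[0])
        return cache["y"], cache

    def _head_backward(self, cache, dy, grads):
        l = self._n_head - 1
        grads[f"head_W{l}"] = cache["X"][-1][:, None] * dy
        grads[f"head_b{l}"] = np.array([dy])
        dh = self.params[f"head_W{l}"][:, 0] * dy
        for l in reversed(range(self._n_head - 1)):
            if cache["mask"][l] is not None:
                dh = dh * cache["mask"][l]
            dz = dh * self._act_grad(cache["Z"][l])
            grads[f"head_W{l}"] = np.outer(cache["X"][l], dz)
            grads[f"head_b{l}"] = dz
            dh = dz @ self.params[f"head_W{l}"].T
        return dh  # gradient w.r.t. the fused input vector

    def fuse_and_predict(
        self,
        drug_emb: np.ndarray,
        protein_emb: np.ndarray,
        physics_features,
        ligand_id: str = "",
    ) -> AffinityPrediction:
        """Concatenate embeddings + physics features, run the dense head.

        Inference-mode only (dropout inactive). Raises InputError if the
        physics features fall outside [0,1] — they must already be scaled.
        """
        phys = self._check_physics(physics_features)
        x = np.concatenate([drug_emb, protein_emb, phys])
        y, _ = self._head_forward(x, training=False)
        return AffinityPrediction(ligand_id=ligand_id, predicted_energy=y)

    # -- full pair pass ------------------------------------------------------

    def forward(
        self,
        ligand_graph: LigandGraph,
        protein_graph: ProteinGraph,
        physics_features,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Full forward pass; returns (prediction, cache) for backprop."""
        phys = self._check_physics(physics_features)
        xd = ligand_graph.atom_feature_matrix()
        ad, xd = _graph_inputs(ligand_graph, xd)
        if xd.shape[1] != self.config.drug_feature_dim:
            raise InputError(
                f"ligand feature length {xd.shape[1]} != configured "
                f"{self.config.drug_feature_dim}"
            )
        xp = protein_graph.residue_feature_matrix()
        ap, xp = _graph_inputs(protein_graph, xp)
        d_emb, d_cache = self._gcn_forward("drug", 2, ad, xd)
        p_emb, p_cache = self._gcn_forward(
            "prot", len(self.config.protein_hidden_dims), ap, xp
        )
        x = np.concatenate([d_emb, p_emb, phys])
        y, h_cache = self._head_forward(x, training=training, rng=rng)
        return y, {"drug": d_cache, "prot": p_cache, "head": h_cache}

    def backward(self, cache, dy: float) -> dict[str, np.ndarray]:
        """Parameter gradients for a scalar output gradient ``dy``."""
        grads: dict[str, np.ndarray] = {}
        dx = self._head_backward(cache["head"], dy, grads)
        nd = self.config.drug_hidden_dims[-1]
        npr = self.config.protein_hidden_dims[-1]
        self._gcn_backward("drug", 2, cache["drug"], dx[:nd], grads)
        self._gcn_backward(
            "prot",
            len(self.config.protein_hidden_dims),
            cache["prot"],
            dx[nd : nd + npr],
            grads,
        )
        return grads

    def predict_pair(
        self, ligand_graph: LigandGraph, protein_graph: ProteinGraph, physics_features
    ) -> AffinityPrediction:
        y, _ = self.forward(ligand_graph, protein_graph, physics_features)
        return AffinityPrediction(
            ligand_id=ligand_graph.record.id, predicted_energy=y
        )

    # -- serialization -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k in self.params:
            if k not in state:
                raise InputError(f"checkpoint is missing parameter {k!r}")
            self.params[k] = np.asarray(state[k], dtype=float).copy()

    def config_json(self) -> str:
        return json.dumps(self.config.to_dict())
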