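"""Generic synchronous message-passing engine.

The general formulation the production layers specialise: each node i
carries a state vector s_i^k initialised from its label l_i; at every
iteration each node receives from each neighbour j the message
(s_j^{k-1}, e_ij) — the source state concatenated with the edge label —
aggregates messages with a coefficient a (a = 1/|Ne| gives the mean
aggregator, a = 1 the sum aggregator), and applies an update function F to
(previous state, aggregate). Iteration stops when the per-node Euclidean
state change drops below a tolerance for every node, or at a maximum
iteration count.

This engine is deliberately simple and loop-based so it can serve as a
verifiable reference for the vectorised production model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ComputationError, InputError

__all__ = ["GraphState", "MPConfig", "message", "aggregate", "propagate"]


@dataclass
class GraphState:
    """Per-node state vectors after ``iteration`` synchronous updates."""

    states: list[np.ndarray]
    iteration: int


@dataclass(frozen=True)
class MPConfig:
    aggregation: str = "mean"  # "mean" -> a = 1/|Ne|, "sum" -> a = 1
    tolerance: float = 1e-4
    max_iterations: int = 10

    def __post_init__(self):
        if self.aggregation not in ("mean", "sum"):
            raise InputError(f"unknown aggregation {self.aggregation!r}")
        if self.tolerance <= 0 or self.max_iterations < 1:
            raise InputError("tolerance must be > 0 and max_iterations >= 1")


def message(source_state: np.ndarray, edge_label: np.ndarray | None) -> np.ndarray:
    """The message along an edge: (source state, edge label) concatenated."""
    source_state = np.asarray(source_state, dtype=float)
    if edge_label is None:
        return source_state.copy()
    return np.concatenate([source_state, np.asarray(edge_label, dtype=float)])


def aggregate(messages: list[np.ndarray], config: MPConfig) -> np.ndarray:
    """a * sum(messages); the empty neighbourhood yields a zero vector."""
    if not messages:
        return np.zeros(0)
    total = np.sum(np.stack([np.asarray(m, dtype=float) for m in messages]), axis=0)
    if config.aggregation == "mean":
        total = total / len(messages)
    return total


def propagate(
    n_nodes: int,
    edges: list[tuple[int, int]],
    init_labels: list[np.ndarray],
    update_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    config: MPConfig = MPConfig(),
    edge_labels: dict[tuple[int, int], np.ndarray] | None = None,
) -> GraphState:
    """Iterate synchronous state updates until convergence or max_iterations.

    ``edges`` are undirected; each endpoint sees the other as a neighbour.
    ``update_fn`` maps (previous state, aggregated message) to the new state
    (same dimension as the previous state). Isolated nodes receive a
    zero-vector aggregate of message length.
    """
    if len(init_labels) != n_nodes:
        raise InputError(f"expected {n_nodes} labels, got {len(init_labels)}")
    neighbors: list[list[int]] = [[] for _ in range(n_nodes)]
    for i, j in edges:
        neighbors[i].append(j)
        neighbors[j].append(i)

    def edge_label(i: int, j: int):
        if edge_labels is None:
            return None
        key = (i, j) if (i, j) in edge_labels else (j, i)
        return edge_labels.get(key)

    states = [np.asarray(l, dtype=float).copy() for l in init_labels]
    state_dim = states[0].shape[0]
    edge_dim = 0
    if edge_labels:
        edge_dim = len(next(iter(edge_labels.values())))
    msg_dim = state_dim + edge_dim

    iteration = 0
    for k in range(1, config.max_iterations + 1):
        new_states = []
        for i in range(n_nodes):
            msgs = [message(states[j], edge_label(i, j)) for j in neighbors[i]]
            agg = aggregate(msgs, config) if msgs else np.zeros(msg_dim)
            s = np.asarray(update_fn(states[i], agg), dtype=float)
            if not np.all(np.isfinite(s)):
                raise ComputationError(
                    f"update produced a non-finite state at node {i}, iteration {k}"
                )
            if s.shape != states[i].shape:
                raise InputError(
                    f"update changed the state dimension at node {i}: "
                    f"{states[i].shape} -> {s.shape}"
                )
            new_states.append(s)
        deltas = [np.linalg.norm(n - o) for n, o in zip(new_states, states)]
        states = new_states
        iteration = k
        if max(deltas) < config.tolerance:
            break
    return GraphState(states=states, iteration=iteration)
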