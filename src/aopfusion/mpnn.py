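"""Message passing neural network over peptide molecular graphs.

Three message-passing steps with degree-conditioned update matrices:

    m_v^{t+1} = sum over u in N(v) of concat(h_u^t, e_vu)
    h_v^{t+1} = sigma(H_t^{deg(v)} m_v^{t+1})

followed by a permutation-invariant readout (per-node linear projection to
128 dimensions, mean over nodes).  The update matrices carry no bias, so a
layer is exactly the matrix-vector product the update rule prescribes.

Multiple graphs are encoded as one disjoint union ("batched graph"), which
is algebraically identical to encoding them one at a time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .chem import EDGE_FEATURE_DIM, NODE_FEATURE_DIM, MolGraph
from .nn import ParamDict, add_linear, count_params, linear, uniform_init


@dataclass(frozen=True)
class MPNNConfig:
    """Reference configuration: 3 steps, 128-dim readout, ~75 k parameters."""

    n_steps: int = 3
    hidden_dim: int = 71
    max_degree: int = 4
    readout_dim: int = 128
    node_feature_dim: int = NODE_FEATURE_DIM
    edge_feature_dim: int = EDGE_FEATURE_DIM

    @property
    def message_dim(self) -> int:
        return self.hidden_dim + self.edge_feature_dim


@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs with directed edge lists."""

    node_features: np.ndarray   # (N, node_feature_dim)
    edge_src: np.ndarray        # (2E,) directed
    edge_dst: np.ndarray        # (2E,)
    edge_features: np.ndarray   # (2E, edge_feature_dim)
    graph_index: np.ndarray     # (N,) which graph each node belongs to
    n_graphs: int
    degrees: np.ndarray         # (N,) undirected degree

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


def batch_graphs(graphs: Sequence[MolGraph]) -> GraphBatch:
    if not graphs:
        raise ValueError("cannot batch zero graphs")
    nodes, srcs, dsts, efeats, gidx = [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        if g.n_atoms == 0:
            raise ValueError("empty graph in batch")
        nodes.append(g.node_features)
        if g.n_bonds:
            a = g.edges[:, 0] + offset
            b = g.edges[:, 1] + offset
            srcs.append(np.concatenate([a, b]))
            dsts.append(np.concatenate([b, a]))
            efeats.append(np.concatenate([g.edge_features, g.edge_features]))
        gidx.append(np.full(g.n_atoms, gi))
        offset += g.n_atoms
    node_features = np.concatenate(nodes)
    edge_src = np.concatenate(srcs) if srcs else np.empty(0, dtype=np.int64)
    edge_dst = np.concatenate(dsts) if dsts else np.empty(0, dtype=np.int64)
    edge_features = (np.concatenate(efeats) if efeats
                     else np.empty((0, EDGE_FEATURE_DIM)))
    degrees = np.bincount(edge_dst, minlength=node_features.shape[0])
    if np.any(degrees == 0):
        raise AssertionError("isolated vertex: impossible for a valid peptide")
    return GraphBatch(node_features=node_features, edge_src=edge_src,
                      edge_dst=edge_dst, edge_features=edge_features,
                      graph_index=np.concatenate(gidx), n_graphs=len(graphs),
                      degrees=degrees)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def init_graph_params(config: MPNNConfig, rng, dtype=np.float64) -> ParamDict:
    params: ParamDict = {}
    add_linear(params, "enc", rng, config.node_feature_dim, config.hidden_dim,
               dtype=dtype)
    for t in range(config.n_steps):
        for deg in range(1, config.max_degree + 1):
            # Eq-style update sigma(H m): the H matrices are bias-free
            params[f"H.t{t}.d{deg}"] = uniform_init(
                rng, (config.message_dim, config.hidden_dim), dtype=dtype)
    add_linear(params, "readout", rng, config.hidden_dim, config.readout_dim,
               dtype=dtype)
    return params


def count_graph_params(config: MPNNConfig, params: ParamDict) -> int:
    return count_params(params)


# ---------------------------------------------------------------------------
# forward operations
# ---------------------------------------------------------------------------

def message_step(batch: GraphBatch, states: Tensor,
                 edge_features: Tensor) -> Tensor:
    """Sum of concat(neighbor state, edge feature) over each node's neighbors."""
    h_src = ad.gather_rows(states, batch.edge_src)
    msgs = ad.concat([h_src, edge_features], axis=-1)
    return ad.scatter_sum_rows(msgs, batch.edge_dst, batch.n_nodes)


def update_step(params: ParamDict, config: MPNNConfig, batch: GraphBatch,
                messages: Tensor, t: int) -> Tensor:
    """h_v = sigma(H_t^{deg(v)} m_v); degrees above max_degree share its matrix."""
    clamped = np.minimum(batch.degrees, config.max_degree)
    pieces = None
    for deg in range(1, config.max_degree + 1):
        idx = np.flatnonzero(clamped == deg)
        if idx.size == 0:
            continue
        rows = ad.gather_rows(messages, idx)
        mapped = ad.matmul(rows, params[f"H.t{t}.d{deg}"])
        scattered = ad.scatter_sum_rows(mapped, idx, batch.n_nodes)
        pieces = scattered if pieces is None else ad.add(pieces, scattered)
    return ad.sigmoid(pieces)


def readout(params: ParamDict, states: Tensor, batch: GraphBatch) -> Tensor:
    """Permutation-invariant graph embedding: project nodes, average per graph."""
    proj = linear(params, "readout", states)
    sums = ad.scatter_sum_rows(proj, batch.graph_index, batch.n_graphs)
    counts = np.bincount(batch.graph_index,
                         minlength=batch.n_graphs).astype(states.dtype)
    return ad.mul(sums, (1.0 / counts)[:, None])


def forward_graph_batch(params: ParamDict, config: MPNNConfig,
                        batch: GraphBatch) -> Tensor:
    """Input encoding, n_steps of message passing, readout.  (B, 128)."""
    dtype = params["enc.W"].dtype
    states = ad.sigmoid(linear(params, "enc",
                               Tensor(batch.node_features.astype(dtype))))
    efeat = Tensor(batch.edge_features.astype(dtype))
    for t in range(config.n_steps):
        messages = message_step(batch, states, efeat)
        states = update_step(params, config, batch, messages, t)
    return readout(params, states, batch)


def encode_graph(config: MPNNConfig, params: ParamDict,
                 graph: MolGraph) -> np.ndarray:
    """128-dim embedding of one molecular graph (inference mode)."""
    if graph.n_atoms == 0:
        raise ValueError("cannot encode an empty graph")
    return forward_graph_batch(params, config, batch_graphs([graph])).data[0]
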