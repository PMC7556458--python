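"""Unrolling recurrent networks through time.

Two unrolling conventions are supported.  In *engineering* time, feedforward
connections take no time: at step t, layer n receives bottom-up input from
layer n-1 at the same step and lateral input from itself at step t-1, and one
readout is taken after each complete sweep.  In *biological* time every
connection (bottom-up and lateral alike) takes one tick.  For networks whose
recurrence is lateral only, the two conventions yield equivalent
computational graphs: the biological-time node (layer n, tick k) computes
exactly the engineering-time activation (layer n, step t = k - n + 1),
neglecting computations that cannot reach a readout.

Nodes are labelled ``("input",)``, ``("layer", n, t)`` (1-based) and
``("readout", t)``; edges carry a kind tag ("bottom_up", "lateral",
"readout").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .network import ModelParams, _batchnorm, _ro_key, _wb_key, _wl_key, layer_defs
from .specs import ArchitectureSpec

Node = tuple
Edge = tuple  # (src, dst, kind)


@dataclass(frozen=True)
class UnrolledGraph:
    mode: str
    nodes: tuple[Node, ...]
    edges: tuple[Edge, ...]
    readouts: tuple[Node, ...]

    def in_edges(self, node: Node) -> list[Edge]:
        return [e for e in self.edges if e[1] == node]


def unroll(spec: ArchitectureSpec, mode: str = "engineering") -> UnrolledGraph:
    """Build the unrolled computational graph for a spec.

    Biological mode is only defined for lateral-only recurrence (any spec of
    this family) and raises for non-recurrent specs run for several steps.
    """
    if mode not in ("engineering", "biological"):
        raise ValueError(f"unknown unrolling mode {mode!r}")
    n_layers = len(layer_defs(spec))
    T = spec.n_timesteps
    has_lateral = spec.is_recurrent
    if mode == "biological" and not has_lateral and T > 1:
        raise ValueError("biological unrolling undefined for non-recurrent specs with T > 1")

    lateral_layers = {li + 1 for li, L in enumerate(layer_defs(spec)) if L.lateral}
    nodes: list[Node] = [("input",)]
    edges: list[Edge] = []
    readouts: list[Node] = []
    for t in range(1, T + 1):
        for n in range(1, n_layers + 1):
            node = ("layer", n, t)
            nodes.append(node)
            src = ("input",) if n == 1 else ("layer", n - 1, t)
            edges.append((src, node, "bottom_up"))
            if n in lateral_layers and t > 1:
                edges.append((("layer", n, t - 1), node, "lateral"))
        ro = ("readout", t)
        nodes.append(ro)
        readouts.append(ro)
        edges.append((("layer", n_layers, t), ro, "readout"))

    if mode == "engineering":
        return UnrolledGraph("engineering", tuple(nodes), tuple(edges), tuple(readouts))

    # biological time: relabel (layer n, step t) -> (layer n, tick t + n - 1);
    # every edge then spans exactly one tick.  The readout for step t fires at
    # tick t + n_layers - 1 (after the sweep that started at tick t).
    def to_tick(node: Node) -> Node:
        if node[0] == "layer":
            _, n, t = node
            return ("layer", n, t + n - 1)
        if node[0] == "readout":
            return ("readout", node[1] + n_layers - 1)
        return node

    bio_nodes = tuple(to_tick(nd) for nd in nodes)
    bio_edges = tuple((to_tick(a), to_tick(b), kind) for a, b, kind in edges)
    bio_readouts = tuple(to_tick(r) for r in readouts)
    return UnrolledGraph("biological", bio_nodes, bio_edges, bio_readouts)


def biological_to_engineering(node: Node, n_layers: int) -> Node:
    """Map a biological-time node onto its engineering-time counterpart."""
    if node[0] == "layer":
        _, n, k = node
        return ("layer", n, k - n + 1)
    if node[0] == "readout":
        return ("readout", node[1] - n_layers + 1)
    return node


def run_biological(spec: ArchitectureSpec, model: ModelParams, x: np.ndarray) -> np.ndarray:
    """Execute the network tick-by-tick in biological time.

    Independent code path from :func:`rvt.network.forward`: activations are
    stored per (layer, tick) and every connection is read from the previous
    tick.  Batch-norm for (layer n, tick k) uses the per-step parameters of
    engineering step k - n + 1.  Returns per-readout probabilities with the
    same (N, T, n_classes) layout as the engineering forward pass, ordered by
    readout tick.
    """
    layers = layer_defs(spec)
    n_layers = len(layers)
    T = spec.n_timesteps
    h: dict[tuple[int, int], np.ndarray] = {}
    pooled: dict[tuple[int, int], np.ndarray] = {}
    probs = []
    for k in range(1, n_layers + T):
        for n in range(1, n_layers + 1):
            t = k - n + 1
            if not 1 <= t <= T:
                continue  # cannot reach a readout; neglected
            L = layers[n - 1]
            bottom = x if n == 1 else pooled[(n - 1, k - 1)]
            z, _ = nn.conv2d_forward(bottom, model.params[_wb_key(spec, n - 1, t - 1)])
            if L.lateral and t > 1:
                zl, _ = nn.conv2d_forward(h[(n, k - 1)], model.params[_wl_key(spec, n - 1, t - 1)])
                z = z + zl
            z, _ = _batchnorm(model, f"layer{n - 1}/bn{t - 1}", z, training=False)
            act, _ = nn.relu_forward(z)
            h[(n, k)] = act
            pooled[(n, k)] = nn.maxpool_forward(act)[0] if L.pool_after else act
        t_ro = k - n_layers + 1
        if 1 <= t_ro <= T:
            g = nn.global_avg_pool(pooled[(n_layers, k)])
            logits = g @ model.params[_ro_key(spec, "W", t_ro - 1)] \
                + model.params[_ro_key(spec, "b", t_ro - 1)]
            probs.append(nn.softmax(logits))
    return np.stack(probs, axis=1)
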