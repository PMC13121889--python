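"""Signed per-atom feature attribution for the affinity model.

Four methods are provided, all targeting the scalar predicted affinity of
one compound (under the masks of the pair being explained, or whole-
molecule masks for a standalone compound):

* ``cam`` — last-layer node activations dotted with the effective linear
  readout weights of the node's branch (requires a linear pooling mode).
* ``grad_cam`` — channel weights are the node-mean of d(yhat)/d(h_last);
  node score is the channel-weighted activation sum, kept SIGNED (no
  rectification) because the ground-truth labels are +-1.
* ``gradient_x_input`` — sum over feature columns of input * gradient,
  for node and edge features.
* ``integrated_gradients`` — trapezoid-rule path integral of the
  gradients from the all-zero-feature baseline on the same topology.

Edge attributions can be redistributed onto endpoint atoms with
:func:`redistribute_edge_to_nodes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from .mol_graphs import MolecularGraph
from .nn import ModelState, forward_compound

METHODS = ("cam", "grad_cam", "gradient_x_input", "integrated_gradients")


@dataclass
class AttributionMap:
    compound_id: str
    method: str
    node_scores: np.ndarray
    edge_scores: np.ndarray | None = None  # per directed edge
    options: dict = field(default_factory=dict)


def _forward_with_grads(state, graph, mask_common, mask_uncommon,
                        x_value=None, e_value=None):
    """Eval-mode forward with the inputs as differentiable leaves; returns
    (forward, x Tensor, e Tensor) after backpropagating from yhat."""
    P = state.as_tensors(requires_grad=False)
    x = ad.Tensor(graph.node_features if x_value is None else x_value,
                  requires_grad=True)
    e = ad.Tensor(graph.edge_features if e_value is None else e_value,
                  requires_grad=True)
    fwd = forward_compound(graph, state, mask_common, mask_uncommon, P,
                           training=False, x_override=x, e_override=e)
    fwd.yhat.backward()
    return fwd, x, e


def _grad_or_zero(t):
    return t.grad if t.grad is not None else np.zeros_like(t.value)


def attribute(
    state: ModelState,
    graph: MolecularGraph,
    method: str,
    options: dict | None = None,
    mask_common=None,
    mask_uncommon=None,
) -> AttributionMap:
    """Attribution map of one compound's predicted affinity."""
    if method not in METHODS:
        raise ValueError(f"unknown attribution method {method!r}; "
                         f"expected one of {METHODS}")
    options = dict(options or {})
    n = graph.n_atoms
    if mask_common is None:
        mask_common = np.ones(n)
        mask_uncommon = np.zeros(n)

    if method == "cam":
        if state.config.pooling not in ("mean", "sum"):
            raise ValueError(
                "CAM requires a linear readout path (mean or sum pooling); "
                f"got pooling={state.config.pooling!r}"
            )
        fwd = forward_compound(graph, state, mask_common, mask_uncommon)
        s = state.config.subgraph_dim
        w_cn = state.params["proj_CN_W"] @ state.params["affinity_W"][:s]
        w_ucn = state.params["proj_UCN_W"] @ state.params["affinity_W"][s:]
        common = np.asarray(mask_common, bool)
        h = fwd.h.value
        scores = np.where(common, h @ w_cn, h @ w_ucn)
        return AttributionMap(graph.compound_id, method, scores, None, options)

    if method == "grad_cam":
        fwd, _, _ = _forward_with_grads(state, graph, mask_common,
                                        mask_uncommon)
        grad_h = _grad_or_zero(fwd.h)
        channel_w = grad_h.mean(axis=0)
        scores = fwd.h.value @ channel_w  # signed: no rectification
        return AttributionMap(graph.compound_id, method, scores, None, options)

    if method == "gradient_x_input":
        fwd, x, e = _forward_with_grads(state, graph, mask_common,
                                        mask_uncommon)
        node = (x.value * _grad_or_zero(x)).sum(axis=1)
        edge = (e.value * _grad_or_zero(e)).sum(axis=1)
        return AttributionMap(graph.compound_id, method, node, edge, options)

    # integrated gradients
    steps = int(options.get("steps", 64))
    options["steps"] = steps
    if steps < 2:
        raise ValueError("integrated gradients needs steps >= 2")
    x0 = graph.node_features
    e0 = graph.edge_features
    acc_x = np.zeros_like(x0)
    acc_e = np.zeros_like(e0)
    for k in range(steps + 1):  # trapezoid rule on steps intervals
        t = k / steps
        w = (0.5 if k in (0, steps) else 1.0) / steps
        _, x, e = _forward_with_grads(state, graph, mask_common,
                                      mask_uncommon,
                                      x_value=t * x0, e_value=t * e0)
        acc_x += w * _grad_or_zero(x)
        acc_e += w * _grad_or_zero(e)
    node = (x0 * acc_x).sum(axis=1)
    edge = (e0 * acc_e).sum(axis=1)
    return AttributionMap(graph.compound_id, "integrated_gradients",
                          node, edge, options)


def redistribute_edge_to_nodes(amap: AttributionMap,
                               graph: MolecularGraph) -> AttributionMap:
    """Fold edge attributions onto endpoint atoms.

    The two directed-edge scores of a bond are first averaged into one
    per-bond score, which then splits half to each endpoint, so the total
    attribution mass (old node sum + per-bond sum) is conserved exactly.
    """
    if amap.edge_scores is None:
        raise ValueError("map has no edge scores to redistribute")
    node = amap.node_scores.astype(float).copy()
    es = amap.edge_scores
    for t, (a, b, *_rest) in enumerate(graph.bonds):
        bond_score = 0.5 * (es[2 * t] + es[2 * t + 1])
        node[a] += 0.5 * bond_score
        node[b] += 0.5 * bond_score
    return AttributionMap(amap.compound_id, amap.method, node, None,
                          dict(amap.options))


def node_level_map(state, graph, method, options=None,
                   mask_common=None, mask_uncommon=None) -> AttributionMap:
    """Attribution map reduced to node scores only (edges redistributed)."""
    amap = attribute(state, graph, method, options, mask_common,
                     mask_uncommon)
    if amap.edge_scores is not None:
        amap = redistribute_edge_to_nodes(amap, graph)
    return amap


def maps_for_pairs(state, pair_list, graphs, method, options=None) -> dict:
    """Node-level maps for both compounds of every pair, computed under
    each pair's own masks: pair_id -> (map_i, map_j)."""
    out = {}
    for p in pair_list:
        out[p.pair_id] = (
            node_level_map(state, graphs[p.i], method, options,
                           p.mask_common_i, p.mask_uncommon_i),
            node_level_map(state, graphs[p.j], method, options,
                           p.mask_common_j, p.mask_uncommon_j),
        )
    return out


def export_map(amap: AttributionMap) -> dict:
    """JSON-ready dict for one compound's attribution map."""
    out = {
        "compound_id": amap.compound_id,
        "method": amap.method,
        "node_scores": [float(v) for v in amap.node_scores],
    }
    if amap.edge_scores is not None:
        out["edge_scores"] = [float(v) for v in amap.edge_scores]
    return out
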