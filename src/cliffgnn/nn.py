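"""The message-passing affinity model with masked subgraph readouts.

Architecture: 50-d atom and 10-d bond features are linearly embedded into a
shared 32-d space; three message-passing layers (edge-conditioned
convolution by default, GIN or GAT as alternatives) with additive
neighbour aggregation, each followed by batch normalization and ReLU,
produce node embeddings.  A pair's common/uncommon binary masks split the
node set into two subgraphs; each is pooled into a 32-d readout, projected
to 16-d, and the concatenation feeds a final linear affinity head.  Two
scalar subgraph heads (weights beta_CN / beta_UCN) predict the common- and
uncommon-part contribution to a pair's activity difference; these are the
parameters the group-lasso penalties act on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autodiff as ad
from .mol_graphs import MolecularGraph, N_ATOM_FEATURES, N_BOND_FEATURES

BACKBONES = ("edge_conditioned", "gin", "gat")
POOLINGS = ("mean", "sum", "max", "attention")
_DEFAULT_POOLING = {"edge_conditioned": "mean", "gin": "sum", "gat": "mean"}
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "edge_conditioned"
    n_layers: int = 3
    hidden_dim: int = 32
    subgraph_dim: int = 16
    pooling: str | None = None  # None -> backbone default
    head_input: str = "projected"  # subgraph heads consume the 16-d projections

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"backbone must be one of {BACKBONES}")
        if self.pooling is None:
            object.__setattr__(self, "pooling", _DEFAULT_POOLING[self.backbone])
        if self.pooling not in POOLINGS:
            raise ValueError(f"pooling must be one of {POOLINGS}")
        if min(self.n_layers, self.hidden_dim, self.subgraph_dim) <= 0:
            raise ValueError("layer count and dimensions must be positive")


@dataclass
class ModelState:
    """All learnable parameters plus batch-norm running statistics."""

    config: ModelConfig
    params: dict  # name -> ndarray
    bn_running: dict  # name -> ndarray
    seed: int = 0

    def as_tensors(self, requires_grad: bool = True) -> dict:
        return {k: ad.Tensor(v, requires_grad=requires_grad)
                for k, v in self.params.items()}

    def apply_update(self, new_values: dict):
        for k, v in new_values.items():
            self.params[k] = np.asarray(v, dtype=np.float64)

    def copy(self) -> "ModelState":
        return ModelState(
            config=self.config,
            params={k: v.copy() for k, v in self.params.items()},
            bn_running={k: v.copy() for k, v in self.bn_running.items()},
            seed=self.seed,
        )

    # ------------------------------------------------------------ checkpoint
    def save(self, path):
        payload = {
            "version": CHECKPOINT_VERSION,
            "seed": self.seed,
            "config": asdict(self.config),
            "params": {k: v.tolist() for k, v in self.params.items()},
            "bn_running": {k: v.tolist() for k, v in self.bn_running.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ModelState":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version in {path}")
        return cls(
            config=ModelConfig(**payload["config"]),
            params={k: np.asarray(v, dtype=np.float64)
                    for k, v in payload["params"].items()},
            bn_running={k: np.asarray(v, dtype=np.float64)
                        for k, v in payload["bn_running"].items()},
            seed=payload["seed"],
        )


def _glorot(rng, shape):
    fan_in, fan_out = shape[0], shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


def init_state(config: ModelConfig, seed: int = 0) -> ModelState:
    """Glorot-initialized parameters; biases and GIN epsilons start at zero."""
    rng = np.random.default_rng(seed)
    d = config.hidden_dim
    s = config.subgraph_dim
    p = {
        "node_embed_W": _glorot(rng, (N_ATOM_FEATURES, d)),
        "node_embed_b": np.zeros(d),
        "edge_embed_W": _glorot(rng, (N_BOND_FEATURES, d)),
        "edge_embed_b": np.zeros(d),
    }
    bn = {}
    for layer in range(config.n_layers):
        if config.backbone == "edge_conditioned":
            p[f"layer{layer}_self_W"] = _glorot(rng, (d, d))
            p[f"layer{layer}_self_b"] = np.zeros(d)
            p[f"layer{layer}_edge_net_W"] = _glorot(rng, (d, d * d))
            p[f"layer{layer}_edge_net_b"] = np.zeros(d * d)
        elif config.backbone == "gin":
            p[f"layer{layer}_eps"] = np.zeros(())
            p[f"layer{layer}_mlp_W1"] = _glorot(rng, (d, d))
            p[f"layer{layer}_mlp_b1"] = np.zeros(d)
            p[f"layer{layer}_mlp_W2"] = _glorot(rng, (d, d))
            p[f"layer{layer}_mlp_b2"] = np.zeros(d)
        else:  # gat
            p[f"layer{layer}_W"] = _glorot(rng, (d, d))
            p[f"layer{layer}_b"] = np.zeros(d)
            p[f"layer{layer}_att_src"] = _glorot(rng, (d, 1)).ravel()
            p[f"layer{layer}_att_dst"] = _glorot(rng, (d, 1)).ravel()
        p[f"layer{layer}_bn_gamma"] = np.ones(d)
        p[f"layer{layer}_bn_beta"] = np.zeros(d)
        bn[f"layer{layer}_mean"] = np.zeros(d)
        bn[f"layer{layer}_var"] = np.ones(d)
    p.update(
        head_CN_W=_glorot(rng, (d, 1)).ravel(),
        head_CN_b=np.zeros(()),
        head_UCN_W=_glorot(rng, (d, 1)).ravel(),
        head_UCN_b=np.zeros(()),
        proj_CN_W=_glorot(rng, (d, s)),
        proj_CN_b=np.zeros(s),
        proj_UCN_W=_glorot(rng, (d, s)),
        proj_UCN_b=np.zeros(s),
        affinity_W=_glorot(rng, (2 * s, 1)).ravel(),
        affinity_b=np.zeros(()),
        beta_CN=_glorot(rng, (s, 1)).ravel(),
        b_CN=np.zeros(()),
        beta_UCN=_glorot(rng, (s, 1)).ravel(),
        b_UCN=np.zeros(()),
    )
    if config.pooling == "attention":
        p["pool_gate"] = _glorot(rng, (d, 1)).ravel()
    return ModelState(config=config, params=p, bn_running=bn, seed=seed)


# ------------------------------------------------------------- propagation
def _batchnorm(z, P, bn_running, layer, training):
    gamma = P[f"layer{layer}_bn_gamma"]
    beta = P[f"layer{layer}_bn_beta"]
    if training and z.shape[0] > 1:
        mu = ad.mean_(z, axis=0, keepdims=True)
        var = ad.mean_(ad.square(z - mu), axis=0, keepdims=True)
        bn_running[f"layer{layer}_mean"] = (
            (1 - _BN_MOMENTUM) * bn_running[f"layer{layer}_mean"]
            + _BN_MOMENTUM * mu.value.ravel()
        )
        bn_running[f"layer{layer}_var"] = (
            (1 - _BN_MOMENTUM) * bn_running[f"layer{layer}_var"]
            + _BN_MOMENTUM * var.value.ravel()
        )
        norm = (z - mu) / ad.sqrt(var + _BN_EPS)
    else:
        mu = bn_running[f"layer{layer}_mean"]
        var = bn_running[f"layer{layer}_var"]
        norm = (z - mu) * (1.0 / np.sqrt(var + _BN_EPS))
    return norm * gamma + beta


def _segment_softmax(scores, idx, n):
    """Softmax of `scores` within segments given by `idx` (numerically
    shifted by the detached per-segment max)."""
    shift = np.full(n, -np.inf)
    np.maximum.at(shift, idx, scores.value)
    shift[~np.isfinite(shift)] = 0.0
    z = ad.exp(scores - ad.Tensor(shift[idx]))
    denom = ad.segment_sum(ad.reshape(z, (-1, 1)), idx, n)
    return z / ad.reshape(ad.gather_rows(denom, idx), (-1,))


def propagate(x, e, src, dst, n, P, config: ModelConfig, bn_running,
              training: bool = False):
    """Run embedding + `n_layers` message-passing rounds on one (possibly
    batched disjoint-union) graph; returns the (n, hidden) node embeddings."""
    h = x @ P["node_embed_W"] + P["node_embed_b"]
    d = config.hidden_dim
    if config.backbone == "edge_conditioned":
        e_emb = e @ P["edge_embed_W"] + P["edge_embed_b"]
    for layer in range(config.n_layers):
        if config.backbone == "edge_conditioned":
            w_e = ad.reshape(
                e_emb @ P[f"layer{layer}_edge_net_W"]
                + P[f"layer{layer}_edge_net_b"],
                (-1, d, d),
            )
            msg = ad.bmm_vec(w_e, ad.gather_rows(h, src))
            agg = ad.segment_sum(msg, dst, n)
            z = h @ P[f"layer{layer}_self_W"] + P[f"layer{layer}_self_b"] + agg
        elif config.backbone == "gin":
            agg = ad.segment_sum(ad.gather_rows(h, src), dst, n)
            z = (1.0 + P[f"layer{layer}_eps"]) * h + agg
            z = ad.relu(z @ P[f"layer{layer}_mlp_W1"]
                        + P[f"layer{layer}_mlp_b1"])
            z = z @ P[f"layer{layer}_mlp_W2"] + P[f"layer{layer}_mlp_b2"]
        else:  # gat, with self-loops so every node attends to itself
            wh = h @ P[f"layer{layer}_W"]
            src_a = np.concatenate([src, np.arange(n)])
            dst_a = np.concatenate([dst, np.arange(n)])
            s_src = wh @ ad.reshape(P[f"layer{layer}_att_src"], (d, 1))
            s_dst = wh @ ad.reshape(P[f"layer{layer}_att_dst"], (d, 1))
            scores = ad.leaky_relu(
                ad.reshape(ad.gather_rows(s_src, src_a), (-1,))
                + ad.reshape(ad.gather_rows(s_dst, dst_a), (-1,))
            )
            alpha = _segment_softmax(scores, dst_a, n)
            msg = ad.reshape(alpha, (-1, 1)) * ad.gather_rows(wh, src_a)
            z = ad.segment_sum(msg, dst_a, n) + P[f"layer{layer}_b"]
        h = ad.relu(_batchnorm(z, P, bn_running, layer, training))
    return h


def embed_and_propagate(graph: MolecularGraph, state: ModelState,
                        P: dict | None = None, training: bool = False):
    """Node embeddings (n, hidden) for one featurized compound."""
    if graph.node_features is None:
        raise ValueError(f"graph {graph.compound_id} is not featurized")
    if graph.node_features.shape[1] != N_ATOM_FEATURES:
        raise ValueError("node feature width does not match the model")
    if P is None:
        P = state.as_tensors(requires_grad=False)
    x = ad.Tensor(graph.node_features)
    e = ad.Tensor(graph.edge_features)
    src, dst = graph.directed_edge_index
    return propagate(x, e, src, dst, graph.n_atoms, P, state.config,
                     state.bn_running, training)


# ---------------------------------------------------------------- readouts
def masked_readout(h, mask, pooling: str = "mean", gate=None):
    """Pool the rows of `h` selected by the binary `mask` into one vector.

    Mean pooling divides by the number of selected nodes (not n); an
    all-zero mask yields the zero vector for every pooling mode.
    """
    mask = np.asarray(mask, dtype=np.float64)
    if not isinstance(h, ad.Tensor):
        h = ad.Tensor(h)
    if mask.shape[0] != h.shape[0]:
        raise ValueError("mask length does not match node count")
    k = float(mask.sum())
    if k == 0:
        return ad.Tensor(np.zeros(h.shape[1]))
    if pooling == "sum":
        return ad.reshape(ad.Tensor(mask.reshape(1, -1)) @ h, (-1,))
    if pooling == "mean":
        return ad.reshape(ad.Tensor(mask.reshape(1, -1) / k) @ h, (-1,))
    idx = np.flatnonzero(mask)
    hs = ad.gather_rows(h, idx)
    if pooling == "max":
        return ad.max_rows(hs)
    if pooling == "attention":
        if gate is None:
            raise ValueError("attention pooling requires the gate vector")
        d = h.shape[1]
        scores = ad.reshape(hs @ ad.reshape(gate, (d, 1)), (-1,))
        alpha = _segment_softmax(scores, np.zeros(len(idx), dtype=np.intp), 1)
        return ad.reshape(ad.reshape(alpha, (1, -1)) @ hs, (-1,))
    raise ValueError(f"unknown pooling {pooling!r}")


def affinity_head(g_cn, g_ucn, P):
    """Scalar affinity from the concatenated projected readouts."""
    g = ad.concat([g_cn, g_ucn], axis=0)
    return ad.sum_(g * P["affinity_W"]) + P["affinity_b"]


def subgraph_head(g, P, which: str):
    """MLP_CN / MLP_UCN: beta . g + b on a subgraph readout."""
    beta = P[f"beta_{which}"]
    bias = P[f"b_{which}"]
    return ad.sum_(g * beta) + bias


@dataclass
class CompoundForward:
    """Tape handles from one compound's forward pass."""

    compound_id: str
    x: object  # input node feature Tensor
    e: object  # input edge feature Tensor
    h: object  # last-layer node embeddings Tensor (n, hidden)
    r_cn: object  # 32-d pooled readouts (pre-projection)
    r_ucn: object
    g_cn: object  # 16-d projected readouts
    g_ucn: object
    yhat: object  # scalar Tensor
    mask_common: np.ndarray = None
    mask_uncommon: np.ndarray = None


@dataclass
class PairForward:
    forward_i: CompoundForward
    forward_j: CompoundForward
    delta_cn: object  # Tensor
    delta_ucn: object  # Tensor

    @property
    def yhat_i(self):
        return float(self.forward_i.yhat.value)

    @property
    def yhat_j(self):
        return float(self.forward_j.yhat.value)


def forward_compound(
    graph: MolecularGraph,
    state: ModelState,
    mask_common=None,
    mask_uncommon=None,
    P: dict | None = None,
    training: bool = False,
    x_override=None,
    e_override=None,
) -> CompoundForward:
    """Full single-compound forward pass.

    Without explicit masks the whole molecule is treated as common
    (standalone prediction); within a pair the pair's masks are used.
    `x_override`/`e_override` let attribution methods substitute
    interpolated input tensors.
    """
    if graph.node_features is None:
        raise ValueError(f"graph {graph.compound_id} is not featurized")
    n = graph.n_atoms
    if mask_common is None:
        mask_common = np.ones(n)
        mask_uncommon = np.zeros(n)
    mask_common = np.asarray(mask_common, dtype=np.float64)
    mask_uncommon = np.asarray(mask_uncommon, dtype=np.float64)
    if mask_common.shape[0] != n or mask_uncommon.shape[0] != n:
        raise ValueError(
            f"mask length does not match atom count for {graph.compound_id}"
        )
    if P is None:
        P = state.as_tensors(requires_grad=False)
    x = x_override if x_override is not None else ad.Tensor(graph.node_features)
    e = e_override if e_override is not None else ad.Tensor(graph.edge_features)
    src, dst = graph.directed_edge_index
    cfg = state.config
    h = propagate(x, e, src, dst, n, P, cfg, state.bn_running, training)
    gate = P.get("pool_gate")
    r_cn = masked_readout(h, mask_common, cfg.pooling, gate)
    r_ucn = masked_readout(h, mask_uncommon, cfg.pooling, gate)
    g_cn = ad.reshape(ad.reshape(r_cn, (1, -1)) @ P["proj_CN_W"], (-1,)) \
        + P["proj_CN_b"]
    g_ucn = ad.reshape(ad.reshape(r_ucn, (1, -1)) @ P["proj_UCN_W"], (-1,)) \
        + P["proj_UCN_b"]
    yhat = affinity_head(g_cn, g_ucn, P)
    if not np.isfinite(yhat.value):
        raise FloatingPointError(f"non-finite prediction for {graph.compound_id}")
    return CompoundForward(
        compound_id=graph.compound_id,
        x=x, e=e, h=h,
        r_cn=r_cn, r_ucn=r_ucn, g_cn=g_cn, g_ucn=g_ucn, yhat=yhat,
        mask_common=mask_common, mask_uncommon=mask_uncommon,
    )


def node_attribution_scores(fwd: CompoundForward, P) -> np.ndarray:
    """Per-node scores from the 32->1 attribution heads (CAM-style readout);
    these heads do not enter the affinity prediction path."""
    h = fwd.h.value
    common = fwd.mask_common.astype(bool)
    s_cn = h @ P["head_CN_W"].value + P["head_CN_b"].value
    s_ucn = h @ P["head_UCN_W"].value + P["head_UCN_b"].value
    return np.where(common, s_cn, s_ucn)


def subgraph_delta(fwd_i: CompoundForward, fwd_j: CompoundForward, P):
    """(delta_CN, delta_UCN): head differences between the two compounds;
    the head biases cancel exactly."""
    which = "CN"
    d_cn = subgraph_head(fwd_i.g_cn, P, which) - subgraph_head(fwd_j.g_cn, P, which)
    d_ucn = subgraph_head(fwd_i.g_ucn, P, "UCN") - subgraph_head(
        fwd_j.g_ucn, P, "UCN"
    )
    return d_cn, d_ucn


def forward_pair(pair, graphs: dict, state: ModelState,
                 P: dict | None = None, training: bool = False) -> PairForward:
    """Forward both compounds of a pair with the pair's masks."""
    if P is None:
        P = state.as_tensors(requires_grad=False)
    g_i, g_j = graphs[pair.i], graphs[pair.j]
    if pair.mask_common_i.shape[0] != g_i.n_atoms or \
            pair.mask_common_j.shape[0] != g_j.n_atoms:
        raise ValueError(f"mask/graph length mismatch for pair {pair.pair_id}")
    fwd_i = forward_compound(g_i, state, pair.mask_common_i,
                             pair.mask_uncommon_i, P, training)
    fwd_j = forward_compound(g_j, state, pair.mask_common_j,
                             pair.mask_uncommon_j, P, training)
    d_cn, d_ucn = subgraph_delta(fwd_i, fwd_j, P)
    return PairForward(fwd_i, fwd_j, d_cn, d_ucn)
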