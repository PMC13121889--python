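"""Seeded training loop with plateau LR decay and early stopping, plus the
k-fold cross-validation driver.

Minibatches are processed as disjoint-union graphs: the unique compounds of
a batch are concatenated into one big graph, propagated once, and the
per-pair masked readouts are recovered with a constant selection matrix.
This keeps the per-step cost nearly independent of how many pairs share a
compound, which is the normal situation in congeneric series.  Batch
normalization uses the union-batch statistics during training and running
statistics at evaluation time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from . import nn as nncore
from .objectives import LossConfig, penalty_term
from .pairs import ACPair, make_fold_splits

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainSchedule:
    max_epochs: int = 300
    batch_size: int = 32
    lr: float = 1e-3
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    min_lr: float = 1e-5
    early_stop_patience: int = 30
    improvement_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie in (0, 1)")
        if min(self.plateau_patience, self.early_stop_patience) < 1:
            raise ValueError("patience values must be >= 1")


@dataclass
class TrainResult:
    state: nncore.ModelState
    history: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_rmse: float = float("inf")
    stopped_epoch: int = 0
    reason: str = ""


# ----------------------------------------------------------- batched pass
def _union(pair_list, graphs):
    """Disjoint union of the unique structures referenced by `pair_list`.

    Compounds parsed from the same SMILES string share atom ordering and
    node features, so they are embedded once and their (per-compound)
    masks all address the same block of the union graph.
    """
    key_offset = {}
    offsets = {}
    xs, es, srcs, dsts = [], [], [], []
    n = 0
    for p in pair_list:
        for cid in (p.i, p.j):
            if cid in offsets:
                continue
            g = graphs[cid]
            key = g.source_smiles or cid
            if key in key_offset:
                offsets[cid] = key_offset[key]
                continue
            key_offset[key] = n
            offsets[cid] = n
            xs.append(g.node_features)
            es.append(g.edge_features)
            srcs.append(g.directed_edge_index[0] + n)
            dsts.append(g.directed_edge_index[1] + n)
            n += g.n_atoms
    x = np.vstack(xs)
    e = np.vstack(es) if es else np.zeros((0, 10))
    src = np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.intp)
    dst = np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.intp)
    return x, e, src, dst, n, offsets


def _selection(pair_list, offsets, n, pooling):
    """Constant (2B, n) readout matrices: rows 0..B-1 select compound i of
    each pair, rows B..2B-1 compound j; one matrix per branch."""
    b = len(pair_list)
    s_cn = np.zeros((2 * b, n))
    s_ucn = np.zeros((2 * b, n))
    for k, p in enumerate(pair_list):
        for row, cid, mc, mu in (
            (k, p.i, p.mask_common_i, p.mask_uncommon_i),
            (b + k, p.j, p.mask_common_j, p.mask_uncommon_j),
        ):
            off = offsets[cid]
            for s, m in ((s_cn, mc), (s_ucn, mu)):
                tot = m.sum()
                if tot > 0:
                    w = m / tot if pooling == "mean" else m
                    s[row, off:off + len(m)] = w
    return s_cn, s_ucn


def batch_objective(pair_list, graphs, state, P, loss_cfg, training):
    """Objective over a batch of pairs via one union-graph forward.

    Falls back to per-pair forwards for pooling modes (max, attention)
    that are not a linear map of the node embeddings.  Returns
    (loss Tensor, breakdown dict, predictions array aligned to
    [i-compounds..., j-compounds...]).
    """
    cfg = state.config
    if cfg.pooling not in ("mean", "sum"):
        from .objectives import total_objective

        fwds = [nncore.forward_pair(p, graphs, state, P, training)
                for p in pair_list]
        loss, breakdown = total_objective(fwds, pair_list, P, loss_cfg)
        yhat = np.array([f.yhat_i for f in fwds] + [f.yhat_j for f in fwds])
        return loss, breakdown, yhat
    b = len(pair_list)
    x, e, src, dst, n, offsets = _union(pair_list, graphs)
    h = nncore.propagate(ad.Tensor(x), ad.Tensor(e), src, dst, n, P,
                         cfg, state.bn_running, training)
    s_cn, s_ucn = _selection(pair_list, offsets, n, cfg.pooling)
    r_cn = ad.Tensor(s_cn) @ h
    r_ucn = ad.Tensor(s_ucn) @ h
    g_cn = r_cn @ P["proj_CN_W"] + P["proj_CN_b"]
    g_ucn = r_ucn @ P["proj_UCN_W"] + P["proj_UCN_b"]
    g_all = ad.concat([g_cn, g_ucn], axis=1)
    yhat = ad.reshape(
        g_all @ ad.reshape(P["affinity_W"], (-1, 1)), (-1,)
    ) + P["affinity_b"]
    y = np.array([p.y_i for p in pair_list] + [p.y_j for p in pair_list])
    resid = yhat - ad.Tensor(y)
    mse_mean = ad.sum_(ad.square(resid)) * (1.0 / b)  # per-pair compound sums
    mlp_cn = ad.reshape(g_cn @ ad.reshape(P["beta_CN"], (-1, 1)), (-1,)) \
        + P["b_CN"]
    mlp_ucn = ad.reshape(g_ucn @ ad.reshape(P["beta_UCN"], (-1, 1)), (-1,)) \
        + P["b_UCN"]
    d_cn = mlp_cn[np.arange(b)] - mlp_cn[np.arange(b, 2 * b)]
    d_ucn = mlp_ucn[np.arange(b)] - mlp_ucn[np.arange(b, 2 * b)]
    dy = np.array([p.delta_y for p in pair_list])
    node_resid = (loss_cfg.lambda_cn * d_cn + loss_cfg.lambda_ucn * d_ucn
                  - ad.Tensor(dy))
    node_mean = ad.sum_(ad.square(node_resid)) * (1.0 / b)
    pen = penalty_term(P, loss_cfg)
    total = mse_mean + node_mean + pen
    breakdown = {
        "mse": float(mse_mean.value),
        "node": float(node_mean.value),
        "penalty": float(pen.value),
        "total": float(total.value),
    }
    for name, v in breakdown.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite objective term: {name}")
    return total, breakdown, yhat.value.copy()


def predict_pairs(pair_list, graphs, state):
    """Evaluation-mode predictions for every pair compound.

    Returns (yhat, y) arrays of length 2B ordered [i..., j...]."""
    P = state.as_tensors(requires_grad=False)
    cfg = state.config
    y = np.array([p.y_i for p in pair_list] + [p.y_j for p in pair_list])
    if cfg.pooling in ("mean", "sum"):
        x, e, src, dst, n, offsets = _union(pair_list, graphs)
        h = nncore.propagate(ad.Tensor(x), ad.Tensor(e), src, dst, n, P,
                             cfg, state.bn_running, training=False)
        s_cn, s_ucn = _selection(pair_list, offsets, n, cfg.pooling)
        g_cn = (ad.Tensor(s_cn) @ h) @ P["proj_CN_W"] + P["proj_CN_b"]
        g_ucn = (ad.Tensor(s_ucn) @ h) @ P["proj_UCN_W"] + P["proj_UCN_b"]
        g_all = ad.concat([g_cn, g_ucn], axis=1)
        yhat = ad.reshape(
            g_all @ ad.reshape(P["affinity_W"], (-1, 1)), (-1,)
        ) + P["affinity_b"]
        return yhat.value.copy(), y
    fwds = [nncore.forward_pair(p, graphs, state, P) for p in pair_list]
    return np.array([f.yhat_i for f in fwds] + [f.yhat_j for f in fwds]), y


def _val_rmse(pair_list, graphs, state):
    yhat, y = predict_pairs(pair_list, graphs, state)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for k, g in grads.items():
            if g is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            params[k] = params[k] - self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps
            )


def train_model(
    train_pairs: list[ACPair],
    val_pairs: list[ACPair],
    graphs: dict,
    model_cfg: nncore.ModelConfig,
    loss_cfg: LossConfig,
    schedule: TrainSchedule,
) -> TrainResult:
    """Adam training of the full objective with plateau LR decay and early
    stopping on validation RMSE; fully reproducible given the seed."""
    if not train_pairs:
        raise ValueError("empty training pair set")
    if not val_pairs:
        raise ValueError("empty validation pair set; early stopping undefined")
    state = nncore.init_state(model_cfg, seed=schedule.seed)
    result = TrainResult(state=state.copy())
    if schedule.max_epochs == 0:
        result.reason = "max_epochs=0"
        return result
    shuffle_seed = int(
        np.random.SeedSequence([schedule.seed, 7919]).generate_state(1)[0]
        % (2**31)
    )
    rng = np.random.default_rng(shuffle_seed)
    opt = _Adam(state.params, schedule.lr)
    lr = schedule.lr
    best_rmse = float("inf")
    since_improve = 0
    since_plateau = 0
    for epoch in range(schedule.max_epochs):
        order = rng.permutation(len(train_pairs))
        epoch_terms = []
        try:
            for start in range(0, len(order), schedule.batch_size):
                batch = [train_pairs[k]
                         for k in order[start:start + schedule.batch_size]]
                P = state.as_tensors(requires_grad=True)
                loss, breakdown, _ = batch_objective(
                    batch, graphs, state, P, loss_cfg, training=True
                )
                loss.backward()
                opt.lr = lr
                opt.step(state.params, {k: t.grad for k, t in P.items()})
                epoch_terms.append(breakdown)
        except FloatingPointError as err:
            result.reason = f"diverged: {err}"
            result.stopped_epoch = epoch
            log.warning("training aborted at epoch %d: %s", epoch, err)
            return result
        val_rmse = _val_rmse(val_pairs, graphs, state)
        mean_terms = {k: float(np.mean([t[k] for t in epoch_terms]))
                      for k in epoch_terms[0]}
        result.history.append(
            {"epoch": epoch, "lr": lr, "val_rmse": val_rmse, **mean_terms}
        )
        improved = val_rmse < best_rmse - schedule.improvement_tol
        if improved:
            best_rmse = val_rmse
            result.state = state.copy()
            result.best_epoch = epoch
            result.best_val_rmse = val_rmse
            since_improve = 0
            since_plateau = 0
        else:
            since_improve += 1
            since_plateau += 1
        if since_plateau >= schedule.plateau_patience:
            lr = max(lr * schedule.plateau_factor, schedule.min_lr)
            since_plateau = 0
        if since_improve >= schedule.early_stop_patience:
            result.reason = "early_stop"
            result.stopped_epoch = epoch
            return result
    result.reason = "max_epochs"
    result.stopped_epoch = schedule.max_epochs - 1
    return result


# --------------------------------------------------------- cross-validation
@dataclass
class CVResult:
    folds: list
    rmse_mean: float
    rmse_sd: float
    pcc_mean: float
    pcc_sd: float
    rmse_weighted: float
    pcc_weighted: float


def cross_validate(
    compounds,
    pairs: list[ACPair],
    graphs: dict,
    model_cfg: nncore.ModelConfig,
    loss_cfg: LossConfig,
    schedule: TrainSchedule,
    k: int = 5,
    fractions=(0.7, 0.1, 0.2),
    seed: int = 0,
) -> CVResult:
    """k independent seeded splits; per-fold training and test evaluation.

    Aggregates report the plain mean +- sd over folds and the
    pair-count-weighted means (weights = number of test pairs per fold).
    """
    from scipy import stats

    pair_by_id = {p.pair_id: p for p in pairs}
    splits = make_fold_splits(compounds, pairs, k=k, fractions=fractions,
                              seed=seed)
    folds = []
    for split in splits:
        test_pairs = [pair_by_id[pid] for pid in split.test_pairs]
        train_pairs = [pair_by_id[pid] for pid in split.train_pairs]
        val_pairs = [pair_by_id[pid] for pid in split.val_pairs]
        for p in test_pairs:  # leakage re-check: first-ligand rule
            assert p.i not in split.train_compounds, (
                f"leakage: test pair {p.pair_id} first ligand in train set"
            )
        if not test_pairs:
            log.warning("fold %d has no test pairs; skipped", split.fold)
            continue
        fold_seed = int(
            np.random.SeedSequence([seed, split.fold, 104729])
            .generate_state(1)[0] % (2**31)
        )
        fold_schedule = TrainSchedule(
            **{**schedule.__dict__, "seed": fold_seed}
        )
        tr = train_model(train_pairs, val_pairs, graphs, model_cfg,
                         loss_cfg, fold_schedule)
        yhat, y = predict_pairs(test_pairs, graphs, tr.state)
        rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
        pcc = float(stats.pearsonr(yhat, y)[0]) if np.std(yhat) > 0 else \
            float("nan")
        folds.append({
            "fold": split.fold,
            "train_result": tr,
            "split": split,
            "test_rmse": rmse,
            "test_pcc": pcc,
            "n_test_pairs": len(test_pairs),
        })
    if not folds:
        raise ValueError("no usable folds")
    rmses = np.array([f["test_rmse"] for f in folds])
    pccs = np.array([f["test_pcc"] for f in folds])
    w = np.array([f["n_test_pairs"] for f in folds], dtype=float)
    w = w / w.sum()
    return CVResult(
        folds=folds,
        rmse_mean=float(rmses.mean()),
        rmse_sd=float(rmses.std(ddof=1)) if len(folds) > 1 else 0.0,
        pcc_mean=float(np.nanmean(pccs)),
        pcc_sd=float(np.nanstd(pccs, ddof=1)) if len(folds) > 1 else 0.0,
        rmse_weighted=float((w * rmses).sum()),
        pcc_weighted=float((w * pccs).sum()),
    )
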