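"""Training objective: affinity MSE + node-level pair loss + structured
sparsity penalties on the two subgraph-head weight groups.

The node-level loss ties the predicted common/uncommon activity-difference
parts to the observed difference of a cliff pair:

    L_N = (lambda_CN * dyhat_CN + lambda_UCN * dyhat_UCN - dy)^2

The group lasso penalty treats beta_CN and beta_UCN (the subgraph-head
weights) as two groups, lambda * (sqrt(p_CN)||beta_CN||_2 +
sqrt(p_UCN)||beta_UCN||_2); the sparse group lasso mixes in an L1 term,
(1-alpha) * GL + alpha * lambda * ||beta||_1, so alpha=0 recovers the
group lasso and alpha=1 the lasso.  Penalties enter the objective as
differentiable terms with subgradient 0 at the origin; the closed-form
proximal operators are provided for exact-sparsity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad

PENALTIES = ("none", "group_lasso", "sparse_group_lasso")
MODES = ("N", "UCN_only")
GROUP_WEIGHTS = ("sqrt", "linear")


@dataclass(frozen=True)
class LossConfig:
    lambda_cn: float = 1.0
    lambda_ucn: float = 1.0
    penalty: str = "none"
    lambda_pen: float = 1e-3
    alpha: float = 0.5
    mode: str = "N"
    group_size_weight: str = "sqrt"  # sqrt(p_g) weighting, the GL convention

    def __post_init__(self):
        if self.penalty not in PENALTIES:
            raise ValueError(f"penalty must be one of {PENALTIES}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.group_size_weight not in GROUP_WEIGHTS:
            raise ValueError(f"group_size_weight must be one of {GROUP_WEIGHTS}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if min(self.lambda_cn, self.lambda_ucn, self.lambda_pen) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.mode == "UCN_only":
            object.__setattr__(self, "lambda_cn", 0.0)


def _as_tensor(x):
    return x if isinstance(x, ad.Tensor) else ad.Tensor(np.asarray(x, float))


def mse_loss(predictions, targets):
    """Sum of squared affinity residuals over the compounds of a pair
    (or any matched prediction/target lists)."""
    if len(predictions) != len(targets):
        raise ValueError("prediction/target length mismatch")
    if len(predictions) == 0:
        raise ValueError("empty prediction list")
    total = None
    for yhat, y in zip(predictions, targets):
        term = ad.square(_as_tensor(yhat) - float(y))
        total = term if total is None else total + term
    return total


def node_pair_loss(delta_cn, delta_ucn, delta_y, cfg: LossConfig):
    """Single squared residual linking the weighted subgraph-head deltas to
    the observed activity difference; with mode="UCN_only" this reduces to
    the uncommon-only baseline (lambda_CN = 0)."""
    resid = (
        cfg.lambda_cn * _as_tensor(delta_cn)
        + cfg.lambda_ucn * _as_tensor(delta_ucn)
        - float(delta_y)
    )
    return ad.square(resid)


def _group_term(beta, weight_mode):
    beta = _as_tensor(beta)
    p = beta.value.size
    w = np.sqrt(p) if weight_mode == "sqrt" else float(p)
    return w * ad.l2_norm(beta)


def group_lasso_penalty(beta_cn, beta_ucn, lambda_pen,
                        group_size_weight: str = "sqrt"):
    """lambda * (sqrt(p_CN)||beta_CN||_2 + sqrt(p_UCN)||beta_UCN||_2);
    head biases are never penalized."""
    return lambda_pen * (
        _group_term(beta_cn, group_size_weight)
        + _group_term(beta_ucn, group_size_weight)
    )


def sparse_group_lasso_penalty(beta_cn, beta_ucn, lambda_pen, alpha,
                               group_size_weight: str = "sqrt"):
    """(1-alpha) * group lasso + alpha * lambda * ||(beta_CN, beta_UCN)||_1."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    gl = group_lasso_penalty(beta_cn, beta_ucn, lambda_pen, group_size_weight)
    l1 = lambda_pen * (
        ad.sum_(ad.abs_(_as_tensor(beta_cn)))
        + ad.sum_(ad.abs_(_as_tensor(beta_ucn)))
    )
    return (1.0 - alpha) * gl + alpha * l1


def penalty_term(P, cfg: LossConfig):
    """The configured penalty on the subgraph-head weight tensors."""
    if cfg.penalty == "none":
        return ad.Tensor(0.0)
    if cfg.penalty == "group_lasso":
        return group_lasso_penalty(P["beta_CN"], P["beta_UCN"],
                                   cfg.lambda_pen, cfg.group_size_weight)
    return sparse_group_lasso_penalty(P["beta_CN"], P["beta_UCN"],
                                      cfg.lambda_pen, cfg.alpha,
                                      cfg.group_size_weight)


def total_objective(forwards, batch_pairs, P, cfg: LossConfig):
    """Batch objective: mean per-pair MSE + mean per-pair node loss +
    penalty (the penalty is not batch-scaled).  Returns (loss Tensor,
    per-term breakdown dict of floats)."""
    if len(forwards) != len(batch_pairs) or not forwards:
        raise ValueError("batch forwards and pairs must align and be nonempty")
    n = float(len(batch_pairs))
    mse_total = None
    node_total = None
    for fwd, pair in zip(forwards, batch_pairs):
        m = mse_loss([fwd.forward_i.yhat, fwd.forward_j.yhat],
                     [pair.y_i, pair.y_j])
        nl = node_pair_loss(fwd.delta_cn, fwd.delta_ucn, pair.delta_y, cfg)
        mse_total = m if mse_total is None else mse_total + m
        node_total = nl if node_total is None else node_total + nl
    mse_mean = (1.0 / n) * mse_total
    node_mean = (1.0 / n) * node_total
    pen = penalty_term(P, cfg)
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
    return total, breakdown


# ---------------------------------------------------------------- proximal
def soft_threshold(beta: np.ndarray, t: float) -> np.ndarray:
    """Elementwise L1 proximal operator."""
    return np.sign(beta) * np.maximum(np.abs(beta) - t, 0.0)


def prox_group(beta: np.ndarray, t: float) -> np.ndarray:
    """Group (L2-norm) proximal operator: shrink the whole group, zeroing
    it when its norm falls below the threshold."""
    nrm = float(np.linalg.norm(beta))
    if nrm <= t:
        return np.zeros_like(beta)
    return (1.0 - t / nrm) * beta


def prox_sparse_group(beta: np.ndarray, t_l1: float, t_group: float) -> np.ndarray:
    """Sparse-group proximal operator: soft-threshold then group-shrink."""
    return prox_group(soft_threshold(beta, t_l1), t_group)
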