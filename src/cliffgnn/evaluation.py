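"""Quantitative evaluation of predictions and attribution maps.

Regression quality is summarized by RMSE and Pearson correlation.
Attribution quality is scored against the MCS-derived ground truth:

* *global direction* (gdir) per pair — 1 when the difference of mean
  uncommon-atom attributions between the two compounds has the same sign
  as the true activity difference, swept over MCS-coverage thresholds;
* node-coloring accuracy / macro-F1, Spearman alignment, and directional
  AUROC (positives scored raw, negatives with inverted scores) over
  uncommon atoms;
* perturbation stability — Spearman alignment recomputed under seeded
  bond dropout at fixed rates;
* paired t and Wilcoxon signed-rank tests for fold- or target-level model
  comparisons.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import f1_score, roc_auc_score

from .attribution import maps_for_pairs
from .mol_graphs import MolecularGraph, featurize

log = logging.getLogger(__name__)

MCS_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))
DROPOUT_RATES = (0.0, 0.05, 0.10, 0.20, 0.30)


@dataclass
class EvaluationReport:
    rmse: float = float("nan")
    pcc: float | None = None
    gdir_by_threshold: dict = field(default_factory=dict)
    coloring_accuracy: float | None = None
    coloring_f1: float | None = None
    spearman_rho: float | None = None
    auroc_pos: float | None = None
    auroc_neg: float | None = None
    stability: dict = field(default_factory=dict)
    paired_tests: dict = field(default_factory=dict)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)


# ------------------------------------------------------------- regression
def regression_metrics(yhat, y):
    """(rmse, pcc); pcc is None (with a warning) for zero-variance input."""
    yhat = np.asarray(yhat, float)
    y = np.asarray(y, float)
    rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
    if len(y) < 2 or np.std(yhat) == 0 or np.std(y) == 0:
        log.warning("PCC undefined (zero variance or n < 2)")
        return rmse, None
    return rmse, float(stats.pearsonr(yhat, y)[0])


# ---------------------------------------------------------------- gdir
def global_direction(pair, map_i, map_j) -> int:
    """1 iff the mean uncommon-atom attribution difference preserves the
    sign of the activity difference; exact ties score 0."""
    if pair.delta_y == 0:
        raise ValueError(f"pair {pair.pair_id} is not a cliff (delta_y=0)")
    for m in (map_i, map_j):
        if m.edge_scores is not None:
            raise ValueError("global_direction expects node-only maps")
    u_i = pair.mask_uncommon_i.astype(bool)
    u_j = pair.mask_uncommon_j.astype(bool)
    r_i = float(map_i.node_scores[u_i].mean()) if u_i.any() else 0.0
    r_j = float(map_j.node_scores[u_j].mean()) if u_j.any() else 0.0
    return int(np.sign(r_i - r_j) == np.sign(pair.delta_y))


def gdir_curve(pair_list, maps, thresholds=MCS_THRESHOLDS) -> dict:
    """Mean gdir over pairs whose BOTH shared fractions reach each
    threshold; empty subsets are reported as None."""
    scores = {
        p.pair_id: global_direction(p, *maps[p.pair_id]) for p in pair_list
    }
    curve = {}
    for t in thresholds:
        sel = [scores[p.pair_id] for p in pair_list
               if p.shared_fraction_i >= t and p.shared_fraction_j >= t]
        curve[float(t)] = float(np.mean(sel)) if sel else None
    return curve


# ----------------------------------------------------------- node coloring
def _collect_uncommon(pair_list, maps, colorings):
    """Flatten (score, +-1 label) over uncommon atoms of all pairs."""
    scores, labels = [], []
    for p in pair_list:
        m_i, m_j = maps[p.pair_id]
        col = colorings[p.pair_id]
        for m, lab in ((m_i, col.labels_i), (m_j, col.labels_j)):
            sel = lab != 0
            scores.extend(m.node_scores[sel])
            labels.extend(lab[sel])
    return np.asarray(scores, float), np.asarray(labels, int)


def coloring_metrics(pair_list, maps, colorings, include_common=False,
                     zero_threshold=0.0):
    """(accuracy, macro-F1) of sign(score) vs +-1 labels on uncommon atoms.

    Default (binary) variant: only uncommon atoms are scored and zero
    scores count as misclassified.  With ``include_common=True`` common
    atoms enter as a third (zero) class and scores with magnitude <=
    ``zero_threshold`` (caller-chosen) predict that class; F1 is then
    macro over the three classes.
    """
    if include_common:
        scores, labels = [], []
        for p in pair_list:
            m_i, m_j = maps[p.pair_id]
            col = colorings[p.pair_id]
            for m, lab in ((m_i, col.labels_i), (m_j, col.labels_j)):
                scores.extend(m.node_scores)
                labels.extend(lab)
        scores = np.asarray(scores, float)
        labels = np.asarray(labels, int)
        pred = np.where(np.abs(scores) <= zero_threshold, 0,
                        np.sign(scores)).astype(int)
        classes = [-1, 0, 1]
    else:
        scores, labels = _collect_uncommon(pair_list, maps, colorings)
        pred = np.sign(scores).astype(int)
        classes = [-1, 1]
    if len(labels) == 0:
        log.warning("no atoms to score")
        return None, None
    acc = float(np.mean(pred == labels))
    f1 = float(f1_score(labels, pred, labels=classes, average="macro",
                        zero_division=0))
    return acc, f1


def spearman_alignment(pair_list, maps, colorings):
    """Spearman rank correlation between scores and +-1 labels on uncommon
    atoms; None when a class is absent or fewer than 3 atoms."""
    scores, labels = _collect_uncommon(pair_list, maps, colorings)
    if len(labels) < 3 or len(np.unique(labels)) < 2:
        log.warning("Spearman alignment undefined on this set")
        return None
    return float(stats.spearmanr(scores, labels)[0])


def directional_auroc(pair_list, maps, colorings):
    """(auroc_pos, auroc_neg): AUROC for +1 atoms with raw scores and for
    -1 atoms with negated scores (midrank tie handling)."""
    scores, labels = _collect_uncommon(pair_list, maps, colorings)
    if len(np.unique(labels)) < 2:
        log.warning("directional AUROC undefined: single class")
        return None, None
    pos = float(roc_auc_score(labels == 1, scores))
    neg = float(roc_auc_score(labels == -1, -scores))
    return pos, neg


# ------------------------------------------------------------- stability
def _drop_bonds(graph: MolecularGraph, keep: np.ndarray) -> MolecularGraph:
    g = copy.copy(graph)
    g.bonds = [b for t, b in enumerate(graph.bonds) if keep[t]]
    return featurize(g)


def perturbation_stability(
    state,
    pair_list,
    graphs,
    colorings,
    method: str = "gradient_x_input",
    options: dict | None = None,
    rates=DROPOUT_RATES,
    seed: int = 0,
) -> dict:
    """Spearman alignment under seeded bond dropout at each rate.

    Each undirected bond is dropped independently with the given
    probability (both directed edges removed); rate 0 reproduces the
    unperturbed graphs, hence the unperturbed rho, exactly.
    """
    out = {}
    for r_idx, rate in enumerate(rates):
        rng = np.random.default_rng(
            int(np.random.SeedSequence([seed, r_idx]).generate_state(1)[0]
                % (2**31))
        )
        perturbed = {}
        for cid, g in graphs.items():
            if rate == 0 or not g.bonds:
                perturbed[cid] = g
            else:
                keep = rng.random(len(g.bonds)) >= rate
                perturbed[cid] = _drop_bonds(g, keep)
        maps = maps_for_pairs(state, pair_list, perturbed, method, options)
        out[float(rate)] = spearman_alignment(pair_list, maps, colorings)
    return out


# ------------------------------------------------------------ paired tests
def paired_tests(metric_a, metric_b):
    """(t_p, wilcoxon_p), two-sided, paired over folds/targets.

    All-zero differences give t_p = 1 by convention and an undefined
    (None) Wilcoxon p.  Zero differences are dropped from the Wilcoxon
    statistic; the exact null distribution is used for n <= 25 and the
    normal approximation above.
    """
    a = np.asarray(metric_a, float)
    b = np.asarray(metric_b, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("paired tests need equal lengths >= 3")
    d = a - b
    if np.all(d == 0):
        return 1.0, None
    t_p = float(stats.ttest_rel(a, b)[1])
    nz = d[d != 0]
    method = "exact" if len(nz) <= 25 else "approx"
    try:
        w_p = float(stats.wilcoxon(nz, method=method)[1])
    except ValueError:
        w_p = None
    return t_p, w_p


# --------------------------------------------------------------- pipeline
def evaluate_model(
    state,
    pair_list,
    graphs,
    colorings,
    method: str = "gradient_x_input",
    options: dict | None = None,
    stability_rates=DROPOUT_RATES,
    seed: int = 0,
    with_stability: bool = True,
) -> EvaluationReport:
    """Full evaluation of one trained model on a test pair set."""
    from .training import predict_pairs

    yhat, y = predict_pairs(pair_list, graphs, state)
    rmse, pcc = regression_metrics(yhat, y)
    maps = maps_for_pairs(state, pair_list, graphs, method, options)
    acc, f1 = coloring_metrics(pair_list, maps, colorings)
    pos, neg = directional_auroc(pair_list, maps, colorings)
    report = EvaluationReport(
        rmse=rmse,
        pcc=pcc,
        gdir_by_threshold=gdir_curve(pair_list, maps),
        coloring_accuracy=acc,
        coloring_f1=f1,
        spearman_rho=spearman_alignment(pair_list, maps, colorings),
        auroc_pos=pos,
        auroc_neg=neg,
    )
    if with_stability:
        report.stability = perturbation_stability(
            state, pair_list, graphs, colorings, method, options,
            stability_rates, seed,
        )
    return report


def plot_curves(report: EvaluationReport, path=None):
    """Two-panel figure: gdir vs MCS threshold and stability vs dropout.

    Returns the matplotlib Figure; saves to `path` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    pts = [(t, v) for t, v in sorted(report.gdir_by_threshold.items())
           if v is not None]
    if pts:
        ax1.plot(*zip(*pts), marker="o")
    ax1.set_xlabel("minimum shared MCS fraction")
    ax1.set_ylabel("mean global direction")
    ax1.set_ylim(-0.05, 1.05)
    pts = [(r, v) for r, v in sorted(report.stability.items())
           if v is not None]
    if pts:
        ax2.plot(*zip(*pts), marker="o", color="firebrick")
    ax2.set_xlabel("edge dropout rate")
    ax2.set_ylabel("Spearman alignment")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def curves_to_csv(report: EvaluationReport, path):
    """Tidy CSV with the threshold and dropout curves for plotting."""
    import csv as _csv

    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["curve", "x", "value"])
        for t, v in report.gdir_by_threshold.items():
            w.writerow(["gdir_by_threshold", t, "" if v is None else v])
        for r, v in report.stability.items():
            w.writerow(["stability", r, "" if v is None else v])
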