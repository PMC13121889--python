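"""Model/Results facade over the pipeline, statsmodels-style.

:class:`ActivityCliffGNN` is constructed from compound data (records, a
DataFrame, or a synthetic benchmark spec); pair assembly happens at
construction.  ``fit()`` trains one model on a leakage-controlled split
and returns an :class:`ActivityCliffResults` carrying the trained state,
training history, test metrics, a ``summary()`` table, and attribution /
evaluation methods.  ``fit_cv()`` runs the k-fold cross-validation
protocol.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport, evaluate_model, regression_metrics
from .attribution import node_level_map
from .mol_graphs import CompoundRecord, graph_from_smiles, to_pic50
from .nn import ModelConfig
from .objectives import LossConfig
from .pairs import (
    DEFAULT_CLIFF_THRESHOLD,
    DEFAULT_MIN_PAIRS,
    DEFAULT_MIN_SHARED_FRACTION,
    assemble_pair_dataset,
    make_fold_splits,
)
from .training import TrainSchedule, cross_validate, predict_pairs, train_model


class ActivityCliffGNN:
    """Single-target affinity model trained on activity-cliff pairs."""

    def __init__(
        self,
        compounds: list[CompoundRecord],
        model_config: ModelConfig | None = None,
        loss_config: LossConfig | None = None,
        schedule: TrainSchedule | None = None,
        min_shared_fraction: float = DEFAULT_MIN_SHARED_FRACTION,
        cliff_threshold: float = DEFAULT_CLIFF_THRESHOLD,
        min_pairs: int = DEFAULT_MIN_PAIRS,
        pair_dataset=None,
    ):
        self.compounds = list(compounds)
        self.model_config = model_config or ModelConfig()
        self.loss_config = loss_config or LossConfig()
        self.schedule = schedule or TrainSchedule()
        self.graphs = {c.compound_id: graph_from_smiles(c.smiles, c.compound_id)
                       for c in self.compounds}
        if pair_dataset is None:
            pair_dataset = assemble_pair_dataset(
                self.compounds,
                graphs=self.graphs,
                min_shared_fraction=min_shared_fraction,
                cliff_threshold=cliff_threshold,
                min_pairs=min_pairs,
            )
        self.dataset = pair_dataset
        if not self.dataset.pairs:
            raise ValueError(
                f"no usable pair dataset: {self.dataset.diagnostics}"
            )
        self._pair_by_id = {p.pair_id: p for p in self.dataset.pairs}

    # ------------------------------------------------------------ builders
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        id_column: str = "compound_id",
        smiles_column: str = "smiles",
        activity_column: str = "activity",
        activity_kind: str = "pIC50",
        **kwargs,
    ) -> "ActivityCliffGNN":
        records = [
            CompoundRecord(str(r[id_column]), str(r[smiles_column]),
                           to_pic50(float(r[activity_column]), activity_kind))
            for _, r in df.iterrows()
        ]
        return cls(records, **kwargs)

    @classmethod
    def from_synthetic(cls, spec=None, **kwargs):
        """Build from the synthetic congeneric-series benchmark; the truth
        object is attached as ``model.truth``."""
        from .synthetic import SyntheticSpec, generate_benchmark

        records, truth = generate_benchmark(spec or SyntheticSpec())
        model = cls(records, **kwargs)
        model.truth = truth
        return model

    # ----------------------------------------------------------------- fit
    def fit(self, seed: int = 0, fractions=(0.7, 0.1, 0.2)) -> "ActivityCliffResults":
        """Train on one seeded 70/10/20 compound-level split."""
        split = make_fold_splits(self.compounds, self.dataset.pairs, k=1,
                                 fractions=fractions, seed=seed)[0]
        train_pairs = [self._pair_by_id[i] for i in split.train_pairs]
        val_pairs = [self._pair_by_id[i] for i in split.val_pairs]
        test_pairs = [self._pair_by_id[i] for i in split.test_pairs]
        schedule = TrainSchedule(**{**self.schedule.__dict__, "seed": seed})
        tr = train_model(train_pairs, val_pairs, self.graphs,
                         self.model_config, self.loss_config, schedule)
        return ActivityCliffResults(self, tr, split, test_pairs)

    def fit_cv(self, k: int = 5, seed: int = 0):
        """The k-fold cross-validation protocol; returns a CVResult."""
        return cross_validate(
            self.compounds, self.dataset.pairs, self.graphs,
            self.model_config, self.loss_config, self.schedule,
            k=k, seed=seed,
        )


class ActivityCliffResults:
    """Fitted-model results: trained state, history, and diagnostics."""

    def __init__(self, model: ActivityCliffGNN, train_result, split,
                 test_pairs):
        self.model = model
        self.train_result = train_result
        self.state = train_result.state
        self.split = split
        self.test_pairs = test_pairs
        if test_pairs:
            yhat, y = predict_pairs(test_pairs, model.graphs, self.state)
            self.rmse, self.pcc = regression_metrics(yhat, y)
        else:
            self.rmse, self.pcc = float("nan"), None

    @property
    def history(self) -> pd.DataFrame:
        return pd.DataFrame(self.train_result.history)

    def evaluate(self, method: str = "gradient_x_input", options=None,
                 seed: int = 0, with_stability: bool = True) -> EvaluationReport:
        """Attribution-quality evaluation on the held-out test pairs."""
        colorings = {p.pair_id: self.model.dataset.colorings[p.pair_id]
                     for p in self.test_pairs}
        return evaluate_model(self.state, self.test_pairs, self.model.graphs,
                              colorings, method=method, options=options,
                              seed=seed, with_stability=with_stability)

    def attribute(self, compound_id: str, method: str = "gradient_x_input",
                  options=None):
        """Node-level attribution map for one compound (whole molecule
        treated as common)."""
        return node_level_map(self.state, self.model.graphs[compound_id],
                              method, options)

    def summary(self) -> str:
        tr = self.train_result
        buf = io.StringIO()
        cfg = self.model.model_config
        loss = self.model.loss_config
        w = buf.write
        w("Activity-cliff GNN results\n")
        w("=" * 58 + "\n")
        w(f"backbone: {cfg.backbone:<18} pooling: {cfg.pooling}\n")
        w(f"layers:   {cfg.n_layers:<18} hidden dim: {cfg.hidden_dim}\n")
        w(f"loss mode: {loss.mode:<17} penalty: {loss.penalty}\n")
        if loss.penalty != "none":
            w(f"lambda_pen: {loss.lambda_pen:<16} alpha: {loss.alpha}\n")
        w("-" * 58 + "\n")
        w(f"compounds: {len(self.model.compounds):<17} "
          f"cliff pairs: {len(self.model.dataset.pairs)}\n")
        w(f"train/val/test pairs: {len(self.split.train_pairs)}/"
          f"{len(self.split.val_pairs)}/{len(self.split.test_pairs)}\n")
        w(f"epochs run: {len(tr.history):<16} stop: {tr.reason}\n")
        w(f"best val RMSE: {tr.best_val_rmse:.4f} (epoch {tr.best_epoch})\n")
        pcc = "nan" if self.pcc is None else f"{self.pcc:.4f}"
        w(f"test RMSE: {self.rmse:.4f}{'':10} test PCC: {pcc}\n")
        gl = float(np.linalg.norm(self.state.params["beta_CN"]))
        gu = float(np.linalg.norm(self.state.params["beta_UCN"]))
        w(f"||beta_CN||2: {gl:.4f}{'':8} ||beta_UCN||2: {gu:.4f}\n")
        w("=" * 58)
        return buf.getvalue()

    def __repr__(self):
        return (f"<ActivityCliffResults rmse={self.rmse:.4f} "
                f"pairs={len(self.test_pairs)}>")
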