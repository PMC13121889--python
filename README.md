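# cliffgnn

Activity-cliff-aware graph neural networks for single-target
compound–protein affinity prediction, with group-lasso-regularized
subgraph heads and quantitative benchmarking of atom-level feature
attributions.

## Who this is for

Computational chemists and method developers working on single-target
QSAR with limited data who want a model that (a) exploits
matched-molecular-pair activity cliffs — pairs of compounds sharing a
scaffold but differing ≥ 1 log unit in pIC50 — during training, and (b)
whose atom-level explanations can be scored against MCS-derived ground
truth rather than eyeballed.

## The model

Each compound is a heavy-atom graph with 50-d atom and 10-d bond
features, embedded to a shared 32-d space and propagated through three
message-passing layers (edge-conditioned convolution by default; GIN and
GAT available), each followed by batch norm and ReLU. For a cliff pair
(i, j) with masks splitting each molecule into common (CN) and uncommon
(UCN) atoms, masked pooling gives subgraph readouts g^CN, g^UCN; their
16-d projections are concatenated into the affinity prediction ŷ, and two
scalar heads β_CN, β_UCN predict the subgraph contributions to the
activity difference. The objective for n pairs is

    L = (1/n) Σ_k Σ_{c∈{i,j}} (y_c − ŷ_c)²
      + (1/n) Σ_k (λ_CN Δŷ_k^CN + λ_UCN Δŷ_k^UCN − Δy_k)²
      + λ [ (1−α)(√p_CN‖β_CN‖₂ + √p_UCN‖β_UCN‖₂) + α‖β‖₁ ]

where α = 0 is the group lasso, α = 1 the lasso, and λ controls how hard
the common/uncommon head groups are pruned. Attribution maps (CAM,
Grad-CAM, Gradient×Input, integrated gradients — all signed) are scored
by global direction (does the mean uncommon-atom attribution difference
preserve the sign of Δy?), node-coloring accuracy/F1, Spearman alignment,
directional AUROC, and stability under bond dropout. Full details in
[docs/methods.md](docs/methods.md).

Everything runs on an in-package reverse-mode autodiff core over NumPy;
RDKit handles chemistry (SMILES, FMCS).

## Worked example

The built-in synthetic benchmark is a congeneric series — one benzamide
scaffold, eight single-atom substituents with additive effects spanning
three log units, Gaussian assay noise — so every pair's ground-truth atom
coloring is known by construction:

```python
import cliffgnn as cg
from cliffgnn.objectives import LossConfig

model = cg.ActivityCliffGNN.from_synthetic(
    loss_config=LossConfig(penalty="group_lasso"))
results = model.fit(seed=1)
print(results.summary())
report = results.evaluate(method="gradient_x_input", with_stability=False)
print(f"gdir@50% MCS threshold: {report.gdir_by_threshold[0.5]:.3f}")
```

prints

```
Activity-cliff GNN results
==========================================================
backbone: edge_conditioned   pooling: mean
layers:   3                  hidden dim: 32
loss mode: N                 penalty: group_lasso
lambda_pen: 0.001            alpha: 0.5
----------------------------------------------------------
compounds: 60                cliff pairs: 856
train/val/test pairs: 610/60/186
epochs run: 34               stop: early_stop
best val RMSE: 0.1059 (epoch 3)
test RMSE: 0.1369           test PCC: 0.9943
||beta_CN||2: 1.1967         ||beta_UCN||2: 1.3053
==========================================================
gdir@50% MCS threshold: 1.000
```

Reading: the 60 sampled compounds yield 856 qualifying cliff pairs;
training early-stops once validation RMSE plateaus near the 0.1-log-unit
noise floor; held-out predictions track the planted activities (RMSE
0.137, PCC 0.994); and Gradient×Input attributions point at the
substituent atoms with the correct sign relationship in every test pair
(global direction 1.0). On this run the attribution quality metrics were
coloring accuracy/F1 0.930/0.930 and directional AUROC 0.978 for both
atom classes.

`model.fit_cv(k=5)` runs the 5-fold protocol (independent seeded 70/10/20
compound splits, pairs following their first ligand) and returns per-fold
and pair-count-weighted aggregates. Real data enter through
`ActivityCliffGNN.from_dataframe(...)` or `load_compound_table(...)`
(CSV with id, SMILES, and pIC50 or IC50 columns).

A CLI mirrors the stages:

```sh
cliffgnn synth --seed 17 --out run/
cliffgnn train --set data.compound_csv=run/compounds.csv --out run/
cliffgnn crossval --out run/
```

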