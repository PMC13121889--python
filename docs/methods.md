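# Methods

## Problem setting

Single-target potency prediction from activity-cliff pairs. An *activity
cliff* is a pair of structurally similar compounds binding the same target
whose potencies differ by at least one log unit of pIC50. A *matched
molecular pair* shares a common core and differs by a substituent at one
site. The package trains a message-passing neural network on such pairs
for one protein target, using the pair structure twice: the
common/uncommon atom partition shapes the architecture (masked subgraph
readouts), and the observed activity difference supplies an extra
node-level supervision signal. Structured sparsity penalties (group lasso
/ sparse group lasso) on the two subgraph prediction heads prune the
common- vs. uncommon-subgraph contributions, and per-atom feature
attributions are scored quantitatively against MCS-derived ground truth.

## Pair construction

The maximum common substructure (MCS) of a candidate pair is computed with
RDKit's FMCS under element-exact atom matching, bond-order-exact bond
matching, ring-atoms/bonds-match-only-ring rules, and connectivity of the
result. Atom count is maximized rather than bond count so that the result
coincides with exhaustive connected-common-subgraph enumeration, which is
the oracle the test suite uses. FMCS is bond-based and reports nothing for
single-atom overlaps; `find_mcs` falls back to a one-atom mapping in that
case. Ties among equal-size solutions are broken by taking the first
substructure match in RDKit's canonical order of the first compound, which
makes masks deterministic.

A pair is admitted when |Δ pIC50| ≥ 1.0 (inclusive) and the MCS covers at
least a configurable fraction (default 0.5) of **both** molecules. One
ordered pair is emitted per unordered combination — the compound earlier in
the input list is the "first ligand" — because splits key on the first
ligand. Datasets with fewer than 50 admitted pairs are rejected, mirroring
the minimum-size rule for single-target benchmarks. Ground-truth atom
labels are +1 on the uncommon atoms of the more potent compound, −1 on the
uncommon atoms of the less potent one, 0 on the shared core.

Splits are compound-level 70/10/20 (train/validation/test, validation
carved from the training compounds); each pair follows its first ligand,
so no test pair's first ligand is ever a training compound. Note that the
second compound of a training pair may be a test compound — that is the
protocol this benchmark family defines, and the known optimism of random
splits on congeneric series applies.

## Model

Atom features (50-d: element one-hot over a fixed 35-symbol vocabulary +
"other", degree 0–5, implicit-H count 0–4, clipped formal charge, aromatic
and ring flags) and bond features (10-d: bond-order one-hot, stereo
one-hot over {Z, E, ANY, NONE}, conjugation, ring flag) are linearly
embedded into a shared 32-d space. Three message-passing layers with
additive neighbour aggregation follow, each with its own parameters,
followed by batch normalization and ReLU. Backbones:

* **edge-conditioned** (default): an edge network maps each 32-d edge
  embedding to a 32×32 weight matrix (one linear layer, 32 → 1024) that
  modulates the message from the source node;
* **gin**: (1+ε)·h + Σ neighbours through a two-layer MLP, node features
  only;
* **gat**: single-head additive attention with self-loops, node features
  only.

For a pair, the binary common/uncommon masks split each molecule's node
embeddings into two subgraphs; each is pooled (mean by default for the
edge-conditioned and GAT backbones, sum for GIN; max and attention gating
are also available — mean pooling divides by the number of selected atoms,
and an empty selection yields the zero vector). The two 32-d pooled
readouts are projected to 16-d and concatenated; a final linear layer
(32 → 1) predicts pIC50. Two scalar subgraph heads (weights β_CN, β_UCN on
the 16-d projections) predict the common- and uncommon-part contributions
to a pair's activity difference; their biases cancel in the differences.
Per-node 32 → 1 attribution heads are exposed for CAM-style inspection but
do not enter the affinity path.

Whether the subgraph heads should consume the 32-d readouts or the 16-d
projections was genuinely open; the 16-d projections are used (p_CN =
p_UCN = 16), configurable via the head-input setting.

## Objective

For a batch of pairs,

    L = mean_k Σ_{c∈{i,j}} (y_c − ŷ_c)²                (affinity MSE)
      + mean_k (λ_CN Δŷ_CN + λ_UCN Δŷ_UCN − Δy_k)²     (node-level loss)
      + penalty(β_CN, β_UCN)

with λ_CN = λ_UCN = 1 by default; the uncommon-only baseline is the same
loss with λ_CN = 0. The printed form of the node loss reads as a single
squared residual of the weighted sum of both deltas, and that reading is
implemented; the alternative two-term decomposition is noted but not the
default. Penalties:

    GL  = λ (√p_CN ‖β_CN‖₂ + √p_UCN ‖β_UCN‖₂)
    SGL = (1−α) GL + α λ ‖β‖₁,   α ∈ [0, 1]

√p_g group-size weighting is the standard group-lasso convention and the
default (a linear-p variant is a config switch). Only the subgraph-head
weights are penalized, never biases or backbone weights. Penalties enter
the objective as differentiable terms with subgradient 0 at the origin —
adequate at these scales — so Adam iterates hover near, not exactly at,
zero; the closed-form proximal operators (`objectives.prox_*`) are
provided for exact-sparsity analyses and are what the sparsity tests use.
Defaults: λ = 1e-3, α = 0.5.

## Training

The whole model is differentiated with a small in-package reverse-mode
autodiff core over float64 NumPy arrays (`cliffgnn._autodiff`); every
operation's vector–Jacobian product is closed-form and finite-difference
tested. Minibatches are processed as disjoint-union graphs with the unique
*structures* of the batch embedded once (compounds parsed from the same
SMILES share atom ordering); masked readouts for all pairs are recovered
with one constant selection matrix. Batch normalization uses union-batch
statistics in training and running statistics (momentum 0.1) at
evaluation.

Optimizer: Adam, initial rate 1e-3, batch 32 pairs, at most 300 epochs.
Validation RMSE drives both schedules: the learning rate halves after 10
epochs without improvement (floor 1e-5) and training stops after 30
epochs without improvement; "improvement" means a decrease > 1e-4. The
best-validation-RMSE state is returned. One master seed drives parameter
initialization, shuffling, and the per-fold seeds, so runs are bit
reproducible. Cross-validation uses k independent seeded splits (the
protocol resamples compounds per fold rather than partitioning them) and
reports per-fold test RMSE/PCC with plain and pair-count-weighted
aggregates, re-checking the first-ligand rule on every fold.

## Attribution

All methods target the scalar predicted affinity of one compound,
evaluated under the masks of the pair being explained (or whole-molecule
masks standalone). `cam` dots last-layer node activations with the
effective linear readout weights of the node's branch and therefore
requires a linear pooling mode (mean/sum); `grad_cam` weights channels by
the node-mean of ∂ŷ/∂h and is kept signed — no ReLU rectification —
because the ground truth is ±1; `gradient_x_input` and
`integrated_gradients` reduce feature dimensions by summation (not mean or
L2), which keeps the linear-model equivalences exact. IG integrates from
the all-zero-feature baseline on the same topology with the trapezoid
rule, 64 steps by default. With ReLU kinks along the path the trapezoid
completeness error is O(1/steps); it vanishes exactly when the model is
affine on the path, which is how the completeness axiom is verified. Edge
attributions are folded onto atoms by averaging the two directed scores of
each bond and splitting the result evenly between its endpoints, which
conserves the (node + per-bond) attribution mass exactly.

## Evaluation

* **Global direction** per pair: 1 when the difference of mean
  uncommon-atom attributions has the sign of Δy; an exact tie scores 0,
  since a zero difference cannot preserve a nonzero direction. Swept over
  MCS-coverage thresholds 0.50–0.95 in 0.05 steps (both compounds must
  reach the threshold; threshold subsets are nested by construction).
* **Coloring accuracy / macro-F1** on uncommon atoms only: a signed score
  has no natural third class for the common (label 0) atoms, so they are
  excluded; zero scores count as misclassified. A three-class variant with
  a user-chosen magnitude threshold is left to the caller.
* **Spearman alignment** between scores and ±1 labels (midranks), and
  **directional AUROC**: positives scored raw, negatives with negated
  scores, midrank tie handling.
* **Perturbation stability**: Spearman alignment recomputed under seeded
  independent bond dropout at rates {0, 0.05, 0.10, 0.20, 0.30}; rate 0
  reproduces the unperturbed value bitwise. Message passing tolerates the
  resulting isolated atoms.
* **Paired tests**: two-sided paired t and Wilcoxon signed-rank p-values
  over folds/targets; zero differences are dropped from the Wilcoxon
  statistic (the original procedure), exact null for n ≤ 25, normal
  approximation above; all-zero differences give t_p = 1 by convention and
  an undefined Wilcoxon p.

## Synthetic benchmark

The generator emulates a congeneric series: a para-substituted
benzamide scaffold decorated at one site with one of 8 single-atom
substituents (F, Cl, Br, I, O, N, C, S) carrying additive effects 0.0–3.0
log units; observed pIC50 = 6.0 + effect + N(0, 0.1); 60 compounds
sampled with replacement (seed 17). Because every substituent is a single
atom of a distinct element, an element-exact MCS can never extend into a
substituent, so the scaffold/substituent partition — and hence every
pair's ground-truth coloring — is known exactly by construction, and the
pipeline's mask recovery can be validated (it is 100% on the default
spec). The defaults yield several hundred cliff pairs, the scale of the
smaller single-kinase benchmark sets.

What the generator does **not** emulate: multi-site and non-additive
(cooperative) substituent effects, scaffold diversity within a target,
assay heterogeneity, heavy-tailed potency distributions, and any real
binding physics. Passing the recovery tests therefore shows that the
machinery — pairing, masking, training, attribution, scoring — is
internally correct and that attributions recover planted additive signals;
it does not certify accuracy on real kinase data.

## Numerical choices and degenerate inputs

float64 throughout; batch-norm ε = 1e-5; |·| and ‖·‖₂ use subgradient 0 at
the origin; segment softmax is shifted by the detached per-segment max;
empty masks pool to the zero vector (never NaN); molecules with no bonds
propagate self-information only; non-finite losses abort training with the
last improving checkpoint and a diagnostic naming the offending term;
zero-variance predictions report PCC as missing rather than raising.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the default benchmark (60
compounds, ~900 pairs) with single splits or 5 short-schedule folds, and
multi-seed comparisons use 5 seeds with the full 300-epoch schedule under
early stopping (which typically triggers between epochs 30 and 60). These
sizes were chosen so the whole verification cycle runs on one CPU core in
minutes while leaving the training protocol itself untouched.

## Known limitations

* The 50/10-column feature layouts are this package's documented choice;
  other featurizations of the same width will not be checkpoint-compatible.
* The first-ligand split rule controls leakage only through the first
  compound of each pair (see above).
* MCS-derived labels are a heuristic benchmark, not causal ground truth;
  distal electronic or conformational effects are invisible to them.
* Gradient×Input and IG signs on one-hot inputs can be globally shifted
  for some trained models (rank-based metrics stay high while sign-based
  coloring accuracy drops); this is a property of the methods, not a
  defect of the scorer.
* The GAT and GIN backbones ignore edge features by design; use the
  edge-conditioned backbone when bond information matters.
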