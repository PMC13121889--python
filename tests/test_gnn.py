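"""Model-core contracts: propagation, readouts, heads, and gradients."""

import numpy as np
import pytest
from rdkit import Chem

import cliffgnn as cg
from cliffgnn import _autodiff as ad
from cliffgnn.nn import (
    ModelConfig,
    affinity_head,
    embed_and_propagate,
    forward_compound,
    forward_pair,
    init_state,
    masked_readout,
    subgraph_delta,
)
from cliffgnn.objectives import LossConfig, total_objective
from cliffgnn.training import batch_objective


def permuted_graph(smiles, cid="perm"):
    """The same molecule with a renumbered atom order."""
    mol = Chem.MolFromSmiles(smiles)
    n = mol.GetNumAtoms()
    perm = list(np.random.default_rng(0).permutation(n))
    new = Chem.RenumberAtoms(mol, [int(p) for p in perm])
    g = cg.featurize(cg.parse_smiles(Chem.MolToSmiles(new, canonical=False),
                                     cid))
    return g


class TestPropagation:
    @pytest.mark.parametrize("backbone", ["edge_conditioned", "gin", "gat"])
    def test_single_atom_graph_no_messages(self, backbone):
        state = init_state(ModelConfig(backbone=backbone), seed=0)
        g = cg.graph_from_smiles("C", "methane")
        h = embed_and_propagate(g, state)
        assert h.value.shape == (1, 32)
        assert np.all(np.isfinite(h.value))

    @pytest.mark.parametrize("backbone", ["edge_conditioned", "gin", "gat"])
    def test_permutation_equivariance(self, backbone):
        smiles = "O=C(N)c1ccc(Cl)cc1"
        state = init_state(ModelConfig(backbone=backbone), seed=1)
        g = cg.graph_from_smiles(smiles, "orig")
        h = embed_and_propagate(g, state).value
        gp = permuted_graph(smiles)
        hp = embed_and_propagate(gp, state).value
        # match rows via the atom correspondence from substructure match
        match = gp.mol.GetSubstructMatch(g.mol)
        assert np.allclose(h, hp[list(match)], atol=1e-10)

    def test_edge_conditioned_matches_loop_reference(self):
        """Batched propagation equals a plain per-node loop implementation."""
        state = init_state(ModelConfig(), seed=2)
        g = cg.graph_from_smiles("CC(=O)Oc1ccccc1", "asp")
        got = embed_and_propagate(g, state).value
        p = state.params
        bn = state.bn_running
        h = g.node_features @ p["node_embed_W"] + p["node_embed_b"]
        e_emb = g.edge_features @ p["edge_embed_W"] + p["edge_embed_b"]
        src, dst = g.directed_edge_index
        for layer in range(3):
            w_e = (e_emb @ p[f"layer{layer}_edge_net_W"]
                   + p[f"layer{layer}_edge_net_b"]).reshape(-1, 32, 32)
            z = h @ p[f"layer{layer}_self_W"] + p[f"layer{layer}_self_b"]
            z = z.copy()
            for k in range(len(src)):
                z[dst[k]] += w_e[k] @ h[src[k]]
            z = (z - bn[f"layer{layer}_mean"]) / np.sqrt(
                bn[f"layer{layer}_var"] + 1e-5)
            z = z * p[f"layer{layer}_bn_gamma"] + p[f"layer{layer}_bn_beta"]
            h = np.maximum(z, 0.0)
        assert np.allclose(got, h, atol=1e-12)


class TestMaskedReadout:
    def setup_method(self):
        self.h = np.array([[1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])

    @pytest.mark.parametrize("pooling", ["mean", "sum", "max"])
    def test_single_node_mask_returns_that_row(self, pooling):
        out = masked_readout(self.h, [0, 1, 0], pooling).value
        assert np.allclose(out, self.h[1])

    def test_mean_of_identical_rows_is_that_row(self):
        h = np.tile([[2.0, -1.0, 0.5]], (4, 1))
        out = masked_readout(h, [1, 0, 1, 1], "mean").value
        assert np.allclose(out, [2.0, -1.0, 0.5])

    def test_sum_hand_example(self):
        out = masked_readout(self.h, [1, 0, 1], "sum").value
        assert out[0] == pytest.approx(4.0)

    def test_mean_divides_by_selected_count_not_n(self):
        out = masked_readout(self.h, [1, 0, 1], "mean").value
        assert out[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("pooling", ["mean", "sum", "max"])
    def test_empty_mask_gives_zero_vector(self, pooling):
        out = masked_readout(self.h, [0, 0, 0], pooling).value
        assert np.allclose(out, 0.0) and not np.any(np.isnan(out))

    def test_attention_pooling_is_convex_combination(self):
        gate = ad.Tensor(np.array([1.0, 0.0, 0.0]))
        out = masked_readout(self.h, [1, 1, 1], "attention", gate).value
        assert self.h[:, 0].min() < out[0] < self.h[:, 0].max()

    def test_mask_length_mismatch(self):
        with pytest.raises(ValueError):
            masked_readout(self.h, [1, 0], "mean")


class TestHeads:
    def _tensors(self, state):
        return state.as_tensors(requires_grad=False)

    def test_zero_readouts_give_bias(self, random_state):
        P = self._tensors(random_state)
        z = ad.Tensor(np.zeros(16))
        y = affinity_head(z, z, P)
        assert float(y.value) == pytest.approx(
            float(random_state.params["affinity_b"]))

    def test_affinity_linearity(self, random_state):
        state = random_state.copy()
        state.params["affinity_b"] = np.zeros(())
        P = state.as_tensors(False)
        g1 = ad.Tensor(np.arange(16, dtype=float))
        g2 = ad.Tensor(np.ones(16))
        y1 = float(affinity_head(g1, g2, P).value)
        state2 = state.copy()
        state2.params["affinity_W"] = 2 * state2.params["affinity_W"]
        y2 = float(affinity_head(g1, g2, state2.as_tensors(False)).value)
        assert y2 == pytest.approx(2 * y1)

    def test_subgraph_delta_cancels_bias(self, random_state, small_pair):
        _, graphs, pair, _ = small_pair
        state = random_state.copy()
        fwd = forward_pair(pair, graphs, state)
        state2 = state.copy()
        state2.params["b_CN"] = state2.params["b_CN"] + 100.0
        state2.params["b_UCN"] = state2.params["b_UCN"] - 3.0
        fwd2 = forward_pair(pair, graphs, state2)
        assert float(fwd.delta_cn.value) == pytest.approx(
            float(fwd2.delta_cn.value), abs=1e-9)
        assert float(fwd.delta_ucn.value) == pytest.approx(
            float(fwd2.delta_ucn.value), abs=1e-9)

    def test_delta_hand_arithmetic(self, random_state):
        state = random_state.copy()
        beta = np.zeros(16)
        beta[0] = 1.0
        state.params["beta_CN"] = beta
        P = state.as_tensors(False)
        gi = ad.Tensor(np.r_[3.0, np.zeros(15)])
        gj = ad.Tensor(np.r_[1.0, np.zeros(15)])

        class FakeFwd:
            pass

        fi, fj = FakeFwd(), FakeFwd()
        fi.g_cn, fi.g_ucn = gi, gi
        fj.g_cn, fj.g_ucn = gj, gj
        d_cn, _ = subgraph_delta(fi, fj, P)
        assert float(d_cn.value) == pytest.approx(2.0)


class TestForwardPair:
    def test_identical_compounds_zero_deltas(self, random_state):
        recs = [cg.CompoundRecord("a", "Cc1ccccc1", 8.0),
                cg.CompoundRecord("b", "Cc1ccccc1", 6.0)]
        graphs = {r.compound_id: cg.graph_from_smiles(r.smiles, r.compound_id)
                  for r in recs}
        ds = cg.assemble_pair_dataset(recs, graphs=graphs, min_pairs=1)
        fwd = forward_pair(ds.pairs[0], graphs, random_state)
        assert fwd.yhat_i == pytest.approx(fwd.yhat_j)
        assert float(fwd.delta_cn.value) == pytest.approx(0.0, abs=1e-12)
        assert float(fwd.delta_ucn.value) == pytest.approx(0.0, abs=1e-12)

    def test_full_shared_fraction_no_nan(self, random_state):
        # uncommon mask empty on both sides: readout must be zero, not NaN
        g = cg.graph_from_smiles("Cc1ccccc1", "a")
        fwd = forward_compound(g, random_state)
        assert np.all(fwd.r_ucn.value == 0.0)
        assert np.isfinite(fwd.yhat.value)

    def test_mask_mismatch_names_pair(self, random_state, small_pair):
        _, graphs, pair, _ = small_pair
        bad = cg.ACPair(**{**pair.__dict__,
                           "mask_common_i": np.ones(3),
                           "mask_uncommon_i": np.zeros(3)})
        with pytest.raises(ValueError, match=pair.pair_id):
            forward_pair(bad, graphs, random_state)

    def test_batched_objective_matches_per_pair_eval(self, pair_data,
                                                     random_state, gl_loss):
        """Union-graph batching equals per-pair forwards in eval mode."""
        _, _, graphs, dataset = pair_data
        batch = dataset.pairs[:6]
        state = random_state
        P = state.as_tensors(False)
        loss_b, bd_b, yhat_b = batch_objective(batch, graphs, state, P,
                                               gl_loss, training=False)
        fwds = [forward_pair(p, graphs, state, P) for p in batch]
        loss_p, bd_p = total_objective(fwds, batch, P, gl_loss)
        assert bd_b["total"] == pytest.approx(bd_p["total"], rel=1e-10)
        yhat_p = np.array([f.yhat_i for f in fwds] + [f.yhat_j for f in fwds])
        assert np.allclose(yhat_b, yhat_p, atol=1e-10)


class TestGradients:
    @pytest.mark.parametrize("penalty", ["none", "group_lasso",
                                         "sparse_group_lasso"])
    @pytest.mark.parametrize("backbone", ["edge_conditioned", "gin", "gat"])
    def test_finite_difference_agreement(self, pair_data, penalty, backbone):
        """Analytic gradients of the total objective match central finite
        differences to 1e-4 relative for every penalty mode and backbone."""
        _, _, graphs, dataset = pair_data
        batch = dataset.pairs[:4]
        cfg = ModelConfig(backbone=backbone)
        state = init_state(cfg, seed=7)
        loss_cfg = LossConfig(penalty=penalty, lambda_pen=0.01)
        P = state.as_tensors(True)
        loss, _, _ = batch_objective(batch, graphs, state, P, loss_cfg,
                                     training=False)
        loss.backward()
        rng = np.random.default_rng(0)
        names = ["node_embed_W", "beta_CN", "beta_UCN", "affinity_W",
                 "proj_UCN_W"]
        if backbone == "edge_conditioned":
            names.append("layer0_edge_net_W")
        for name in names:
            arr = state.params[name]
            idx = tuple(int(rng.integers(0, s)) for s in arr.shape)
            eps = 1e-6
            orig = arr[idx]

            def f():
                P2 = state.as_tensors(False)
                l2, _, _ = batch_objective(batch, graphs, state, P2,
                                           loss_cfg, training=False)
                return float(l2.value)

            arr[idx] = orig + eps
            fp = f()
            arr[idx] = orig - eps
            fm = f()
            arr[idx] = orig
            num = (fp - fm) / (2 * eps)
            ana = P[name].grad[idx]
            denom = max(1e-6, abs(num), abs(ana))
            assert abs(num - ana) / denom < 1e-4, (name, num, ana)
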