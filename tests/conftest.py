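import numpy as np
import pytest
from rdkit import Chem

import cliffgnn as cg
from cliffgnn.objectives import LossConfig


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic congeneric series with its construction truth."""
    records, truth = cg.generate_benchmark()
    return records, truth


@pytest.fixture(scope="session")
def pair_data(benchmark):
    records, truth = benchmark
    graphs = {r.compound_id: cg.graph_from_smiles(r.smiles, r.compound_id)
              for r in records}
    dataset = cg.assemble_pair_dataset(records, graphs=graphs)
    return records, truth, graphs, dataset


@pytest.fixture(scope="session")
def random_state():
    """Freshly initialized (untrained) model state for structural tests."""
    return cg.init_state(cg.ModelConfig(), seed=11)


@pytest.fixture(scope="session")
def positive_state():
    """A linear-surrogate state: affine along the zero-baseline path.

    GIN backbone (messages do not multiply edge and node inputs, unlike
    the edge-conditioned convolution), all weights nonnegative and all
    biases strictly positive, batch-norm running means zero: with one-hot
    (nonnegative) inputs every ReLU pre-activation stays strictly
    positive along the whole interpolation path, so the model is affine
    there and gradient-based attributions have exact closed forms.
    """
    state = cg.init_state(cg.ModelConfig(backbone="gin"), seed=5)
    for k, v in state.params.items():
        state.params[k] = np.abs(v)
        if k.endswith(("_b", "_b1", "_b2", "bn_beta")) or k in ("b_CN", "b_UCN"):
            state.params[k] = np.full_like(v, 0.1)
    for k in state.bn_running:
        if k.endswith("_mean"):
            state.bn_running[k] = np.zeros_like(state.bn_running[k])
    return state


@pytest.fixture(scope="session")
def small_pair():
    """A featurized toluene/ethylbenzene cliff pair with MCS masks."""
    records = [
        cg.CompoundRecord("tol", "Cc1ccccc1", 7.5),
        cg.CompoundRecord("eb", "CCc1ccccc1", 6.0),
    ]
    graphs = {r.compound_id: cg.graph_from_smiles(r.smiles, r.compound_id)
              for r in records}
    dataset = cg.assemble_pair_dataset(records, graphs=graphs, min_pairs=1)
    assert len(dataset.pairs) == 1
    return records, graphs, dataset.pairs[0], dataset.colorings


def random_small_mol(rng, max_atoms=8):
    """Random small sanitizable molecule built as a tree plus maybe one
    ring-closing bond, used as MCS-oracle fodder."""
    elements = ["C", "C", "C", "N", "O"]
    for _ in range(50):
        n = int(rng.integers(2, max_atoms + 1))
        mol = Chem.RWMol()
        for _ in range(n):
            mol.AddAtom(Chem.Atom(elements[int(rng.integers(len(elements)))]))
        for i in range(1, n):
            j = int(rng.integers(0, i))
            order = Chem.BondType.DOUBLE if rng.random() < 0.15 \
                else Chem.BondType.SINGLE
            mol.AddBond(i, j, order)
        if n >= 4 and rng.random() < 0.4:
            a, b = rng.choice(n, size=2, replace=False)
            if mol.GetBondBetweenAtoms(int(a), int(b)) is None:
                mol.AddBond(int(a), int(b), Chem.BondType.SINGLE)
        try:
            m = mol.GetMol()
            Chem.SanitizeMol(m)
            return Chem.MolToSmiles(m)
        except Exception:
            continue
    raise RuntimeError("could not build a random molecule")


@pytest.fixture(scope="session")
def gl_loss():
    return LossConfig(penalty="group_lasso")
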