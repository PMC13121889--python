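"""Activity-cliff matched pairs: MCS matching, node masks, and fold splits.

A matched pair is two compounds sharing a maximum common substructure
(MCS) that covers at least a configurable fraction of both molecules,
with a potency difference of at least one log unit.  Atoms inside the
MCS mapping are the pair's *common* nodes; the rest are *uncommon* and
carry the signed ground-truth attribution labels: +1 on the uncommon
atoms of the more potent compound, -1 on those of the less potent one,
0 on the shared scaffold.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit.Chem import rdFMCS

from .mol_graphs import CompoundRecord, MolecularGraph, graph_from_smiles

log = logging.getLogger(__name__)

DEFAULT_CLIFF_THRESHOLD = 1.0  # log units of pIC50
DEFAULT_MIN_SHARED_FRACTION = 0.5
DEFAULT_MIN_PAIRS = 50
DEFAULT_MCS_TIMEOUT_S = 10


@dataclass
class ACPair:
    """Ordered activity-cliff pair; compound ``i`` is the first ligand."""

    pair_id: str
    i: str
    j: str
    y_i: float
    y_j: float
    mask_common_i: np.ndarray
    mask_uncommon_i: np.ndarray
    mask_common_j: np.ndarray
    mask_uncommon_j: np.ndarray
    shared_fraction_i: float
    shared_fraction_j: float

    @property
    def delta_y(self) -> float:
        return self.y_i - self.y_j


@dataclass
class GroundTruthColoring:
    """Signed per-atom labels for one pair: {+1, 0, -1} per atom."""

    pair_id: str
    labels_i: np.ndarray
    labels_j: np.ndarray


@dataclass
class FoldSplit:
    """One leakage-controlled compound-level split with derived pair sets."""

    fold: int
    seed: int
    train_compounds: frozenset
    val_compounds: frozenset
    test_compounds: frozenset
    train_pairs: list
    val_pairs: list
    test_pairs: list


@dataclass
class PairDataset:
    """Admitted pairs, their colorings, and assembly diagnostics."""

    pairs: list
    colorings: dict  # pair_id -> GroundTruthColoring
    diagnostics: dict = field(default_factory=dict)


# --------------------------------------------------------------------- MCS
def find_mcs(
    g_i: MolecularGraph,
    g_j: MolecularGraph,
    timeout_s: int = DEFAULT_MCS_TIMEOUT_S,
) -> dict[int, int] | None:
    """Maximum connected common substructure as an atom-index mapping.

    Matching rules: element-exact atoms, bond-order-exact bonds, ring
    atoms/bonds match only ring atoms/bonds, and the substructure must be
    connected.  Atom count is maximized (not bond count) so the result
    agrees with exhaustive connected-common-subgraph enumeration.  Among
    equal-size solutions the first substructure match in canonical RDKit
    order of compound ``i`` is taken, which makes the mapping
    deterministic.  Returns ``None`` on timeout.
    """
    res = rdFMCS.FindMCS(
        [g_i.mol, g_j.mol],
        maximizeBonds=False,
        matchValences=False,
        ringMatchesRingOnly=True,
        completeRingsOnly=False,
        timeout=int(timeout_s),
    )
    if res.canceled:
        return None
    if res.numAtoms >= 1 and res.queryMol is not None:
        match_i = g_i.mol.GetSubstructMatch(res.queryMol)
        match_j = g_j.mol.GetSubstructMatch(res.queryMol)
        if match_i and match_j:
            return dict(zip(match_i, match_j))
    # rdFMCS is bond-based and reports nothing for single-atom overlaps;
    # fall back to the largest (= any) single-atom common substructure.
    j_keys = {(sym, ring) for sym, _, _, ring, _, _ in g_j.atoms}
    for ai, (sym, _, _, ring, _, _) in enumerate(g_i.atoms):
        if (sym, ring) in j_keys:
            aj = next(
                k
                for k, (s2, _, _, r2, _, _) in enumerate(g_j.atoms)
                if (s2, r2) == (sym, ring)
            )
            return {ai: aj}
    return {}


def compute_masks(mapping: dict[int, int], g_i, g_j):
    """Binary common/uncommon node masks and shared heavy-atom fractions."""
    mask_common_i = np.zeros(g_i.n_atoms)
    mask_common_j = np.zeros(g_j.n_atoms)
    for ai, aj in mapping.items():
        mask_common_i[ai] = 1.0
        mask_common_j[aj] = 1.0
    return (
        mask_common_i,
        1.0 - mask_common_i,
        mask_common_j,
        1.0 - mask_common_j,
        float(mask_common_i.sum() / g_i.n_atoms),
        float(mask_common_j.sum() / g_j.n_atoms),
    )


def is_activity_cliff(y_i, y_j, threshold: float = DEFAULT_CLIFF_THRESHOLD) -> bool:
    """True iff the potency difference is at least `threshold` log units."""
    return abs(y_i - y_j) >= threshold


def ground_truth_coloring(pair: ACPair) -> GroundTruthColoring:
    """Signed atom labels: sign(delta_y) on uncommon atoms of i, the
    opposite sign on uncommon atoms of j, zero on common atoms."""
    if pair.delta_y == 0:
        raise ValueError(f"pair {pair.pair_id} has delta_y = 0; not a cliff")
    s = float(np.sign(pair.delta_y))
    return GroundTruthColoring(
        pair_id=pair.pair_id,
        labels_i=s * pair.mask_uncommon_i,
        labels_j=-s * pair.mask_uncommon_j,
    )


def assemble_pair_dataset(
    compounds: list[CompoundRecord],
    graphs: dict[str, MolecularGraph] | None = None,
    min_shared_fraction: float = DEFAULT_MIN_SHARED_FRACTION,
    cliff_threshold: float = DEFAULT_CLIFF_THRESHOLD,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    timeout_s: int = DEFAULT_MCS_TIMEOUT_S,
) -> PairDataset:
    """Enumerate qualifying activity-cliff pairs over a compound set.

    One ordered pair is emitted per unordered combination; the compound
    earlier in the input list is the first ligand.  A pair is admitted
    when |delta_y| >= `cliff_threshold` and the MCS covers at least
    `min_shared_fraction` of BOTH molecules.  Datasets with fewer than
    `min_pairs` admitted pairs are rejected (empty result + diagnostic),
    mirroring the minimum-size rule for single-target benchmarks.
    MCS results are cached per SMILES pair, so congeneric series with
    repeated structures assemble quickly.
    """
    if graphs is None:
        graphs = {c.compound_id: graph_from_smiles(c.smiles, c.compound_id)
                  for c in compounds}
    pairs, colorings = [], {}
    n_timeout = n_below_cliff = n_below_fraction = 0
    mcs_cache: dict[tuple, dict | None] = {}
    for a in range(len(compounds)):
        for b in range(a + 1, len(compounds)):
            ci, cj = compounds[a], compounds[b]
            if not is_activity_cliff(ci.activity, cj.activity, cliff_threshold):
                n_below_cliff += 1
                continue
            gi, gj = graphs[ci.compound_id], graphs[cj.compound_id]
            key = (ci.smiles, cj.smiles)
            if key not in mcs_cache:
                mcs_cache[key] = find_mcs(gi, gj, timeout_s)
            mapping = mcs_cache[key]
            if mapping is None:
                n_timeout += 1
                log.warning("mcs_timeout: pair (%s, %s) excluded",
                            ci.compound_id, cj.compound_id)
                continue
            mc_i, mu_i, mc_j, mu_j, fr_i, fr_j = compute_masks(mapping, gi, gj)
            if fr_i < min_shared_fraction or fr_j < min_shared_fraction:
                n_below_fraction += 1
                continue
            pair = ACPair(
                pair_id=f"{ci.compound_id}__{cj.compound_id}",
                i=ci.compound_id,
                j=cj.compound_id,
                y_i=ci.activity,
                y_j=cj.activity,
                mask_common_i=mc_i,
                mask_uncommon_i=mu_i,
                mask_common_j=mc_j,
                mask_uncommon_j=mu_j,
                shared_fraction_i=fr_i,
                shared_fraction_j=fr_j,
            )
            pairs.append(pair)
            colorings[pair.pair_id] = ground_truth_coloring(pair)
    diagnostics = {
        "n_compounds": len(compounds),
        "n_pairs": len(pairs),
        "n_below_cliff": n_below_cliff,
        "n_below_fraction": n_below_fraction,
        "n_mcs_timeout": n_timeout,
    }
    if len(pairs) < min_pairs:
        diagnostics["rejected"] = (
            f"only {len(pairs)} qualifying pairs; minimum is {min_pairs}"
        )
        log.warning("pair dataset rejected: %s", diagnostics["rejected"])
        return PairDataset([], {}, diagnostics)
    return PairDataset(pairs, colorings, diagnostics)


# ------------------------------------------------------------------ splits
def make_fold_splits(
    compounds: list[CompoundRecord],
    pairs: list[ACPair],
    k: int = 5,
    fractions: tuple = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> list[FoldSplit]:
    """k independent seeded 70/10/20 compound-level splits.

    Every pair follows its FIRST compound: a pair lands in the train,
    validation, or test pair set exactly when its first ligand is in the
    corresponding compound set, so no test pair's first ligand is ever a
    training compound.  The validation set is carved out of the training
    compounds, matching the split procedure used for single-target
    cross-validation benchmarks.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    known = {c.compound_id for c in compounds}
    for p in pairs:
        if p.i not in known or p.j not in known:
            raise ValueError(f"pair {p.pair_id} references unknown compounds")
    ids = [c.compound_id for c in compounds]
    n = len(ids)
    n_test = int(round(fractions[2] * n))
    n_val = int(round(fractions[1] * n))
    splits = []
    for fold in range(k):
        fold_seed = int(np.random.SeedSequence([seed, fold]).generate_state(1)[0]
                        % (2**31))
        rng = np.random.default_rng(fold_seed)
        perm = list(rng.permutation(ids))
        test = frozenset(perm[:n_test])
        val = frozenset(perm[n_test:n_test + n_val])
        train = frozenset(perm[n_test + n_val:])
        splits.append(
            FoldSplit(
                fold=fold,
                seed=fold_seed,
                train_compounds=train,
                val_compounds=val,
                test_compounds=test,
                train_pairs=[p.pair_id for p in pairs if p.i in train],
                val_pairs=[p.pair_id for p in pairs if p.i in val],
                test_pairs=[p.pair_id for p in pairs if p.i in test],
            )
        )
    return splits


# --------------------------------------------------------------------- I/O
def save_pair_dataset(dataset: PairDataset, csv_path, masks_path):
    """Write the pair list as CSV and the node masks as JSON."""
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pair_id", "id_i", "id_j", "delta_y",
                    "shared_fraction_i", "shared_fraction_j"])
        for p in dataset.pairs:
            w.writerow([p.pair_id, p.i, p.j, f"{p.delta_y:.6f}",
                        f"{p.shared_fraction_i:.6f}",
                        f"{p.shared_fraction_j:.6f}"])
    masks = {
        p.pair_id: {
            "id_i": p.i,
            "id_j": p.j,
            "mask_common_i": p.mask_common_i.astype(int).tolist(),
            "mask_common_j": p.mask_common_j.astype(int).tolist(),
            "y_i": p.y_i,
            "y_j": p.y_j,
            "shared_fraction_i": p.shared_fraction_i,
            "shared_fraction_j": p.shared_fraction_j,
        }
        for p in dataset.pairs
    }
    with open(masks_path, "w") as fh:
        json.dump(masks, fh)


def load_pair_dataset(masks_path) -> PairDataset:
    """Rebuild a pair dataset (pairs + colorings) from the masks JSON."""
    with open(masks_path) as fh:
        masks = json.load(fh)
    pairs, colorings = [], {}
    for pid, rec in masks.items():
        mc_i = np.asarray(rec["mask_common_i"], dtype=np.float64)
        mc_j = np.asarray(rec["mask_common_j"], dtype=np.float64)
        pair = ACPair(
            pair_id=pid,
            i=rec["id_i"],
            j=rec["id_j"],
            y_i=float(rec["y_i"]),
            y_j=float(rec["y_j"]),
            mask_common_i=mc_i,
            mask_uncommon_i=1.0 - mc_i,
            mask_common_j=mc_j,
            mask_uncommon_j=1.0 - mc_j,
            shared_fraction_i=float(rec["shared_fraction_i"]),
            shared_fraction_j=float(rec["shared_fraction_j"]),
        )
        pairs.append(pair)
        colorings[pid] = ground_truth_coloring(pair)
    return PairDataset(pairs, colorings, {"n_pairs": len(pairs),
                                          "source": str(masks_path)})
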