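"""SMILES parsing and fixed-width featurization of heavy-atom molecular graphs.

Each compound is a heavy-atom graph (hydrogens implicit) with a 50-column
atom feature matrix and a 10-column bond feature matrix; every undirected
bond contributes two directed edges with identical feature rows.  The
column layout is fixed and versioned (see :data:`ATOM_FEATURE_LAYOUT` and
:data:`BOND_FEATURE_LAYOUT`) so that trained models and attribution maps
are comparable across runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

log = logging.getLogger(__name__)

N_ATOM_FEATURES = 50
N_BOND_FEATURES = 10

#: 35 element symbols + a trailing "other" slot = 36 one-hot columns.
ELEMENT_VOCAB = (
    "C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B",
    "Si", "Se", "Te", "As", "Al", "Zn", "Ca", "Mg", "Na", "K",
    "Li", "Fe", "Cu", "Mn", "Co", "Ni", "Cr", "Sn", "Ge", "Sb",
    "Bi", "Ag", "Pd", "Pt", "H",
)
DEGREES = (0, 1, 2, 3, 4, 5)
IMPLICIT_HS = (0, 1, 2, 3, 4)

ATOM_FEATURE_LAYOUT = (
    ("element_onehot", len(ELEMENT_VOCAB) + 1),  # 36, last slot = "other"
    ("degree_onehot", len(DEGREES)),             # 6
    ("implicit_h_onehot", len(IMPLICIT_HS)),     # 5
    ("formal_charge", 1),                        # clipped to [-1, 1]
    ("aromatic", 1),
    ("in_ring", 1),
)

BOND_ORDERS = ("single", "double", "triple", "aromatic")
BOND_STEREO = ("Z", "E", "ANY", "NONE")

BOND_FEATURE_LAYOUT = (
    ("order_onehot", len(BOND_ORDERS)),   # 4
    ("stereo_onehot", len(BOND_STEREO)),  # 4
    ("conjugated", 1),
    ("in_ring", 1),
)

assert sum(n for _, n in ATOM_FEATURE_LAYOUT) == N_ATOM_FEATURES
assert sum(n for _, n in BOND_FEATURE_LAYOUT) == N_BOND_FEATURES

_RDKIT_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}
_RDKIT_STEREO = {
    Chem.BondStereo.STEREOZ: "Z",
    Chem.BondStereo.STEREOE: "E",
    Chem.BondStereo.STEREOANY: "ANY",
    Chem.BondStereo.STEREONONE: "NONE",
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass
class MolecularGraph:
    """Featurized heavy-atom graph of one compound."""

    compound_id: str
    n_atoms: int
    atoms: list  # (symbol, formal_charge, aromatic, in_ring, degree, implicit_h)
    bonds: list  # (a, b, order, stereo, in_ring, conjugated)
    node_features: np.ndarray | None = None
    edge_features: np.ndarray | None = None
    directed_edge_index: np.ndarray | None = None  # (2, n_directed_edges)
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)
    #: the literal SMILES the graph was parsed from; graphs parsed from the
    #: same string share atom ordering and can be batched as one structure
    source_smiles: str = ""

    @property
    def n_directed_edges(self) -> int:
        return 2 * len(self.bonds)


def parse_smiles(smiles: str, compound_id: str = "") -> MolecularGraph:
    """Parse a SMILES string into an (unfeaturized) heavy-atom graph.

    Atom ordering follows the RDKit parse order, which is deterministic for
    identical input strings.  Aromaticity is perceived by RDKit
    sanitization; hydrogens stay implicit.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"SMILES has no heavy atoms: {smiles!r}")
    atoms = [
        (
            a.GetSymbol(),
            a.GetFormalCharge(),
            a.GetIsAromatic(),
            a.IsInRing(),
            a.GetDegree(),
            a.GetNumImplicitHs() + a.GetNumExplicitHs(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        order = _RDKIT_BOND_ORDER.get(b.GetBondType())
        if order is None:
            raise SmilesParseError(
                f"unsupported bond type {b.GetBondType()} in {smiles!r}"
            )
        bonds.append(
            (
                b.GetBeginAtomIdx(),
                b.GetEndAtomIdx(),
                order,
                _RDKIT_STEREO.get(b.GetStereo(), "NONE"),
                b.IsInRing(),
                b.GetIsConjugated(),
            )
        )
    return MolecularGraph(
        compound_id=compound_id,
        n_atoms=mol.GetNumAtoms(),
        atoms=atoms,
        bonds=bonds,
        mol=mol,
        source_smiles=smiles,
    )


def _atom_row(symbol, charge, aromatic, in_ring, degree, n_h):
    row = np.zeros(N_ATOM_FEATURES)
    try:
        idx = ELEMENT_VOCAB.index(symbol)
    except ValueError:
        idx = len(ELEMENT_VOCAB)  # "other" slot
        log.warning("element %s outside vocabulary; mapped to 'other'", symbol)
    row[idx] = 1.0
    off = len(ELEMENT_VOCAB) + 1
    row[off + min(degree, DEGREES[-1])] = 1.0
    off += len(DEGREES)
    row[off + min(n_h, IMPLICIT_HS[-1])] = 1.0
    off += len(IMPLICIT_HS)
    row[off] = float(np.clip(charge, -1, 1))
    row[off + 1] = float(aromatic)
    row[off + 2] = float(in_ring)
    return row


def _bond_row(order, stereo, in_ring, conjugated):
    row = np.zeros(N_BOND_FEATURES)
    row[BOND_ORDERS.index(order)] = 1.0
    row[len(BOND_ORDERS) + BOND_STEREO.index(stereo)] = 1.0
    row[8] = float(conjugated)
    row[9] = float(in_ring)
    return row


def featurize(graph: MolecularGraph) -> MolecularGraph:
    """Populate the fixed-width feature matrices of a parsed graph in place.

    Directed edges are emitted in bond order, (a, b) then (b, a), with
    identical feature rows for the two directions.
    """
    graph.node_features = np.array(
        [_atom_row(*a) for a in graph.atoms], dtype=np.float64
    ).reshape(graph.n_atoms, N_ATOM_FEATURES)
    src, dst, rows = [], [], []
    for a, b, order, stereo, in_ring, conj in graph.bonds:
        row = _bond_row(order, stereo, in_ring, conj)
        src += [a, b]
        dst += [b, a]
        rows += [row, row]
    graph.edge_features = (
        np.array(rows, dtype=np.float64).reshape(-1, N_BOND_FEATURES)
        if rows
        else np.zeros((0, N_BOND_FEATURES))
    )
    graph.directed_edge_index = np.array(
        [src, dst], dtype=np.intp
    ).reshape(2, -1)
    return graph


def graph_from_smiles(smiles: str, compound_id: str = "") -> MolecularGraph:
    """Convenience: parse and featurize in one call."""
    return featurize(parse_smiles(smiles, compound_id))


@dataclass(frozen=True)
class CompoundRecord:
    """One compound with its potency in pIC50 (log10 molar) units."""

    compound_id: str
    smiles: str
    activity: float  # pIC50

    def __post_init__(self):
        if not math.isfinite(self.activity):
            raise ValueError(f"non-finite activity for {self.compound_id}")


_ACTIVITY_KINDS = ("pIC50", "IC50_nM", "IC50_M")


def to_pic50(value: float, activity_kind: str) -> float:
    """Convert a raw activity value to pIC50 = -log10(IC50 in molar)."""
    if activity_kind == "pIC50":
        return float(value)
    if activity_kind == "IC50_nM":
        return -math.log10(value * 1e-9)
    if activity_kind == "IC50_M":
        return -math.log10(value)
    raise ValueError(f"unknown activity_kind {activity_kind!r}; "
                     f"expected one of {_ACTIVITY_KINDS}")


def load_compound_table(
    path,
    id_column: str = "compound_id",
    smiles_column: str = "smiles",
    activity_column: str = "activity",
    activity_kind: str = "IC50_nM",
) -> list[CompoundRecord]:
    """Load a compound CSV and convert activities to pIC50.

    Rows whose activity is missing or non-finite after conversion are
    dropped (the count is logged).  Duplicate compound ids are an error.
    The default activity unit is nanomolar IC50, the common database
    convention; pass ``activity_kind="pIC50"`` for pre-converted tables.
    """
    df = pd.read_csv(path)
    for col in (id_column, smiles_column, activity_column):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    dup = df[id_column][df[id_column].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate compound ids in {path}: {sorted(set(dup))}")
    records = []
    dropped = 0
    for _, row in df.iterrows():
        raw = row[activity_column]
        try:
            act = to_pic50(float(raw), activity_kind)
        except (TypeError, ValueError):
            act = float("nan")
        if not math.isfinite(act):
            dropped += 1
            continue
        records.append(
            CompoundRecord(str(row[id_column]), str(row[smiles_column]), act)
        )
    if dropped:
        log.info("dropped %d rows with missing/non-finite activity", dropped)
    return records
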