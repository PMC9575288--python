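"""Drug featurization: molecular graph and 881-bit substructure fingerprint.

A drug enters the network through two channels.  The *graph* channel sees the
heavy-atom molecular graph with a 78-dimensional binary feature vector per
atom (atom-symbol one-hot over 44 symbols with an "other" bucket, degree
one-hot 0-10, total-hydrogen one-hot 0-10, implicit-valence one-hot 0-10, and
an aromaticity flag: 44 + 11 + 11 + 11 + 1 = 78).  The *fingerprint* channel
sees a deterministic 881-bit substructure presence vector (see
:mod:`nerd._fingerprint_keys` for the key dictionary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from ._fingerprint_keys import N_BITS, evaluate_keys

ATOM_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
]  # + "other" bucket -> 44-wide one-hot
N_SYMBOLS = len(ATOM_SYMBOLS) + 1
MAX_ONEHOT = 10  # degree / hydrogens / valence are bucketed at 10
ATOM_FEATURE_DIM = N_SYMBOLS + 3 * (MAX_ONEHOT + 1) + 1  # = 78

FINGERPRINT_BITS = N_BITS


@dataclass
class Fingerprint:
    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (FINGERPRINT_BITS,):
            raise ValueError(
                f"fingerprint must have {FINGERPRINT_BITS} bits, got {self.bits.shape}")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be binary")


@dataclass
class MolecularGraph:
    node_features: np.ndarray  # (n_atoms, 78) binary
    adjacency: np.ndarray      # (n_atoms, n_atoms) binary, zero diagonal

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=np.float32)
        self.adjacency = np.asarray(self.adjacency, dtype=np.float32)
        n = self.node_features.shape[0]
        if self.node_features.ndim != 2 or self.node_features.shape[1] != ATOM_FEATURE_DIM:
            raise ValueError(f"node features must be (n, {ATOM_FEATURE_DIM})")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape must match node count")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency must have zero diagonal (no stored self-loops)")

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]


@dataclass
class DrugRecord:
    drug_id: str
    smiles: str
    fingerprint: Fingerprint | None = None
    graph: MolecularGraph | None = field(default=None, repr=False)


def _one_hot(value: int, size: int) -> np.ndarray:
    vec = np.zeros(size, dtype=np.float32)
    vec[min(value, size - 1)] = 1.0
    return vec


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    symbol = atom.GetSymbol()
    idx = ATOM_SYMBOLS.index(symbol) if symbol in ATOM_SYMBOLS else N_SYMBOLS - 1
    return np.concatenate([
        _one_hot(idx, N_SYMBOLS),
        _one_hot(atom.GetDegree(), MAX_ONEHOT + 1),
        _one_hot(atom.GetTotalNumHs(), MAX_ONEHOT + 1),
        _one_hot(atom.GetImplicitValence(), MAX_ONEHOT + 1),
        np.array([1.0 if atom.GetIsAromatic() else 0.0], dtype=np.float32),
    ])


def _parse(smiles: str, drug_id: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        who = f" (drug {drug_id})" if drug_id else ""
        raise ValueError(f"unparseable SMILES{who}: {smiles!r}")
    return mol


def smiles_to_graph(smiles: str, drug_id: str | None = None) -> MolecularGraph:
    """Heavy-atom molecular graph: one node per atom, one undirected edge per bond."""
    mol = _parse(smiles, drug_id)
    n = mol.GetNumAtoms()
    features = np.stack([_atom_features(a) for a in mol.GetAtoms()])
    adjacency = np.zeros((n, n), dtype=np.float32)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i, j] = adjacency[j, i] = 1.0
    return MolecularGraph(features, adjacency)


def compute_fingerprint(smiles: str, drug_id: str | None = None) -> Fingerprint:
    """Deterministic 881-bit substructure presence vector."""
    mol = _parse(smiles, drug_id)
    return Fingerprint(np.asarray(evaluate_keys(mol), dtype=np.uint8))


def load_fingerprint_table(path: str | Path) -> dict[str, Fingerprint]:
    """Read precomputed fingerprints: one row per drug, drug_id + 881 binary columns."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[1] != FINGERPRINT_BITS:
        raise ValueError(
            f"{path}: expected {FINGERPRINT_BITS} fingerprint columns, got {df.shape[1]}")
    out: dict[str, Fingerprint] = {}
    for i, (drug_id, row) in enumerate(df.iterrows()):
        values = row.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"{path}: non-binary fingerprint value at row {i}")
        out[str(drug_id)] = Fingerprint(values.astype(np.uint8))
    return out
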