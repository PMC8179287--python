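"""Heavy-atom molecular graphs and discrete atom/bond featurisation.

Molecules are handled as heavy-atom graphs: explicit hydrogens are folded
into a per-atom hydrogen count.  Atom-map numbers, when present, are the
join key used to locate reacting atoms across a reaction's reactant set.
RDKit does all parsing and canonicalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .errors import MappingError, ParseError

RDLogger.DisableLog("rdApp.*")

# Element vocabulary: C, O, N, P, S, F, Cl, Br, I, Si, B one-hot + an
# "other" bucket; hydrogen is folded into the per-atom H count.
ELEMENT_LIST = [6, 8, 7, 15, 16, 9, 17, 35, 53, 14, 5]
MAX_DEGREE = 5          # one-hot 0..5
MAX_VALENCE = 6         # one-hot 0..6
MAX_NUM_H = 4           # one-hot 0..4
BOND_TYPES = ["single", "double", "triple", "aromatic"]

# documented slot budget of the discrete featurisation
ATOM_FDIM = (len(ELEMENT_LIST) + 1) + (MAX_DEGREE + 1) + (MAX_VALENCE + 1) + (MAX_NUM_H + 1) + 1 + 1
BOND_FDIM = len(BOND_TYPES) + 1

_BOND_TYPE_OF = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass
class AtomNode:
    index: int
    map_number: Optional[int]
    element: int
    degree: int
    valence: int
    aromatic: bool
    num_H: int
    formal_charge: int = 0


@dataclass
class BondEdge:
    i: int
    j: int
    bond_type: str
    in_ring: bool


@dataclass
class MolGraph:
    atoms: list
    bonds: list
    smiles_canonical: str
    net_formal_charge: int
    mol: Chem.Mol = field(repr=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def map_to_index(self) -> dict:
        """Map-number -> atom-index lookup (mapped atoms only)."""
        return {a.map_number: a.index for a in self.atoms if a.map_number}


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES with atom maps stripped (table join key)."""
    mol = mol_from_smiles(smiles)
    mol = Chem.Mol(mol)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def graph_from_mol(mol: Chem.Mol) -> MolGraph:
    maps = [a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0]
    if len(maps) != len(set(maps)):
        raise MappingError("duplicated atom-map numbers in reactant set")
    atoms = [
        AtomNode(
            index=a.GetIdx(),
            map_number=a.GetAtomMapNum() or None,
            element=a.GetAtomicNum(),
            degree=a.GetDegree(),
            valence=a.GetTotalValence(),
            aromatic=a.GetIsAromatic(),
            num_H=a.GetTotalNumHs(),
            formal_charge=a.GetFormalCharge(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [
        BondEdge(
            i=b.GetBeginAtomIdx(),
            j=b.GetEndAtomIdx(),
            bond_type=_BOND_TYPE_OF.get(b.GetBondType(), "single"),
            in_ring=b.IsInRing(),
        )
        for b in mol.GetBonds()
    ]
    return MolGraph(
        atoms=atoms,
        bonds=bonds,
        smiles_canonical=Chem.MolToSmiles(mol),
        net_formal_charge=Chem.GetFormalCharge(mol),
        mol=mol,
    )


def parse_mapped_smiles(smiles: str) -> MolGraph:
    """Parse a (possibly atom-mapped, possibly multi-component) SMILES.

    Hydrogens are folded into per-atom counts; duplicate map numbers raise
    :class:`MappingError`.
    """
    return graph_from_mol(mol_from_smiles(smiles))


def _one_hot(value: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[min(value, size - 1)] = 1.0
    return v


def atom_features(g: MolGraph) -> np.ndarray:
    """Discrete per-atom feature matrix (n_atoms x ATOM_FDIM).

    Slots: element one-hot (+other), degree, valence, H-count one-hots,
    aromatic flag, formal charge.  Out-of-vocabulary elements land in the
    "other" bucket; they never error.
    """
    rows = []
    for a in g.atoms:
        elem = np.zeros(len(ELEMENT_LIST) + 1)
        elem[ELEMENT_LIST.index(a.element) if a.element in ELEMENT_LIST else -1] = 1.0
        rows.append(
            np.concatenate(
                [
                    elem,
                    _one_hot(a.degree, MAX_DEGREE + 1),
                    _one_hot(a.valence, MAX_VALENCE + 1),
                    _one_hot(a.num_H, MAX_NUM_H + 1),
                    [1.0 if a.aromatic else 0.0],
                    [float(a.formal_charge)],
                ]
            )
        )
    return np.array(rows).reshape(g.n_atoms, ATOM_FDIM)


def bond_features_discrete(g: MolGraph) -> np.ndarray:
    """One-hot bond type + ring flag per bond (n_bonds x BOND_FDIM)."""
    rows = []
    for b in g.bonds:
        v = np.zeros(BOND_FDIM)
        v[BOND_TYPES.index(b.bond_type)] = 1.0
        v[-1] = 1.0 if b.in_ring else 0.0
        rows.append(v)
    return np.array(rows).reshape(g.n_bonds, BOND_FDIM)


def directed_edges(g: MolGraph):
    """Directed-edge arrays (src, dst, rev, bond_index) for message passing.

    Every undirected bond contributes two directed edges; ``rev[e]`` is the
    index of the opposite direction and ``bond_index[e]`` the originating
    undirected bond.
    """
    src, dst, bond_index = [], [], []
    for k, b in enumerate(g.bonds):
        src += [b.i, b.j]
        dst += [b.j, b.i]
        bond_index += [k, k]
    n_edges = len(src)
    rev = np.arange(n_edges) ^ 1  # edges come in (e, e^1) pairs
    return (
        np.array(src, dtype=np.intp),
        np.array(dst, dtype=np.intp),
        rev,
        np.array(bond_index, dtype=np.intp),
    )
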