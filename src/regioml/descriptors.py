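"""QM reactivity descriptors: data model, CSV I/O, and RBF expansion.

Six descriptors are carried per molecule: four atomic (partial charge,
electrophilic and nucleophilic condensed Fukui indices, isotropic NMR
shielding) and two per bond (bond order, bond length).  For a neutral
molecule the charges sum to the net formal charge and each Fukui channel
sums to one; externally computed tables may violate these sums up to a
small tolerance and can be renormalised on ingestion, while model-predicted
tables satisfy them exactly.

Storage convention: tables are keyed by map-stripped canonical SMILES and
atom indices refer to the atom order obtained by re-parsing that canonical
SMILES.  Map numbers are never stored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

from .errors import AlignmentError, SchemaError
from .mol_graph import canonical_smiles, parse_mapped_smiles

ATOM_CHANNELS = ["charge", "fukui_elec", "fukui_nuc", "nmr"]
BOND_CHANNELS = ["bond_order", "bond_length"]

ATOM_CSV_COLUMNS = ["smiles", "atom_index", "charge", "fukui_elec", "fukui_nuc", "nmr"]
BOND_CSV_COLUMNS = ["smiles", "atom_index_1", "atom_index_2", "bond_order", "bond_length"]

#: tolerance accepted for conservation sums of externally computed tables
EXTERNAL_SUM_TOL = 1e-2


@dataclass
class RBFSpec:
    """Radial-basis grid: strictly increasing centers and width gamma.

    Component ``k`` of the expansion of scalar ``x`` is
    ``exp(-gamma * (x - centers[k])**2)``.
    """

    centers: np.ndarray
    gamma: float

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.centers.ndim != 1 or len(self.centers) < 1:
            raise ValueError("centers must be a 1-D grid")
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("centers must be strictly increasing")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def dim(self) -> int:
        return len(self.centers)


def rbf_expand(x, spec: RBFSpec) -> np.ndarray:
    """Gaussian expansion of scalar(s) ``x`` on the grid of ``spec``.

    A scalar maps to a vector of length ``spec.dim``; an array of shape
    ``(n,)`` maps to ``(n, spec.dim)``.  Values outside the center range are
    legal; components simply decay.
    """
    x = np.asarray(x, dtype=np.float64)
    return np.exp(-spec.gamma * (x[..., None] - spec.centers) ** 2)


def _grid(lo: float, hi: float, dim: int) -> RBFSpec:
    centers = np.linspace(lo, hi, dim)
    spacing = centers[1] - centers[0]
    # neighbouring Gaussians cross at half height
    return RBFSpec(centers=centers, gamma=np.log(2.0) / spacing**2)


def default_rbf_specs(dim: int = 8) -> Dict[str, RBFSpec]:
    """Versioned default grids, one per descriptor, all of equal dimension.

    Equal dimension keeps the concatenated QM block the same width as the
    learned embedding block so neither dominates the fused representation.
    Ranges cover the values the synthetic oracle and typical DFT tables
    produce: charges in e, shielding in ppm, lengths in Angstrom.
    """
    return {
        "charge": _grid(-1.0, 1.0, dim),
        "fukui_elec": _grid(0.0, 0.5, dim),
        "fukui_nuc": _grid(0.0, 0.5, dim),
        "nmr": _grid(0.0, 300.0, dim),
        "bond_order": _grid(0.5, 3.0, dim),
        "bond_length": _grid(0.9, 2.4, dim),
    }


@dataclass
class MolDescriptors:
    """Descriptors of one molecule in canonical atom order.

    ``bonds`` maps an unordered atom-index pair (stored as a sorted tuple)
    to ``(bond_order, bond_length)``.
    """

    charge: np.ndarray
    fukui_elec: np.ndarray
    fukui_nuc: np.ndarray
    nmr: np.ndarray
    bonds: Dict[Tuple[int, int], Tuple[float, float]] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.charge)

    def atom_channel(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def bond_value(self, i: int, j: int) -> Tuple[float, float]:
        return self.bonds[(min(i, j), max(i, j))]


class DescriptorTable:
    """Per-molecule descriptor store keyed by canonical SMILES."""

    def __init__(self):
        self._data: Dict[str, MolDescriptors] = {}

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, smiles: str) -> bool:
        return canonical_smiles(smiles) in self._data

    def smiles(self) -> Iterable[str]:
        return self._data.keys()

    def add(self, smiles: str, desc: MolDescriptors) -> None:
        key = canonical_smiles(smiles)
        g = parse_mapped_smiles(key)
        if desc.n_atoms != g.n_atoms:
            raise AlignmentError(
                f"{key}: table has {desc.n_atoms} atom rows, molecule has {g.n_atoms} heavy atoms"
            )
        self._data[key] = desc

    def get(self, smiles: str) -> MolDescriptors:
        return self._data[canonical_smiles(smiles)]

    def items(self):
        return self._data.items()

    # ------------------------------------------------------------------
    def check_conservation(self, tol: float = EXTERNAL_SUM_TOL) -> None:
        """Raise if any molecule violates the conservation sums beyond tol."""
        for smi, d in self._data.items():
            net = parse_mapped_smiles(smi).net_formal_charge
            for name, target in [("charge", net), ("fukui_elec", 1.0), ("fukui_nuc", 1.0)]:
                s = float(d.atom_channel(name).sum())
                if abs(s - target) > tol:
                    raise AlignmentError(f"{smi}: sum({name}) = {s:.4f}, expected {target}")

    def renormalize(self) -> None:
        """Spread each molecule's conservation excess uniformly over atoms."""
        for smi, d in self._data.items():
            net = parse_mapped_smiles(smi).net_formal_charge
            n = d.n_atoms
            d.charge += (net - d.charge.sum()) / n
            d.fukui_elec += (1.0 - d.fukui_elec.sum()) / n
            d.fukui_nuc += (1.0 - d.fukui_nuc.sum()) / n


def save_descriptor_table(table: DescriptorTable, path: str) -> None:
    """Write a table as ``atoms.csv`` + ``bonds.csv`` under directory ``path``."""
    os.makedirs(path, exist_ok=True)
    atom_rows, bond_rows = [], []
    for smi, d in table.items():
        for i in range(d.n_atoms):
            atom_rows.append([smi, i, d.charge[i], d.fukui_elec[i], d.fukui_nuc[i], d.nmr[i]])
        for (i, j), (order, length) in sorted(d.bonds.items()):
            bond_rows.append([smi, i, j, order, length])
    pd.DataFrame(atom_rows, columns=ATOM_CSV_COLUMNS).to_csv(
        os.path.join(path, "atoms.csv"), index=False, float_format="%.17g"
    )
    pd.DataFrame(bond_rows, columns=BOND_CSV_COLUMNS).to_csv(
        os.path.join(path, "bonds.csv"), index=False, float_format="%.17g"
    )


def load_descriptor_table(path: str) -> DescriptorTable:
    """Load ``atoms.csv`` + ``bonds.csv`` from directory ``path``.

    Raises :class:`SchemaError` on missing columns and
    :class:`AlignmentError` when a molecule's row count does not match its
    heavy-atom count.
    """
    atoms = pd.read_csv(os.path.join(path, "atoms.csv"), float_precision="round_trip")
    bonds = pd.read_csv(os.path.join(path, "bonds.csv"), float_precision="round_trip")
    for df, cols, which in [(atoms, ATOM_CSV_COLUMNS, "atom"), (bonds, BOND_CSV_COLUMNS, "bond")]:
        missing = set(cols) - set(df.columns)
        if missing:
            raise SchemaError(f"{which} table missing columns: {sorted(missing)}")

    table = DescriptorTable()
    bond_groups = {k: v for k, v in bonds.groupby("smiles")}
    for smi, grp in atoms.groupby("smiles"):
        grp = grp.sort_values("atom_index")
        if not np.array_equal(grp["atom_index"].to_numpy(), np.arange(len(grp))):
            raise AlignmentError(f"{smi}: atom indices are not 0..n-1")
        desc = MolDescriptors(
            charge=grp["charge"].to_numpy(dtype=np.float64),
            fukui_elec=grp["fukui_elec"].to_numpy(dtype=np.float64),
            fukui_nuc=grp["fukui_nuc"].to_numpy(dtype=np.float64),
            nmr=grp["nmr"].to_numpy(dtype=np.float64),
        )
        if smi in bond_groups:
            for _, row in bond_groups[smi].iterrows():
                i, j = int(row["atom_index_1"]), int(row["atom_index_2"])
                desc.bonds[(min(i, j), max(i, j))] = (
                    float(row["bond_order"]),
                    float(row["bond_length"]),
                )
        table.add(smi, desc)
    return table
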