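"""Synthetic test substrate: molecules, a descriptor oracle, toy reactions.

Nothing here is downloaded or claims chemical accuracy.  The oracle maps
local topology to descriptor values through simple, documented rules so
that learning experiments have a known ground truth:

* partial charge: electronegativity differences over bonded neighbours
  (plus the folded hydrogens), recentred so charges sum exactly to the net
  formal charge;
* Fukui indices: positive site scores shaped by classic activation
  patterns -- donor substituents raise the nucleophilic index ortho/para
  (topological distance 1 and 3 from the ipso atom), acceptors and ring
  nitrogens lower it there and favour meta -- normalised to sum to one;
* NMR shielding: an element baseline shifted by neighbour
  electronegativity and aromaticity;
* bond order/length: bond-type baselines (aromatic 1.5) and covalent-radius
  sums contracted by bond order.

Gaussian channel noise is applied per molecule with a seed derived from
the molecule's canonical SMILES, then conserved channels are renormalised,
so tables are bitwise reproducible and constraints hold exactly.

Toy selective reactions are aromatic halogenations whose major site is the
argmax of (nucleophilic Fukui index - steric penalty), the steric penalty
being the count of heavy atoms within two bonds of the site.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from rdkit import Chem

from .curation import ReactionTemplate, enumerate_candidates
from .descriptors import DescriptorTable, MolDescriptors
from .errors import NoMatch
from .mol_graph import canonical_smiles, mol_from_smiles, parse_mapped_smiles
from .records import CandidateOutcome, ReactionRecord

# Pauling electronegativities and covalent radii (Angstrom) for the vocabulary
EN = {1: 2.20, 5: 2.04, 6: 2.55, 7: 3.04, 8: 3.44, 9: 3.98, 14: 1.90,
      15: 2.19, 16: 2.58, 17: 3.16, 35: 2.96, 53: 2.66}
RCOV = {1: 0.31, 5: 0.84, 6: 0.76, 7: 0.71, 8: 0.66, 9: 0.57, 14: 1.11,
        15: 1.07, 16: 1.05, 17: 1.02, 35: 1.20, 53: 1.39}
NMR_BASE = {6: 120.0, 7: 180.0, 8: 260.0, 16: 400.0, 15: 320.0, 9: 330.0,
            17: 560.0, 35: 2400.0, 53: 4500.0, 5: 90.0, 14: 340.0}

# oracle coefficients (documented constants; the "ground truth physics")
CHARGE_NBR_COEF = 0.08      # e per unit electronegativity difference, per bond
CHARGE_H_COEF = 0.05        # e per folded hydrogen
FUKUI_BASE_AROM_C = 1.0
FUKUI_BASE_AROM_HET = 0.25
FUKUI_BASE_OTHER = 0.30
DONOR_OP_BOOST = 0.9        # ortho/para boost per unit donor strength
DONOR_META_BOOST = 0.18     # opposite-parity (meta-like) effect size
ACCEPTOR_OP_PENALTY = 0.55
RING_N_OP_PENALTY = 0.35
DIRECTING_DECAY = 0.6       # per-bond decay of directing effects beyond ortho
NMR_NBR_COEF = 25.0         # ppm per unit electronegativity difference
NMR_AROM_SHIFT = 18.0
BOND_ORDER_OF = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}

DEFAULT_NOISE = {"charge": 0.0, "fukui_elec": 0.0, "fukui_nuc": 0.0,
                 "nmr": 0.0, "bond_order": 0.0, "bond_length": 0.0}


@dataclass
class OracleSpec:
    """Deterministic topology-to-descriptor rules plus per-channel noise."""

    noise_sigma: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def sigma(self, channel: str) -> float:
        return self.noise_sigma.get(channel, 0.0)


@dataclass
class ToyReactionSpec:
    """Ground-truth selectivity rule for the toy reaction generator."""

    steric_weight: float = 0.005   # Fukui units per heavy atom within 2 bonds
    label_noise: float = 0.0       # probability of flipping major to a minor site
    min_rule_gap: float = 1e-6     # discard substrates whose top-2 sites tie:
                                   # an exact tie leaves the argmax undefined
    yield_low: float = 50.0
    yield_high: float = 100.0


# ----------------------------------------------------------------------
# molecule generator
# ----------------------------------------------------------------------
AROMATIC_CORES = [
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1ccc2ccccc2c1", "c1ccsc1", "c1ccoc1",
    "c1ccc(-c2ccccc2)cc1", "c1ccc2ncccc2c1", "c1ccc2occc2c1", "c1ccc2sccc2c1",
    "c1cnc2ccccc2c1", "c1ccc(Cc2ccccc2)cc1",
]
ALIPHATIC_CORES = ["CC", "CCC", "CCO", "CCN", "CC(C)C", "C1CCCCC1", "CCOC"]
SUBSTITUENTS = ["C", "CC", "C(C)C", "C(C)(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
                "F", "Cl", "Br", "C#N", "C(C)=O", "C(=O)OC", "C(=O)N", "C(F)(F)F",
                "S", "SC", "CO", "CCl", "CC#N", "COC", "CN"]


def _attach(mol: Chem.Mol, site: int, frag_smiles: str) -> Optional[Chem.Mol]:
    frag = Chem.MolFromSmiles(frag_smiles)
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combo.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def generate_molecules(n: int, seed: int = 0, aromatic_fraction: float = 0.7) -> List[str]:
    """Generate ``n`` distinct, valid, neutral molecules, deterministically."""
    rng = np.random.default_rng(seed)
    out: List[str] = []
    seen = set()
    attempts = 0
    while len(out) < n and attempts < 200 * n:
        attempts += 1
        aromatic = rng.random() < aromatic_fraction
        core = AROMATIC_CORES[rng.integers(len(AROMATIC_CORES))] if aromatic else \
            ALIPHATIC_CORES[rng.integers(len(ALIPHATIC_CORES))]
        mol = Chem.MolFromSmiles(core)
        for _ in range(int(rng.integers(1, 5))):
            sites = [
                a.GetIdx()
                for a in mol.GetAtoms()
                if a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0
                and (a.GetIsAromatic() == aromatic or not aromatic)
            ]
            if not sites:
                break
            nxt = _attach(
                mol,
                int(sites[rng.integers(len(sites))]),
                SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))],
            )
            if nxt is not None:
                mol = nxt
        smi = Chem.MolToSmiles(mol)
        if smi not in seen and Chem.GetFormalCharge(mol) == 0:
            seen.add(smi)
            out.append(smi)
    return out


# ----------------------------------------------------------------------
# descriptor oracle
# ----------------------------------------------------------------------
def _substituent_effects(mol: Chem.Mol):
    """(ipso_idx, strength) lists of donors and acceptors on aromatic atoms."""
    donors, acceptors = [], []
    for atom in mol.GetAtoms():
        if not atom.GetIsAromatic():
            continue
        for nbr in atom.GetNeighbors():
            if nbr.GetIsAromatic():
                continue
            z = nbr.GetAtomicNum()
            has_multi = any(
                b.GetBondTypeAsDouble() > 1.0 for b in nbr.GetBonds()
            )
            n_fluoro = sum(1 for x in nbr.GetNeighbors() if x.GetAtomicNum() == 9)
            if z in (8, 7, 16) and not has_multi:
                donors.append((atom.GetIdx(), 1.0))
            elif z in (9, 17, 35, 53):
                donors.append((atom.GetIdx(), 0.4))
            elif z == 6 and (has_multi or n_fluoro >= 2):
                acceptors.append((atom.GetIdx(), 1.0))
            elif z == 6:
                donors.append((atom.GetIdx(), 0.25))
    return donors, acceptors


def oracle_descriptors(smiles: str, spec: Optional[OracleSpec] = None) -> MolDescriptors:
    """Deterministic six-channel descriptor entry for one neutral molecule."""
    spec = spec or OracleSpec()
    key = canonical_smiles(smiles)
    g = parse_mapped_smiles(key)
    mol = g.mol
    n = g.n_atoms
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, zlib.crc32(key.encode())]))

    en = np.array([EN.get(a.element, 2.5) for a in g.atoms])
    num_h = np.array([a.num_H for a in g.atoms], dtype=float)

    # --- charge ---------------------------------------------------------
    q = np.zeros(n)
    for b in g.bonds:
        delta = CHARGE_NBR_COEF * (en[b.j] - en[b.i])
        q[b.i] += delta
        q[b.j] -= delta
    q += CHARGE_H_COEF * num_h * (EN[1] - en)
    q += rng.normal(0.0, spec.sigma("charge"), size=n)
    q += (g.net_formal_charge - q.sum()) / n

    # --- Fukui indices --------------------------------------------------
    dist = Chem.GetDistanceMatrix(mol)
    arom = np.array([a.aromatic for a in g.atoms])
    base = np.where(
        arom & (np.array([a.element for a in g.atoms]) == 6),
        FUKUI_BASE_AROM_C,
        np.where(arom, FUKUI_BASE_AROM_HET, FUKUI_BASE_OTHER),
    ).astype(float)
    s_nuc = base.copy()
    s_elec = base.copy()
    donors, acceptors = _substituent_effects(mol)
    for atom in g.atoms:
        if atom.aromatic and atom.element in (7, 8, 16):
            strength = RING_N_OP_PENALTY if atom.element == 7 else 0.15
            acceptors.append((atom.index, strength))

    # directing effects with parity (odd distance = ortho/para-like) and a
    # per-bond decay so topologically distinct sites get distinct values
    def _apply(ipso: int, strength: float, donor: bool) -> None:
        d = dist[ipso]
        reach = arom & (d >= 1)
        decay = DIRECTING_DECAY ** (d[reach] - 1.0)
        odd = (d[reach] % 2) == 1
        shape = np.where(odd, DONOR_OP_BOOST, -DONOR_META_BOOST) * strength * decay
        if donor:
            s_nuc[reach] += shape
            s_elec[reach] -= 0.5 * shape
        else:
            s_nuc[reach] -= ACCEPTOR_OP_PENALTY / DONOR_OP_BOOST * shape
            s_elec[reach] += shape

    for ipso, strength in donors:
        _apply(ipso, strength, donor=True)
    for ipso, strength in acceptors:
        _apply(ipso, strength, donor=False)

    def _normalise(s, sigma):
        s = np.clip(s, 0.02, None)
        f = s / s.sum()
        f += rng.normal(0.0, sigma, size=n)
        f = np.clip(f, 1e-4, None)
        return f / f.sum()

    f_nuc = _normalise(s_nuc, spec.sigma("fukui_nuc"))
    f_elec = _normalise(s_elec, spec.sigma("fukui_elec"))

    # --- NMR shielding ---------------------------------------------------
    nmr = np.array([NMR_BASE.get(a.element, 200.0) for a in g.atoms])
    for b in g.bonds:
        nmr[b.i] -= NMR_NBR_COEF * (en[b.j] - en[b.i])
        nmr[b.j] -= NMR_NBR_COEF * (en[b.i] - en[b.j])
    nmr -= NMR_AROM_SHIFT * arom
    nmr += rng.normal(0.0, spec.sigma("nmr"), size=n)

    # --- bonds -----------------------------------------------------------
    bonds = {}
    for b in g.bonds:
        order = BOND_ORDER_OF[b.bond_type]
        order -= 0.02 * (g.atoms[b.i].degree + g.atoms[b.j].degree - 2)
        order += rng.normal(0.0, spec.sigma("bond_order"))
        order = max(order, 0.2)
        r_sum = RCOV.get(g.atoms[b.i].element, 0.9) + RCOV.get(g.atoms[b.j].element, 0.9)
        length = r_sum * (1.06 - 0.07 * (order - 1.0))
        length += rng.normal(0.0, spec.sigma("bond_length"))
        length = max(length, 0.6)
        bonds[(min(b.i, b.j), max(b.i, b.j))] = (float(order), float(length))

    return MolDescriptors(charge=q, fukui_elec=f_elec, fukui_nuc=f_nuc, nmr=nmr, bonds=bonds)


def oracle_table(smiles_list, spec: Optional[OracleSpec] = None) -> DescriptorTable:
    table = DescriptorTable()
    for smi in smiles_list:
        table.add(smi, oracle_descriptors(smi, spec))
    return table


# ----------------------------------------------------------------------
# toy selective reactions
# ----------------------------------------------------------------------
HALOGENATIONS = [
    ("bromination", "BrBr", ReactionTemplate("[cH1:1].[Br:2][Br:3]>>[c:1][Br:2]", radius=0)),
    ("chlorination", "ClCl", ReactionTemplate("[cH1:1].[Cl:2][Cl:3]>>[c:1][Cl:2]", radius=0)),
]


def _mapped_substrate(smiles: str) -> str:
    """Canonical substrate with map numbers = canonical atom index + 1."""
    mol = mol_from_smiles(canonical_smiles(smiles))
    for a in mol.GetAtoms():
        a.SetAtomMapNum(a.GetIdx() + 1)
    return Chem.MolToSmiles(mol, canonical=False)


def steric_count(mol: Chem.Mol, site: int) -> int:
    """Heavy atoms within two bonds of a site (purely topological)."""
    dist = Chem.GetDistanceMatrix(mol)
    return int(((dist[site] > 0) & (dist[site] <= 2)).sum())


def site_score(desc: MolDescriptors, mol: Chem.Mol, site: int, spec: ToyReactionSpec) -> float:
    return float(desc.fukui_nuc[site]) - spec.steric_weight * steric_count(mol, site)


def generate_selective_reactions(
    n: int,
    spec: Optional[ToyReactionSpec] = None,
    seed: int = 0,
    oracle: Optional[OracleSpec] = None,
) -> List[ReactionRecord]:
    """Generate ``n`` selective toy halogenation records, deterministically.

    Every record has >= 2 symmetry-distinct candidate sites; the major
    index is the argmax of the noiseless selectivity rule, optionally
    flipped with probability ``label_noise``.
    """
    spec = spec or ToyReactionSpec()
    oracle = oracle or OracleSpec()
    rng = np.random.default_rng(seed)
    substrates = generate_molecules(6 * n, seed=seed + 1, aromatic_fraction=1.0)
    records: List[ReactionRecord] = []
    k = 0
    for smi in substrates:
        if len(records) >= n:
            break
        name, el_smiles, template = HALOGENATIONS[int(rng.integers(len(HALOGENATIONS)))]
        sub_mapped = _mapped_substrate(smi)
        sub_mol = mol_from_smiles(canonical_smiles(smi))
        n_sub = sub_mol.GetNumAtoms()
        el_mol = mol_from_smiles(el_smiles)
        for a in el_mol.GetAtoms():
            a.SetAtomMapNum(n_sub + a.GetIdx() + 1)
        reactants = f"{sub_mapped}.{Chem.MolToSmiles(el_mol, canonical=False)}"
        try:
            candidates = enumerate_candidates(template, reactants)
        except NoMatch:
            continue
        if len(candidates) < 2:
            continue
        desc = oracle_descriptors(smi, OracleSpec(seed=oracle.seed))  # noiseless rule input
        scores = sorted(
            [site_score(desc, sub_mol, c.pair[0] - 1, spec) for c in candidates],
            reverse=True,
        )
        if scores[0] - scores[1] < spec.min_rule_gap:
            continue
        scores = [site_score(desc, sub_mol, c.pair[0] - 1, spec) for c in candidates]
        major = int(np.argmax(scores))
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            others = [i for i in range(len(candidates)) if i != major]
            major = int(others[rng.integers(len(others))])
        records.append(
            ReactionRecord(
                reaction_id=f"rx{k:05d}",
                reactant_smiles=reactants,
                candidates=candidates,
                major_index=major,
                yield_pct=float(np.round(rng.uniform(spec.yield_low, spec.yield_high), 1)),
                reaction_class=name,
            )
        )
        k += 1
    return records


# ----------------------------------------------------------------------
# bundle writer
# ----------------------------------------------------------------------
def make_fixture_bundle(
    outdir: str,
    n_molecules: int = 200,
    n_reactions: int = 100,
    seed: int = 0,
    noise_sigma: Optional[Dict[str, float]] = None,
    toy_spec: Optional[ToyReactionSpec] = None,
) -> dict:
    """Write a self-consistent fixture bundle (molecules, descriptor tables,
    reactions, manifest) and return the manifest."""
    from .descriptors import save_descriptor_table
    from .records import save_reaction_dataset

    os.makedirs(outdir, exist_ok=True)
    ospec = OracleSpec(noise_sigma=noise_sigma or {}, seed=seed)
    molecules = generate_molecules(n_molecules, seed=seed)
    with open(os.path.join(outdir, "molecules.txt"), "w") as fh:
        fh.write("\n".join(molecules) + "\n")
    records = generate_selective_reactions(n_reactions, toy_spec, seed=seed, oracle=ospec)
    save_reaction_dataset(records, os.path.join(outdir, "reactions.csv"))
    # the table covers the molecule list plus every reaction component, so
    # the bundle is self-consistent for QM-mode training
    reactant_components = {
        canonical_smiles(part) for r in records for part in r.reactant_smiles.split(".")
    }
    table = oracle_table(sorted(set(molecules) | reactant_components), ospec)
    save_descriptor_table(table, os.path.join(outdir, "descriptors"))
    manifest = {
        "kind": "regioml-fixture-bundle",
        "seed": seed,
        "n_molecules": len(molecules),
        "n_reactions": len(records),
        "noise_sigma": ospec.noise_sigma,
        "toy_spec": vars(toy_spec or ToyReactionSpec()),
        "oracle_coefficients": {
            "charge_nbr": CHARGE_NBR_COEF,
            "charge_h": CHARGE_H_COEF,
            "donor_op_boost": DONOR_OP_BOOST,
            "acceptor_op_penalty": ACCEPTOR_OP_PENALTY,
            "ring_n_op_penalty": RING_N_OP_PENALTY,
            "nmr_nbr": NMR_NBR_COEF,
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
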