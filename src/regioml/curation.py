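"""Mining selective substitution reactions.

Pipeline: extract a subgraph rewrite rule (reaction-SMARTS template) from a
mapped reaction, reapply it to enumerate every symmetry-distinct candidate
product, flag records where more than one candidate exists and the recorded
product is one of them, filter by yield, and build random-CV and scaffold
splits.

Template extraction diffs the mapped reactant and product connectivity,
grows the changed-atom core by a bond radius, and renders each side as
SMARTS with explicit H counts on the reactant side so that only sites with
the right hydrogen count match.  The contract, regardless of how the rule
was produced, is self-application: the rule applied to its own source
reactants must regenerate the recorded product.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import (
    InsufficientData,
    NoChangeDetected,
    NoMatch,
    ParseError,
    RecordedProductNotAmongCandidates,
    RegiomlError,
    UnmappedProductAtom,
)
from .mol_graph import canonical_smiles, mol_from_smiles
from .records import CandidateOutcome, ReactionRecord


# ----------------------------------------------------------------------
# templates
# ----------------------------------------------------------------------
@dataclass
class ReactionTemplate:
    """Reaction-SMARTS rewrite rule with bookkeeping for reapplication.

    ``pair_maps`` are the two template map numbers joined by the newly
    formed bond; they anchor the reacting atom pair when the template is
    reapplied.
    """

    smarts: str
    radius: int
    pair_maps: Tuple[int, int] = field(init=False)
    n_reactant_components: int = field(init=False)

    def __post_init__(self):
        rxn = AllChem.ReactionFromSmarts(self.smarts)
        if rxn is None:
            raise ParseError(f"invalid reaction SMARTS: {self.smarts!r}")
        self.n_reactant_components = rxn.GetNumReactantTemplates()
        r_bonds, p_bonds = set(), set()
        for side, store in [(rxn.GetReactants(), r_bonds), (rxn.GetProducts(), p_bonds)]:
            for mol in side:
                for b in mol.GetBonds():
                    m1 = b.GetBeginAtom().GetAtomMapNum()
                    m2 = b.GetEndAtom().GetAtomMapNum()
                    if m1 and m2:
                        store.add(frozenset((m1, m2)))
        new_bonds = sorted(tuple(sorted(fs)) for fs in (p_bonds - r_bonds))
        if not new_bonds:
            raise NoChangeDetected("template forms no new bond between mapped atoms")
        self.pair_maps = new_bonds[0]

    def rxn(self):
        return AllChem.ReactionFromSmarts(self.smarts)


def _atom_query(atom: Chem.Atom, with_h: bool) -> str:
    """Bracket-atom SMARTS for one template atom."""
    sym = atom.GetSymbol()
    if atom.GetIsAromatic():
        sym = sym.lower()
    q = sym
    if with_h:
        q += f"H{atom.GetTotalNumHs()}"
    chg = atom.GetFormalCharge()
    if chg:
        q += ("+" if chg > 0 else "-") + (str(abs(chg)) if abs(chg) > 1 else "")
    if atom.GetAtomMapNum():
        q += f":{atom.GetAtomMapNum()}"
    return f"[{q}]"


def _fragment_smarts(mol: Chem.Mol, atom_idx: Sequence[int], with_h: bool) -> str:
    symbols = [_atom_query(a, with_h) for a in mol.GetAtoms()]
    return Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=list(atom_idx),
        atomSymbols=symbols,
        canonical=False,
        allBondsExplicit=True,
    )


def extract_template(mapped_rxn_smiles: str, radius: int = 1) -> ReactionTemplate:
    """Extract a rewrite rule from a mapped single-product reaction.

    The changed-atom core consists of mapped atoms whose bonding, hydrogen
    count or formal charge differs between the two sides, plus reactant
    atoms that disappear; the core is grown ``radius`` bonds outward over
    the reactant graphs.
    """
    parts = mapped_rxn_smiles.split(">")
    if len(parts) != 3:
        raise ParseError(f"expected reactants>reagents>products: {mapped_rxn_smiles!r}")
    rmol = mol_from_smiles(parts[0])
    pmol = mol_from_smiles(parts[2])
    for a in pmol.GetAtoms():
        if a.GetAtomMapNum() == 0:
            raise UnmappedProductAtom(f"product atom {a.GetIdx()} ({a.GetSymbol()}) is unmapped")

    rmap = {a.GetAtomMapNum(): a for a in rmol.GetAtoms() if a.GetAtomMapNum()}
    pmap = {a.GetAtomMapNum(): a for a in pmol.GetAtoms() if a.GetAtomMapNum()}

    def mapped_bonds(mol):
        out = {}
        for b in mol.GetBonds():
            m1, m2 = b.GetBeginAtom().GetAtomMapNum(), b.GetEndAtom().GetAtomMapNum()
            if m1 and m2:
                out[frozenset((m1, m2))] = b.GetBondTypeAsDouble()
        return out

    rb, pb = mapped_bonds(rmol), mapped_bonds(pmol)
    changed = set()
    for key in set(rb) | set(pb):
        if rb.get(key) != pb.get(key):
            changed |= set(key)
    for m in set(rmap) & set(pmap):
        ra, pa = rmap[m], pmap[m]
        if ra.GetTotalNumHs() != pa.GetTotalNumHs() or ra.GetFormalCharge() != pa.GetFormalCharge():
            changed.add(m)
    changed |= set(rmap) ^ set(pmap)  # atoms appearing on only one side
    changed &= set(rmap)              # anchor on reactant-side atoms
    if not changed:
        raise NoChangeDetected("reactants and product have identical mapped connectivity")

    # grow the core over the reactant graph
    core_idx = {rmap[m].GetIdx() for m in changed}
    selected = set(core_idx)
    frontier = set(core_idx)
    for _ in range(radius):
        nxt = set()
        for idx in frontier:
            for nbr in rmol.GetAtomWithIdx(idx).GetNeighbors():
                if nbr.GetIdx() not in selected:
                    nxt.add(nbr.GetIdx())
        selected |= nxt
        frontier = nxt

    # reactant side: one fragment per molecule that holds selected atoms
    frags = []
    for frag_atoms in Chem.GetMolFrags(rmol):
        hit = [i for i in frag_atoms if i in selected]
        if hit:
            frags.append(_fragment_smarts(rmol, hit, with_h=True))
    sel_maps = {rmol.GetAtomWithIdx(i).GetAtomMapNum() for i in selected}
    p_idx = [a.GetIdx() for a in pmol.GetAtoms() if a.GetAtomMapNum() in sel_maps]
    p_frag = _fragment_smarts(pmol, p_idx, with_h=False)

    template = ReactionTemplate(smarts=f"{'.'.join(frags)}>>{p_frag}", radius=radius)

    # self-application contract
    recorded = canonical_smiles(parts[2])
    cands = enumerate_candidates(template, parts[0])
    if recorded not in {canonical_smiles(c.product_smiles) for c in cands}:
        raise RegiomlError(
            f"template {template.smarts!r} does not regenerate its source product"
        )
    return template


def enumerate_candidates(template: ReactionTemplate, reactant_smiles: str) -> List[CandidateOutcome]:
    """Apply a template at every matching site of the mapped reactants.

    Outcomes are deduplicated by canonical product SMILES, so symmetry
    equivalent sites collapse into a single candidate.  The reacting pair
    of each candidate is reported as input atom-map numbers.
    """
    rxn = template.rxn()
    whole = mol_from_smiles(reactant_smiles)
    frag_mols = list(Chem.GetMolFrags(whole, asMols=True, sanitizeFrags=True))
    comps = [rxn.GetReactantTemplate(i) for i in range(rxn.GetNumReactantTemplates())]
    map_to_comp = {}
    for ci, comp in enumerate(comps):
        for a in comp.GetAtoms():
            if a.GetAtomMapNum():
                map_to_comp[a.GetAtomMapNum()] = ci

    seen: Dict[str, CandidateOutcome] = {}
    assignments = [
        assign
        for assign in itertools.permutations(range(len(frag_mols)), len(comps))
        if all(frag_mols[f].HasSubstructMatch(comps[c]) for c, f in enumerate(assign))
    ]
    for assign in assignments:
        reactants = tuple(frag_mols[f] for f in assign)
        for pset in rxn.RunReactants(reactants):
            try:
                product = pset[0]
                Chem.SanitizeMol(product)
            except Exception:
                continue
            pair = []
            for m in template.pair_maps:
                hit = None
                for a in product.GetAtoms():
                    if a.HasProp("old_mapno") and a.GetIntProp("old_mapno") == m:
                        hit = a
                        break
                if hit is None or not hit.HasProp("react_atom_idx"):
                    pair = []
                    break
                src_mol = reactants[map_to_comp[m]]
                src_atom = src_mol.GetAtomWithIdx(hit.GetIntProp("react_atom_idx"))
                pair.append(src_atom.GetAtomMapNum())
            if len(pair) != 2:
                continue
            key = canonical_smiles(Chem.MolToSmiles(product))
            if key not in seen:
                seen[key] = CandidateOutcome(pair=(pair[0], pair[1]), product_smiles=key)
    if not seen:
        raise NoMatch(f"template does not apply to {reactant_smiles!r}")
    return sorted(seen.values(), key=lambda c: c.product_smiles)


def identify_selective(candidates: List[CandidateOutcome], recorded_product: str):
    """Return ``(is_selective, major_index)`` for enumerated candidates.

    A record is selective iff at least two distinct candidates exist; the
    candidate matching the recorded product becomes the major index.
    """
    recorded = canonical_smiles(recorded_product)
    matches = [k for k, c in enumerate(candidates) if canonical_smiles(c.product_smiles) == recorded]
    if not matches:
        raise RecordedProductNotAmongCandidates(
            f"recorded product {recorded!r} not among {len(candidates)} candidates"
        )
    return len(candidates) >= 2, matches[0]


# ----------------------------------------------------------------------
# filtering and splitting
# ----------------------------------------------------------------------
def filter_yield(records: List[ReactionRecord], threshold_pct: float = 50.0) -> List[ReactionRecord]:
    """Keep records with a reported yield at or above the threshold.

    Records with missing yield are dropped: without a yield one cannot be
    confident the recorded product is the major one.
    """
    if not 0.0 <= threshold_pct <= 100.0:
        raise ValueError("threshold must be in [0, 100]")
    return [r for r in records if r.yield_pct is not None and r.yield_pct >= threshold_pct]


def scaffold_key(record: ReactionRecord) -> str:
    """Generic Murcko framework of the largest aromatic-ring reactant."""
    best = None
    for smi in record.reactant_smiles.split("."):
        mol = mol_from_smiles(smi)
        n_arom = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
        key = (n_arom > 0, mol.GetNumAtoms())
        if best is None or key > best[0]:
            best = (key, mol)
    mol = Chem.Mol(best[1])
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    try:
        scaf = MurckoScaffold.GetScaffoldForMol(mol)
        generic = MurckoScaffold.MakeScaffoldGeneric(scaf)
        key = Chem.MolToSmiles(generic)
    except Exception:
        key = ""
    return key or "acyclic"


def scaffold_split(
    records: List[ReactionRecord],
    ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    return_manifest: bool = False,
):
    """Single deterministic train/val/test split with scaffold disjointness.

    Scaffold groups are assigned largest-first (ties broken by
    lexicographic scaffold key) to the currently most-underfilled
    partition, a greedy bin-packing.  No scaffold key appears in two
    partitions; extreme group sizes can make the ratios unreachable, which
    is reported in the manifest rather than raised.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    groups: Dict[str, List[ReactionRecord]] = {}
    for r in records:
        groups.setdefault(scaffold_key(r), []).append(r)
    order = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n = len(records)
    targets = [ratio * n for ratio in ratios]
    bins: List[List[ReactionRecord]] = [[], [], []]
    assignment: Dict[str, int] = {}
    for key, members in order:
        deficits = [targets[b] - len(bins[b]) for b in range(3)]
        b = int(np.argmax(deficits))
        bins[b].extend(members)
        assignment[key] = b
    train, val, test = bins
    if not return_manifest:
        return train, val, test
    manifest = {
        "ratios": list(ratios),
        "sizes": [len(b) for b in bins],
        "targets": targets,
        "ratios_reachable": all(
            abs(len(b) - t) <= max(len(m) for _, m in order) for b, t in zip(bins, targets)
        ),
        "scaffold_assignment": {k: ["train", "val", "test"][v] for k, v in assignment.items()},
    }
    return train, val, test, manifest


def cv_splits(
    records: List[ReactionRecord],
    folds: int = 10,
    test_size: Optional[int] = None,
    train_downsample: Optional[int] = None,
    seed: int = 0,
):
    """Cross-validation folds with fixed-size disjoint test sets.

    The training remainder of each fold is shuffled with a fold-derived
    seed and optionally downsampled; test membership of a fold is identical
    across downsample levels by construction.  Yields
    ``(train, val, test)`` record lists.
    """
    n = len(records)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if test_size is None:
        test_size = n // folds
    if folds * test_size > n or test_size < 1:
        raise InsufficientData(f"cannot draw {folds} disjoint test sets of {test_size} from {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    for f in range(folds):
        test_idx = perm[f * test_size : (f + 1) * test_size]
        rest_idx = np.concatenate([perm[: f * test_size], perm[(f + 1) * test_size :]])
        fold_rng = np.random.default_rng(np.random.SeedSequence([seed, f]))
        rest_idx = fold_rng.permutation(rest_idx)
        val_idx = rest_idx[:test_size]
        train_idx = rest_idx[test_size:]
        if train_downsample is not None:
            train_idx = train_idx[:train_downsample]
        yield (
            [records[i] for i in train_idx],
            [records[i] for i in val_idx],
            [records[i] for i in test_idx],
        )
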