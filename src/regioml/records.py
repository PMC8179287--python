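"""Reaction records: candidate outcomes, validation, and CSV round-trip.

A record holds an atom-mapped reactant set, the enumerated regio-isomeric
candidate outcomes (each a reacting atom-map pair plus the product SMILES),
the index of the recorded major outcome, and optional yield/class metadata.

CSV schema: ``reaction_id, mapped_rxn_smiles, candidate_pairs,
candidate_products, major_index, yield_pct, class`` where
``mapped_rxn_smiles`` is ``reactants>>major_product``, candidate pairs are
semicolon-separated ``a-b`` map-number pairs and candidate products are
semicolon-separated SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import pandas as pd

from .errors import DegenerateRecord, SchemaError, UnresolvedMapNumber
from .mol_graph import mol_from_smiles, parse_mapped_smiles

CSV_COLUMNS = [
    "reaction_id",
    "mapped_rxn_smiles",
    "candidate_pairs",
    "candidate_products",
    "major_index",
    "yield_pct",
    "class",
]


@dataclass
class CandidateOutcome:
    pair: Tuple[int, int]           # atom-map numbers of the reacting pair
    product_smiles: str


@dataclass
class ReactionRecord:
    reaction_id: str
    reactant_smiles: str            # atom-mapped, possibly multi-molecule
    candidates: List[CandidateOutcome]
    major_index: int
    yield_pct: Optional[float] = None
    reaction_class: str = ""

    def validate(self, require_selective: bool = False) -> None:
        if not self.candidates:
            raise DegenerateRecord(f"{self.reaction_id}: no candidates")
        if require_selective and len(self.candidates) < 2:
            raise DegenerateRecord(f"{self.reaction_id}: fewer than two candidates")
        if not (0 <= self.major_index < len(self.candidates)):
            raise DegenerateRecord(f"{self.reaction_id}: major_index out of range")
        g = parse_mapped_smiles(self.reactant_smiles)
        known = set(g.map_to_index())
        for c in self.candidates:
            for m in c.pair:
                if m not in known:
                    raise UnresolvedMapNumber(
                        f"{self.reaction_id}: map number {m} not in reactant set"
                    )
            mol_from_smiles(c.product_smiles)

    @property
    def major_product(self) -> str:
        return self.candidates[self.major_index].product_smiles


def save_reaction_dataset(records: List[ReactionRecord], path: str) -> None:
    rows = []
    for r in records:
        rows.append(
            [
                r.reaction_id,
                f"{r.reactant_smiles}>>{r.major_product}",
                ";".join(f"{a}-{b}" for a, b in (c.pair for c in r.candidates)),
                ";".join(c.product_smiles for c in r.candidates),
                r.major_index,
                r.yield_pct if r.yield_pct is not None else "",
                r.reaction_class,
            ]
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def load_reaction_dataset(path: str, validate: bool = True) -> List[ReactionRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"reaction dataset missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        pairs = [tuple(int(x) for x in p.split("-")) for p in str(row["candidate_pairs"]).split(";")]
        products = str(row["candidate_products"]).split(";")
        if len(pairs) != len(products):
            raise SchemaError(f"{row['reaction_id']}: pair/product count mismatch")
        rec = ReactionRecord(
            reaction_id=str(row["reaction_id"]),
            reactant_smiles=str(row["mapped_rxn_smiles"]).split(">")[0],
            candidates=[CandidateOutcome(p, s) for p, s in zip(pairs, products)],
            major_index=int(row["major_index"]),
            yield_pct=float(row["yield_pct"]) if str(row["yield_pct"]) != "" else None,
            reaction_class=str(row["class"]),
        )
        if validate:
            rec.validate()
        records.append(rec)
    return records
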