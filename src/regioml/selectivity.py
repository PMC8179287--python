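"""Regioselectivity scoring: the QM-GNN fusion model and its baselines.

Candidate regio-isomeric outcomes of a reaction are ranked by a softmax
over per-candidate scores, so the model learns to order major vs minor
outcomes relatively.  Five modes share this scoring head:

* ``GNN``        graph-only: WLN encoder on discrete atom/bond features,
                 global attention, no descriptors;
* ``QM-GNN``     the fusion model: the WLN consumes RBF-expanded bond order
                 and length in place of discrete bond features, and the
                 learned atomic embedding is concatenated with the RBF
                 expansions of the four atomic descriptors (channel order:
                 charge, electrophilic Fukui, nucleophilic Fukui, NMR);
* ``ml-QM-GNN``  as QM-GNN but descriptors come from a fitted multitask
                 descriptor model, cached per canonical SMILES;
* ``QM``         descriptor-only FFNN on the fused RBF blocks of the two
                 reacting atoms (no graph encoder);
* ``FP``         difference of 2048-bit radius-2 Morgan fingerprints
                 (product minus reactants) into an FFNN.

WLN update rule (L rounds, documented for the hand-computed test oracle):

    a(l+1)_v = relu(U1 a(l)_v + sum_{u in N(v)} relu(V [a(l)_u ; f_uv]))

Global attention is single-head scaled dot product over all atoms of all
reactant molecules (reagents included when present in the mapped string);
the context is added residually to the local embedding.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, DataStructs

from . import nn
from .descriptors import DescriptorTable, MolDescriptors, RBFSpec, default_rbf_specs, rbf_expand
from .dmpnn import DescriptorResults
from .errors import (
    DegenerateRecord,
    EmptyDataset,
    LengthMismatch,
    MissingDescriptor,
    NonFiniteLoss,
    UnresolvedMapNumber,
)
from .mol_graph import (
    ATOM_FDIM,
    BOND_FDIM,
    atom_features,
    bond_features_discrete,
    directed_edges,
    parse_mapped_smiles,
)
from .records import ReactionRecord

MODES = ("GNN", "QM-GNN", "ml-QM-GNN", "QM", "FP")
ATOM_DESC_ORDER = ("charge", "fukui_elec", "fukui_nuc", "nmr")


@dataclass
class SelectivityConfig:
    hidden: int = 32          # learned embedding width H
    depth: int = 2            # WLN rounds L
    rbf_dim: int = 8
    ffnn_hidden: int = 64
    latent: int = 32          # penultimate (latent) width
    epochs: int = 40
    batch_size: int = 16
    lr: float = 3e-3
    val_fraction: float = 0.1
    fp_bits: int = 2048
    fp_radius: int = 2

    def to_dict(self):
        return asdict(self)


@dataclass
class SelectivityScores:
    scores: np.ndarray        # per-candidate probabilities, sum to one

    @property
    def top1_index(self) -> int:
        return int(np.argmax(self.scores))  # ties -> lowest candidate index


def latent_distance(v1, v2) -> float:
    """Euclidean distance between two latent reaction vectors."""
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    if v1.shape != v2.shape:
        raise LengthMismatch(f"latent shapes differ: {v1.shape} vs {v2.shape}")
    return float(np.linalg.norm(v1 - v2))


def pool_reacting_pair(fused: np.ndarray, pair_indices) -> np.ndarray:
    """Elementwise sum of the two fused atom representations."""
    i, j = pair_indices
    return fused[i] + fused[j]


# ----------------------------------------------------------------------
# network
# ----------------------------------------------------------------------
class SelectivityNet:
    def __init__(self, config: SelectivityConfig, mode: str, rng: np.random.Generator):
        H = config.hidden
        R = config.rbf_dim
        self.config, self.mode = config, mode
        self.uses_graph = mode in ("GNN", "QM-GNN", "ml-QM-GNN")
        self.uses_qm = mode in ("QM-GNN", "ml-QM-GNN", "QM")
        if self.uses_graph:
            bond_fdim = 2 * R if self.uses_qm else BOND_FDIM
            self.W0 = nn.Linear(ATOM_FDIM, H, rng)
            self.U1 = nn.Linear(H, H, rng)
            self.V = nn.Linear(H + bond_fdim, H, rng)
            self.Wq = nn.Linear(H, H, rng, bias=False)
            self.Wk = nn.Linear(H, H, rng, bias=False)
            self.Wv = nn.Linear(H, H, rng, bias=False)
        if mode in ("QM-GNN", "ml-QM-GNN"):
            pooled_dim = H + 4 * R
        elif mode == "GNN":
            pooled_dim = H
        elif mode == "QM":
            pooled_dim = 4 * R
        else:  # FP
            pooled_dim = config.fp_bits
        self.scorer = nn.MLP([pooled_dim, config.ffnn_hidden, config.latent, 1], rng)

    def params(self):
        ps = []
        if self.uses_graph:
            for layer in (self.W0, self.U1, self.V, self.Wq, self.Wk, self.Wv):
                ps += layer.params()
        return ps + self.scorer.params()

    def state(self):
        return [p.data.copy() for p in self.params()]

    def load_state(self, state):
        for p, s in zip(self.params(), state):
            p.data = s.copy()


def wln_encode(net: SelectivityNet, X: np.ndarray, src, dst, Ef: np.ndarray) -> nn.Tensor:
    """L rounds of neighbourhood aggregation; returns local atom embeddings."""
    n = X.shape[0]
    a = nn.relu(net.W0(nn.Tensor(X)))
    for _ in range(net.config.depth):
        msg_in = nn.concat([a.gather(src), nn.Tensor(Ef)], axis=1)
        msg = nn.relu(net.V(msg_in))
        nbr = nn.segment_sum(msg, dst, n)
        a = nn.relu(net.U1(a) + nbr)
    return a


def global_attention(net: SelectivityNet, a: nn.Tensor):
    """Scaled dot-product attention over all atoms; returns (context, alpha)."""
    H = net.config.hidden
    q, k, v = net.Wq(a), net.Wk(a), net.Wv(a)
    logits = q.matmul(k.T) * (1.0 / np.sqrt(H))
    alpha = nn.softmax(logits, axis=1)
    return alpha.matmul(v), alpha


def encode_reactants(net: SelectivityNet, prep: "PreparedRecord") -> nn.Tensor:
    """Learned atomic embedding: WLN + residual global attention context."""
    a = wln_encode(net, prep.X, prep.src, prep.dst, prep.Ef)
    ctx, _ = global_attention(net, a)
    return a + ctx


def fuse_qm(embedding: nn.Tensor, qm_block: np.ndarray) -> nn.Tensor:
    """Concatenate the learned embedding with the RBF descriptor block."""
    return nn.concat([embedding, nn.Tensor(qm_block)], axis=1)


# ----------------------------------------------------------------------
# feature preparation
# ----------------------------------------------------------------------
@dataclass
class PreparedRecord:
    record: ReactionRecord
    pair_idx: List[tuple]                 # candidate (i, j) atom indices
    major: int
    X: Optional[np.ndarray] = None
    src: Optional[np.ndarray] = None
    dst: Optional[np.ndarray] = None
    Ef: Optional[np.ndarray] = None       # per-directed-edge bond features
    qm_block: Optional[np.ndarray] = None  # (n_atoms, 4*rbf_dim)
    fp: Optional[np.ndarray] = None       # (n_candidates, fp_bits)


def _canonical_row_map(frag_mol: Chem.Mol):
    """canonical SMILES of a fragment + input-atom -> canonical-row map."""
    stripped = Chem.Mol(frag_mol)
    for a in stripped.GetAtoms():
        a.SetAtomMapNum(0)
    smi = Chem.MolToSmiles(stripped)
    order = json.loads(stripped.GetProp("_smilesAtomOutputOrder"))
    inv = {int(src): row for row, src in enumerate(order)}
    return smi, inv


class DescriptorSource:
    """Uniform lookup over a static table or a fitted descriptor model."""

    def __init__(self, source):
        self.source = source

    def get(self, smiles: str) -> MolDescriptors:
        if isinstance(self.source, DescriptorResults):
            return self.source.predict(smiles).descriptors
        try:
            return self.source.get(smiles)
        except KeyError:
            raise MissingDescriptor(f"no descriptor entry for {smiles!r}")


def prepare_record(
    record: ReactionRecord,
    mode: str,
    specs: Dict[str, RBFSpec],
    desc_source: Optional[DescriptorSource],
    config: SelectivityConfig,
) -> PreparedRecord:
    g = parse_mapped_smiles(record.reactant_smiles)
    m2i = g.map_to_index()
    pair_idx = []
    for c in record.candidates:
        try:
            pair_idx.append((m2i[c.pair[0]], m2i[c.pair[1]]))
        except KeyError as exc:
            raise UnresolvedMapNumber(
                f"{record.reaction_id}: map number {exc} not found in reactants"
            )
    prep = PreparedRecord(record=record, pair_idx=pair_idx, major=record.major_index)

    uses_graph = mode in ("GNN", "QM-GNN", "ml-QM-GNN")
    uses_qm = mode in ("QM-GNN", "ml-QM-GNN", "QM")

    if uses_qm:
        atom_desc = np.zeros((g.n_atoms, 4))
        bond_desc: Dict[tuple, tuple] = {}
        frag_tuples = Chem.GetMolFrags(g.mol)
        frag_mols = Chem.GetMolFrags(g.mol, asMols=True, sanitizeFrags=True)
        for atoms_in_frag, frag_mol in zip(frag_tuples, frag_mols):
            smi, inv = _canonical_row_map(frag_mol)
            desc = desc_source.get(smi)
            local = {atoms_in_frag[k]: inv[k] for k in range(len(atoms_in_frag))}
            for comb_idx, row in local.items():
                atom_desc[comb_idx] = [desc.atom_channel(ch)[row] for ch in ATOM_DESC_ORDER]
            for b in g.bonds:
                if b.i in local and b.j in local:
                    try:
                        bond_desc[(b.i, b.j)] = desc.bond_value(local[b.i], local[b.j])
                    except KeyError:
                        raise MissingDescriptor(
                            f"{smi}: bond ({local[b.i]},{local[b.j]}) lacks order/length"
                        )
        prep.qm_block = np.concatenate(
            [rbf_expand(atom_desc[:, k], specs[ch]) for k, ch in enumerate(ATOM_DESC_ORDER)],
            axis=1,
        )

    if uses_graph:
        prep.X = atom_features(g)
        src, dst, rev, bond_index = directed_edges(g)
        prep.src, prep.dst = src, dst
        if uses_qm:
            rows = []
            for b in g.bonds:
                order, length = bond_desc[(b.i, b.j)]
                rows.append(
                    np.concatenate(
                        [rbf_expand(order, specs["bond_order"]), rbf_expand(length, specs["bond_length"])]
                    )
                )
            E = np.array(rows).reshape(g.n_bonds, 2 * config.rbf_dim)
        else:
            E = bond_features_discrete(g)
        prep.Ef = E[bond_index] if g.n_bonds else np.zeros((0, E.shape[1] if E.size else BOND_FDIM))
    elif mode == "QM":
        # descriptor-only: the fused block of the two reacting atoms
        prep.qm_block = prep.qm_block
    elif mode == "FP":
        stripped = Chem.Mol(g.mol)
        for a in stripped.GetAtoms():
            a.SetAtomMapNum(0)
        r_fp = _morgan(stripped, config)
        fps = []
        for c in record.candidates:
            p_mol = Chem.MolFromSmiles(c.product_smiles)
            fps.append(_morgan(p_mol, config) - r_fp)
        prep.fp = np.array(fps)
    return prep


def _morgan(mol: Chem.Mol, config: SelectivityConfig) -> np.ndarray:
    bv = AllChem.GetMorganFingerprintAsBitVect(mol, config.fp_radius, nBits=config.fp_bits)
    arr = np.zeros(config.fp_bits, dtype=np.float64)
    DataStructs.ConvertToNumpyArray(bv, arr)
    return arr


def candidate_logits(net: SelectivityNet, prep: PreparedRecord) -> nn.Tensor:
    """Per-candidate raw scores (before the softmax across candidates)."""
    mode = net.mode
    if mode in ("GNN", "QM-GNN", "ml-QM-GNN"):
        emb = encode_reactants(net, prep)
        fused = fuse_qm(emb, prep.qm_block) if net.uses_qm else emb
        a_idx = np.array([p[0] for p in prep.pair_idx], dtype=np.intp)
        b_idx = np.array([p[1] for p in prep.pair_idx], dtype=np.intp)
        pooled = fused.gather(a_idx) + fused.gather(b_idx)
    elif mode == "QM":
        block = nn.Tensor(prep.qm_block)
        a_idx = np.array([p[0] for p in prep.pair_idx], dtype=np.intp)
        b_idx = np.array([p[1] for p in prep.pair_idx], dtype=np.intp)
        pooled = block.gather(a_idx) + block.gather(b_idx)
    else:  # FP
        pooled = nn.Tensor(prep.fp)
    return net.scorer(pooled).reshape(-1)


# ----------------------------------------------------------------------
# Model / Results
# ----------------------------------------------------------------------
class SelectivityModel:
    """Selectivity ranking model bound to a reaction dataset.

    Parameters
    ----------
    records : list of ReactionRecord
        Training records; each must be selective (>= 2 candidates).
    mode : one of MODES
    descriptor_source : DescriptorTable or DescriptorResults
        Required for the QM modes; ``ml-QM-GNN`` takes a fitted
        :class:`DescriptorResults` whose predictions are cached per
        canonical SMILES.
    val_records : optional explicit validation set; otherwise a seeded
        fraction of the training records is held out in :meth:`fit`.
    """

    def __init__(
        self,
        records: List[ReactionRecord],
        mode: str = "QM-GNN",
        descriptor_source=None,
        val_records: Optional[List[ReactionRecord]] = None,
        config: Optional[SelectivityConfig] = None,
        rbf_specs: Optional[Dict[str, RBFSpec]] = None,
    ):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.mode = mode
        self.config = config or SelectivityConfig()
        self.specs = rbf_specs or default_rbf_specs(self.config.rbf_dim)
        needs_desc = mode in ("QM-GNN", "ml-QM-GNN", "QM")
        if needs_desc and descriptor_source is None:
            raise MissingDescriptor(f"mode {mode} requires a descriptor source")
        self.desc_source = DescriptorSource(descriptor_source) if needs_desc else None
        if not records:
            raise EmptyDataset("no training records")
        for r in records + (val_records or []):
            r.validate(require_selective=True)
        self.train_records = records
        self.val_records = val_records
        self._prep_cache: Dict[str, PreparedRecord] = {}

    def _prepare(self, record: ReactionRecord) -> PreparedRecord:
        key = record.reaction_id
        if key not in self._prep_cache:
            self._prep_cache[key] = prepare_record(
                record, self.mode, self.specs, self.desc_source, self.config
            )
        return self._prep_cache[key]

    def fit(self, seed: int = 0, epochs: Optional[int] = None) -> "SelectivityResults":
        cfg = self.config
        n_epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(seed)
        net = SelectivityNet(cfg, self.mode, rng)

        train = list(self.train_records)
        if self.val_records is None:
            idx = rng.permutation(len(train))
            n_val = max(1, int(len(train) * cfg.val_fraction)) if len(train) > 1 else 0
            val = [train[i] for i in idx[:n_val]]
            train = [train[i] for i in idx[n_val:]]
        else:
            val = list(self.val_records)

        train_prep = [self._prepare(r) for r in train]
        val_prep = [self._prepare(r) for r in val]
        opt = nn.Adam(net.params(), lr=cfg.lr)
        accuracy_curve = []
        best_state, best_acc = net.state(), -1.0

        for _ in range(n_epochs):
            order = rng.permutation(len(train_prep))
            for lo in range(0, len(train_prep), cfg.batch_size):
                chunk = [train_prep[i] for i in order[lo : lo + cfg.batch_size]]
                loss = None
                for prep in chunk:
                    ce = nn.cross_entropy_logits(candidate_logits(net, prep), prep.major)
                    loss = ce if loss is None else loss + ce
                loss = loss * (1.0 / len(chunk))
                if not np.isfinite(loss.data):
                    raise NonFiniteLoss(f"loss became {loss.data}")
                opt.zero_grad()
                loss.backward()
                opt.step()
            if val_prep:
                acc = self._accuracy(net, val_prep)
                accuracy_curve.append(acc)
                if acc > best_acc:
                    best_acc, best_state = acc, net.state()
            else:
                best_state = net.state()
        net.load_state(best_state)
        return SelectivityResults(
            net=net,
            model=self,
            seed=seed,
            accuracy_curve=accuracy_curve,
            val_accuracy=best_acc if val_prep else np.nan,
        )

    @staticmethod
    def _accuracy(net, preps) -> float:
        hits = 0
        for prep in preps:
            logits = candidate_logits(net, prep).data
            hits += int(np.argmax(logits) == prep.major)
        return hits / len(preps)


class SelectivityResults:
    """Fitted selectivity model: scoring, latents, metrics, summary."""

    def __init__(self, net: SelectivityNet, model: SelectivityModel, seed: int,
                 accuracy_curve, val_accuracy: float):
        self.net = net
        self.model = model
        self.seed = seed
        self.accuracy_curve = list(accuracy_curve)
        self.val_accuracy = val_accuracy

    def _prepare(self, record: ReactionRecord) -> PreparedRecord:
        return self.model._prepare(record)

    def predict(self, record: ReactionRecord) -> SelectivityScores:
        record.validate()
        prep = self._prepare(record)
        logits = candidate_logits(self.net, prep).data
        e = np.exp(logits - logits.max())
        return SelectivityScores(scores=e / e.sum())

    def top1_accuracy(self, records: List[ReactionRecord]) -> float:
        preps = [self._prepare(r) for r in records]
        return self.model._accuracy(self.net, preps)

    def extract_latent(self, record: ReactionRecord, candidate_index: int) -> np.ndarray:
        """Penultimate-layer activation for one candidate outcome."""
        prep = self._prepare(record)
        if not 0 <= candidate_index < len(prep.pair_idx):
            raise IndexError(f"candidate index {candidate_index} out of range")
        mode = self.net.mode
        if mode in ("GNN", "QM-GNN", "ml-QM-GNN"):
            emb = encode_reactants(self.net, prep)
            fused = emb if not self.net.uses_qm else fuse_qm(emb, prep.qm_block)
            i, j = prep.pair_idx[candidate_index]
            pooled = fused.gather([i]) + fused.gather([j])
        elif mode == "QM":
            i, j = prep.pair_idx[candidate_index]
            pooled = nn.Tensor(prep.qm_block[[i]] + prep.qm_block[[j]])
        else:
            pooled = nn.Tensor(prep.fp[[candidate_index]])
        return self.net.scorer.hidden_of(pooled).data[0].copy()

    def predict_dataset(self, records: List[ReactionRecord]):
        import pandas as pd

        rows = []
        for r in records:
            s = self.predict(r)
            rows.append(
                [r.reaction_id, ";".join(f"{x:.8f}" for x in s.scores), s.top1_index]
            )
        return pd.DataFrame(rows, columns=["reaction_id", "scores", "top1_index"])

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            f"Selectivity model ({self.net.mode})",
            "=" * 54,
            f"embedding width H     {cfg.hidden}",
            f"WLN rounds L          {cfg.depth}",
            f"RBF dim per channel   {cfg.rbf_dim}",
            f"latent width          {cfg.latent}",
            f"seed                  {self.seed}",
            f"epochs run            {len(self.accuracy_curve)}",
            f"best val top-1        {self.val_accuracy:.4f}"
            if np.isfinite(self.val_accuracy)
            else "best val top-1        n/a",
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        manifest = {
            "kind": "regioml-selectivity-model",
            "mode": self.net.mode,
            "config": self.model.config.to_dict(),
            "seed": self.seed,
            "accuracy_curve": self.accuracy_curve,
            "val_accuracy": self.val_accuracy,
        }
        with open(os.path.join(path, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        np.savez(
            os.path.join(path, "weights.npz"),
            **{f"p{k}": p.data for k, p in enumerate(self.net.params())},
        )


def score_candidates(record: ReactionRecord, results: SelectivityResults) -> SelectivityScores:
    """Functional wrapper around :meth:`SelectivityResults.predict`."""
    return results.predict(record)


def train_selectivity(
    train: List[ReactionRecord],
    val: Optional[List[ReactionRecord]],
    mode: str,
    descriptor_source=None,
    config: Optional[SelectivityConfig] = None,
    seed: int = 0,
) -> SelectivityResults:
    """Convenience one-call training mirroring the Model/fit split."""
    model = SelectivityModel(
        train, mode=mode, descriptor_source=descriptor_source, val_records=val, config=config
    )
    return model.fit(seed=seed)
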