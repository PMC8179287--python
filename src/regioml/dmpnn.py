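"""Multitask constrained descriptor predictor.

A single directed-message-passing encoder (D-MPNN) is shared by six readout
heads, one per descriptor.  The conserved atomic channels -- partial charge
(sums to the net formal charge) and the two condensed Fukui indices (each
sums to one) -- go through an attention-based constraint: a learnable query
vector u scores every atom's hidden state, a softmax turns the scores into
weights w_i, and the excess of the unconstrained readout over the target sum
Q is spread over the atoms,

    q_i_final = q_i + w_i * (Q - sum_j q_j),

so the constrained sum holds to machine precision for any parameters,
trained or not.  Shielding constants, bond orders and bond lengths are read
out unconstrained; the bond heads consume the symmetrised (summed) hidden
states of the two directed edges of each bond.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import numpy as np

from . import nn
from .descriptors import ATOM_CHANNELS, BOND_CHANNELS, DescriptorTable, MolDescriptors
from .errors import EmptyDataset, NonFiniteLoss, UnsupportedMolecule
from .mol_graph import (
    ATOM_FDIM,
    BOND_FDIM,
    MolGraph,
    atom_features,
    bond_features_discrete,
    canonical_smiles,
    directed_edges,
    parse_mapped_smiles,
)

CONSTRAINED = {"charge": None, "fukui_elec": 1.0, "fukui_nuc": 1.0}  # None -> net formal charge


@dataclass
class DescriptorConfig:
    hidden: int = 64
    depth: int = 4            # message-passing rounds T
    head_hidden: int = 64
    epochs: int = 60
    batch_size: int = 32
    lr: float = 5e-3
    similarity: str = "dot"   # constraint attention similarity: "dot" or "cosine"
    val_fraction: float = 0.1  # used when no validation table is given

    def to_dict(self):
        return asdict(self)


# ----------------------------------------------------------------------
# network parameters
# ----------------------------------------------------------------------
class DmpnnNet:
    """All learnable parameters of the multitask model, seeded construction."""

    def __init__(self, config: DescriptorConfig, rng: np.random.Generator):
        H = config.hidden
        self.config = config
        self.W_in = nn.Linear(ATOM_FDIM + BOND_FDIM, H, rng)
        self.W_h = nn.Linear(H, H, rng, bias=False)
        self.W_a = nn.Linear(ATOM_FDIM + H, H, rng)
        self.atom_heads = {c: nn.MLP([H, config.head_hidden, 1], rng) for c in ATOM_CHANNELS}
        self.u = {
            c: nn.Tensor(rng.normal(0.0, 1.0 / np.sqrt(H), size=(H,)), requires_grad=True)
            for c in CONSTRAINED
        }
        self.bond_heads = {c: nn.MLP([H, config.head_hidden, 1], rng) for c in BOND_CHANNELS}

    def params(self):
        ps = self.W_in.params() + self.W_h.params() + self.W_a.params()
        for c in ATOM_CHANNELS:
            ps += self.atom_heads[c].params()
        ps += list(self.u.values())
        for c in BOND_CHANNELS:
            ps += self.bond_heads[c].params()
        return ps

    def state(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state(self, state: List[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p.data = s.copy()


# ----------------------------------------------------------------------
# graph preparation and packing
# ----------------------------------------------------------------------
@dataclass
class PreparedMol:
    smiles: str
    n_atoms: int
    n_bonds: int
    X: np.ndarray
    Ed: np.ndarray          # directed-edge bond features (2m x BOND_FDIM)
    src: np.ndarray
    dst: np.ndarray
    rev: np.ndarray
    net_charge: int
    targets: Optional[Dict[str, np.ndarray]] = None


def prepare_molecule(smiles: str, desc: Optional[MolDescriptors] = None) -> PreparedMol:
    key = canonical_smiles(smiles)
    g = parse_mapped_smiles(key)
    X = atom_features(g)
    E = bond_features_discrete(g)
    src, dst, rev, bond_index = directed_edges(g)
    Ed = E[bond_index] if g.n_bonds else np.zeros((0, BOND_FDIM))
    targets = None
    if desc is not None:
        targets = {c: desc.atom_channel(c) for c in ATOM_CHANNELS}
        order = np.array([desc.bond_value(b.i, b.j)[0] for b in g.bonds])
        length = np.array([desc.bond_value(b.i, b.j)[1] for b in g.bonds])
        targets["bond_order"] = order
        targets["bond_length"] = length
    return PreparedMol(
        smiles=key,
        n_atoms=g.n_atoms,
        n_bonds=g.n_bonds,
        X=X,
        Ed=Ed,
        src=src,
        dst=dst,
        rev=rev,
        net_charge=g.net_formal_charge,
        targets=targets,
    )


@dataclass
class PackedBatch:
    """Several molecules concatenated into one disjoint graph."""

    X: np.ndarray
    Ed: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    rev: np.ndarray
    mol_id: np.ndarray        # per-atom molecule index
    bond_mol_id: np.ndarray   # per-bond molecule index
    n_mols: int
    net_charges: np.ndarray
    targets: Optional[Dict[str, np.ndarray]] = None


def pack(mols: List[PreparedMol]) -> PackedBatch:
    atom_off, edge_off = 0, 0
    Xs, Eds, srcs, dsts, revs, mol_ids, bond_mol_ids = [], [], [], [], [], [], []
    for k, m in enumerate(mols):
        Xs.append(m.X)
        Eds.append(m.Ed)
        srcs.append(m.src + atom_off)
        dsts.append(m.dst + atom_off)
        revs.append(m.rev + edge_off)
        mol_ids.append(np.full(m.n_atoms, k, dtype=np.intp))
        bond_mol_ids.append(np.full(m.n_bonds, k, dtype=np.intp))
        atom_off += m.n_atoms
        edge_off += 2 * m.n_bonds
    targets = None
    if all(m.targets is not None for m in mols):
        targets = {
            c: np.concatenate([m.targets[c] for m in mols]) if atom_off else np.zeros(0)
            for c in ATOM_CHANNELS + BOND_CHANNELS
        }
    return PackedBatch(
        X=np.concatenate(Xs) if Xs else np.zeros((0, ATOM_FDIM)),
        Ed=np.concatenate(Eds) if Eds else np.zeros((0, BOND_FDIM)),
        src=np.concatenate(srcs).astype(np.intp),
        dst=np.concatenate(dsts).astype(np.intp),
        rev=np.concatenate(revs).astype(np.intp),
        mol_id=np.concatenate(mol_ids).astype(np.intp),
        bond_mol_id=np.concatenate(bond_mol_ids).astype(np.intp)
        if bond_mol_ids
        else np.zeros(0, dtype=np.intp),
        n_mols=len(mols),
        net_charges=np.array([m.net_charge for m in mols], dtype=np.float64),
        targets=targets,
    )


# ----------------------------------------------------------------------
# functional pieces (also used directly by the test oracles)
# ----------------------------------------------------------------------
def dmpnn_encode_packed(net: DmpnnNet, batch: PackedBatch):
    """Run the encoder on a packed batch; returns (atom hidden, edge hidden)."""
    n_atoms = batch.X.shape[0]
    Hin = np.concatenate([batch.X[batch.src], batch.Ed], axis=1)
    h0 = nn.relu(net.W_in(nn.Tensor(Hin)))
    h = h0
    for _ in range(net.config.depth - 1):
        S = nn.segment_sum(h, batch.dst, n_atoms)
        m = S.gather(batch.src) - h.gather(batch.rev)
        h = nn.relu(h0 + net.W_h(m))
    Minc = nn.segment_sum(h, batch.dst, n_atoms)
    a = nn.relu(net.W_a(nn.concat([nn.Tensor(batch.X), Minc], axis=1)))
    return a, h


def dmpnn_encode(g: MolGraph, net: DmpnnNet):
    """Encode a single molecule; returns per-atom and per-directed-edge
    hidden states as plain arrays."""
    batch = pack([prepare_molecule(g.smiles_canonical)])
    a, h = dmpnn_encode_packed(net, batch)
    return a.data, h.data


def constraint_weights(a, u, similarity: str = "dot") -> np.ndarray:
    """Softmax attention weights of atoms against the query vector u."""
    a = np.asarray(a, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    if similarity == "dot":
        scores = a @ u
    elif similarity == "cosine":
        na = np.linalg.norm(a, axis=1) + 1e-12
        scores = (a @ u) / (na * (np.linalg.norm(u) + 1e-12))
    else:
        raise ValueError(f"unknown similarity {similarity!r}")
    scores = scores - scores.max()
    e = np.exp(scores)
    return e / e.sum()


def apply_constraint(q_init, w, Q: float) -> np.ndarray:
    """Spread the excess (Q - sum q) over atoms with weights w."""
    q_init = np.asarray(q_init, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    return q_init + w * (Q - q_init.sum())


def _similarity_scores(a: nn.Tensor, u: nn.Tensor, similarity: str) -> nn.Tensor:
    if similarity == "dot":
        return a.matmul(u.reshape(-1, 1)).reshape(-1)
    # cosine
    na = nn.Tensor((np.linalg.norm(a.data, axis=1) + 1e-12))
    nu = float(np.linalg.norm(u.data) + 1e-12)
    return a.matmul(u.reshape(-1, 1)).reshape(-1) / (na * nu)


def forward_heads(net: DmpnnNet, batch: PackedBatch, scales: Dict[str, tuple]):
    """Full forward pass: encoder + all heads, constraints applied.

    Returns a dict channel -> Tensor of physical-unit predictions (per atom
    for atomic channels, per bond for bond channels).
    """
    a, h = dmpnn_encode_packed(net, batch)
    out = {}
    for c in ATOM_CHANNELS:
        mean, std = scales[c]
        raw = net.atom_heads[c](a).reshape(-1) * std + mean
        if c in CONSTRAINED:
            sim = _similarity_scores(a, net.u[c], net.config.similarity)
            w = nn.segment_softmax(sim, batch.mol_id, batch.n_mols)
            sums = nn.segment_sum(raw, batch.mol_id, batch.n_mols)
            Q = batch.net_charges if c == "charge" else np.full(batch.n_mols, CONSTRAINED[c])
            excess = nn.Tensor(Q) - sums
            out[c] = raw + w * excess.gather(batch.mol_id)
        else:
            out[c] = raw
    if batch.bond_mol_id.size or batch.Ed.shape[0]:
        h_sym = h + h.gather(batch.rev)
        even = np.arange(0, h.data.shape[0], 2)
        b_hidden = h_sym.gather(even)
        for c in BOND_CHANNELS:
            mean, std = scales[c]
            out[c] = nn.softplus(net.bond_heads[c](b_hidden).reshape(-1)) * std + mean
    else:
        for c in BOND_CHANNELS:
            out[c] = nn.Tensor(np.zeros(0))
    return out


# ----------------------------------------------------------------------
# Model / Results
# ----------------------------------------------------------------------
class DescriptorModel:
    """Multitask constrained descriptor model bound to training data.

    Parameters
    ----------
    train_table, val_table : DescriptorTable
        Oracle or externally computed descriptor tables.  When no
        validation table is given a seeded fraction of the training
        molecules is held out.  Net-charged molecules are rejected: the
        Fukui channels are undefined for them in this framework.
    config : DescriptorConfig
    """

    def __init__(self, train_table: DescriptorTable, val_table: Optional[DescriptorTable] = None,
                 config: Optional[DescriptorConfig] = None):
        self.config = config or DescriptorConfig()
        self.train_mols = self._ingest(train_table)
        self.val_mols = self._ingest(val_table) if val_table is not None else None
        if not self.train_mols:
            raise EmptyDataset("no usable training molecules")

    @staticmethod
    def _ingest(table: DescriptorTable) -> List[PreparedMol]:
        mols = []
        for smi, desc in table.items():
            prepared = prepare_molecule(smi, desc)
            if prepared.net_charge != 0:
                raise UnsupportedMolecule(
                    f"{smi}: net-charged molecules are outside the supported domain"
                )
            mols.append(prepared)
        return mols

    def _scales(self, mols: List[PreparedMol]) -> Dict[str, tuple]:
        scales = {}
        for c in ATOM_CHANNELS + BOND_CHANNELS:
            vals_list = [m.targets[c] for m in mols if m.targets[c].size]
            vals = np.concatenate(vals_list) if vals_list else np.zeros(1)
            std = float(vals.std())
            scales[c] = (float(vals.mean()), std if std > 1e-8 else 1.0)
        return scales

    @staticmethod
    def _loss(net, batch, scales):
        out = forward_heads(net, batch, scales)
        total = None
        for c in ATOM_CHANNELS + BOND_CHANNELS:
            target = batch.targets[c]
            if target.size == 0:
                continue
            mean, std = scales[c]
            resid = (out[c] - nn.Tensor(target)) * (1.0 / std)
            term = (resid**2).mean()
            total = term if total is None else total + term
        return total

    def fit(self, seed: int = 0, epochs: Optional[int] = None) -> "DescriptorResults":
        cfg = self.config
        n_epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(seed)
        net = DmpnnNet(cfg, rng)

        train = list(self.train_mols)
        if self.val_mols is None:
            idx = rng.permutation(len(train))
            n_val = max(1, int(len(train) * cfg.val_fraction)) if len(train) > 1 else 0
            val = [train[i] for i in idx[:n_val]]
            train = [train[i] for i in idx[n_val:]]
        else:
            val = list(self.val_mols)

        scales = self._scales(train)
        opt = nn.Adam(net.params(), lr=cfg.lr)
        history = []
        val_batch = pack(val) if val else None
        best_state, best_val = net.state(), np.inf
        if val_batch is not None:
            best_val = float(self._loss(net, val_batch, scales).data)
            history.append(best_val)

        for _ in range(n_epochs):
            order = rng.permutation(len(train))
            for lo in range(0, len(train), cfg.batch_size):
                batch = pack([train[i] for i in order[lo : lo + cfg.batch_size]])
                loss = self._loss(net, batch, scales)
                if not np.isfinite(loss.data):
                    raise NonFiniteLoss(f"loss became {loss.data}")
                opt.zero_grad()
                loss.backward()
                opt.step()
            if val_batch is not None:
                vl = float(self._loss(net, val_batch, scales).data)
                history.append(vl)
                if vl < best_val:
                    best_val, best_state = vl, net.state()
            else:
                best_state = net.state()
        net.load_state(best_state)

        metrics = self._metrics(net, pack(val) if val else None, scales)
        return DescriptorResults(
            net=net, scales=scales, config=cfg, seed=seed,
            val_loss_history=history, metrics=metrics,
        )

    def _metrics(self, net, val_batch, scales):
        if val_batch is None:
            return {}
        out = forward_heads(net, val_batch, scales)
        metrics = {}
        for c in ATOM_CHANNELS + BOND_CHANNELS:
            target = val_batch.targets[c]
            if target.size == 0:
                continue
            pred = out[c].data
            mae = float(np.abs(pred - target).mean())
            ss_res = float(((pred - target) ** 2).sum())
            ss_tot = float(((target - target.mean()) ** 2).sum())
            metrics[c] = {"mae": mae, "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan}
        return metrics


@dataclass
class DescriptorPrediction:
    descriptors: MolDescriptors
    provenance: str = "ml"


class DescriptorResults:
    """Fitted multitask descriptor model: prediction, metrics, persistence."""

    def __init__(self, net: DmpnnNet, scales, config: DescriptorConfig, seed: int,
                 val_loss_history=None, metrics=None):
        self.net = net
        self.scales = scales
        self.config = config
        self.seed = seed
        self.val_loss_history = val_loss_history or []
        self.metrics = metrics or {}
        self._cache: Dict[str, MolDescriptors] = {}

    # ------------------------------------------------------------------
    def predict(self, smiles: str) -> DescriptorPrediction:
        """Predict all six descriptor channels for one neutral molecule.

        Results are cached by canonical SMILES so repeated reactants cost a
        single network evaluation.
        """
        key = canonical_smiles(smiles)
        if key in self._cache:
            return DescriptorPrediction(self._cache[key], provenance="ml")
        prepared = prepare_molecule(key)
        if prepared.net_charge != 0:
            raise UnsupportedMolecule(f"{key}: cannot predict descriptors for charged molecules")
        batch = pack([prepared])
        out = forward_heads(self.net, batch, self.scales)
        g = parse_mapped_smiles(key)
        bonds = {}
        for k, b in enumerate(g.bonds):
            bonds[(min(b.i, b.j), max(b.i, b.j))] = (
                float(out["bond_order"].data[k]),
                float(out["bond_length"].data[k]),
            )
        desc = MolDescriptors(
            charge=out["charge"].data.copy(),
            fukui_elec=out["fukui_elec"].data.copy(),
            fukui_nuc=out["fukui_nuc"].data.copy(),
            nmr=out["nmr"].data.copy(),
            bonds=bonds,
        )
        self._cache[key] = desc
        return DescriptorPrediction(desc, provenance="ml")

    def predict_table(self, smiles_list) -> DescriptorTable:
        table = DescriptorTable()
        for smi in smiles_list:
            table.add(smi, self.predict(smi).descriptors)
        return table

    def summary(self) -> str:
        lines = [
            "Multitask constrained descriptor model",
            "=" * 54,
            f"hidden width          {self.config.hidden}",
            f"message-passing depth {self.config.depth}",
            f"seed                  {self.seed}",
            f"epochs run            {max(0, len(self.val_loss_history) - 1)}",
            "-" * 54,
            f"{'channel':<14}{'val MAE':>12}{'val R2':>12}",
        ]
        for c, m in self.metrics.items():
            lines.append(f"{c:<14}{m['mae']:>12.4f}{m['r2']:>12.4f}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        manifest = {
            "kind": "regioml-descriptor-model",
            "config": self.config.to_dict(),
            "seed": self.seed,
            "scales": {c: list(v) for c, v in self.scales.items()},
            "metrics": self.metrics,
            "val_loss_history": self.val_loss_history,
        }
        with open(os.path.join(path, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        np.savez(
            os.path.join(path, "weights.npz"),
            **{f"p{k}": p.data for k, p in enumerate(self.net.params())},
        )

    @classmethod
    def load(cls, path: str) -> "DescriptorResults":
        with open(os.path.join(path, "manifest.json")) as fh:
            manifest = json.load(fh)
        config = DescriptorConfig(**manifest["config"])
        net = DmpnnNet(config, np.random.default_rng(0))
        with np.load(os.path.join(path, "weights.npz")) as blob:
            net.load_state([blob[f"p{k}"] for k in range(len(net.params()))])
        res = cls(
            net=net,
            scales={c: tuple(v) for c, v in manifest["scales"].items()},
            config=config,
            seed=manifest["seed"],
            val_loss_history=manifest["val_loss_history"],
            metrics=manifest["metrics"],
        )
        return res


def predict_descriptors(smiles: str, results: DescriptorResults) -> DescriptorPrediction:
    """Functional wrapper around :meth:`DescriptorResults.predict`."""
    return results.predict(smiles)


def train_multitask(
    train_table: DescriptorTable,
    val_table: Optional[DescriptorTable] = None,
    config: Optional[DescriptorConfig] = None,
    seed: int = 0,
):
    """Convenience one-call training; returns (results, per-channel metrics)."""
    results = DescriptorModel(train_table, val_table, config=config).fit(seed=seed)
    return results, results.metrics
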