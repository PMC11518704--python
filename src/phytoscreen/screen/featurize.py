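"""Curation, splitting and featurization for drug-target screening.

Activity tables are curated into binary records (``Active`` -> 1, every
other activity category -> 0; duplicates, mixtures and carbon-free
entries dropped).  Molecules become 2-D graphs with 74-dimensional
atom-node vectors — the concatenation of eight one-hot/integer blocks
(atom type 43, degree 11, implicit H 7, formal charge 1, radical
electrons 1, hybridization 5, aromaticity 1, total H 5) — padded with
all-zero virtual nodes to a fixed node budget.  Proteins become integer
sequences over a 23-symbol alphabet (20 amino acids + 3 auxiliary),
truncated or zero-padded to a fixed length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

__all__ = [
    "ActivityRecord",
    "curate",
    "split",
    "featurize_molecule",
    "encode_protein",
    "ATOM_TYPES",
    "PROTEIN_ALPHABET",
    "NUM_ATOM_FEATURES",
]

ACTIVITY_CATEGORIES = ("Active", "Inactive", "Inclusive", "Unspecified")

#: 43 atom symbols of the canonical featurizer vocabulary
ATOM_TYPES = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
]
_HYBRIDIZATIONS = [
    Chem.rdchem.HybridizationType.SP,
    Chem.rdchem.HybridizationType.SP2,
    Chem.rdchem.HybridizationType.SP3,
    Chem.rdchem.HybridizationType.SP3D,
    Chem.rdchem.HybridizationType.SP3D2,
]
NUM_ATOM_FEATURES = 74  # 43 + 11 + 7 + 1 + 1 + 5 + 1 + 5

#: 20 amino acids + 3 auxiliary symbols; index 0 is reserved for padding
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBUX"
_AA_INDEX = {a: i + 1 for i, a in enumerate(PROTEIN_ALPHABET)}


@dataclass(frozen=True)
class ActivityRecord:
    """One (molecule, protein, binary activity) training unit."""

    substance_id: str
    smiles: str
    target_id: str
    sequence: str
    category: str
    label: int

    def __post_init__(self):
        if self.category not in ACTIVITY_CATEGORIES:
            raise ValueError(f"unknown activity category: {self.category!r}")
        expected = 1 if self.category == "Active" else 0
        if self.label != expected:
            raise ValueError("label inconsistent with activity category")


def curate(table) -> List[ActivityRecord]:
    """Curate a raw activity table (pandas DataFrame) into records.

    Requires columns ``smiles``, ``sequence``, ``category`` (optional
    ``substance_id``, ``target_id``).  Duplicate (molecule, target)
    pairs keep the first occurrence; multi-component SMILES (mixtures),
    carbon-free entries (inorganics) and unparseable molecules are
    dropped with a logged reason.
    """
    records: List[ActivityRecord] = []
    seen = set()
    for i, row in table.reset_index(drop=True).iterrows():
        smi = str(row["smiles"])
        seq = str(row["sequence"]).upper()
        sid = str(row.get("substance_id", f"SID{i}"))
        tid = str(row.get("target_id", f"T{hash(seq) & 0xFFFF:04X}"))
        key = (smi, seq)
        if key in seen:
            log.info("dropping duplicate pair %s/%s", sid, tid)
            continue
        if "." in smi:
            log.info("dropping mixture %s", sid)
            continue
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            log.info("dropping unparseable molecule %s", sid)
            continue
        if not any(a.GetSymbol() == "C" for a in mol.GetAtoms()):
            log.info("dropping carbon-free record %s", sid)
            continue
        seen.add(key)
        category = str(row["category"])
        records.append(
            ActivityRecord(
                substance_id=sid,
                smiles=smi,
                target_id=tid,
                sequence=seq,
                category=category,
                label=1 if category == "Active" else 0,
            )
        )
    return records


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> List[int]:
    # remainder ties go to the later split, so 80/10/10 of 5,945
    # gives 4,756/594/595
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    rem = [e - s for e, s in zip(exact, sizes)]
    leftover = n - sum(sizes)
    order = sorted(range(len(fractions)), key=lambda i: (rem[i], i), reverse=True)
    for i in order[:leftover]:
        sizes[i] += 1
    return sizes


def split(
    records: Sequence,
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    stratified: bool = True,
):
    """Random (optionally label-stratified) train/validation/test split.

    Disjoint, exhaustive, reproducible under ``seed``; sizes follow
    largest-remainder rounding of the fractions.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    records = list(records)

    def _split_indices(idx: np.ndarray) -> List[np.ndarray]:
        idx = rng.permutation(idx)
        sizes = _largest_remainder_sizes(len(idx), fractions)
        out, start = [], 0
        for s in sizes:
            out.append(idx[start : start + s])
            start += s
        return out

    if stratified and records and hasattr(records[0], "label"):
        labels = np.array([r.label for r in records])
        parts = [np.empty(0, dtype=int)] * 3
        for lab in sorted(set(labels.tolist())):
            chunks = _split_indices(np.flatnonzero(labels == lab))
            parts = [np.concatenate([p, c]) for p, c in zip(parts, chunks)]
        parts = [np.sort(p) for p in parts]
    else:
        parts = _split_indices(np.arange(len(records)))
    return tuple([records[i] for i in p] for p in parts)


# ---------------------------------------------------------------------------
# molecule graphs


def _one_hot(value, choices) -> List[int]:
    return [1 if value == c else 0 for c in choices]


def atom_feature_vector(atom) -> np.ndarray:
    """74-dim integer feature vector for one heavy atom."""
    sym = atom.GetSymbol()
    v = _one_hot(sym if sym in ATOM_TYPES else "C", ATOM_TYPES)
    v += _one_hot(min(atom.GetDegree(), 10), list(range(11)))
    v += _one_hot(min(atom.GetNumImplicitHs(), 6), list(range(7)))
    v += [atom.GetFormalCharge()]
    v += [atom.GetNumRadicalElectrons()]
    v += _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
    v += [1 if atom.GetIsAromatic() else 0]
    v += _one_hot(min(atom.GetTotalNumHs(), 4), list(range(5)))
    return np.array(v, dtype=np.float32)


@dataclass(frozen=True)
class MoleculeGraph:
    """Padded node features + symmetrically normalized adjacency."""

    features: np.ndarray  # (theta_d, 74); virtual-node rows all zero
    adjacency: np.ndarray  # (theta_d, theta_d) normalized A+I over real nodes
    n_real: int


def featurize_molecule(smiles: str, theta_d: int) -> MoleculeGraph:
    """SMILES -> 2-D molecular graph with padded 74-dim node features.

    Molecules with more than ``theta_d`` heavy atoms are truncated with
    a warning (mirroring the protein-length convention).
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    if n > theta_d:
        warnings.warn(
            f"molecule with {n} atoms truncated to {theta_d} nodes", stacklevel=2
        )
        n = theta_d
    feats = np.zeros((theta_d, NUM_ATOM_FEATURES), dtype=np.float32)
    for i in range(n):
        feats[i] = atom_feature_vector(mol.GetAtomWithIdx(i))

    adj = np.zeros((theta_d, theta_d), dtype=np.float32)
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a < n and b < n:
            adj[a, b] = adj[b, a] = 1.0
    adj[np.arange(n), np.arange(n)] = 1.0  # self loops on real nodes only
    deg = adj.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = deg[nz] ** -0.5
    adj = adj * inv_sqrt[:, None] * inv_sqrt[None, :]
    return MoleculeGraph(features=feats, adjacency=adj, n_real=n)


def encode_protein(sequence: str, theta_p: int) -> np.ndarray:
    """Protein sequence -> integer indices (0 = padding), truncated or
    zero-padded to ``theta_p``."""
    idx = np.zeros(theta_p, dtype=np.int64)
    for i, aa in enumerate(sequence[:theta_p]):
        idx[i] = _AA_INDEX.get(aa, _AA_INDEX["X"])
    return idx
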