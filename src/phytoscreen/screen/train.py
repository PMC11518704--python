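"""Training, evaluation and candidate ranking for the screening model."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .featurize import ActivityRecord, MoleculeGraph, encode_protein, featurize_molecule
from .metrics import EvalMetrics, evaluate_scores
from .model import DrugTargetModel, ModelConfig
from .nn import Adam

log = logging.getLogger(__name__)

__all__ = ["prepare_batches", "train", "evaluate", "rank_candidates"]


def _effective_dims(records: Sequence[ActivityRecord], config: ModelConfig):
    """Tight node/length budgets for a dataset (capped at the config)."""
    from rdkit import Chem

    max_atoms = 1
    max_len = 1
    graphs: Dict[str, MoleculeGraph] = {}
    for r in records:
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is not None:
            max_atoms = max(max_atoms, mol.GetNumAtoms())
        max_len = max(max_len, len(r.sequence))
    theta_d = min(max_atoms, config.theta_d)
    theta_p = min(max_len, config.theta_p)
    return theta_d, theta_p


class _Dataset:
    """Featurized, padded arrays for a fixed record list."""

    def __init__(self, records: Sequence[ActivityRecord], theta_d: int, theta_p: int):
        self.records = list(records)
        self.theta_d = theta_d
        self.theta_p = theta_p
        mol_cache: Dict[str, MoleculeGraph] = {}
        prot_cache: Dict[str, np.ndarray] = {}
        feats, adjs, prots, labels = [], [], [], []
        for r in self.records:
            if r.smiles not in mol_cache:
                mol_cache[r.smiles] = featurize_molecule(r.smiles, theta_d)
            if r.sequence not in prot_cache:
                prot_cache[r.sequence] = encode_protein(r.sequence, theta_p)
            g = mol_cache[r.smiles]
            feats.append(g.features)
            adjs.append(g.adjacency)
            prots.append(prot_cache[r.sequence])
            labels.append(r.label)
        self.mol_feats = np.stack(feats)
        self.adjacency = np.stack(adjs)
        self.protein_idx = np.stack(prots)
        self.labels = np.array(labels, dtype=np.float32)

    def __len__(self):
        return len(self.records)


def prepare_batches(dataset: _Dataset, batch_size: int, rng=None):
    idx = np.arange(len(dataset))
    if rng is not None:
        idx = rng.permutation(idx)
    for start in range(0, len(idx), batch_size):
        sel = idx[start : start + batch_size]
        yield (
            dataset.mol_feats[sel],
            dataset.adjacency[sel],
            dataset.protein_idx[sel],
            dataset.labels[sel],
        )


def train(
    records: Sequence[ActivityRecord],
    config: ModelConfig,
    validation: Optional[Sequence[ActivityRecord]] = None,
) -> Tuple[DrugTargetModel, List[float]]:
    """Fit the model with Adam on binary cross-entropy.

    Returns the trained model and the per-epoch mean training loss.
    Reproducible for a fixed ``config.seed``; raises on a single-class
    training set.
    """
    if not records:
        raise ValueError("empty training set")
    labels = {r.label for r in records}
    if len(labels) < 2:
        raise ValueError("training set contains a single class")

    theta_d, theta_p = _effective_dims(records, config)
    dataset = _Dataset(records, theta_d, theta_p)
    model = DrugTargetModel(config)
    model._theta = (theta_d, theta_p)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    losses: List[float] = []
    for epoch in range(config.epochs):
        epoch_loss, n_batches = 0.0, 0
        for mf, adj, prot, y in prepare_batches(dataset, config.batch_size, rng):
            logits = model.forward(mf, adj, prot)
            loss = logits.bce_with_logits(y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
        log.debug("epoch %d loss %.4f", epoch + 1, losses[-1])
    return model, losses


def _predict(model: DrugTargetModel, dataset: _Dataset, batch_size=128) -> np.ndarray:
    probs = []
    for mf, adj, prot, _y in prepare_batches(dataset, batch_size):
        probs.append(model.predict_proba(mf, adj, prot))
    return np.concatenate(probs) if probs else np.empty(0)


def predict_records(model: DrugTargetModel, records: Sequence[ActivityRecord]) -> np.ndarray:
    # the model is padding-invariant, so the tight budget of *these*
    # records suffices regardless of the budget used in training
    td, tp = _effective_dims(records, model.config)
    dataset = _Dataset(records, td, tp)
    return _predict(model, dataset)


def evaluate(model: DrugTargetModel, records: Sequence[ActivityRecord]) -> EvalMetrics:
    """Metrics on a held-out record list (needs both classes)."""
    scores = predict_records(model, records)
    return evaluate_scores(scores, np.array([r.label for r in records]))


def rank_candidates(
    model: DrugTargetModel,
    molecules: Sequence[Tuple[str, str]],  # (name, smiles)
    targets: Sequence[Tuple[str, str]],  # (target id, sequence)
) -> pd.DataFrame:
    """Score all molecule × target pairs, sorted by descending score."""
    recs = [
        ActivityRecord(
            substance_id=mn,
            smiles=smi,
            target_id=tn,
            sequence=seq.upper(),
            category="Unspecified",
            label=0,
        )
        for mn, smi in molecules
        for tn, seq in targets
    ]
    scores = predict_records(model, recs)
    df = pd.DataFrame(
        {
            "molecule": [r.substance_id for r in recs],
            "target": [r.target_id for r in recs],
            "score": scores,
        }
    )
    return df.sort_values(
        ["score", "molecule", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)
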