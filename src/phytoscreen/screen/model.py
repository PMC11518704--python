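"""Bilinear-attention drug-target interaction model.

Drug branch: a linear projection of the 74-dim atom features followed by
a three-layer graph convolution (symmetrically normalized adjacency with
self loops), keeping the representation at the node level.  Protein
branch: a trainable 23-symbol embedding followed by three 'same'-padded
1-D convolutions, each row describing a protein subsequence.  A bilinear
interaction map scores every (atom node, subsequence) pair, a softmax
over real pairs gives attention weights, bilinear pooling produces the
joint representation, and a small fully connected head yields the
interaction probability.

Padded positions (virtual atom nodes, protein padding) are masked after
every layer and excluded from attention, so growing the padding never
changes the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .featurize import NUM_ATOM_FEATURES, PROTEIN_ALPHABET, MoleculeGraph
from .nn import Adam, Tensor, constant, parameter

__all__ = ["ModelConfig", "DrugTargetModel"]


@dataclass
class ModelConfig:
    """Hyperparameters; layer counts fixed at 3/3 unless overridden."""

    theta_d: int = 290  # max drug nodes
    theta_p: int = 1200  # max protein length
    d_drug: int = 128
    d_prot: int = 128
    gcn_layers: int = 3
    conv_layers: int = 3
    kernel_sizes: Tuple[int, ...] = (3, 6, 9)
    attention_dim: int = 64
    classifier_hidden: Tuple[int, ...] = (64,)
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 5e-4
    seed: int = 0

    def __post_init__(self):
        if len(self.kernel_sizes) != self.conv_layers:
            raise ValueError("need one kernel size per conv layer")
        for name in ("theta_d", "theta_p", "d_drug", "d_prot", "attention_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class DrugTargetModel:
    """Numpy implementation of the GCN / CNN / bilinear-attention network."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config

        def glorot(*shape):
            fan_in, fan_out = shape[0], shape[-1]
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return parameter(
                rng.uniform(-limit, limit, size=shape).astype(np.float32)
            )

        def zeros(*shape):
            return parameter(np.zeros(shape, dtype=np.float32))

        self.w0 = glorot(NUM_ATOM_FEATURES, c.d_drug)
        self.b0 = zeros(c.d_drug)
        self.gcn_w = [glorot(c.d_drug, c.d_drug) for _ in range(c.gcn_layers)]
        self.gcn_b = [zeros(c.d_drug) for _ in range(c.gcn_layers)]

        self.embedding = glorot(len(PROTEIN_ALPHABET), c.d_prot)
        self.conv_w = [
            parameter(
                rng.uniform(
                    -np.sqrt(6.0 / (k * c.d_prot + c.d_prot)),
                    np.sqrt(6.0 / (k * c.d_prot + c.d_prot)),
                    size=(k, c.d_prot, c.d_prot),
                ).astype(np.float32)
            )
            for k in c.kernel_sizes
        ]
        self.conv_b = [zeros(c.d_prot) for _ in c.kernel_sizes]

        self.att_u = glorot(c.d_drug, c.attention_dim)
        self.att_v = glorot(c.d_prot, c.attention_dim)

        dims = (c.attention_dim,) + tuple(c.classifier_hidden) + (1,)
        self.cls_w = [glorot(a, b) for a, b in zip(dims[:-1], dims[1:])]
        self.cls_b = [zeros(b) for b in dims[1:]]

    # -- parameter plumbing -------------------------------------------
    def parameters(self) -> List[Tensor]:
        return (
            [self.w0, self.b0]
            + self.gcn_w
            + self.gcn_b
            + [self.embedding]
            + self.conv_w
            + self.conv_b
            + [self.att_u, self.att_v]
            + self.cls_w
            + self.cls_b
        )

    def state_dict(self) -> dict:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.array(state[f"p{i}"], dtype=p.data.dtype)

    # -- forward -------------------------------------------------------
    def forward(
        self,
        mol_feats: np.ndarray,  # (B, Td, 74)
        adjacency: np.ndarray,  # (B, Td, Td)
        protein_idx: np.ndarray,  # (B, Tp) ints, 0 = pad
        return_attention: bool = False,
    ):
        """Interaction logits (B,) plus optional attention map."""
        B, Td, _ = mol_feats.shape
        Tp = protein_idx.shape[1]
        node_mask = constant(
            (mol_feats.sum(axis=2, keepdims=True) != 0).astype(np.float32)
        )  # (B, Td, 1)
        prot_mask = constant((protein_idx > 0).astype(np.float32)[:, :, None])

        # drug encoder
        h = (constant(mol_feats) @ self.w0 + self.b0) * node_mask
        adj = constant(adjacency)
        for w, b in zip(self.gcn_w, self.gcn_b):
            h = ((adj @ h) @ w + b).relu() * node_mask

        # protein encoder: embedding lookup (pad index 0 masked to zero)
        emb_idx = np.clip(protein_idx - 1, 0, None)
        p = self.embedding.gather_rows(emb_idx) * prot_mask
        for w, b in zip(self.conv_w, self.conv_b):
            p = p.conv1d(w, b).relu() * prot_mask

        # bilinear interaction map over (node, subsequence) pairs
        a = h @ self.att_u  # (B, Td, K)
        v = p @ self.att_v  # (B, Tp, K)
        scale = 1.0 / np.sqrt(self.config.attention_dim)
        logits = (a @ v.transpose((0, 2, 1))) * scale  # (B, Td, Tp)
        pair_mask = node_mask.data * prot_mask.data.transpose(0, 2, 1)  # (B,Td,Tp)
        neg = constant((1.0 - pair_mask) * np.float32(-1e9))
        att = (logits + neg).reshape(B, Td * Tp).softmax(axis=1).reshape(B, Td, Tp)

        # bilinear pooling: f_k = sum_ij att_ij * a_ik * v_jk
        ctx = att @ v  # (B, Td, K)
        f = (a * ctx).sum(axis=1)  # (B, K)

        for i, (w, b) in enumerate(zip(self.cls_w, self.cls_b)):
            f = f @ w + b
            if i < len(self.cls_w) - 1:
                f = f.relu()
        out = f.reshape(B)
        if return_attention:
            return out, att.data
        return out

    def predict_proba(self, mol_feats, adjacency, protein_idx) -> np.ndarray:
        """Interaction probabilities in [0, 1] (no gradient tape kept)."""
        logits = self.forward(mol_feats, adjacency, protein_idx)
        probs = 1.0 / (1.0 + np.exp(-np.clip(logits.data, -60, 60)))
        logits.clear_graph()
        return probs
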