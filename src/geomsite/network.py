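"""Edge-enhanced graph transformer with ligand-specific heads.

The shared trunk stacks layers of (i) multi-head attention over the
residue graph in which projected edge features are added to both keys and
values, with a residual connection, (ii) a residual edge update from the
concatenated (source, edge, target) states, and (iii) a gated global
context update that modulates node states with a sigmoid gate computed
from the per-protein mean state. All scalars entering the network are
SE(3)-invariant, so the logits inherit rigid-motion invariance. One small
MLP head per ligand type maps the final node state to a binding logit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import FEATURE_VERSION

NONLINEARITY = "elu"


@dataclass
class ModelConfig:
    node_in_dim: int
    edge_in_dim: int
    hidden_dim: int = 128
    n_layers: int = 4
    n_heads: int = 4
    n_tasks: int = 10
    head_hidden: int | None = None      # default hidden_dim // 2
    dropout: float = 0.2
    use_layer_norm: bool = True
    seed: int = 0
    feature_version: str = FEATURE_VERSION

    def __post_init__(self) -> None:
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.n_tasks < 1:
            raise ValueError("need at least one task")
        if self.head_hidden is None:
            self.head_hidden = max(self.hidden_dim // 2, 1)


class GraphTransformerLayer:
    """One round of message passing, edge update and global gating."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.hidden_dim
        self.cfg = cfg
        self.W_Q = ad.Linear(d, d, rng, bias=False)
        self.W_K = ad.Linear(d, d, rng, bias=False)
        self.W_V = ad.Linear(d, d, rng, bias=False)
        self.W_E = ad.Linear(d, d, rng, bias=False)
        self.W_O = ad.Linear(d, d, rng)
        self.edge_mlp = ad.MLP([3 * d, d, d], rng)
        self.gate_mlp = ad.MLP([d, d, d], rng)
        self.ln_node = ad.LayerNorm(d) if cfg.use_layer_norm else None
        self.ln_edge = ad.LayerNorm(d) if cfg.use_layer_norm else None

    # --- Eq.-level operations ------------------------------------------------

    def message_passing(self, h, e, edge_index, *, training=False, rng=None):
        """Residual multi-head attention over incoming edges.

        For edge j->i and each head: w = q_i . (k_j + W_E e_ji) / sqrt(d_head),
        alpha = softmax over j in N(i) u {i}, and the node update is
        h_i + W_O concat_heads( sum_j alpha_ji (v_j + W_E e_ji) ).
        Also returns the attention weights for diagnostics.
        """
        cfg = self.cfg
        d, H = cfg.hidden_dim, cfg.n_heads
        dh = d // H
        j_idx, i_idx = edge_index[:, 0], edge_index[:, 1]
        n = h.shape[0]
        E = len(j_idx)

        q = ad.gather(self.W_Q(h), i_idx)
        k = ad.add(ad.gather(self.W_K(h), j_idx), self.W_E(e))
        v = ad.add(ad.gather(self.W_V(h), j_idx), self.W_E(e))
        qh = ad.reshape(q, (E, H, dh))
        kh = ad.reshape(k, (E, H, dh))
        vh = ad.reshape(v, (E, H, dh))

        logits = ad.mul(_sum_last(ad.mul(qh, kh)), 1.0 / np.sqrt(dh))  # (E, H)
        alpha = ad.segment_softmax(logits, i_idx, n)
        alpha_d = ad.dropout(alpha, cfg.dropout, rng, training)
        weighted = ad.mul(vh, ad.reshape(alpha_d, (E, H, 1)))
        agg = ad.segment_sum(weighted, i_idx, n)                        # (n, H, dh)
        out = self.W_O(ad.reshape(agg, (n, d)))
        return ad.add(h, out), alpha

    def edge_update(self, h_hat, e, edge_index, *, training=False, rng=None):
        """e_ji <- e_ji + EdgeMLP(h_j || e_ji || h_i)."""
        j_idx, i_idx = edge_index[:, 0], edge_index[:, 1]
        cat = ad.concat([ad.gather(h_hat, j_idx), e, ad.gather(h_hat, i_idx)], axis=1)
        delta = self.edge_mlp(cat, dropout_p=self.cfg.dropout, rng=rng, training=training)
        return ad.add(e, delta)

    def global_node_update(self, h_hat, protein_ids, n_proteins, *,
                           training=False, rng=None):
        """h_i <- h_i * sigmoid(GateMLP(c)), c the protein's mean node state."""
        counts = np.bincount(protein_ids, minlength=n_proteins)
        if np.any(counts == 0):
            raise ValueError("empty protein in batch")
        c = ad.segment_mean(h_hat, protein_ids, n_proteins)
        gate = ad.sigmoid(self.gate_mlp(c, dropout_p=self.cfg.dropout,
                                        rng=rng, training=training))
        return ad.mul(h_hat, ad.gather(gate, protein_ids))

    def __call__(self, h, e, edge_index, protein_ids, n_proteins, *,
                 training=False, rng=None):
        h_hat, _ = self.message_passing(h, e, edge_index, training=training, rng=rng)
        if self.ln_node is not None:
            h_hat = self.ln_node(h_hat)
        e = self.edge_update(h_hat, e, edge_index, training=training, rng=rng)
        if self.ln_edge is not None:
            e = self.ln_edge(e)
        h = self.global_node_update(h_hat, protein_ids, n_proteins,
                                    training=training, rng=rng)
        return h, e

    def parameters(self):
        ps = (self.W_Q.parameters() + self.W_K.parameters() + self.W_V.parameters()
              + self.W_E.parameters() + self.W_O.parameters()
              + self.edge_mlp.parameters() + self.gate_mlp.parameters())
        if self.ln_node is not None:
            ps += self.ln_node.parameters() + self.ln_edge.parameters()
        return ps


def _sum_last(t: Tensor) -> Tensor:
    """Sum over the trailing axis via a matmul with ones (keeps the tape)."""
    ones = np.ones((t.shape[-1], 1))
    return ad.reshape(ad.matmul(ad.reshape(t, (-1, t.shape[-1])), ones),
                      t.shape[:-1])


class GPSiteModel:
    """Shared trunk + per-ligand heads; deterministic under a fixed seed."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.hidden_dim
        self.node_proj = ad.MLP([cfg.node_in_dim, d, d], rng)
        self.edge_proj = ad.MLP([cfg.edge_in_dim, d, d], rng)
        self.layers = [GraphTransformerLayer(cfg, rng) for _ in range(cfg.n_layers)]
        self.heads = [ad.MLP([d, cfg.head_hidden, 1], rng) for _ in range(cfg.n_tasks)]
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

    def input_projection(self, node_feats, edge_feats, *, training=False, rng=None):
        h = self.node_proj(ad.as_tensor(node_feats), dropout_p=self.cfg.dropout,
                           rng=rng, training=training)
        e = self.edge_proj(ad.as_tensor(edge_feats), dropout_p=self.cfg.dropout,
                           rng=rng, training=training)
        return h, e

    def forward(self, node_feats, edge_feats, edge_index, protein_ids=None,
                training: bool = False) -> Tensor:
        """Per-residue logits of shape (n, n_tasks)."""
        node_feats = np.asarray(node_feats, float)
        edge_feats = np.asarray(edge_feats, float)
        edge_index = np.asarray(edge_index, np.int64)
        if node_feats.shape[1] != self.cfg.node_in_dim:
            raise ValueError(
                f"node feature width {node_feats.shape[1]} != {self.cfg.node_in_dim}")
        if edge_feats.shape[1] != self.cfg.edge_in_dim:
            raise ValueError(
                f"edge feature width {edge_feats.shape[1]} != {self.cfg.edge_in_dim}")
        n = node_feats.shape[0]
        if protein_ids is None:
            protein_ids = np.zeros(n, dtype=np.int64)
        protein_ids = np.asarray(protein_ids, np.int64)
        n_proteins = int(protein_ids.max()) + 1 if n else 0
        rng = self._dropout_rng if training else None

        h, e = self.input_projection(node_feats, edge_feats, training=training, rng=rng)
        for layer in self.layers:
            h, e = layer(h, e, edge_index, protein_ids, n_proteins,
                         training=training, rng=rng)
        logits = ad.concat(
            [head(h, dropout_p=self.cfg.dropout, rng=rng, training=training)
             for head in self.heads], axis=1)
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("non-finite logits")
        return logits

    def predict_proba(self, node_feats, edge_feats, edge_index,
                      protein_ids=None) -> np.ndarray:
        logits = self.forward(node_feats, edge_feats, edge_index, protein_ids,
                              training=False)
        return 1.0 / (1.0 + np.exp(-logits.data))

    def parameters(self):
        ps = self.node_proj.parameters() + self.edge_proj.parameters()
        for layer in self.layers:
            ps += layer.parameters()
        for head in self.heads:
            ps += head.parameters()
        return ps

    def head_parameters(self, task: int):
        return self.heads[task].parameters()

    def trunk_parameters(self):
        ps = self.node_proj.parameters() + self.edge_proj.parameters()
        for layer in self.layers:
            ps += layer.parameters()
        return ps

    # --- checkpointing -------------------------------------------------------

    def save(self, path: str) -> None:
        arrays = {f"param_{k}": p.data for k, p in enumerate(self.parameters())}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "GPSiteModel":
        with np.load(path) as data:
            cfg_dict = json.loads(bytes(data["__config__"]).decode())
            if cfg_dict.get("feature_version") != FEATURE_VERSION:
                raise ValueError(
                    f"checkpoint feature version {cfg_dict.get('feature_version')!r} "
                    f"does not match this featurizer ({FEATURE_VERSION!r}); "
                    "re-featurize and retrain, or use a matching package version")
            model = cls(ModelConfig(**cfg_dict))
            params = model.parameters()
            for k, p in enumerate(params):
                arr = data[f"param_{k}"]
                if arr.shape != p.data.shape:
                    raise ValueError("checkpoint parameter shape mismatch")
                p.data = arr.astype(np.float64)
        return model


def ensemble_predict_proba(models, node_feats, edge_feats, edge_index,
                           protein_ids=None) -> np.ndarray:
    """Arithmetic mean of the sigmoid outputs of several models."""
    probs = [m.predict_proba(node_feats, edge_feats, edge_index, protein_ids)
             for m in models]
    return np.mean(probs, axis=0)
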