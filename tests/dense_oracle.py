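"""Literal, loop-based reference implementation of the graph transformer.

Computes the same architecture as geomsite.network one node at a time
with dense numpy arithmetic — attention logits, softmax over the incoming
neighborhood, edge-augmented values, residual edge MLP, and the global
gated context — sharing only the trained parameter values with the sparse
implementation under test.
"""

import numpy as np


def _mlp(mlp, x):
    for k, layer in enumerate(mlp.layers):
        x = x @ layer.W.data + layer.b.data
        if k < len(mlp.layers) - 1:
            x = np.where(x > 0, x, np.exp(np.minimum(x, 0)) - 1.0)  # ELU
    return x


def _ln(ln, x):
    mu = x.mean(axis=-1, keepdims=True)
    sd = np.sqrt(x.var(axis=-1, keepdims=True) + 1e-5)
    return (x - mu) / sd * ln.gain.data + ln.bias.data


def dense_forward(model, node_feats, edge_feats, edge_index, protein_ids=None):
    """Eval-mode forward pass with explicit per-node loops."""
    cfg = model.cfg
    n = node_feats.shape[0]
    if protein_ids is None:
        protein_ids = np.zeros(n, dtype=int)
    d, H = cfg.hidden_dim, cfg.n_heads
    dh = d // H
    h = _mlp(model.node_proj, np.asarray(node_feats, float))
    e = _mlp(model.edge_proj, np.asarray(edge_feats, float))
    edges = [(int(j), int(i), k) for k, (j, i) in enumerate(edge_index)]

    for layer in model.layers:
        q = h @ layer.W_Q.W.data
        key = h @ layer.W_K.W.data
        val = h @ layer.W_V.W.data
        ep = e @ layer.W_E.W.data
        h_hat = np.zeros_like(h)
        for i in range(n):
            incoming = [(j, k) for (j, ii, k) in edges if ii == i]
            agg = np.zeros(d)
            for head in range(H):
                sl = slice(head * dh, (head + 1) * dh)
                logits = np.array([
                    q[i, sl] @ (key[j, sl] + ep[k, sl]) / np.sqrt(dh)
                    for j, k in incoming])
                w = np.exp(logits - logits.max())
                alpha = w / w.sum()
                agg[sl] = sum(a * (val[j, sl] + ep[k, sl])
                              for a, (j, k) in zip(alpha, incoming))
            h_hat[i] = h[i] + agg @ layer.W_O.W.data + layer.W_O.b.data
        if layer.ln_node is not None:
            h_hat = _ln(layer.ln_node, h_hat)
        e_new = np.array([
            e[k] + _mlp(layer.edge_mlp,
                        np.concatenate([h_hat[j], e[k], h_hat[i]]))
            for (j, i, k) in edges])
        if layer.ln_edge is not None:
            e_new = _ln(layer.ln_edge, e_new)
        e = e_new
        h_next = np.zeros_like(h_hat)
        for p in np.unique(protein_ids):
            members = np.flatnonzero(protein_ids == p)
            c = h_hat[members].mean(axis=0)
            gate = 1.0 / (1.0 + np.exp(-_mlp(layer.gate_mlp, c)))
            h_next[members] = h_hat[members] * gate
        h = h_next

    logits = np.stack([_mlp(head, h)[:, 0] for head in model.heads], axis=1)
    return logits
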