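"""Neighborhood-aggregation embedding of transcript graphs.

A 2-layer GraphSAGE-style encoder over the transcript graph: each node's
input feature is its one-hot gene identity (the only per-transcript
covariate a segmentation-free method has), and each layer pools a fixed
fan-out sample of neighbors with softmax-normalized learned attention
scores before combining with the node's own projection. The encoder is
trained unsupervised by binary edge prediction: true edges are scored
against sampled non-edges through the sigmoid of an inner-product link
score, with binary cross-entropy loss. Forward, backward and the Adam
update are implemented directly on NumPy arrays; all sampling is driven by
a seeded generator, so training is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class EmbeddingConfig:
    n_layers: int = 2
    hidden: tuple[int, int] = (50, 50)
    fanout: tuple[int, int] = (20, 10)
    n_roots_per_tissue: int = 5000
    hops: int = 3
    epochs: int = 30
    learning_rate: float = 0.01
    negative_ratio: float = 1.0
    max_edges_per_epoch: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers != 2:
            raise ValueError("the encoder is fixed at 2 layers")
        if len(self.fanout) != self.n_layers:
            raise ValueError("fanout length must equal n_layers")
        if min(self.hidden) < 1 or min(self.fanout) < 1 or self.epochs < 1:
            raise ValueError("hidden sizes, fanouts and epochs must be positive")


@dataclass
class _Adjacency:
    """CSR adjacency built once from an edge array."""

    indptr: np.ndarray
    indices: np.ndarray

    @classmethod
    def from_edges(cls, n_nodes: int, edges: np.ndarray) -> "_Adjacency":
        if len(edges) == 0:
            return cls(np.zeros(n_nodes + 1, dtype=np.int64), np.empty(0, dtype=np.int64))
        src = np.concatenate([edges[:, 0], edges[:, 1]])
        dst = np.concatenate([edges[:, 1], edges[:, 0]])
        order = np.argsort(src, kind="stable")
        src, dst = src[order], dst[order]
        indptr = np.zeros(n_nodes + 1, dtype=np.int64)
        np.add.at(indptr, src + 1, 1)
        np.cumsum(indptr, out=indptr)
        return cls(indptr, dst.astype(np.int64))

    def sample_neighbors(self, nodes: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
        """(len(nodes), k) neighbor sample with replacement; isolated nodes self-loop."""
        nodes = np.asarray(nodes, dtype=np.int64)
        if len(self.indices) == 0:
            return np.repeat(nodes[:, None], k, axis=1)
        deg = self.indptr[nodes + 1] - self.indptr[nodes]
        u = rng.random((len(nodes), k))
        offs = np.floor(u * np.maximum(deg, 1)[:, None]).astype(np.int64)
        nbr = self.indices[np.minimum(self.indptr[nodes][:, None] + offs, len(self.indices) - 1)]
        isolated = deg == 0
        if isolated.any():
            nbr[isolated] = nodes[isolated][:, None]
        return nbr


def _softmax(s: np.ndarray) -> np.ndarray:
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class EmbeddingModel:
    """Trained encoder parameters plus the gene vocabulary they index."""

    gene_vocab: list[str]
    cfg: EmbeddingConfig
    params: dict[str, np.ndarray]
    losses: list[float] = field(default_factory=list)

    def embed(
        self,
        gene_codes: np.ndarray,
        adj: "_Adjacency",
        seed: int = 0,
        chunk: int = 20000,
    ) -> np.ndarray:
        """Embeddings for every node, computed in chunks.

        Layer-1 representations are computed for all nodes first (layer 2
        aggregates neighbors' layer-1 outputs), then layer 2 per chunk.
        """
        p = self.params
        rng = np.random.default_rng(seed)
        n = len(gene_codes)
        k1, k2 = self.cfg.fanout
        h1_all = np.empty((n, self.cfg.hidden[0]), dtype=np.float32)
        for lo in range(0, n, chunk):
            idx = np.arange(lo, min(lo + chunk, n))
            nbr1 = adj.sample_neighbors(idx, k1, rng)  # global node ids
            m1 = p["Wn1"][gene_codes[nbr1]]  # (c, K1, H)
            a1 = _softmax(m1 @ p["q1"])
            n1 = np.einsum("ck,ckh->ch", a1, m1)
            h1_all[idx] = np.maximum(p["Ws1"][gene_codes[idx]] + n1 + p["b1"], 0.0)
        z_all = np.empty((n, self.cfg.hidden[1]), dtype=np.float32)
        for lo in range(0, n, chunk):
            idx = np.arange(lo, min(lo + chunk, n))
            nbr2 = adj.sample_neighbors(idx, k2, rng)
            m2 = h1_all[nbr2] @ p["Wn2"]  # (c, K2, H)
            a2 = _softmax(m2 @ p["q2"])
            n2 = np.einsum("ck,ckh->ch", a2, m2)
            z_all[idx] = h1_all[idx] @ p["Ws2"] + n2 + p["b2"]
        return z_all


def _init_params(n_genes: int, hidden: tuple[int, int], rng: np.random.Generator):
    h1, h2 = hidden
    def glorot(shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[-1]))
        return rng.uniform(-lim, lim, size=shape).astype(np.float32)

    return {
        "Wn1": glorot((n_genes, h1)),
        "Ws1": glorot((n_genes, h1)),
        "b1": np.zeros(h1, dtype=np.float32),
        "q1": (rng.standard_normal(h1) * 0.1).astype(np.float32),
        "Wn2": glorot((h1, h2)),
        "Ws2": glorot((h1, h2)),
        "b2": np.zeros(h2, dtype=np.float32),
        "q2": (rng.standard_normal(h2) * 0.1).astype(np.float32),
    }


def train_embedding(
    gene_codes: np.ndarray,
    edges: np.ndarray,
    gene_vocab: list[str],
    cfg: EmbeddingConfig | None = None,
) -> EmbeddingModel:
    """Train the encoder on a (joint) transcript graph by edge prediction.

    ``gene_codes`` maps each node to its gene index in ``gene_vocab``;
    ``edges`` is an (E, 2) undirected edge array of node indices.
    """
    cfg = cfg or EmbeddingConfig()
    edges = np.asarray(edges, dtype=np.int64)
    if len(edges) == 0:
        raise ValueError("cannot train edge prediction on a graph with zero edges")
    n = len(gene_codes)
    rng = np.random.default_rng(cfg.seed)
    adj = _Adjacency.from_edges(n, edges)
    model = EmbeddingModel(
        gene_vocab=list(gene_vocab),
        cfg=cfg,
        params=_init_params(len(gene_vocab), cfg.hidden, rng),
    )
    p = model.params
    adam_m = {k: np.zeros_like(v) for k, v in p.items()}
    adam_v = {k: np.zeros_like(v) for k, v in p.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    k1, k2 = cfg.fanout

    for epoch in range(1, cfg.epochs + 1):
        # --- batch: positive edges + uniform negative pairs
        n_pos = min(cfg.max_edges_per_epoch, len(edges))
        pos = edges[rng.choice(len(edges), size=n_pos, replace=False)]
        n_neg = int(round(cfg.negative_ratio * n_pos))
        neg = rng.integers(0, n, size=(n_neg, 2))
        batch_pairs = np.vstack([pos, neg])
        y = np.concatenate([np.ones(n_pos, np.float32), np.zeros(n_neg, np.float32)])

        nodes, inv = np.unique(batch_pairs.ravel(), return_inverse=True)
        inv = inv.reshape(batch_pairs.shape)
        g = gene_codes[nodes]

        # --- forward: layer 1 for batch nodes and their layer-2 frontier
        nbr2_global = adj.sample_neighbors(nodes, k2, rng)  # (B, K2) global ids
        frontier, f_inv = np.unique(
            np.concatenate([nodes, nbr2_global.ravel()]), return_inverse=True
        )
        node_loc = f_inv[: len(nodes)]
        nbr2 = f_inv[len(nodes):].reshape(nbr2_global.shape)
        gf = gene_codes[frontier]
        nbr1 = adj.sample_neighbors(frontier, k1, rng)  # global ids; features via gene_codes
        # layer 1 over the frontier (nbr1 features looked up globally)
        m1 = p["Wn1"][gene_codes[nbr1]]  # (F, K1, H)
        s1 = m1 @ p["q1"]
        a1 = _softmax(s1)
        n1 = np.einsum("fk,fkh->fh", a1, m1)
        h1_pre = p["Ws1"][gf] + n1 + p["b1"]
        h1 = np.maximum(h1_pre, 0.0)  # (F, H)
        # layer 2 over batch nodes
        h1_self = h1[node_loc]
        h1_nbr = h1[nbr2]  # (B, K2, H)
        m2 = h1_nbr @ p["Wn2"]
        s2 = m2 @ p["q2"]
        a2 = _softmax(s2)
        n2 = np.einsum("bk,bkh->bh", a2, m2)
        z = h1_self @ p["Ws2"] + n2 + p["b2"]  # (B, H)

        # --- loss
        zu, zv = z[inv[:, 0]], z[inv[:, 1]]
        score = np.einsum("ij,ij->i", zu, zv)
        prob = 1.0 / (1.0 + np.exp(-np.clip(score, -30, 30)))
        loss = float(
            -np.mean(y * np.log(prob + 1e-12) + (1 - y) * np.log(1 - prob + 1e-12))
        )
        model.losses.append(loss)

        # --- backward
        dscore = (prob - y) / len(y)
        dz = np.zeros_like(z)
        np.add.at(dz, inv[:, 0], dscore[:, None] * zv)
        np.add.at(dz, inv[:, 1], dscore[:, None] * zu)

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["b2"] = dz.sum(axis=0)
        grads["Ws2"] = h1_self.T @ dz
        dh1 = np.zeros_like(h1)
        np.add.at(dh1, node_loc, dz @ p["Ws2"].T)
        # attention block of layer 2
        da2 = np.einsum("bh,bkh->bk", dz, m2)
        dm2 = a2[:, :, None] * dz[:, None, :]
        ds2 = a2 * (da2 - (a2 * da2).sum(axis=1, keepdims=True))
        grads["q2"] = np.einsum("bk,bkh->h", ds2, m2)
        dm2 += ds2[:, :, None] * p["q2"][None, None, :]
        grads["Wn2"] = np.einsum("bkh,bkg->hg", h1_nbr, dm2)
        dh1_nbr = dm2 @ p["Wn2"].T
        np.add.at(dh1, nbr2, dh1_nbr)
        # through relu into layer 1
        dh1_pre = dh1 * (h1_pre > 0)
        grads["b1"] = dh1_pre.sum(axis=0)
        np.add.at(grads["Ws1"], gf, dh1_pre)
        da1 = np.einsum("fh,fkh->fk", dh1_pre, m1)
        dm1 = a1[:, :, None] * dh1_pre[:, None, :]
        ds1 = a1 * (da1 - (a1 * da1).sum(axis=1, keepdims=True))
        grads["q1"] = np.einsum("fk,fkh->h", ds1, m1)
        dm1 += ds1[:, :, None] * p["q1"][None, None, :]
        np.add.at(grads["Wn1"], gene_codes[nbr1].ravel(), dm1.reshape(-1, dm1.shape[-1]))

        # --- Adam step
        for key in p:
            gk = grads[key].astype(np.float32)
            adam_m[key] = beta1 * adam_m[key] + (1 - beta1) * gk
            adam_v[key] = beta2 * adam_v[key] + (1 - beta2) * gk * gk
            mhat = adam_m[key] / (1 - beta1**epoch)
            vhat = adam_v[key] / (1 - beta2**epoch)
            p[key] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    return model


def embed_graph(
    model: EmbeddingModel,
    gene_codes: np.ndarray,
    edges: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Apply a trained encoder to a full graph and return per-node embeddings."""
    adj = _Adjacency.from_edges(len(gene_codes), np.asarray(edges, dtype=np.int64))
    return model.embed(np.asarray(gene_codes), adj, seed=seed)
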