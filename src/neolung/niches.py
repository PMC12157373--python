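"""Multicellular niche detection, cell-based and transcript-based.

Cell-based niches (CNiches): each cell's neighborhood is the cell-type
composition of its k nearest neighbor cells; k-means on these composition
vectors partitions the cohort into ``n_niches`` niches.

Transcript-based niches (TNiches) are segmentation-free: transcripts are
nodes of a per-tissue graph with edges between transcripts within 3 um,
small connected components (likely background) are pruned, subgraphs
rooted at randomly sampled nodes are merged into a joint training graph,
a neighborhood-aggregation encoder embeds every transcript, a Gaussian
mixture on the embeddings yields per-transcript niche labels, and labels
are summarized into hexagonal bins and transferred to cell centroids.

A deterministic, non-learned embedding (distance-weighted neighborhood
gene composition) is available alongside the learned encoder; it exercises
everything downstream of the embedding quickly and reproducibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .embedding import EmbeddingConfig, EmbeddingModel, _Adjacency, train_embedding
from .io_qc import is_control

logger = logging.getLogger(__name__)

UNASSIGNED_NICHE = -1  # explicit label for cells near no retained hex bin


# ---------------------------------------------------------------------------
# cell-based niches

@dataclass(frozen=True)
class CNicheConfig:
    k_neighbors: int = 10
    n_niches: int = 11
    seed: int = 0
    include_self: bool = True
    n_init: int = 10

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_niches < 2:
            raise ValueError("n_niches must be >= 2")


def neighborhood_compositions(
    cells: pd.DataFrame, cfg: CNicheConfig
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell cell-type composition of the k-nearest-neighbor neighborhood.

    Neighborhoods never cross section boundaries; sections with fewer than
    ``k_neighbors + 1`` cells are skipped with a log entry. Returns the
    retained cells and their composition count matrix (cells x types).
    """
    types = np.array(sorted(cells["cell_type"].unique()))
    type_idx = {t: i for i, t in enumerate(types)}
    key = cells["section_id"] if "section_id" in cells.columns else cells["sample_id"]
    kept, mats = [], []
    for sec, grp in cells.groupby(key, sort=False):
        if len(grp) < cfg.k_neighbors + 1:
            logger.info("section %s skipped for CNiches: only %d cells", sec, len(grp))
            continue
        xy = grp[["centroid_x_um", "centroid_y_um"]].to_numpy(float)
        nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(xy)
        _, idx = nn.kneighbors(xy)
        nbr = idx if cfg.include_self else idx[:, 1:]
        codes = grp["cell_type"].map(type_idx).to_numpy()
        comp = np.zeros((len(grp), len(types)), dtype=np.int32)
        rows = np.repeat(np.arange(len(grp)), nbr.shape[1])
        np.add.at(comp, (rows, codes[nbr.ravel()]), 1)
        kept.append(grp)
        mats.append(comp)
    if not kept:
        return cells.iloc[0:0], np.zeros((0, len(types)), dtype=np.int32)
    return pd.concat(kept), np.vstack(mats)


def cniche_assign(cells: pd.DataFrame, cfg: CNicheConfig | None = None) -> pd.DataFrame:
    """k-means niches from k-nearest-neighbor cell-type compositions.

    Returns a frame with ``cell_id`` and ``cniche`` in 1..n_niches. The
    composition matrix is sorted by cell_id before clustering so labels do
    not depend on the input row order.
    """
    cfg = cfg or CNicheConfig()
    kept, comp = neighborhood_compositions(cells, cfg)
    if len(kept) < cfg.n_niches:
        raise ValueError(
            f"only {len(kept)} cells with neighborhoods, need >= n_niches = {cfg.n_niches}"
        )
    order = np.argsort(kept["cell_id"].to_numpy(), kind="stable")
    km = KMeans(
        n_clusters=cfg.n_niches,
        init="k-means++",
        n_init=cfg.n_init,
        random_state=cfg.seed,
    )
    labels_sorted = km.fit_predict(comp[order].astype(float))
    labels = np.empty(len(kept), dtype=int)
    labels[order] = labels_sorted + 1
    return pd.DataFrame({"cell_id": kept["cell_id"].to_numpy(), "cniche": labels})


# ---------------------------------------------------------------------------
# transcript graphs

@dataclass
class TranscriptGraph:
    """An undirected spatial transcript graph for one tissue section.

    ``nodes`` holds transcript_id, x_um, y_um, feature (index-aligned with
    edge endpoints); ``edges`` is an (E, 2) array of node indices. After
    pruning, every connected component has at least ``min_component``
    nodes.
    """

    nodes: pd.DataFrame
    edges: np.ndarray
    tissue: str = ""
    edge_radius_um: float = 3.0
    min_component: float = 10

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_transcript_graph(
    t: pd.DataFrame,
    edge_radius_um: float = 3.0,
    min_component: int = 10,
    qv_min: float = 20.0,
    tissue: str = "",
) -> TranscriptGraph:
    """Build the pruned transcript graph for one tissue's transcripts.

    Low-quality (qv < ``qv_min``) and control transcripts are excluded;
    unassigned transcripts stay (the method is segmentation-free). Edges
    connect transcripts within ``edge_radius_um``; connected components
    smaller than ``min_component`` are dropped as likely background. An
    empty graph after pruning is returned explicitly (0 nodes).
    """
    keep = (t["qv"].to_numpy(float) >= qv_min) & ~is_control(t["feature"]).to_numpy()
    nodes = t.loc[keep, ["transcript_id", "x_um", "y_um", "feature"]].reset_index(drop=True)
    if len(nodes) == 0:
        return TranscriptGraph(nodes, np.empty((0, 2), dtype=np.int64), tissue, edge_radius_um, min_component)
    xy = nodes[["x_um", "y_um"]].to_numpy(float)
    pairs = cKDTree(xy).query_pairs(edge_radius_um, output_type="ndarray")
    n = len(nodes)
    if len(pairs):
        adj = csr_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, comp = connected_components(adj, directed=False)
    else:
        comp = np.arange(n)
    sizes = np.bincount(comp)
    node_keep = sizes[comp] >= min_component
    remap = -np.ones(n, dtype=np.int64)
    remap[node_keep] = np.arange(node_keep.sum())
    nodes = nodes.loc[node_keep].reset_index(drop=True)
    if len(pairs):
        epairs = pairs[node_keep[pairs[:, 0]] & node_keep[pairs[:, 1]]]
        edges = remap[epairs]
    else:
        edges = np.empty((0, 2), dtype=np.int64)
    return TranscriptGraph(nodes, edges.astype(np.int64), tissue, edge_radius_um, min_component)


def write_edge_list(graph: TranscriptGraph, path) -> None:
    """Export a transcript graph as an edge-list CSV (transcript id pairs)."""
    ids = graph.nodes["transcript_id"].to_numpy()
    pd.DataFrame(
        {"source": ids[graph.edges[:, 0]], "target": ids[graph.edges[:, 1]]}
        if graph.n_edges
        else {"source": [], "target": []}
    ).to_csv(path, index=False)


def build_tissue_graphs(
    t: pd.DataFrame, edge_radius_um: float = 3.0, min_component: int = 10, qv_min: float = 20.0
) -> dict[str, TranscriptGraph]:
    """One pruned transcript graph per tissue section."""
    key = "section_id" if "section_id" in t.columns else "sample_id"
    return {
        str(sec): build_transcript_graph(grp, edge_radius_um, min_component, qv_min, str(sec))
        for sec, grp in t.groupby(key, sort=False)
    }


def sample_subgraphs(
    graphs: dict[str, TranscriptGraph],
    n_roots_per_tissue: int = 5000,
    hops: int = 3,
    seed: int = 0,
) -> TranscriptGraph:
    """Sample per-tissue rooted subgraphs and merge them into a joint graph.

    Per tissue: min(n_roots_per_tissue, n_nodes) root nodes are drawn
    without replacement, their ``hops``-hop neighborhoods collected, and
    all existing edges among the selected nodes induced. Tissues are then
    disjoint-unioned. Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    node_frames, edge_blocks = [], []
    offset = 0
    for name in sorted(graphs):
        g = graphs[name]
        if g.n_nodes == 0:
            continue
        adj = _Adjacency.from_edges(g.n_nodes, g.edges)
        n_roots = min(n_roots_per_tissue, g.n_nodes)
        roots = rng.choice(g.n_nodes, size=n_roots, replace=False)
        selected = np.zeros(g.n_nodes, dtype=bool)
        selected[roots] = True
        frontier = roots
        for _ in range(hops):
            if len(frontier) == 0:
                break
            nxt = adj.indices[
                np.concatenate(
                    [np.arange(adj.indptr[v], adj.indptr[v + 1]) for v in frontier]
                )
            ] if len(adj.indices) else np.empty(0, dtype=np.int64)
            nxt = np.unique(nxt)
            frontier = nxt[~selected[nxt]]
            selected[frontier] = True
        remap = -np.ones(g.n_nodes, dtype=np.int64)
        remap[selected] = offset + np.arange(selected.sum())
        sub_nodes = g.nodes.loc[selected].copy()
        sub_nodes["tissue"] = name
        node_frames.append(sub_nodes)
        if g.n_edges:
            keep = selected[g.edges[:, 0]] & selected[g.edges[:, 1]]
            edge_blocks.append(remap[g.edges[keep]])
        offset += int(selected.sum())
    if not node_frames:
        return TranscriptGraph(
            pd.DataFrame(columns=["transcript_id", "x_um", "y_um", "feature", "tissue"]),
            np.empty((0, 2), dtype=np.int64),
            "joint",
        )
    edges = np.vstack(edge_blocks) if edge_blocks else np.empty((0, 2), dtype=np.int64)
    return TranscriptGraph(pd.concat(node_frames, ignore_index=True), edges, "joint")


# ---------------------------------------------------------------------------
# embeddings over transcript graphs

def _gene_codes(nodes: pd.DataFrame, vocab: list[str]) -> np.ndarray:
    idx = {g: i for i, g in enumerate(vocab)}
    codes = nodes["feature"].map(idx)
    if codes.isna().any():
        missing = sorted(set(nodes.loc[codes.isna(), "feature"]))
        raise ValueError(f"genes absent from vocabulary: {missing[:5]}")
    return codes.to_numpy(np.int64)


def train_graph_embedding(
    joint: TranscriptGraph, gene_vocab: list[str], cfg: EmbeddingConfig | None = None
) -> EmbeddingModel:
    """Train the attentional neighborhood-aggregation encoder on a joint graph."""
    return train_embedding(_gene_codes(joint.nodes, gene_vocab), joint.edges, gene_vocab, cfg)


def apply_graph_embedding(
    model: EmbeddingModel, graph: TranscriptGraph, seed: int = 0
) -> np.ndarray:
    adj = _Adjacency.from_edges(graph.n_nodes, graph.edges)
    return model.embed(_gene_codes(graph.nodes, model.gene_vocab), adj, seed=seed)


def composition_embedding(
    graph: TranscriptGraph,
    gene_vocab: list[str],
    radius_um: float = 10.0,
    tau_um: float = 5.0,
) -> np.ndarray:
    """Deterministic fallback embedding: weighted neighborhood gene composition.

    Each transcript is represented by the exp(-d/tau)-weighted gene
    composition of transcripts within ``radius_um`` (itself included at
    weight 1), L1-normalized. No training, no randomness.
    """
    codes = _gene_codes(graph.nodes, gene_vocab)
    n, g = graph.n_nodes, len(gene_vocab)
    emb = np.zeros((n, g), dtype=np.float32)
    emb[np.arange(n), codes] = 1.0
    xy = graph.nodes[["x_um", "y_um"]].to_numpy(float)
    pairs = cKDTree(xy).query_pairs(radius_um, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        w = np.exp(-d / tau_um).astype(np.float32)
        np.add.at(emb, (pairs[:, 0], codes[pairs[:, 1]]), w)
        np.add.at(emb, (pairs[:, 1], codes[pairs[:, 0]]), w)
    total = emb.sum(axis=1, keepdims=True)
    return emb / np.maximum(total, 1e-12)


def tniche_cluster(
    embeddings: np.ndarray, n_niches: int = 11, seed: int = 0, covariance_type: str = "full"
) -> np.ndarray:
    """Gaussian-mixture hard labels (1..K) from transcript embeddings."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    if not np.isfinite(embeddings).all():
        raise ValueError("embeddings must be finite")
    if n_niches > len(embeddings):
        raise ValueError(f"n_niches = {n_niches} exceeds {len(embeddings)} transcripts")
    gmm = GaussianMixture(
        n_components=n_niches,
        covariance_type=covariance_type,
        random_state=seed,
        reg_covar=1e-5,
    )
    return gmm.fit_predict(embeddings) + 1


# ---------------------------------------------------------------------------
# hexagonal binning and label transfer

def _hex_axial(xy: np.ndarray, width: float) -> tuple[np.ndarray, np.ndarray]:
    """Pointy-top axial hex coordinates of points, width = flat-to-flat."""
    size = width / np.sqrt(3.0)
    q = (np.sqrt(3.0) / 3.0 * xy[:, 0] - xy[:, 1] / 3.0) / size
    r = (2.0 / 3.0 * xy[:, 1]) / size
    # cube rounding
    x, z = q, r
    y = -x - z
    rx, ry, rz = np.round(x), np.round(y), np.round(z)
    dx, dy, dz = np.abs(rx - x), np.abs(ry - y), np.abs(rz - z)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx[fix_x] = -ry[fix_x] - rz[fix_x]
    rz[fix_z] = -rx[fix_z] - ry[fix_z]
    return rx.astype(np.int64), rz.astype(np.int64)


def _hex_center(q: np.ndarray, r: np.ndarray, width: float) -> np.ndarray:
    size = width / np.sqrt(3.0)
    x = size * np.sqrt(3.0) * (q + r / 2.0)
    y = size * 1.5 * r
    return np.column_stack([x, y])


def hexbin_transfer(
    labels: np.ndarray,
    transcripts: pd.DataFrame,
    cells: pd.DataFrame,
    width_um: float = 5.0,
    min_transcripts: int = 10,
    cutoff_widths: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize transcript niche labels into hex bins and label cells.

    A pointy-top hexagonal lattice of flat-to-flat width ``width_um`` is
    laid over each section; bins with fewer than ``min_transcripts``
    transcripts are excluded; each retained bin takes the majority
    transcript label (ties broken by the lowest label id). Every cell
    centroid is assigned to its closest retained bin of its section and
    inherits the bin's label; cells farther than ``cutoff_widths`` bin
    widths from every retained bin get the explicit unassigned label (-1).

    Returns ``(bins, cell_assign)``: per-bin (section, q, r, center,
    transcript count, label) and per-cell (cell_id, tniche).
    """
    transcripts = transcripts.assign(_label=np.asarray(labels))
    both = set(transcripts.columns) & set(cells.columns)
    key = "section_id" if "section_id" in both else "sample_id"
    t_key = c_key = key if key in both else (
        "section_id" if "section_id" in transcripts.columns else "sample_id"
    )
    bin_frames = []
    assign_frames = []
    for sec, grp in transcripts.groupby(t_key, sort=False):
        xy = grp[["x_um", "y_um"]].to_numpy(float)
        q, r = _hex_axial(xy, width_um)
        df = pd.DataFrame({"q": q, "r": r, "label": grp["_label"].to_numpy()})
        counts = df.groupby(["q", "r"]).size().rename("n_transcripts")
        # majority label, ties -> lowest label id
        maj = (
            df.groupby(["q", "r", "label"])
            .size()
            .rename("n")
            .reset_index()
            .sort_values(["q", "r", "n", "label"], ascending=[True, True, False, True], kind="stable")
            .drop_duplicates(["q", "r"])
            .set_index(["q", "r"])["label"]
        )
        bins = counts.to_frame().join(maj.rename("label")).reset_index()
        bins = bins[bins["n_transcripts"] >= min_transcripts].reset_index(drop=True)
        centers = _hex_center(bins["q"].to_numpy(), bins["r"].to_numpy(), width_um)
        bins["center_x_um"] = centers[:, 0] if len(bins) else np.empty(0)
        bins["center_y_um"] = centers[:, 1] if len(bins) else np.empty(0)
        bins.insert(0, "section", sec)
        bin_frames.append(bins)

        sec_cells = cells[cells[c_key] == sec]
        if len(sec_cells) == 0:
            continue
        if len(bins) == 0:
            logger.warning("section %s has no retained hex bins; all cells unassigned", sec)
            assign_frames.append(
                pd.DataFrame(
                    {"cell_id": sec_cells["cell_id"].to_numpy(), "tniche": UNASSIGNED_NICHE}
                )
            )
            continue
        tree = cKDTree(centers)
        k = min(2, len(bins))
        d, j = tree.query(sec_cells[["centroid_x_um", "centroid_y_um"]].to_numpy(float), k=k)
        if k == 2:
            # exact distance ties go to the bin earlier in (q, r) order
            tied = np.isclose(d[:, 0], d[:, 1], rtol=0.0, atol=1e-9)
            j = np.where(tied, np.minimum(j[:, 0], j[:, 1]), j[:, 0])
            d = d[:, 0]
        else:
            d, j = np.atleast_1d(d).ravel(), np.atleast_1d(j).ravel()
        lab = bins["label"].to_numpy()[j]
        lab = np.where(d <= cutoff_widths * width_um, lab, UNASSIGNED_NICHE)
        assign_frames.append(
            pd.DataFrame({"cell_id": sec_cells["cell_id"].to_numpy(), "tniche": lab})
        )
    bins_out = (
        pd.concat(bin_frames, ignore_index=True)
        if bin_frames
        else pd.DataFrame(columns=["section", "q", "r", "n_transcripts", "label", "center_x_um", "center_y_um"])
    )
    assign_out = (
        pd.concat(assign_frames, ignore_index=True)
        if assign_frames
        else pd.DataFrame(columns=["cell_id", "tniche"])
    )
    return bins_out, assign_out


# ---------------------------------------------------------------------------
# end-to-end transcript-niche pipeline

@dataclass
class TNicheResult:
    transcript_labels: pd.DataFrame  # transcript_id, tissue, tniche
    bins: pd.DataFrame
    cell_assign: pd.DataFrame  # cell_id, tniche
    model: EmbeddingModel | None = None


def tniche_pipeline(
    transcripts: pd.DataFrame,
    cells: pd.DataFrame,
    gene_vocab: list[str],
    n_niches: int = 11,
    embedding: str = "learned",
    emb_cfg: EmbeddingConfig | None = None,
    edge_radius_um: float = 3.0,
    min_component: int = 10,
    hex_width_um: float = 5.0,
    min_bin_transcripts: int = 10,
    seed: int = 0,
) -> TNicheResult:
    """Graph -> embedding -> Gaussian mixture -> hex-bin transfer, end to end.

    ``embedding`` selects the learned encoder (``"learned"``) or the
    deterministic composition fallback (``"composition"``).
    """
    graphs = build_tissue_graphs(transcripts, edge_radius_um, min_component)
    graphs = {k: g for k, g in graphs.items() if g.n_nodes > 0}
    if not graphs:
        raise ValueError("no non-empty transcript graphs after pruning")
    emb_cfg = emb_cfg or EmbeddingConfig(seed=seed)
    model = None
    if embedding == "learned":
        joint = sample_subgraphs(graphs, emb_cfg.n_roots_per_tissue, emb_cfg.hops, seed)
        model = train_graph_embedding(joint, gene_vocab, emb_cfg)
        embs = [apply_graph_embedding(model, graphs[k], seed=seed) for k in sorted(graphs)]
    elif embedding == "composition":
        embs = [composition_embedding(graphs[k], gene_vocab) for k in sorted(graphs)]
    else:
        raise ValueError(f"unknown embedding route {embedding!r}")
    emb_all = np.vstack(embs)
    labels = tniche_cluster(emb_all, n_niches=n_niches, seed=seed)

    node_frames = []
    pos = 0
    for k in sorted(graphs):
        g = graphs[k]
        nf = g.nodes[["transcript_id", "x_um", "y_um"]].copy()
        nf["section_id"] = k
        nf["tniche"] = labels[pos : pos + g.n_nodes]
        node_frames.append(nf)
        pos += g.n_nodes
    labeled = pd.concat(node_frames, ignore_index=True)
    bins, cell_assign = hexbin_transfer(
        labeled["tniche"].to_numpy(),
        labeled,
        cells,
        width_um=hex_width_um,
        min_transcripts=min_bin_transcripts,
    )
    return TNicheResult(
        transcript_labels=labeled[["transcript_id", "section_id", "tniche"]],
        bins=bins,
        cell_assign=cell_assign,
        model=model,
    )
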