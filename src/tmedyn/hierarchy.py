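"""Recursive hierarchical cell typing.

At every node of the tree the same per-group pipeline is re-run,
because exclusion criteria are cell-type specific (a cancer cell with
low RNA content may still hold more RNA than a healthy T cell):

1. low-RNA filtering on log total UMI content within the node,
2. signal-to-noise gene selection (LTQ sd across cells vs the gene's
   mean sampling error),
3. centered unscaled PCA on the retained cells x genes,
4. elbow choice of the number of PCs,
5. graph-community (Leiden, modularity) clustering on a shared-
   nearest-neighbor graph of the PC scores,
6. density-based isolation filtering on the n*d^3 statistic,
7. marker-based cluster annotation,

and each resulting cluster is recursed into until clustering returns a
single community (the node is a phenotypic continuum) or the node is
too small.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .containers import LTQMatrix
from .qc import low_rna_mask, snr_genes

#: per-depth Leiden resolutions used by the study design this package
#: reimplements: coarse compartments first, then progressively finer
#: subtype splits (conventional T cells need 0.07, DC subsets 0.1).
DEFAULT_RESOLUTION_SCHEDULE = {0: 0.02, 1: 0.03, 2: 0.07, 3: 0.1}


@dataclass
class PCAProjection:
    scores: np.ndarray  # cells x n_pcs
    loadings: np.ndarray  # genes x n_pcs
    variance_explained: np.ndarray  # per PC, non-increasing

    def __post_init__(self) -> None:
        ve = self.variance_explained
        if np.any(np.diff(ve) > 1e-8 * max(ve[0], 1.0)):
            raise ValueError("variance_explained must be non-increasing")


def run_pca(ltq, center: bool = True, scale: bool = False, n_pcs_max: int | None = None) -> PCAProjection:
    """Exact SVD-based PCA of cells over genes.

    ``ltq`` is an :class:`LTQMatrix` or a genes x cells array; cells are
    the observations.  Centered per gene, unscaled by default (the
    variance structure of LTQs is meaningful).  Sign convention: the
    largest-magnitude entry of each loading column is positive.
    """
    X = ltq.ltq if isinstance(ltq, LTQMatrix) else np.asarray(ltq, dtype=float)
    X = X.T  # cells x genes
    n, g = X.shape
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    k = min(n, g)
    if n_pcs_max is not None:
        k = min(k, n_pcs_max)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    flip = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    var = S**2 / max(n - 1, 1)
    return PCAProjection(scores=U * S, loadings=Vt.T, variance_explained=var)


def choose_n_pcs(variance_explained: np.ndarray, n_pcs_max: int = 10) -> int:
    """Automated elbow: the number of PCs at which the forward second
    difference of the variance curve, v[i] - 2 v[i+1] + v[i+2], is
    largest (the sharpest bend), bounded to [2, n_pcs_max]."""
    v = np.asarray(variance_explained, dtype=float)
    if len(v) < 3:
        return int(np.clip(len(v), 2, n_pcs_max))
    d2 = v[:-2] - 2 * v[1:-1] + v[2:]
    n = int(np.argmax(d2)) + 1  # 1-based position of the bend
    return int(np.clip(n, 2, min(n_pcs_max, len(v))))


def _snn_graph(scores: np.ndarray, k_neighbors: int) -> sp.csr_matrix:
    """kNN graph (Euclidean) with shared-nearest-neighbor Jaccard
    weights; edges with zero shared neighbors are dropped."""
    n = scores.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    rows = np.repeat(np.arange(n), k + 1)
    adj = sp.csr_matrix(
        (np.ones(n * (k + 1)), (rows, idx.ravel())), shape=(n, n)
    )  # includes self
    shared = adj @ adj.T  # counts shared neighbors (incl. selves)
    mask = adj.maximum(adj.T)
    shared = shared.multiply(mask)
    shared = sp.coo_matrix(shared)
    keep = shared.row < shared.col
    r, c, s = shared.row[keep], shared.col[keep], shared.data[keep]
    jacc = s / (2.0 * (k + 1) - s)
    return r, c, jacc


def cluster_graph(scores: np.ndarray, k_neighbors: int = 20, resolution: float = 0.05, seed: int = 0) -> np.ndarray:
    """Leiden modularity clustering of the SNN graph of PC scores.

    Resolution follows the usual modularity semantics: smaller values
    merge communities, so well-separated compartments are found at 0.02
    and finer subtypes need larger values.  Deterministic given seed.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n <= 1:
        return np.zeros(n, dtype=int)
    r, c, w = _snn_graph(scores, k_neighbors)
    g = ig.Graph(n=n, edges=list(zip(r.tolist(), c.tolist())))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=w.tolist(),
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=3,
    )
    return np.asarray(part.membership, dtype=int)


def isolation_statistic(scores: np.ndarray, k_neighbors: int = 20) -> np.ndarray:
    """Per-cell n * d^3, where d is the mean Euclidean distance to the
    cell's k nearest neighbors and n the group size.  At constant
    density d^3 scales like 1/n, so the statistic is density-scale-free
    and one cutoff can serve groups of different sizes."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n = scores.shape[0]
    if n < 2:
        return np.zeros(n)
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    dist, _ = nn.kneighbors(scores)
    d = dist[:, 1:].mean(axis=1)
    return n * d**3


def isolation_filter(
    scores: np.ndarray, k_neighbors: int = 20, cutoff_nd3: float | None = None, percentile: float = 95.0
) -> np.ndarray:
    """Keep-mask excluding cells in low-density regions: n*d^3 above
    ``cutoff_nd3`` (default: the group's ``percentile``-th percentile,
    standing in for the visual-inspection cutoff of the original
    procedure)."""
    stat = isolation_statistic(scores, k_neighbors)
    if len(stat) == 0:
        return np.zeros(0, dtype=bool)
    cutoff = np.percentile(stat, percentile) if cutoff_nd3 is None else cutoff_nd3
    return stat <= cutoff


def annotate_clusters(
    labels: np.ndarray,
    ltq: LTQMatrix,
    markers: pd.DataFrame,
    margin: float = 0.5,
) -> dict:
    """Annotate each cluster with the best-scoring cell type.

    Per gene, each cluster's mean LTQ is compared with the mean over
    the other clusters' cells, scaled by the pooled within-cluster sd
    (a marker effect size robust to having only two clusters); a type's
    score in a cluster is the mean effect size over its markers.  The
    best type wins only if it beats the runner-up by ``margin``,
    otherwise the cluster is "unresolved" — ties are never guessed.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    gene_index = pd.Index(ltq.gene_ids)
    unresolved_markers = markers.loc[~markers["gene"].isin(gene_index), "gene"]
    if len(unresolved_markers):
        warnings.warn(f"{len(unresolved_markers)} marker ids not in gene universe", stacklevel=2)
    if len(uniq) < 2:
        return {int(c): "unresolved" for c in uniq}
    means = np.stack([ltq.ltq[:, labels == c].mean(axis=1) for c in uniq])  # clusters x genes
    within_var = np.zeros(ltq.n_genes)
    for ci, c in enumerate(uniq):
        sub = ltq.ltq[:, labels == c]
        within_var += ((sub - means[ci][:, None]) ** 2).sum(axis=1)
    within_sd = np.sqrt(within_var / max(len(labels) - len(uniq), 1) + 1e-4)
    n_c = np.array([(labels == c).sum() for c in uniq], dtype=float)
    rest_mean = (means * n_c[:, None]).sum(axis=0)[None, :] - means * n_c[:, None]
    rest_mean = rest_mean / (n_c.sum() - n_c)[:, None]
    z = (means - rest_mean) / within_sd[None, :]

    out = {}
    types = markers["cell_type"].unique()
    for ci, c in enumerate(uniq):
        scores = {}
        for t in types:
            gidx = gene_index.get_indexer(markers.loc[markers["cell_type"] == t, "gene"])
            gidx = gidx[gidx >= 0]
            if len(gidx):
                scores[t] = float(z[ci, gidx].mean())
        if not scores:
            out[int(c)] = "unresolved"
            continue
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        if len(ranked) == 1 or ranked[0][1] - ranked[1][1] > margin:
            out[int(c)] = ranked[0][0]
        else:
            out[int(c)] = "unresolved"
    return out


@dataclass
class TypingNode:
    """One level of the recursive typing tree."""

    cell_indices: np.ndarray  # indices into the root LTQ cell axis
    depth: int
    annotation: str = "unresolved"
    gene_subset: np.ndarray | None = None
    pca: PCAProjection | None = None
    n_pcs: int | None = None
    labels: np.ndarray | None = None  # over retained cells
    resolution: float | None = None
    children: list = field(default_factory=list)
    excluded: dict = field(default_factory=dict)  # filter name -> root indices
    child_annotations: dict = field(default_factory=dict)
    stop_reason: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for ch in self.children:
                yield from ch.leaves()

    def final_labels(self, n_cells_total: int) -> np.ndarray:
        """Per-root-cell leaf annotation; cells removed by any filter on
        the way down are labeled 'excluded'."""
        out = np.full(n_cells_total, "excluded", dtype=object)
        for leaf in self.leaves():
            out[leaf.cell_indices] = leaf.annotation
        return out

    def to_dict(self) -> dict:
        return {
            "annotation": self.annotation,
            "depth": self.depth,
            "n_cells": int(len(self.cell_indices)),
            "resolution": self.resolution,
            "n_pcs": self.n_pcs,
            "stop_reason": self.stop_reason,
            "excluded": {k: len(v) for k, v in self.excluded.items()},
            "children": [c.to_dict() for c in self.children],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _resolve_resolution(schedule, depth: int) -> float:
    if callable(schedule):
        return float(schedule(depth))
    if depth in schedule:
        return float(schedule[depth])
    return float(schedule[max(schedule)])


def recursive_typing(
    ltq: LTQMatrix,
    markers: pd.DataFrame,
    resolution_schedule=None,
    cell_totals: np.ndarray | None = None,
    snr_threshold: float = 0.25,
    k_neighbors: int = 20,
    min_cells: int = 40,
    max_depth: int = 4,
    mad_k: float = 3.0,
    isolation_percentile: float = 95.0,
    n_pcs_max: int = 10,
    annotation_margin: float = 0.5,
    seed: int = 0,
) -> TypingNode:
    """Build the full typing tree by recursive PCA + Leiden clustering.

    Recursion stops when clustering returns one community (the node is
    a continuum at its scheduled resolution — flagged in
    ``stop_reason``), when a node is smaller than ``min_cells`` or than
    ``k_neighbors + 2``, or at ``max_depth``.
    """
    if resolution_schedule is None:
        resolution_schedule = DEFAULT_RESOLUTION_SCHEDULE
    counter = [0]

    def build(cells: np.ndarray, depth: int, annotation: str, inherited: str) -> TypingNode:
        # a node called "unresolved" among its siblings keeps the nearest
        # resolved ancestor call: deeper splits of a pure population are
        # phenotypic structure, not new cell types
        if annotation == "unresolved" and inherited not in ("root",):
            annotation = inherited
        node = TypingNode(cell_indices=cells, depth=depth, annotation=annotation)
        if len(cells) < max(min_cells, k_neighbors + 2):
            node.stop_reason = "too_few_cells"
            return node
        if depth > max_depth:
            node.stop_reason = "max_depth"
            return node

        retained = cells
        if cell_totals is not None:
            keep = low_rna_mask(np.asarray(cell_totals)[cells], mad_k=mad_k)
            node.excluded["low_rna"] = cells[~keep]
            retained = cells[keep]
        sub = ltq.subset(cell_mask=retained)
        genes = snr_genes(sub, threshold=snr_threshold)
        node.gene_subset = genes
        if len(genes) < 3 or len(retained) < max(min_cells, k_neighbors + 2):
            node.stop_reason = "too_few_genes" if len(genes) < 3 else "too_few_cells_after_filter"
            return node

        pca = run_pca(sub.ltq[genes, :], n_pcs_max=max(n_pcs_max, 3))
        node.pca = pca
        node.n_pcs = choose_n_pcs(pca.variance_explained, n_pcs_max=n_pcs_max)
        scores = pca.scores[:, : node.n_pcs]

        node.resolution = _resolve_resolution(resolution_schedule, depth)
        counter[0] += 1
        labels = cluster_graph(scores, k_neighbors=k_neighbors, resolution=node.resolution,
                               seed=seed + counter[0])
        keep = np.ones(len(retained), dtype=bool)
        for c in np.unique(labels):
            m = labels == c
            keep[m] = isolation_filter(scores[m], k_neighbors=k_neighbors,
                                       percentile=isolation_percentile)
        node.excluded["isolation"] = retained[~keep]
        retained, labels, scores = retained[keep], labels[keep], scores[keep]
        node.labels = labels

        uniq, counts = np.unique(labels, return_counts=True)
        uniq = uniq[counts >= 2]
        if len(uniq) <= 1:
            node.stop_reason = "continuum"  # one community at this resolution
            return node

        ann = annotate_clusters(labels, ltq.subset(cell_mask=retained), markers,
                                margin=annotation_margin)
        node.child_annotations = ann
        resolved = node.annotation not in ("root", "unresolved")
        for c in uniq:
            child_cells = retained[labels == c]
            # once a node is confidently typed, deeper splits are
            # phenotypes of that type, never re-assignments
            child_ann = node.annotation if resolved else ann.get(int(c), "unresolved")
            child = build(child_cells, depth + 1, child_ann, node.annotation)
            node.children.append(child)
        return node

    root = build(np.arange(ltq.n_cells), 0, "root", "root")
    return root
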