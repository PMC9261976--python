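"""Cluster-specific marker-gene detection for a cell x gene count matrix.

The workflow mirrors the conventional droplet single-cell recipe: library-size
log-normalization, PCA, a shared-nearest-neighbor (SNN) graph, label-propagation
community detection, then a two-sided Wilcoxon rank-sum test per gene and
cluster with ``min.pct`` / log-fold-change / adjusted-p filters.  The three
fit-shaped stages are exposed as scikit-learn estimators
(:class:`KNNGraphClusterer`, :class:`WilcoxonMarkerDetector`); the module-level
functions wrap them for the genes x cells container used by the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "CellCountMatrix",
    "MarkerParams",
    "KNNGraphClusterer",
    "WilcoxonMarkerDetector",
    "normalize_counts",
    "build_knn_graph",
    "cluster_cells",
    "find_markers",
    "benjamini_hochberg",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class CellCountMatrix:
    """Nonnegative integer gene x cell count matrix with optional cluster labels."""

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_barcodes: list[str]
    cluster_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_barcodes) != n_cells:
            raise ValueError("gene/cell sidecar lengths do not match matrix shape")
        if len(set(self.cell_barcodes)) != n_cells:
            raise ValueError("cell barcodes must be unique")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene IDs must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        if self.cluster_labels is not None:
            self.cluster_labels = np.asarray(self.cluster_labels)
            if self.cluster_labels.shape[0] != n_cells:
                raise ValueError("cluster_labels length must equal n_cells")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    # -- 10x-style Matrix Market triplet directory ----------------------
    def write_mtx_dir(self, outdir: str | Path) -> Path:
        """Write matrix.mtx + features.tsv + barcodes.tsv (+ clusters.tsv)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(outdir / "matrix.mtx"), self.counts.astype(np.int64))
        (outdir / "features.tsv").write_text("".join(g + "\n" for g in self.gene_ids))
        (outdir / "barcodes.tsv").write_text(
            "".join(b + "\n" for b in self.cell_barcodes)
        )
        if self.cluster_labels is not None:
            pd.DataFrame(
                {"barcode": self.cell_barcodes, "cluster": self.cluster_labels}
            ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        return outdir

    @classmethod
    def read_mtx_dir(cls, indir: str | Path) -> "CellCountMatrix":
        indir = Path(indir)
        counts = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")))
        genes = (indir / "features.tsv").read_text().splitlines()
        barcodes = (indir / "barcodes.tsv").read_text().splitlines()
        labels = None
        if (indir / "clusters.tsv").exists():
            cl = pd.read_csv(indir / "clusters.tsv", sep="\t")
            labels = cl.set_index("barcode").loc[barcodes, "cluster"].to_numpy()
        return cls(counts, genes, barcodes, labels)


@dataclass
class MarkerParams:
    """Filters and normalization constants for marker detection.

    ``min_pct`` and ``logfc_threshold`` default to the values used for the
    shell-field gene set (min.pct = 0.1, log fold difference > 0.6).
    """

    min_pct: float = 0.1
    logfc_threshold: float = 0.6
    alpha: float = 0.05
    pseudocount: float = 1.0
    scale_factor: float = 10_000.0
    log_base: float = 2.0
    min_pct_mode: str = "either"  # "either" (conventional) or "both"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_pct <= 1.0:
            raise ValueError("min_pct must lie in [0, 1]")
        if self.logfc_threshold < 0:
            raise ValueError("logfc_threshold must be >= 0")
        if self.pseudocount <= 0 or self.scale_factor <= 0:
            raise ValueError("pseudocount and scale_factor must be positive")
        if self.min_pct_mode not in ("either", "both"):
            raise ValueError("min_pct_mode must be 'either' or 'both'")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------
def normalize_counts(
    m: CellCountMatrix, scale_factor: float = 10_000.0
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Library-size normalize and log-transform: ln(1 + count/total * scale).

    Cells with zero total counts are dropped (logged), not raised on.

    Returns
    -------
    norm:
        Sparse genes x kept-cells matrix of ln(1 + CP10K) values; the
        sparsity pattern of the kept columns is preserved.
    kept:
        Indices of the retained cells in the original column order.
    """
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    kept = np.flatnonzero(totals > 0)
    if kept.size < m.n_cells:
        logger.warning("dropping %d zero-count cell(s)", m.n_cells - kept.size)
    sub = m.counts[:, kept].tocsc().astype(float)
    inv = scale_factor / totals[kept]
    sub = (sub @ sp.diags(inv)).tocsr()
    sub.data = np.log1p(sub.data)
    return sub.tocsr(), kept


# ---------------------------------------------------------------------------
# graph + clustering
# ---------------------------------------------------------------------------
class KNNGraphClusterer(ClusterMixin, BaseEstimator):
    """PCA -> Euclidean kNN -> SNN (Jaccard) graph -> label propagation.

    Parameters
    ----------
    n_pcs : int
        Number of principal components (capped at ``min(n_cells, n_genes) - 1``).
    n_neighbors : int
        k for the kNN graph; must be < n_cells.
    random_state : int or None
        Seed for the label-propagation sweep order.

    Attributes
    ----------
    graph_ : networkx.Graph
        SNN graph over cells; edge weights are Jaccard overlaps of
        (self-inclusive) neighbor sets; zero-weight edges are pruned.
    labels_ : ndarray of int
        Cluster labels, relabeled by decreasing cluster size.
    """

    def __init__(self, n_pcs: int = 20, n_neighbors: int = 20, random_state=None):
        self.n_pcs = n_pcs
        self.n_neighbors = n_neighbors
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)  # cells x features (normalized expression)
        n_cells = X.shape[0]
        if self.n_neighbors >= n_cells:
            raise ValueError(
                f"n_neighbors={self.n_neighbors} must be < n_cells={n_cells}"
            )
        self.graph_ = _snn_graph(X, self.n_pcs, self.n_neighbors)
        self.labels_ = _label_propagation(self.graph_, self.random_state)
        return self


def _snn_graph(X: np.ndarray, n_pcs: int, k: int) -> nx.Graph:
    n_cells, n_feat = X.shape
    n_comp = min(n_pcs, n_cells - 1, n_feat)
    if n_comp >= 1:
        # sklearn's deterministic svd_flip sign convention applies
        X = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = [set(row) | {i} for i, row in enumerate(idx)]  # self-inclusive
    g = nx.Graph()
    g.add_nodes_from(range(n_cells))
    for i, row in enumerate(idx):
        for j in row:
            if i == j or g.has_edge(i, j):
                continue
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = inter / union
            if w > 0:
                g.add_edge(i, int(j), weight=w)
    g.graph["connected"] = nx.is_connected(g) if n_cells else False
    return g


def _label_propagation(g: nx.Graph, seed) -> np.ndarray:
    """Weighted label propagation with seeded, order-randomized sweeps.

    Each node adopts the label with the largest total incident edge weight
    (ties broken toward the smallest label); sweeps repeat until a full pass
    changes nothing.  Labels are then renumbered by decreasing cluster size.
    """
    rng = np.random.default_rng(seed)
    nodes = np.array(sorted(g.nodes()))
    labels = {n: i for i, n in enumerate(nodes)}
    for _ in range(200):
        order = nodes[rng.permutation(len(nodes))]
        changed = False
        for n in order:
            votes: dict[int, float] = {}
            for nb, data in g[n].items():
                lab = labels[nb]
                votes[lab] = votes.get(lab, 0.0) + data.get("weight", 1.0)
            if not votes:
                continue
            best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            if best != labels[n]:
                labels[n] = best
                changed = True
        if not changed:
            break
    # relabel by decreasing size, ties by smallest member node
    out = np.array([labels[n] for n in nodes])
    groups = pd.Series(range(len(nodes))).groupby(out).groups
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    remap = {old: new for new, (old, _) in enumerate(ordered)}
    return np.array([remap[v] for v in out])


def build_knn_graph(
    expr: sp.spmatrix | np.ndarray, n_pcs: int = 20, k: int = 20
) -> nx.Graph:
    """SNN graph over cells from a genes x cells normalized matrix."""
    X = np.asarray(expr.todense() if sp.issparse(expr) else expr, dtype=float).T
    if k >= X.shape[0]:
        raise ValueError(f"k={k} must be < n_cells={X.shape[0]}")
    return _snn_graph(X, n_pcs, k)


def cluster_cells(graph: nx.Graph, seed: int | None = None) -> np.ndarray:
    """Cluster a cell graph by seeded label propagation."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    return _label_propagation(graph, seed)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum marker test
# ---------------------------------------------------------------------------
def _rowwise_tie_term(X: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tied groups, per row."""
    out = np.zeros(X.shape[0])
    for i, row in enumerate(X):
        _, counts = np.unique(row, return_counts=True)
        t = counts[counts > 1].astype(float)
        out[i] = np.sum(t**3 - t)
    return out


def wilcoxon_rank_sum(
    X: np.ndarray, in_group: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Wilcoxon rank-sum test per row of ``X``.

    Normal approximation with tie correction and 0.5 continuity correction;
    rows are genes, columns observations, ``in_group`` a boolean column mask.

    Returns (z, p_two_sided) arrays, one entry per row.
    """
    n = X.shape[1]
    n1 = int(in_group.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    ranks = rankdata(X, axis=1)
    r1 = ranks[:, in_group].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie = _rowwise_tie_term(X)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    sd = np.sqrt(var)
    diff = u - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (diff - np.sign(diff) * 0.5) / sd, 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    return z, np.minimum(p, 1.0)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class WilcoxonMarkerDetector(BaseEstimator):
    """Per-cluster one-vs-rest Wilcoxon marker test with standard filters.

    Fit on a cells x genes count matrix ``X`` and per-cell labels ``y``;
    normalization (ln(1 + CP-scale)) happens internally so raw counts go in.

    Attributes
    ----------
    results_ : DataFrame
        One row per (gene, cluster) tested: avg_log2FC (or natural-log fold
        change when ``log_base`` is e), pct_in, pct_out, p_value, p_adjusted.
    markers_ : DataFrame
        The subset of ``results_`` passing all three filters.
    """

    def __init__(
        self,
        min_pct: float = 0.1,
        logfc_threshold: float = 0.6,
        alpha: float = 0.05,
        pseudocount: float = 1.0,
        scale_factor: float = 10_000.0,
        log_base: float = 2.0,
        min_pct_mode: str = "either",
        target_cluster=None,
    ):
        self.min_pct = min_pct
        self.logfc_threshold = logfc_threshold
        self.alpha = alpha
        self.pseudocount = pseudocount
        self.scale_factor = scale_factor
        self.log_base = log_base
        self.min_pct_mode = min_pct_mode
        self.target_cluster = target_cluster

    def fit(self, X, y, gene_ids: list[str] | None = None):
        params = MarkerParams(
            self.min_pct,
            self.logfc_threshold,
            self.alpha,
            self.pseudocount,
            self.scale_factor,
            self.log_base,
            self.min_pct_mode,
        )
        counts = sp.csr_matrix(X).T  # genes x cells internally
        y = np.asarray(y)
        if counts.shape[1] != y.shape[0]:
            raise ValueError("label length must equal number of cells")
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(counts.shape[0])]
        m = CellCountMatrix(
            counts, list(gene_ids), [f"c{i}" for i in range(counts.shape[1])], y
        )
        self.results_, self.markers_ = _find_markers_impl(
            m, params, self.target_cluster
        )
        return self

    def fit_predict_markers(self, X, y, gene_ids=None) -> pd.DataFrame:
        return self.fit(X, y, gene_ids).markers_


def _find_markers_impl(
    m: CellCountMatrix, params: MarkerParams, target_cluster
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if m.cluster_labels is None:
        raise ValueError("cluster_labels are required for marker detection")
    norm_mat, kept = normalize_counts(m, params.scale_factor)
    labels = np.asarray(m.cluster_labels)[kept]
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("marker detection needs at least 2 clusters")
    clusters = uniq if target_cluster is None else [target_cluster]

    X = np.asarray(norm_mat.todense())
    counts_pos = np.asarray((m.counts[:, kept] > 0).todense())
    expm1 = np.expm1(X)
    log = np.log2 if params.log_base == 2 else np.log
    rows = []
    for cl in clusters:
        mask = labels == cl
        n_in = int(mask.sum())
        if n_in < 3:
            logger.warning("cluster %r has %d < 3 cells; skipped", cl, n_in)
            continue
        if n_in == len(labels):
            logger.warning("cluster %r contains every cell; skipped", cl)
            continue
        z, p = wilcoxon_rank_sum(X, mask)
        mean_in = expm1[:, mask].mean(axis=1)
        mean_out = expm1[:, ~mask].mean(axis=1)
        lfc = log((mean_in + params.pseudocount) / (mean_out + params.pseudocount))
        pct_in = counts_pos[:, mask].mean(axis=1)
        pct_out = counts_pos[:, ~mask].mean(axis=1)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": m.gene_ids,
                    "cluster": cl,
                    "avg_log2FC": lfc,
                    "pct_in": pct_in,
                    "pct_out": pct_out,
                    "p_value": p,
                }
            )
        )
    if not rows:
        raise ValueError("no cluster was large enough to test")
    results = pd.concat(rows, ignore_index=True)
    results["p_adjusted"] = benjamini_hochberg(results["p_value"].to_numpy())

    if params.min_pct_mode == "either":
        pct_ok = np.maximum(results["pct_in"], results["pct_out"]) >= params.min_pct
    else:
        pct_ok = np.minimum(results["pct_in"], results["pct_out"]) >= params.min_pct
    keep = (
        pct_ok
        & (results["avg_log2FC"] > params.logfc_threshold)
        & (results["p_adjusted"] < params.alpha)
    )
    markers = results[keep].reset_index(drop=True)
    return results, markers


def find_markers(
    m: CellCountMatrix,
    params: MarkerParams | None = None,
    target_cluster=None,
    return_all: bool = False,
):
    """Marker records for one cluster (or all), filtered by the three criteria.

    Records keep genes detected in >= ``min_pct`` of cells (in at least one of
    the two groups by default), with fold change above ``logfc_threshold`` and
    BH-adjusted p below ``alpha``.
    """
    params = params or MarkerParams()
    results, markers = _find_markers_impl(m, params, target_cluster)
    return (markers, results) if return_all else markers


def write_markers_tsv(markers: pd.DataFrame, path: str | Path) -> None:
    markers.to_csv(path, sep="\t", index=False)


def read_markers_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
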