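"""Single-cell count-matrix processing.

QC filtering with the study's exclusive thresholds, counts-per-10k log
normalization, dispersion-based highly-variable-gene selection, scaling with
covariate regression, PCA, shared-nearest-neighbor Louvain clustering at
resolution 0.4, and one-vs-rest Wilcoxon marker detection with 0.25 logFC /
25% detection thresholds.

Matrices are genes × cells throughout (the orientation of a digital gene
expression matrix); embeddings are cells × components.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "ProcessedMatrix",
    "ClusterAssignment",
    "qc_filter",
    "lognormalize",
    "select_hvg",
    "scale_regress",
    "pca",
    "cluster_cells",
    "find_markers",
]


@dataclass
class CountMatrix:
    """Genes × cells integer counts with identifiers and per-cell metadata.

    ``cell_meta`` is indexed by cell id and carries at least ``replicate``,
    ``detected_genes``, ``total_counts`` and ``mito_fraction``; the QC
    columns are always recomputable from the counts themselves.
    """

    counts: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError("identifier lengths do not match counts shape")
        if len(self.cell_meta) != n_cells:
            raise ValueError("cell_meta row count must equal cell count")
        dense = self.dense()
        if (dense < 0).any() or not np.allclose(dense, np.round(dense)):
            raise ValueError("counts must be nonnegative integers")

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray | sp.spmatrix,
        gene_ids: list[str],
        cell_ids: list[str],
        cell_meta: pd.DataFrame | None = None,
        mito_prefix: str = "MT-",
        replicate: str = "R1",
    ) -> "CountMatrix":
        """Build a matrix, computing the derived QC columns."""
        if cell_meta is None:
            cell_meta = pd.DataFrame(index=pd.Index(cell_ids))
        cell_meta = cell_meta.copy()
        if "replicate" not in cell_meta:
            cell_meta["replicate"] = replicate
        m = cls(counts=counts, gene_ids=list(gene_ids), cell_ids=list(cell_ids),
                cell_meta=cell_meta)
        m.recompute_qc(mito_prefix=mito_prefix)
        return m

    def dense(self) -> np.ndarray:
        return self.counts.toarray() if sp.issparse(self.counts) else np.asarray(self.counts)

    def recompute_qc(self, mito_prefix: str = "MT-") -> None:
        dense = self.dense()
        total = dense.sum(axis=0)
        mito_mask = np.array([g.startswith(mito_prefix) for g in self.gene_ids])
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, dense[mito_mask].sum(axis=0) / np.maximum(total, 1), 0.0)
        self.cell_meta["detected_genes"] = (dense > 0).sum(axis=0)
        self.cell_meta["total_counts"] = total
        self.cell_meta["mito_fraction"] = mito_frac

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        counts = self.counts[:, keep]
        return CountMatrix(
            counts=counts,
            gene_ids=self.gene_ids,
            cell_ids=[c for c, k in zip(self.cell_ids, keep) if k],
            cell_meta=self.cell_meta.loc[keep].copy(),
        )


@dataclass
class QCThresholds:
    """Exclusive QC bounds: a cell survives iff
    ``min < detected_genes < max`` and ``mito_fraction < max_mito``.

    The boundary is excluded on every side — a cell with exactly
    ``min_genes_exclusive`` detected genes, or exactly the mitochondrial
    cutoff, is removed.
    """

    min_genes_exclusive: int = 200
    max_genes_exclusive: int = 7500
    max_mito_fraction_exclusive: float = 0.03

    def __post_init__(self) -> None:
        if self.min_genes_exclusive >= self.max_genes_exclusive:
            raise ValueError("min gene bound must be below max")
        if not (0 < self.max_mito_fraction_exclusive <= 1):
            raise ValueError("mito fraction bound must lie in (0, 1]")

    def passes(self, detected_genes: int, mito_fraction: float) -> bool:
        return (
            self.min_genes_exclusive < detected_genes < self.max_genes_exclusive
            and mito_fraction < self.max_mito_fraction_exclusive
        )


# the study's per-replicate gastruloid thresholds
GASTRULOID_QC = {
    "R1": QCThresholds(200, 7500, 0.03),
    "R2": QCThresholds(200, 6000, 0.025),
}


@dataclass
class ProcessedMatrix:
    """Normalized expression with optional scaled/HVG/PCA derivatives.

    ``lognorm`` is genes × cells (log1p of counts-per-``scale_factor``);
    ``scaled`` is HVG × cells (covariate residuals, per-gene standardized);
    ``pca`` is cells × components.
    """

    lognorm: pd.DataFrame
    cell_meta: pd.DataFrame
    scaled: pd.DataFrame | None = None
    hvg: list[str] | None = None
    pca: np.ndarray | None = None

    @property
    def cell_ids(self) -> list[str]:
        return list(self.lognorm.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.lognorm.index)


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels (a pandas Series indexed by cell id)."""

    labels: pd.Series

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


def qc_filter(
    m: CountMatrix,
    thresholds: QCThresholds | dict[str, QCThresholds],
    mito_prefix: str = "MT-",
) -> tuple[CountMatrix, dict]:
    """Remove low-quality cells; returns the filtered matrix and a report.

    ``thresholds`` is either one :class:`QCThresholds` for all cells or a
    mapping replicate → thresholds (the study applied different bounds per
    replicate). The report records per-replicate input/retained/removed
    counts.
    """
    m.recompute_qc(mito_prefix=mito_prefix)
    meta = m.cell_meta
    keep = np.zeros(len(meta), dtype=bool)
    for i, (_, row) in enumerate(meta.iterrows()):
        t = (
            thresholds[row["replicate"]]
            if isinstance(thresholds, dict)
            else thresholds
        )
        keep[i] = t.passes(int(row["detected_genes"]), float(row["mito_fraction"]))
    if not keep.any():
        raise ValueError("QC filter removed every cell")
    report: dict = {"per_replicate": {}}
    for rep, grp in meta.groupby("replicate", observed=True):
        idx = meta["replicate"] == rep
        report["per_replicate"][str(rep)] = {
            "input": int(idx.sum()),
            "retained": int((keep & idx.to_numpy()).sum()),
            "removed": int((~keep & idx.to_numpy()).sum()),
        }
    report["total_retained"] = int(keep.sum())
    report["total_removed"] = int((~keep).sum())
    return m.subset_cells(keep), report


def lognormalize(m: CountMatrix, scale_factor: float = 10_000.0) -> ProcessedMatrix:
    """Counts-per-``scale_factor`` then ``log(1 + x)``, per cell."""
    dense = m.dense().astype(float)
    totals = dense.sum(axis=0)
    if (totals == 0).any():
        bad = [c for c, t in zip(m.cell_ids, totals) if t == 0]
        raise ValueError(f"cells with zero total counts (should fail QC): {bad[:5]}")
    lognorm = np.log1p(dense / totals * scale_factor)
    df = pd.DataFrame(lognorm, index=pd.Index(m.gene_ids), columns=pd.Index(m.cell_ids))
    return ProcessedMatrix(lognorm=df, cell_meta=m.cell_meta.copy())


def select_hvg(p: ProcessedMatrix, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Top-``n`` highly variable genes by binned normalized dispersion.

    Mean and dispersion (variance/mean) are computed on the de-logged
    expression; genes are binned by mean into ``n_bins`` bins and each
    gene's dispersion is z-scored within its bin, so highly expressed genes
    do not dominate. Genes with zero dispersion (constant expression) rank
    last. Sets ``p.hvg`` and returns the ordered list.
    """
    if n > len(p.gene_ids):
        raise ValueError("n exceeds gene count")
    expr = np.expm1(p.lognorm.to_numpy())
    mean = expr.mean(axis=1)
    var = expr.var(axis=1, ddof=1) if expr.shape[1] > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
        # log scale for both axes, the convention dispersion plots use
        log_disp = np.where(disp > 0, np.log(np.maximum(disp, 1e-300)), -np.inf)
    df = pd.DataFrame(
        {"mean": np.log1p(mean), "disp": log_disp}, index=p.lognorm.index
    )
    # equal-occupancy bins keep every bin populated enough to z-score
    df["bin"] = pd.qcut(
        df["mean"].rank(method="first"), q=min(n_bins, len(df)), labels=False
    )
    norm = np.zeros(len(df))
    for _, idx in df.groupby("bin", observed=True).groups.items():
        d = df.loc[idx, "disp"]
        fin = d[np.isfinite(d)]
        sd = fin.std(ddof=1)
        loc = df.index.get_indexer(idx)
        if len(fin) <= 1 or not np.isfinite(sd) or sd == 0:
            norm[loc] = np.where(np.isfinite(d), 0.0, -np.inf)
        else:
            norm[loc] = np.where(np.isfinite(d), (d - fin.mean()) / sd, -np.inf)
    # a constant gene (zero dispersion) is never selected over a varying one
    norm = np.where(np.isfinite(df["disp"].to_numpy()), norm, -np.inf)
    order = np.argsort(-norm, kind="stable")
    ranked = [p.gene_ids[i] for i in order]
    varying = int(np.isfinite(norm).sum())
    hvg = ranked[: min(n, varying)] if varying > 0 else ranked[:n]
    p.hvg = hvg
    return hvg


def scale_regress(
    p: ProcessedMatrix,
    covariates: list[str] | None = None,
    genes: list[str] | None = None,
    clip: float = 10.0,
) -> pd.DataFrame:
    """Regress out per-cell covariates, then standardize each gene.

    ``covariates`` names columns of ``p.cell_meta`` (e.g. ``mito_fraction``,
    ``total_counts``, cell-cycle scores added via
    :func:`gastrukit.trajectory.module_score`). Each gene's expression is
    replaced by its OLS residual against the covariates, standardized to
    mean 0 / sd 1, and clipped to ``±clip``. With no covariates this is a
    pure z-score. Operates on ``p.hvg`` (or all genes) and sets
    ``p.scaled``.
    """
    if genes is None:
        genes = p.hvg if p.hvg is not None else p.gene_ids
    Y = p.lognorm.loc[genes].to_numpy().T  # cells × genes
    n_cells = Y.shape[0]
    cols = [np.ones(n_cells)]
    used = []
    for cov in covariates or []:
        v = p.cell_meta[cov].to_numpy(dtype=float)
        if np.std(v) == 0:
            warnings.warn(f"covariate {cov!r} is constant; dropped", stacklevel=2)
            continue
        cols.append(v)
        used.append(cov)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = resid.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (resid - resid.mean(axis=0)) / sd
    z = np.clip(z, -clip, clip)
    scaled = pd.DataFrame(z.T, index=pd.Index(genes), columns=p.lognorm.columns)
    p.scaled = scaled
    return scaled


def pca(p: ProcessedMatrix, n_pc: int = 15) -> np.ndarray:
    """PCA of the scaled matrix; returns and stores cells × ``n_pc`` scores.

    Deterministic (full SVD with sign convention); components are ordered by
    explained variance.
    """
    if p.scaled is None:
        raise ValueError("run scale_regress before pca")
    X = p.scaled.to_numpy().T  # cells × genes
    if n_pc > min(X.shape):
        raise ValueError(f"n_pc={n_pc} exceeds min(cells, genes)={min(X.shape)}")
    model = PCA(n_components=n_pc, svd_solver="full")
    p.pca = model.fit_transform(X)
    return p.pca


def snn_graph(
    embedding: np.ndarray, k_neighbors: int = 20, prune: float = 1 / 15
) -> sp.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbor graph.

    Each cell's neighborhood is itself plus its ``k-1`` nearest neighbors;
    the edge weight between two cells is the Jaccard overlap of their
    neighborhoods, zeroed below ``prune``.
    """
    n = embedding.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be below the number of cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rows = np.repeat(np.arange(n), k_neighbors)
    A = sp.csr_matrix(
        (np.ones(n * k_neighbors), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (A @ A.T).tocoo()  # |N_i ∩ N_j|
    jac = shared.data / (2 * k_neighbors - shared.data)
    keep = (jac >= prune) & (shared.row != shared.col)
    W = sp.csr_matrix((jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))
    return W


def cluster_cells(
    embedding: np.ndarray,
    cell_ids: list[str] | None = None,
    k_neighbors: int = 20,
    resolution: float = 0.4,
    seed: int = 0,
    prune: float = 1 / 15,
) -> ClusterAssignment:
    """SNN graph + Louvain modularity optimization at ``resolution``.

    Clusters are renamed ``"0", "1", ...`` in decreasing size order.
    Deterministic for a fixed seed.
    """
    W = snn_graph(embedding, k_neighbors=k_neighbors, prune=prune)
    n = W.shape[0]
    coo = sp.triu(W, k=1).tocoo()
    g = igraph.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
    )
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights=coo.data.tolist(), resolution=resolution)
    labels = np.asarray(part.membership)
    # stable names: largest community first
    order = pd.Series(labels).value_counts().index.to_list()
    remap = {old: str(new) for new, old in enumerate(order)}
    named = pd.Series(
        [remap[l] for l in labels],
        index=pd.Index(cell_ids if cell_ids is not None else range(n)),
        name="cluster",
    )
    return ClusterAssignment(labels=named)


def find_markers(
    p: ProcessedMatrix,
    clusters: ClusterAssignment,
    min_logfc: float = 0.25,
    min_detection: float = 0.25,
    positive_only: bool = True,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker detection per cluster.

    For each cluster, every gene is tested against all other cells on the
    log-normalized values. Reported per row: natural-log fold change of
    de-logged means, ``ln((mean_in(expm1) + 1) / (mean_out(expm1) + 1))``,
    in/out detection fractions, two-sided p-value and Bonferroni-adjusted
    p-value. Rows failing ``min_logfc`` or ``min_detection`` (in-cluster)
    are excluded; singleton clusters are skipped with a warning.
    """
    labels = clusters.labels.loc[p.lognorm.columns]
    X = p.lognorm.to_numpy()
    expm1 = np.expm1(X)
    n_genes = X.shape[0]
    out_frames = []
    for cl in sorted(labels.unique()):
        in_mask = (labels == cl).to_numpy()
        if in_mask.sum() < 2:
            warnings.warn(f"cluster {cl!r} has <2 cells; skipped", stacklevel=2)
            continue
        if (~in_mask).sum() == 0:
            warnings.warn("only one cluster present; no contrast", stacklevel=2)
            continue
        mean_in = expm1[:, in_mask].mean(axis=1)
        mean_out = expm1[:, ~in_mask].mean(axis=1)
        logfc = np.log((mean_in + 1) / (mean_out + 1))
        pct_in = (X[:, in_mask] > 0).mean(axis=1)
        pct_out = (X[:, ~in_mask] > 0).mean(axis=1)
        keep = pct_in >= min_detection
        keep &= (logfc >= min_logfc) if positive_only else (np.abs(logfc) >= min_logfc)
        if not keep.any():
            continue
        res = stats.mannwhitneyu(
            X[keep][:, in_mask], X[keep][:, ~in_mask],
            axis=1, alternative="two-sided",
        )
        pvals = np.atleast_1d(res.pvalue)
        frame = pd.DataFrame(
            {
                "cluster": cl,
                "gene": np.asarray(p.gene_ids)[keep],
                "log_fc": logfc[keep],
                "pct_in": pct_in[keep],
                "pct_out": pct_out[keep],
                "p_value": pvals,
                "p_adj": np.minimum(pvals * n_genes, 1.0),
            }
        )
        out_frames.append(frame.sort_values("p_adj", kind="stable"))
    if not out_frames:
        return pd.DataFrame(
            columns=["cluster", "gene", "log_fc", "pct_in", "pct_out", "p_value", "p_adj"]
        )
    return pd.concat(out_frames, ignore_index=True)
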