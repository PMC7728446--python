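"""Label transfer from a labeled reference onto query cells.

Query and reference are embedded into one PCA space fit on the reference's
highly variable genes (restricted to shared features, with optional
orthology mapping for cross-species runs). Each query cell then receives a
prediction score per reference label — the weighted fraction of its k
nearest reference neighbors carrying that label — and the label with the
highest score becomes its predicted type or stage.

Per-cluster compositions of predicted labels are tested for enrichment by
randomization: for cluster *i* of size *n_i*, *n_i* cells are resampled with
replacement from all query cells B times; the p-value for label *j* is
``(#{resamples with composition >= observed} + 1) / (B + 1)``, the
pseudo-count keeping p strictly positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .sc import ClusterAssignment, ProcessedMatrix, select_hvg

__all__ = [
    "ReferenceDataset",
    "PredictionScoreMatrix",
    "CompositionTable",
    "PermutationResult",
    "shared_embedding",
    "transfer_labels",
    "assign_predicted",
    "composition",
    "permutation_significance",
    "spearman_cluster_correlation",
]


@dataclass
class ReferenceDataset:
    """Processed reference expression with per-cell type (and stage) labels."""

    matrix: ProcessedMatrix
    type_labels: pd.Series
    stage_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        cells = pd.Index(self.matrix.cell_ids)
        for name, lab in (("type", self.type_labels), ("stage", self.stage_labels)):
            if lab is None:
                continue
            if not cells.isin(lab.index).all():
                raise ValueError(f"{name}_labels do not cover all reference cells")


@dataclass
class PredictionScoreMatrix:
    """Query cells × reference labels; nonnegative rows summing to 1."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if (vals < 0).any():
            raise ValueError("prediction scores must be nonnegative")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("prediction score rows must sum to 1")


@dataclass
class CompositionTable:
    """Query clusters × predicted labels, rows summing to 1."""

    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.allclose(self.fractions.to_numpy().sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("composition rows must sum to 1")


@dataclass
class PermutationResult:
    observed: CompositionTable
    p_values: pd.DataFrame
    B: int
    seed: int
    alpha: float
    significant: pd.DataFrame


def _harmonize(
    query_genes: pd.Index, ref_genes: pd.Index, orthology: pd.DataFrame | None
) -> pd.DataFrame:
    """Two-column table mapping query gene → reference gene.

    With no orthology table, genes are matched case-insensitively by symbol
    (the human/mouse convention difference of FOXA2 vs Foxa2).
    """
    if orthology is not None:
        t = orthology.iloc[:, :2].copy()
        t.columns = ["query", "ref"]
        t = t[t["query"].isin(query_genes) & t["ref"].isin(ref_genes)]
        return t.drop_duplicates("query").drop_duplicates("ref")
    q_up = pd.Series(query_genes, index=pd.Index([g.upper() for g in query_genes]))
    r_up = pd.Series(ref_genes, index=pd.Index([g.upper() for g in ref_genes]))
    q_up, r_up = q_up[~q_up.index.duplicated()], r_up[~r_up.index.duplicated()]
    shared = q_up.index.intersection(r_up.index)
    return pd.DataFrame({"query": q_up.loc[shared].values, "ref": r_up.loc[shared].values})


def shared_embedding(
    query: ProcessedMatrix,
    ref: ReferenceDataset,
    n_features: int = 2000,
    n_pc: int = 15,
    orthology: pd.DataFrame | None = None,
    min_shared: int = 50,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Project query and reference into one reference-fit PCA space.

    Shared genes are selected by the reference's HVG ranking (top
    ``n_features``); both sides are standardized with the reference's
    per-gene mean and sd so the query lands in the reference's coordinate
    frame. Returns ``(query_embedding, ref_embedding, genes_used)`` where
    genes are reference-side identifiers.
    """
    pairs = _harmonize(query.lognorm.index, ref.matrix.lognorm.index, orthology)
    if len(pairs) < min_shared:
        raise ValueError(
            f"only {len(pairs)} shared features after harmonization (<{min_shared})"
        )
    # rank shared genes by reference HVG dispersion
    ref_shared = ProcessedMatrix(
        lognorm=ref.matrix.lognorm.loc[pairs["ref"]],
        cell_meta=ref.matrix.cell_meta,
    )
    n_take = min(n_features, len(pairs))
    hvg_ref = select_hvg(ref_shared, n=n_take)
    ref_to_query = dict(zip(pairs["ref"], pairs["query"]))
    genes_q = [ref_to_query[g] for g in hvg_ref]

    R = ref.matrix.lognorm.loc[hvg_ref].to_numpy().T   # cells × genes
    Q = query.lognorm.loc[genes_q].to_numpy().T
    mu, sd = R.mean(axis=0), R.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Rz, Qz = (R - mu) / sd, (Q - mu) / sd
    n_pc = min(n_pc, min(Rz.shape) - 1) if min(Rz.shape) > 1 else 1
    model = PCA(n_components=n_pc, svd_solver="full").fit(Rz)
    return model.transform(Qz), model.transform(Rz), hvg_ref


def transfer_labels(
    query_emb: np.ndarray,
    ref_emb: np.ndarray,
    labels: pd.Series | np.ndarray,
    k: int = 30,
    weighting: str = "gaussian",
    query_ids: list[str] | None = None,
) -> PredictionScoreMatrix:
    """Per-cell prediction scores from the labels of k reference neighbors.

    ``weighting="uniform"`` scores label L as the plain fraction of the k
    neighbors carrying L; ``"gaussian"`` weights each neighbor by
    ``exp(-d^2 / (2 h^2))`` with per-cell bandwidth h = distance to the k-th
    neighbor, then normalizes. Rows always sum to 1.
    """
    labels = pd.Series(np.asarray(labels))
    if k > ref_emb.shape[0]:
        raise ValueError("k exceeds reference size")
    if weighting not in ("uniform", "gaussian"):
        raise ValueError("weighting must be 'uniform' or 'gaussian'")
    classes = sorted(labels.unique())
    class_idx = {c: i for i, c in enumerate(classes)}
    codes = labels.map(class_idx).to_numpy()

    nn = NearestNeighbors(n_neighbors=k).fit(ref_emb)
    dist, idx = nn.kneighbors(query_emb)
    if weighting == "uniform":
        w = np.ones_like(dist)
    else:
        h = dist[:, -1][:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(h > 0, np.exp(-(dist**2) / (2 * h**2)), 1.0)
    scores = np.zeros((query_emb.shape[0], len(classes)))
    np.add.at(scores, (np.repeat(np.arange(len(scores)), k), codes[idx].ravel()), w.ravel())
    scores /= scores.sum(axis=1, keepdims=True)
    index = pd.Index(query_ids) if query_ids is not None else pd.RangeIndex(len(scores))
    return PredictionScoreMatrix(
        scores=pd.DataFrame(scores, index=index, columns=pd.Index(classes))
    )


def assign_predicted(s: PredictionScoreMatrix) -> tuple[pd.Series, pd.Series]:
    """Argmax label per query cell; lexicographic tie-break with a flag.

    Returns ``(predicted, tied)`` — the label Series and a boolean Series
    marking cells whose top score was shared by several labels.
    """
    cols = sorted(s.scores.columns)
    ordered = s.scores[cols]
    vals = ordered.to_numpy()
    best = vals.argmax(axis=1)  # first (lexicographic) maximum
    tied = (vals == vals.max(axis=1, keepdims=True)).sum(axis=1) > 1
    predicted = pd.Series([cols[i] for i in best], index=s.scores.index, name="predicted")
    return predicted, pd.Series(tied, index=s.scores.index, name="tied")


def composition(
    clusters: ClusterAssignment, predicted: pd.Series
) -> CompositionTable:
    """Per-cluster fractions of predicted labels (rows sum to 1)."""
    labels = clusters.labels
    if not labels.index.equals(predicted.index):
        predicted = predicted.loc[labels.index]
    tab = pd.crosstab(labels, predicted, normalize="index")
    tab = tab.sort_index().sort_index(axis=1)
    return CompositionTable(fractions=tab)


def permutation_significance(
    clusters: ClusterAssignment,
    predicted: pd.Series,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PermutationResult:
    """Randomization test for enriched predicted labels per cluster.

    For each cluster *i* of size ``n_i`` (taken in sorted cluster-name
    order, all from one seeded stream), draw B resamples of ``n_i`` cells
    with replacement from *all* query cells and recompute the label
    composition. ``p_ij = (#{k : Perc_ijk >= Perc_ij} + 1) / (B + 1)``
    (comparison inclusive), so p lies in ``[1/(B+1), 1]``. ``significant``
    marks ``p <= alpha``; no multiple-testing correction is applied.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    labels = clusters.labels
    if not labels.index.equals(predicted.index):
        predicted = predicted.loc[labels.index]
    sizes = labels.value_counts()
    if (sizes == 0).any():
        empty = sizes.index[sizes == 0].tolist()
        raise ValueError(f"empty cluster(s): {empty}")
    obs = composition(clusters, predicted)
    label_names = list(obs.fractions.columns)
    cluster_names = list(obs.fractions.index)
    codes = predicted.map({l: i for i, l in enumerate(label_names)}).to_numpy()
    n_cells, n_labels = len(codes), len(label_names)

    rng = np.random.default_rng(seed)
    pvals = np.empty((len(cluster_names), n_labels))
    for ci, cl in enumerate(cluster_names):
        n_i = int((labels == cl).sum())
        if n_i == 0:
            raise ValueError(f"cluster {cl!r} is empty")
        draws = rng.integers(0, n_cells, size=(B, n_i))
        flat = codes[draws] + np.arange(B)[:, None] * n_labels
        perc = (
            np.bincount(flat.ravel(), minlength=B * n_labels)
            .reshape(B, n_labels)
            .astype(float)
            / n_i
        )
        obs_row = obs.fractions.loc[cl].to_numpy()
        count = (perc >= obs_row - 1e-12).sum(axis=0)
        pvals[ci] = (count + 1) / (B + 1)

    p_df = pd.DataFrame(pvals, index=pd.Index(cluster_names), columns=pd.Index(label_names))
    return PermutationResult(
        observed=obs,
        p_values=p_df,
        B=B,
        seed=seed,
        alpha=alpha,
        significant=p_df <= alpha,
    )


def spearman_cluster_correlation(
    a: ProcessedMatrix,
    clusters_a: ClusterAssignment,
    b: ProcessedMatrix,
    clusters_b: ClusterAssignment,
    features: list[str],
) -> pd.DataFrame:
    """Spearman correlation of cluster-average expression on shared HVGs.

    Rows are ``a``'s clusters, columns ``b``'s. A constant average vector
    makes the correlation undefined; those entries are NaN with a warning.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 shared features")
    means_a = a.lognorm.loc[features].T.groupby(clusters_a.labels).mean().T
    means_b = b.lognorm.loc[features].T.groupby(clusters_b.labels).mean().T
    out = pd.DataFrame(
        np.nan, index=means_a.columns, columns=means_b.columns, dtype=float
    )
    for ca in means_a.columns:
        for cb in means_b.columns:
            x, y = means_a[ca].to_numpy(), means_b[cb].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"constant cluster-average vector for ({ca!r}, {cb!r}); "
                    "correlation undefined",
                    stacklevel=2,
                )
                continue
            out.loc[ca, cb] = stats.spearmanr(x, y).statistic
    return out
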