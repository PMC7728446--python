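"""Gene-module scores, diffusion maps, and probabilistic-BFS pseudotime.

A module score is the mean log-normalized expression of a gene set minus
that of expression-bin-matched random control genes, so a positive score
means the set is expressed above its expression-matched background (the PGC
signature NANOS3, SOX17, TFAP2C, PRDM1, NANOG ships as a packaged set).

The diffusion map builds a symmetric k-nearest-neighbor graph (knn = 40),
applies a Gaussian kernel of global width sigma = 8, density-normalizes it,
and row-normalizes into a cell-to-cell Markov transition matrix whose top
eigenpairs are the diffusion components. Cluster-level transition
probabilities average each cell's outgoing mass per destination cluster.

Pseudotime runs repeated stochastic breadth-first floods of the kNN graph
from a root population; a cell's pseudotime is its mean visit step across
simulations, each normalized by that simulation's depth, rescaled to [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import NearestNeighbors

from .sc import ClusterAssignment, ProcessedMatrix

__all__ = [
    "GeneSet",
    "ModuleScoreVector",
    "DiffusionResult",
    "PseudotimeVector",
    "load_gene_set",
    "pgc_signature",
    "cell_cycle_sets",
    "module_score",
    "diffusion_map",
    "cluster_transitions",
    "pseudotime_pbfs",
]


@dataclass
class GeneSet:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set must be nonempty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene set members must be unique")


@dataclass
class ModuleScoreVector:
    scores: pd.Series
    control_spec: tuple[int, int, int]  # (n_bins, n_ctrl_per_gene, seed)


@dataclass
class DiffusionResult:
    """Eigenpairs and transition matrix of the diffusion operator.

    ``components`` excludes the trivial constant eigenvector;
    ``eigenvalues`` are descending and bounded by 1. ``graph`` is the
    symmetric kNN adjacency the pseudotime walk reuses.
    """

    eigenvalues: np.ndarray
    components: np.ndarray
    transition: sp.csr_matrix
    graph: sp.csr_matrix
    cell_ids: list[str]
    params: dict


@dataclass
class PseudotimeVector:
    values: pd.Series  # in [0, 1]; NaN where unreachable
    root_cells: list[str]
    n_sims: int
    seed: int
    unreachable: list[str]


def load_gene_set(path: str) -> GeneSet:
    """Read a ``{"name": ..., "genes": [...]}`` JSON gene set."""
    with open(path) as fh:
        obj = json.load(fh)
    return GeneSet(name=obj["name"], genes=list(obj["genes"]))


def _packaged(name: str) -> dict:
    with resources.files("gastrukit.data").joinpath(name).open() as fh:
        return json.load(fh)


def pgc_signature() -> GeneSet:
    """The packaged primordial-germ-cell signature gene set."""
    obj = _packaged("gene_sets.json")["PGC"]
    return GeneSet(name="PGC", genes=obj)


def cell_cycle_sets() -> tuple[GeneSet, GeneSet]:
    """Packaged S-phase and G2/M gene lists for cell-cycle scoring."""
    obj = _packaged("cell_cycle_genes.json")
    return GeneSet("S", obj["S"]), GeneSet("G2M", obj["G2M"])


def module_score(
    expr: ProcessedMatrix,
    gs: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    control_genes: list[str] | None = None,
) -> ModuleScoreVector:
    """Average set expression minus expression-bin-matched control average.

    All genes are binned into ``n_bins`` equal-size bins by mean expression;
    for each set gene, ``n_ctrl`` control genes are drawn from its bin, and
    the score of a cell is ``mean(lognorm over set) − mean(lognorm over
    drawn controls)``. ``control_genes`` overrides the random draw (used for
    self-control checks). Set members absent from the matrix are dropped
    with a warning; an empty intersection is an error.
    """
    present = [g for g in gs.genes if g in expr.lognorm.index]
    missing = set(gs.genes) - set(present)
    if not present:
        raise ValueError(f"no gene of set {gs.name!r} present in the matrix")
    if missing:
        warnings.warn(f"set {gs.name!r}: dropping absent genes {sorted(missing)}",
                      stacklevel=2)

    X = expr.lognorm
    if control_genes is None:
        rng = np.random.default_rng(seed)
        mean_expr = X.mean(axis=1)
        ranks = mean_expr.rank(method="first")
        bins = pd.cut(ranks, bins=n_bins, labels=False)
        drawn: list[str] = []
        for g in present:
            pool = bins.index[bins == bins[g]].tolist()
            take = rng.choice(len(pool), size=min(n_ctrl, len(pool)), replace=False)
            drawn += [pool[i] for i in take]
        control_genes = drawn
    score = X.loc[present].mean(axis=0) - X.loc[control_genes].mean(axis=0)
    return ModuleScoreVector(
        scores=pd.Series(score, index=X.columns, name=gs.name),
        control_spec=(n_bins, n_ctrl, seed),
    )


def _embedding_of(p: "ProcessedMatrix | np.ndarray") -> tuple[np.ndarray, list[str]]:
    if isinstance(p, np.ndarray):
        return p, [str(i) for i in range(p.shape[0])]
    if p.pca is not None:
        return p.pca, p.cell_ids
    if p.scaled is not None:
        return p.scaled.to_numpy().T, p.cell_ids
    return p.lognorm.to_numpy().T, p.cell_ids


def diffusion_map(
    data: "ProcessedMatrix | np.ndarray",
    knn: int = 40,
    sigma: float = 8.0,
    n_dc: int = 20,
) -> DiffusionResult:
    """Diffusion map on a symmetric kNN graph with a global Gaussian kernel.

    Kernel ``exp(-d^2 / (2 sigma^2))`` on the union-symmetrized kNN graph,
    density-normalized (``K / (q_i q_j)``) to remove sampling-density bias,
    then row-normalized into the transition matrix P. Eigenpairs come from
    the conjugate symmetric operator, so the leading eigenvalue is exactly 1
    with a constant eigenvector; ``components`` holds the next ``n_dc``
    nontrivial eigenvectors. A disconnected graph triggers a warning.
    """
    X, cell_ids = _embedding_of(data)
    n = X.shape[0]
    if n <= knn:
        raise ValueError("need more cells than knn")
    nn = NearestNeighbors(n_neighbors=knn + 1).fit(X)
    dist, idx = nn.kneighbors(X)  # includes self at distance 0
    rows = np.repeat(np.arange(n), knn + 1)
    D = sp.csr_matrix((dist.ravel(), (rows, idx.ravel())), shape=(n, n))
    adj = sp.csr_matrix((np.ones_like(dist.ravel()), (rows, idx.ravel())), shape=(n, n))
    adj = ((adj + adj.T) > 0).astype(float)  # union symmetrization
    D = D.maximum(D.T)
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        warnings.warn(f"kNN graph has {n_comp} connected components", stacklevel=2)

    K = adj.tocoo()
    kern = np.exp(-(np.asarray(D.tocsr()[K.row, K.col]).ravel() ** 2) / (2 * sigma**2))
    K = sp.csr_matrix((kern, (K.row, K.col)), shape=(n, n))
    q = np.asarray(K.sum(axis=1)).ravel()
    Qinv = sp.diags(1.0 / q)
    Kt = Qinv @ K @ Qinv  # density normalization (alpha = 1)
    d = np.asarray(Kt.sum(axis=1)).ravel()
    P = sp.diags(1.0 / d) @ Kt

    # symmetric conjugate S = D^{-1/2} Kt D^{-1/2} shares P's spectrum
    Dh = sp.diags(1.0 / np.sqrt(d))
    S = Dh @ Kt @ Dh
    k_eig = min(n_dc + 1, n - 1)
    vals, vecs = eigsh(S, k=k_eig, which="LA")
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]
    psi = Dh @ vecs  # right eigenvectors of P
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)
    return DiffusionResult(
        eigenvalues=vals,
        components=psi[:, 1:],
        transition=P.tocsr(),
        graph=adj.tocsr(),
        cell_ids=cell_ids,
        params={"knn": knn, "sigma": sigma, "n_dc": n_dc},
    )


def cluster_transitions(
    d: DiffusionResult, clusters: ClusterAssignment
) -> pd.DataFrame:
    """Average cell-to-cell transition probability between clusters.

    Entry (A, B) is the mean, over cells of A, of their total transition
    probability into B; rows are renormalized to sum to 1.
    """
    labels = clusters.labels.loc[d.cell_ids]
    names = sorted(labels.unique())
    ind = pd.get_dummies(labels)[names].to_numpy(dtype=float)  # cells × clusters
    mass = d.transition @ ind  # per-cell outgoing mass per cluster
    sizes = ind.sum(axis=0)
    M = (ind.T @ mass) / sizes[:, None]
    M /= M.sum(axis=1, keepdims=True)
    return pd.DataFrame(M, index=pd.Index(names), columns=pd.Index(names))


def pseudotime_pbfs(
    d: DiffusionResult,
    roots: list[str],
    n_sims: int = 100,
    cells_per_step_fraction: float = 0.8,
    root_subsample: float = 0.8,
    seed: int = 0,
) -> PseudotimeVector:
    """Probabilistic breadth-first-search pseudotime from root cells.

    Each simulation floods the symmetric kNN graph from a random subset of
    the roots: at every step each yet-unvisited neighbor of the visited set
    is admitted with probability ``cells_per_step_fraction`` (at least one
    per step, to guarantee progress). A cell's visit step is normalized by
    the simulation's total depth; pseudotime is the mean normalized step
    over the simulations that reached the cell, rescaled to [0, 1]. Cells
    never reached stay NaN and are reported as unreachable.
    """
    if not roots:
        raise ValueError("need at least one root cell")
    pos = {c: i for i, c in enumerate(d.cell_ids)}
    missing = [r for r in roots if r not in pos]
    if missing:
        raise ValueError(f"root cells not in graph: {missing[:5]}")
    root_idx = np.array([pos[r] for r in roots])
    n = len(d.cell_ids)
    G = d.graph.tocsr()
    rng = np.random.default_rng(seed)

    sums = np.zeros(n)
    hits = np.zeros(n)
    n_root_take = max(1, int(round(root_subsample * len(root_idx))))
    for _ in range(n_sims):
        take = rng.choice(len(root_idx), size=n_root_take, replace=False)
        visited_step = np.full(n, -1, dtype=np.int64)
        visited_step[root_idx[take]] = 0
        cand = np.unique(G[root_idx[take]].indices)
        cand = cand[visited_step[cand] < 0]
        step = 0
        while cand.size > 0:
            admit = rng.random(cand.size) < cells_per_step_fraction
            if not admit.any():
                admit[rng.integers(cand.size)] = True
            step += 1
            newly = cand[admit]
            visited_step[newly] = step
            # deferred candidates stay eligible next step
            cand = np.union1d(cand[~admit], np.unique(G[newly].indices))
            cand = cand[visited_step[cand] < 0]
        if step == 0:
            continue
        reached = visited_step >= 0
        sums[reached] += visited_step[reached] / step
        hits[reached] += 1

    with np.errstate(invalid="ignore"):
        pt = np.where(hits > 0, sums / np.maximum(hits, 1), np.nan)
    # roots are the origin by definition, even when a simulation's root
    # subsample reached them late
    pt[root_idx] = 0.0
    finite = np.isfinite(pt)
    if finite.any():
        lo, hi = np.nanmin(pt), np.nanmax(pt)
        if hi > lo:
            pt = (pt - lo) / (hi - lo)
        else:
            pt = np.where(finite, 0.0, np.nan)
    unreachable = [d.cell_ids[i] for i in np.flatnonzero(~finite)]
    return PseudotimeVector(
        values=pd.Series(pt, index=pd.Index(d.cell_ids), name="pseudotime"),
        root_cells=list(roots),
        n_sims=n_sims,
        seed=seed,
        unreachable=unreachable,
    )
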