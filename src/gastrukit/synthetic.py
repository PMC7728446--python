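"""Synthetic colonies and count matrices with known ground truth.

Two generators make the whole pipeline testable without any downloads:

* :func:`generate_colony_image` renders a 500 µm micropatterned colony with
  concentric marker rings (default SOX2 center → T → SOX17 → CDX2 edge, the
  radial germ-layer arrangement BMP4 induces) plus a DAPI channel, together
  with the exhaustive table of cell centroids that produced it.
* :func:`generate_counts` draws an overdispersed (Dirichlet–multinomial
  style) gene × cell count matrix with planted clusters, marker-gene
  enrichment, mitochondrial genes and variable library sizes, plus truth
  labels — the statistical structure the QC/HVG/clustering stages assume.

:func:`generate_sorting_layout` additionally produces "mixed" (salt-and-
pepper) versus "sorted" (segregated) spatial configurations of two cell
populations, the ground truth for the cosine-overlap direction checks.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import CentroidAnnotation, FluorescenceImage
from .sc import CountMatrix

__all__ = [
    "ColonySpec",
    "SyntheticColony",
    "CountSimSpec",
    "generate_colony_image",
    "generate_sorting_layout",
    "generate_counts",
    "DEFAULT_RING_LAYOUT",
]

# Radial ring layout of the four canonical markers, as fractions of the
# colony radius: ectoderm (SOX2) at the center, then primitive-streak/
# mesoderm (T), endoderm (SOX17), and extraembryonic-like (CDX2) at the edge.
DEFAULT_RING_LAYOUT: dict[str, tuple[float, float]] = {
    "SOX2": (0.00, 0.40),
    "T": (0.40, 0.62),
    "SOX17": (0.62, 0.82),
    "CDX2": (0.82, 1.00),
}


@dataclass
class ColonySpec:
    """Parameters of one synthetic micropatterned colony."""

    diameter_um: float = 500.0
    pixel_size_um: float = 2.0
    ring_layout: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RING_LAYOUT)
    )
    cells_per_marker: dict[str, int] | None = None
    coexpression_rules: dict[tuple[str, str], float] = field(default_factory=dict)
    spot_sigma_px: float = 2.5
    spot_amplitude: float = 1.0
    background_noise_sd: float = 0.02
    margin_px: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("diameter and pixel size must be positive")
        for marker, (inner, outer) in self.ring_layout.items():
            if not (0 <= inner < outer <= 1):
                raise ValueError(
                    f"ring for {marker!r}: need 0 <= inner < outer <= 1, "
                    f"got ({inner}, {outer})"
                )
        if self.cells_per_marker is None:
            self.cells_per_marker = {m: 200 for m in self.ring_layout}
        for marker, n in self.cells_per_marker.items():
            if marker not in self.ring_layout:
                raise ValueError(f"cells requested for unknown marker {marker!r}")
            if n < 0:
                raise ValueError("cells_per_marker must be >= 0")
        for pair, p in self.coexpression_rules.items():
            if len(pair) != 2 or any(m not in self.ring_layout for m in pair):
                raise ValueError(f"coexpression pair {pair!r} not in ring layout")
            if not (0 <= p <= 1):
                raise ValueError("coexpression probabilities must lie in [0, 1]")
        if self.spot_sigma_px <= 0:
            raise ValueError("spot_sigma_px must be positive")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")

    @property
    def radius_px(self) -> float:
        return self.diameter_um / (2 * self.pixel_size_um)

    @property
    def grid_size(self) -> int:
        return int(np.ceil(self.diameter_um / self.pixel_size_um)) + 2 * self.margin_px


@dataclass
class SyntheticColony:
    """Rendered colony: channel images plus the exhaustive centroid truth.

    ``centroids`` has one row per cell with columns ``x_px``, ``y_px`` and
    ``markers`` (semicolon-joined label set; a co-expressing cell is one
    centroid listed under both markers).
    """

    channels: dict[str, np.ndarray]
    centroids: pd.DataFrame
    spec: ColonySpec | None = None

    def to_image(self, pixel_size_um: float | None = None) -> FluorescenceImage:
        if pixel_size_um is None:
            pixel_size_um = self.spec.pixel_size_um if self.spec else 1.0
        return FluorescenceImage(channels=dict(self.channels), pixel_size_um=pixel_size_um)

    def annotation(self) -> CentroidAnnotation:
        """Explode the marker-set table into one (x, y, marker) row per label."""
        rows = []
        for _, r in self.centroids.iterrows():
            for m in str(r["markers"]).split(";"):
                if m:
                    rows.append((r["x_px"], r["y_px"], m))
        return CentroidAnnotation(
            entries=pd.DataFrame(rows, columns=["x_px", "y_px", "marker"])
        )


def _render(
    channel_names: list[str],
    centroids: pd.DataFrame,
    grid: int,
    sigma: float,
    amplitude: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Additive Gaussian bumps at centroids plus clipped background noise."""
    half = max(1, int(np.ceil(4 * sigma)))
    channels = {}
    for name in channel_names + ["DAPI"]:
        img = np.zeros((grid, grid), dtype=float)
        for _, r in centroids.iterrows():
            labels = str(r["markers"]).split(";")
            if name != "DAPI" and name not in labels:
                continue
            x, y = float(r["x_px"]), float(r["y_px"])
            x0, x1 = max(int(x - half), 0), min(int(x + half) + 1, grid)
            y0, y1 = max(int(y - half), 0), min(int(y + half) + 1, grid)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            img[y0:y1, x0:x1] += amplitude * np.exp(
                -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
            )
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, size=img.shape)
        channels[name] = np.clip(img, 0.0, None)
    return channels


def _sample_annulus(
    rng: np.random.Generator, n: int, inner_frac: float, outer_frac: float,
    radius_px: float, center: float,
) -> np.ndarray:
    """Uniform-in-area points in an annulus; returns (n, 2) array of (x, y)."""
    u = rng.uniform(inner_frac**2, outer_frac**2, size=n)
    r = radius_px * np.sqrt(u)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([center + r * np.cos(theta), center + r * np.sin(theta)])


def generate_colony_image(spec: ColonySpec) -> SyntheticColony:
    """Render one colony from its spec; deterministic for a fixed seed.

    Cells of each marker are placed uniformly (in area) within that marker's
    annulus. For each co-expression rule ``(a, b) -> p``, a Binomial(min(n_a,
    n_b), p) number of cells carry both labels and contribute a single
    centroid, placed in the intersection of the two annuli when it is
    nonempty, else uniformly across their combined radial span.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid_size
    center = (grid - 1) / 2.0
    R = spec.radius_px

    remaining = dict(spec.cells_per_marker)
    records: list[tuple[float, float, str]] = []

    # co-expressing cells first, consuming quota from both markers
    for (a, b), p in spec.coexpression_rules.items():
        n_co = int(rng.binomial(min(remaining[a], remaining[b]), p)) if p > 0 else 0
        if n_co == 0:
            continue
        remaining[a] -= n_co
        remaining[b] -= n_co
        ia, oa = spec.ring_layout[a]
        ib, ob = spec.ring_layout[b]
        lo, hi = max(ia, ib), min(oa, ob)
        if lo >= hi:  # disjoint rings: place across the combined span
            lo, hi = min(ia, ib), max(oa, ob)
        pts = _sample_annulus(rng, n_co, lo, hi, R, center)
        records += [(x, y, f"{a};{b}") for x, y in pts]

    for marker, (inner, outer) in spec.ring_layout.items():
        n = remaining.get(marker, 0)
        if n == 0:
            continue
        pts = _sample_annulus(rng, n, inner, outer, R, center)
        records += [(x, y, marker) for x, y in pts]

    centroids = pd.DataFrame(records, columns=["x_px", "y_px", "markers"])
    channels = _render(
        list(spec.ring_layout), centroids, grid,
        spec.spot_sigma_px, spec.spot_amplitude, spec.background_noise_sd, rng,
    )
    return SyntheticColony(channels=channels, centroids=centroids, spec=spec)


def generate_sorting_layout(
    n_a: int,
    n_b: int,
    mode: str,
    seed: int = 0,
    markers: tuple[str, str] = ("A", "B"),
    diameter_um: float = 500.0,
    pixel_size_um: float = 2.0,
    spot_sigma_px: float = 2.5,
    background_noise_sd: float = 0.02,
    sorted_style: str = "patches",
) -> SyntheticColony:
    """Two cell populations on one disc, either intermingled or segregated.

    ``mode="mixed"`` scatters both populations uniformly over the disc (the
    salt-and-pepper state right after reseeding); ``mode="sorted"`` places
    them apart — ``sorted_style="halves"`` in disjoint half-discs,
    ``"patches"`` (default) in disjoint circular patches, emulating the
    homotypic aggregates that form by 48 h.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("population counts must be positive")
    if mode not in ("mixed", "sorted"):
        raise ValueError("mode must be 'mixed' or 'sorted'")
    rng = np.random.default_rng(seed)
    spec = ColonySpec(
        diameter_um=diameter_um,
        pixel_size_um=pixel_size_um,
        ring_layout={markers[0]: (0.0, 1.0), markers[1]: (0.0, 1.0)},
        cells_per_marker={markers[0]: n_a, markers[1]: n_b},
        spot_sigma_px=spot_sigma_px,
        background_noise_sd=background_noise_sd,
        seed=seed,
    )
    grid = spec.grid_size
    center = (grid - 1) / 2.0
    R = spec.radius_px

    records: list[tuple[float, float, str]] = []
    if mode == "mixed":
        for marker, n in zip(markers, (n_a, n_b)):
            pts = _sample_annulus(rng, n, 0.0, 1.0, R, center)
            records += [(x, y, marker) for x, y in pts]
    elif sorted_style == "halves":
        for marker, n, sign in zip(markers, (n_a, n_b), (1.0, -1.0)):
            pts = _sample_annulus(rng, n, 0.0, 1.0, R, center)
            pts[:, 0] = center + sign * np.abs(pts[:, 0] - center)
            records += [(x, y, marker) for x, y in pts]
    elif sorted_style == "patches":
        # two disjoint patches per population, alternating around the disc
        patch_r = 0.28
        angles = {markers[0]: (0.0, np.pi), markers[1]: (np.pi / 2, 3 * np.pi / 2)}
        for marker, n in zip(markers, (n_a, n_b)):
            counts = [n // 2, n - n // 2]
            for ang, cnt in zip(angles[marker], counts):
                px = center + 0.6 * R * np.cos(ang)
                py = center + 0.6 * R * np.sin(ang)
                u = rng.uniform(0, patch_r**2, size=cnt)
                r = R * np.sqrt(u)
                theta = rng.uniform(0, 2 * np.pi, size=cnt)
                records += [
                    (px + rr * np.cos(tt), py + rr * np.sin(tt), marker)
                    for rr, tt in zip(r, theta)
                ]
    else:
        raise ValueError("sorted_style must be 'halves' or 'patches'")

    centroids = pd.DataFrame(records, columns=["x_px", "y_px", "markers"])
    channels = _render(
        list(markers), centroids, grid,
        spot_sigma_px, spec.spot_amplitude, background_noise_sd, rng,
    )
    return SyntheticColony(channels=channels, centroids=centroids, spec=spec)


@dataclass
class CountSimSpec:
    """Parameters of one synthetic gene × cell count matrix."""

    n_cells_per_cluster: dict[str, int]
    n_genes: int = 2000
    markers_per_cluster: dict[str, list[str]] = field(default_factory=dict)
    marker_fold_change: float = 8.0
    marker_background: float = 1.0
    mito_gene_count: int = 13
    mito_fraction_range: tuple[float, float] = (0.005, 0.02)
    library_size_range: tuple[int, int] = (2000, 8000)
    stage_labels: dict[str, str] | None = None
    mito_prefix: str = "MT-"
    dispersion: float = 0.3
    exact_library: bool = False
    replicate: str = "R1"
    seed: int = 0
    base_seed: int | None = None  # share gene-level abundances across datasets

    def __post_init__(self) -> None:
        if not self.n_cells_per_cluster or any(
            n < 0 for n in self.n_cells_per_cluster.values()
        ):
            raise ValueError("n_cells_per_cluster must be nonempty with counts >= 0")
        if self.marker_fold_change <= 1:
            raise ValueError("marker_fold_change must be > 1")
        for rng_pair, name in (
            (self.mito_fraction_range, "mito_fraction_range"),
            (self.library_size_range, "library_size_range"),
        ):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError(f"{name} must be ordered")
        for cluster in self.markers_per_cluster:
            if cluster not in self.n_cells_per_cluster:
                raise ValueError(f"markers for unknown cluster {cluster!r}")
        union = set().union(*self.markers_per_cluster.values()) if self.markers_per_cluster else set()
        if len(union) + self.mito_gene_count > self.n_genes:
            raise ValueError(
                "n_genes smaller than marker union plus mitochondrial genes"
            )
        if self.stage_labels is not None:
            missing = set(self.n_cells_per_cluster) - set(self.stage_labels)
            if missing:
                raise ValueError(f"stage_labels missing clusters {sorted(missing)}")


def generate_counts(spec: CountSimSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a labeled count matrix with planted cluster structure.

    Per-gene base abundances are log-normal; each cluster's marker genes are
    elevated ``marker_fold_change``-fold (and scaled by
    ``marker_background`` elsewhere — 0 silences them outside their
    cluster). Per cell, gene weights are gamma-perturbed (coefficient of
    variation ``dispersion``) giving negative-binomial-like overdispersion,
    the mitochondrial genes are rescaled to a target fraction drawn from
    ``mito_fraction_range``, and the library size target is drawn uniformly
    from ``library_size_range``. Counts are Poisson at the target by
    default, or an exact multinomial allocation when ``exact_library``.

    Returns the :class:`~gastrukit.sc.CountMatrix` and a truth table with
    per-cell ``cluster`` (and ``stage`` when given).
    """
    rng = np.random.default_rng(spec.seed)
    base_rng = (
        np.random.default_rng(spec.base_seed)
        if spec.base_seed is not None
        else rng
    )

    marker_union: list[str] = []
    for genes in spec.markers_per_cluster.values():
        for g in genes:
            if g not in marker_union:
                marker_union.append(g)
    mito_genes = [f"{spec.mito_prefix}{i + 1}" for i in range(spec.mito_gene_count)]
    n_filler = spec.n_genes - len(marker_union) - len(mito_genes)
    filler = [f"G{i + 1:05d}" for i in range(n_filler)]
    gene_ids = marker_union + mito_genes + filler
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    is_mito = np.zeros(spec.n_genes, dtype=bool)
    is_mito[[gene_index[g] for g in mito_genes]] = True

    base = base_rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)

    clusters = list(spec.n_cells_per_cluster)
    cluster_weights = {}
    for cl in clusters:
        w = base.copy()
        for other, genes in spec.markers_per_cluster.items():
            idx = [gene_index[g] for g in genes]
            w[idx] = base[idx] * (
                spec.marker_fold_change if other == cl else spec.marker_background
            )
        cluster_weights[cl] = w

    n_total = sum(spec.n_cells_per_cluster.values())
    counts = np.zeros((spec.n_genes, n_total), dtype=np.int64)
    cell_clusters: list[str] = []
    col = 0
    shape = 1.0 / spec.dispersion**2 if spec.dispersion > 0 else None
    for cl in clusters:
        for _ in range(spec.n_cells_per_cluster[cl]):
            w = cluster_weights[cl].copy()
            if shape is not None:
                w = w * rng.gamma(shape, 1.0 / shape, size=spec.n_genes)
            # impose the cell's mitochondrial fraction
            f = rng.uniform(*spec.mito_fraction_range)
            w_m, w_o = w[is_mito].sum(), w[~is_mito].sum()
            if w_m > 0 and f > 0:
                w[is_mito] *= f / w_m
                w[~is_mito] *= (1 - f) / w_o
            lib = int(rng.integers(spec.library_size_range[0], spec.library_size_range[1] + 1))
            p = w / w.sum()
            if spec.exact_library:
                counts[:, col] = rng.multinomial(lib, p)
            else:
                counts[:, col] = rng.poisson(lib * p)
            cell_clusters.append(cl)
            col += 1

    cell_ids = [f"cell_{i + 1:05d}" for i in range(n_total)]
    truth = pd.DataFrame({"cluster": cell_clusters}, index=cell_ids)
    if spec.stage_labels is not None:
        truth["stage"] = [spec.stage_labels[c] for c in cell_clusters]

    meta = pd.DataFrame({"replicate": spec.replicate}, index=cell_ids)
    cm = CountMatrix.from_counts(
        counts, gene_ids, cell_ids, cell_meta=meta, mito_prefix=spec.mito_prefix
    )
    cm.cell_meta = cm.cell_meta.join(truth)
    return cm, truth
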