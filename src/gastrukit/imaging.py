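"""Quantification of marker expression in micropatterned colony images.

Implements the three image-derived statistics used throughout the package:

* radial intensity profiles — mean fluorescence in 20 concentric rings from
  the colony center to its edge, normalized to the DAPI profile so that
  intensity differences reflect marker expression rather than cell density;
* density maps — nonnegative grids whose entries are expected cell counts
  per pixel, built from centroid annotations with unit-mass kernels, so that
  the total mass of a map *is* the cell count ``C = sum_ij Y_ij``;
* cosine spatial overlap — the normalized inner product of two density maps,
  0 for disjoint cell populations and 1 for identical spatial distributions.

Images are 2-D projections (one grid per channel); a DAPI channel is required
for normalization and automatic center estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu

__all__ = [
    "FluorescenceImage",
    "RadialProfile",
    "CentroidAnnotation",
    "DensityMap",
    "estimate_center",
    "radial_profile",
    "normalize_to_dapi",
    "average_profiles",
    "density_from_centroids",
    "detect_centroids",
    "cell_count",
    "cosine_overlap",
]

DAPI = "DAPI"


@dataclass
class FluorescenceImage:
    """Multi-channel 2-D fluorescence image.

    All channels share one shape; intensities are nonnegative. Pixel
    coordinates are 0-based with ``x`` = column and ``y`` = row, and pixel
    centers at integer coordinates.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("image must have at least one channel")
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for ch, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {ch!r} is not 2-D")
            if (arr < 0).any():
                raise ValueError(f"channel {ch!r} has negative intensities")
            self.channels[ch] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class RadialProfile:
    """Mean intensity per concentric ring, center → colony edge.

    ``radii_fraction`` holds the outer edge of each ring as a fraction of the
    colony radius (strictly increasing, in (0, 1]).
    """

    marker: str
    radii_fraction: np.ndarray
    mean_intensity: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.radii_fraction = np.asarray(self.radii_fraction, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if self.radii_fraction.shape != self.mean_intensity.shape:
            raise ValueError("radii and intensities must align")
        if np.any(np.diff(self.radii_fraction) <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.radii_fraction[0] <= 0 or self.radii_fraction[-1] > 1 + 1e-12:
            raise ValueError("radii fractions must lie in (0, 1]")


@dataclass
class CentroidAnnotation:
    """Table of cell centroids, one row per (x_px, y_px, marker)."""

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"x_px", "y_px", "marker"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")

    def for_marker(self, marker: str) -> pd.DataFrame:
        return self.entries[self.entries["marker"] == marker]


@dataclass
class DensityMap:
    """Grid of expected cells per pixel; total mass is the cell count."""

    values: np.ndarray
    source: str = "annotation"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("density map must be 2-D")
        if (self.values < 0).any():
            raise ValueError("density map entries must be nonnegative")
        if self.source not in ("annotation", "detection"):
            raise ValueError("source must be 'annotation' or 'detection'")


def estimate_center(image: FluorescenceImage, channel: str = DAPI) -> tuple[float, float]:
    """Colony center as the centroid of the Otsu-thresholded channel mask.

    Returns ``(x, y)`` in pixel coordinates. Falls back to the image center
    for blank channels.
    """
    arr = image.channels[channel]
    if arr.max() <= 0:
        h, w = arr.shape
        return (w - 1) / 2.0, (h - 1) / 2.0
    mask = arr > threshold_otsu(arr)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:  # degenerate threshold
        h, w = arr.shape
        return (w - 1) / 2.0, (h - 1) / 2.0
    return float(xs.mean()), float(ys.mean())


def _radial_distances(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    cx, cy = center
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(xx - cx, yy - cy)


def radial_profile(
    image: FluorescenceImage,
    channel: str,
    center: tuple[float, float] | None = None,
    colony_radius_px: float | None = None,
    n_rings: int = 20,
    mode: str = "annulus",
) -> RadialProfile:
    """Mean intensity in ``n_rings`` concentric rings around ``center``.

    Parameters
    ----------
    center
        ``(x, y)`` colony center in pixels; estimated from DAPI if omitted.
    colony_radius_px
        Outermost ring radius; defaults to the largest radius fully inside
        the image.
    mode
        ``"annulus"`` (default) averages each equal-width annulus;
        ``"perimeter"`` averages the one-pixel-wide circle at each ring
        radius, mimicking circle-perimeter sampling.
    """
    if channel not in image.channels:
        raise KeyError(f"channel {channel!r} not in image")
    arr = image.channels[channel]
    h, w = arr.shape
    if center is None:
        center = estimate_center(image)
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"center {center} outside image of shape {(h, w)}")
    if colony_radius_px is None:
        colony_radius_px = min(cx, cy, w - 1 - cx, h - 1 - cy)
    if colony_radius_px <= 0:
        raise ValueError("colony_radius_px must be positive")
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")

    dist = _radial_distances((h, w), (cx, cy))
    edges = np.linspace(0.0, colony_radius_px, n_rings + 1)
    means = np.empty(n_rings)
    for k in range(n_rings):
        if mode == "annulus":
            sel = (dist >= edges[k]) & (dist < edges[k + 1])
            if k == n_rings - 1:
                sel = (dist >= edges[k]) & (dist <= edges[k + 1])
        elif mode == "perimeter":
            sel = np.abs(dist - edges[k + 1]) <= 0.5
        else:
            raise ValueError("mode must be 'annulus' or 'perimeter'")
        if not sel.any():
            raise ValueError(
                f"ring {k + 1}/{n_rings} contains no pixels "
                f"(radius {edges[k + 1]:.2f}px too fine for the pixel grid)"
            )
        means[k] = arr[sel].mean()

    radii = edges[1:] / colony_radius_px
    return RadialProfile(marker=channel, radii_fraction=radii, mean_intensity=means)


def normalize_to_dapi(
    marker_profile: RadialProfile,
    dapi_profile: RadialProfile,
    epsilon: float = 0.0,
) -> RadialProfile:
    """Pointwise ratio marker / (DAPI + epsilon).

    With ``epsilon == 0`` a zero DAPI ring raises; a positive guard keeps the
    output finite in empty rings.
    """
    if not np.allclose(marker_profile.radii_fraction, dapi_profile.radii_fraction):
        raise ValueError("profiles sampled at different radii")
    denom = dapi_profile.mean_intensity + epsilon
    if np.any(denom <= 0):
        raise ZeroDivisionError(
            "DAPI profile has a zero ring; pass epsilon > 0 to guard"
        )
    ratio = marker_profile.mean_intensity / denom
    return replace(marker_profile, mean_intensity=ratio, normalized=True)


def average_profiles(
    profiles: list[RadialProfile],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-ring mean and standard error over colonies.

    Returns ``(mean, sem, n)`` with ``sem = sd / sqrt(n)`` (sample sd). A
    single profile yields SEM 0 with a warning rather than NaN.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if p.marker != first.marker:
            raise ValueError("profiles are for different markers")
        if not np.allclose(p.radii_fraction, first.radii_fraction):
            raise ValueError("profiles sampled at different radii")
    stack = np.vstack([p.mean_intensity for p in profiles])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n == 1:
        warnings.warn("single profile: SEM reported as 0", stacklevel=2)
        sem = np.zeros_like(mean)
    else:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
    return mean, sem, n


def density_from_centroids(
    ann: CentroidAnnotation,
    marker: str,
    shape: tuple[int, int],
    kernel_sigma_px: float = 8.0,
) -> DensityMap:
    """Ground-truth density map from annotated centroids.

    Each centroid of ``marker`` deposits exactly one unit of mass as a
    Gaussian bump of width ``kernel_sigma_px``, truncated to the grid and
    renormalized so the deposit is unit mass even at edges and corners —
    hence ``cell_count`` of the result equals the centroid count exactly.
    """
    if kernel_sigma_px <= 0:
        raise ValueError("kernel_sigma_px must be positive")
    h, w = shape
    values = np.zeros((h, w), dtype=float)
    rows = ann.for_marker(marker)
    half = max(1, int(np.ceil(4 * kernel_sigma_px)))
    for x, y in zip(rows["x_px"].to_numpy(float), rows["y_px"].to_numpy(float)):
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"centroid ({x}, {y}) outside grid {shape}")
        x0, x1 = int(np.floor(x - half)), int(np.ceil(x + half)) + 1
        y0, y1 = int(np.floor(y - half)), int(np.ceil(y + half)) + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        kern = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * kernel_sigma_px**2))
        values[y0:y1, x0:x1] += kern / kern.sum()
    return DensityMap(values=values, source="annotation")


def detect_centroids(
    image: FluorescenceImage,
    channel: str,
    min_intensity: float,
    min_separation_px: float,
    smooth_sigma_px: float = 1.0,
) -> CentroidAnnotation:
    """Local-maximum blob detection as a centroid-annotation stand-in.

    Smooths the channel lightly, then keeps local maxima above
    ``min_intensity`` separated by at least ``min_separation_px``. An empty
    table is a valid result for blank images.
    """
    if min_intensity < 0 or min_separation_px < 0:
        raise ValueError("thresholds must be nonnegative")
    arr = image.channels[channel]
    if smooth_sigma_px > 0:
        arr = gaussian(arr, sigma=smooth_sigma_px, preserve_range=True)
    peaks = peak_local_max(
        arr,
        min_distance=max(1, int(round(min_separation_px))),
        threshold_abs=min_intensity,
        exclude_border=False,
    )
    table = pd.DataFrame(
        {
            "x_px": peaks[:, 1].astype(float),
            "y_px": peaks[:, 0].astype(float),
            "marker": channel,
        }
    )
    return CentroidAnnotation(entries=table)


def cell_count(dmap: DensityMap) -> float:
    """Total expected cell count of a density map: ``C = sum_ij Y_ij``."""
    return float(dmap.values.sum())


def cosine_overlap(a: DensityMap, b: DensityMap) -> float:
    """Cosine similarity of two density maps.

    ``sum(Y' * Y) / (sqrt(sum Y'^2) * sqrt(sum Y^2))`` — 0 when the two cell
    populations occupy disjoint pixels, 1 when their spatial distributions
    are proportional.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("density maps must share a shape")
    na = np.sqrt((a.values**2).sum())
    nb = np.sqrt((b.values**2).sum())
    if na == 0 or nb == 0:
        raise ValueError("cosine overlap undefined for an all-zero map")
    return float((a.values * b.values).sum() / (na * nb))
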