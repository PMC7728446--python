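"""Readers and writers for the package's standard formats.

Count matrices travel as 10x-style MTX triplets (matrix.mtx + features.tsv +
barcodes.tsv) or dense TSV; colony images as multi-page TIFF (one page per
channel) or per-channel PNG; centroid tables as CSV with semicolon-joined
marker sets; profiles, compositions and p-value matrices as TSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import tifffile

from .imaging import CentroidAnnotation, FluorescenceImage, RadialProfile
from .sc import CountMatrix

__all__ = [
    "write_counts_mtx",
    "read_counts_mtx",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_colony_tiff",
    "read_image_tiff",
    "write_colony_png",
    "read_image_png",
    "write_centroids_csv",
    "read_centroids_csv",
    "write_profiles_tsv",
    "write_json",
]


def write_counts_mtx(m: CountMatrix, outdir: str | Path) -> Path:
    """Write a 10x-style triplet: matrix.mtx, features.tsv, barcodes.tsv.

    Cell metadata (replicate, QC columns, any truth labels) goes to
    ``cell_meta.tsv`` alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = m.counts if sp.issparse(m.counts) else sp.csc_matrix(m.counts)
    sio.mmwrite(outdir / "matrix.mtx", mat, field="integer")
    pd.Series(m.gene_ids).to_csv(outdir / "features.tsv", sep="\t",
                                 index=False, header=False)
    pd.Series(m.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t",
                                 index=False, header=False)
    m.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t")
    return outdir


def read_counts_mtx(indir: str | Path, mito_prefix: str = "MT-") -> CountMatrix:
    indir = Path(indir)
    mat = sp.csc_matrix(sio.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    meta_path = indir / "cell_meta.tsv"
    meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path.exists() else None
    return CountMatrix.from_counts(mat, genes, cells, cell_meta=meta,
                                   mito_prefix=mito_prefix)


def write_counts_tsv(m: CountMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(m.dense(), index=pd.Index(m.gene_ids),
                      columns=pd.Index(m.cell_ids))
    df.to_csv(path, sep="\t")
    return path


def read_counts_tsv(
    path: str | Path,
    meta_path: str | Path | None = None,
    mito_prefix: str = "MT-",
) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path else None
    return CountMatrix.from_counts(
        df.to_numpy(dtype=np.int64), df.index.tolist(), df.columns.tolist(),
        cell_meta=meta, mito_prefix=mito_prefix,
    )


def write_colony_tiff(image: FluorescenceImage, path: str | Path) -> Path:
    """One TIFF page per channel; channel names stored in page descriptions."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = list(image.channels)
    stack = np.stack([image.channels[c].astype(np.float32) for c in names])
    tifffile.imwrite(
        path, stack,
        metadata={"channels": names, "pixel_size_um": image.pixel_size_um},
    )
    return path


def read_image_tiff(
    path: str | Path, channel_names: list[str] | None = None
) -> FluorescenceImage:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if stack.ndim == 2:
        stack = stack[None]
    names = channel_names or meta.get("channels") or [
        f"ch{i}" for i in range(stack.shape[0])
    ]
    return FluorescenceImage(
        channels={n: stack[i].astype(float) for i, n in enumerate(names)},
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
    )


def write_colony_png(image: FluorescenceImage, outdir: str | Path) -> Path:
    """Per-channel 16-bit PNGs, each scaled to its own maximum."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, arr in image.channels.items():
        peak = arr.max() or 1.0
        iio.imwrite(outdir / f"{name}.png",
                    np.round(arr / peak * 65535).astype(np.uint16))
    return outdir


def read_image_png(indir: str | Path, channels: list[str],
                   pixel_size_um: float = 1.0) -> FluorescenceImage:
    indir = Path(indir)
    chans = {c: iio.imread(indir / f"{c}.png").astype(float) for c in channels}
    return FluorescenceImage(channels=chans, pixel_size_um=pixel_size_um)


def write_centroids_csv(centroids: pd.DataFrame, path: str | Path) -> Path:
    """Centroid truth table (x_px, y_px, markers semicolon-joined)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    centroids.to_csv(path, index=False)
    return Path(path)


def read_centroids_csv(path: str | Path) -> CentroidAnnotation:
    """Read a centroid CSV into a one-row-per-(x, y, marker) annotation."""
    df = pd.read_csv(path)
    col = "markers" if "markers" in df.columns else "marker"
    rows = []
    for _, r in df.iterrows():
        for m in str(r[col]).split(";"):
            if m:
                rows.append((float(r["x_px"]), float(r["y_px"]), m))
    return CentroidAnnotation(
        entries=pd.DataFrame(rows, columns=["x_px", "y_px", "marker"])
    )


def write_profiles_tsv(profiles: list[RadialProfile], path: str | Path) -> Path:
    frames = [
        pd.DataFrame({
            "marker": p.marker,
            "radius_fraction": p.radii_fraction,
            "mean_intensity": p.mean_intensity,
            "normalized": p.normalized,
        })
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    return Path(path)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default) + "\n")
    return path
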