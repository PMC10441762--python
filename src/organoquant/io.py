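"""Readers and writers for the formats the pipeline consumes and produces.

TIFF images (8/16-bit, single- or multi-page) via tifffile, Cell Ranger
style MatrixMarket triples (matrix.mtx + features.tsv + barcodes.tsv) via
scipy.io, and long-format CSV tables via pandas.  Readers validate loudly;
no silent coercion.  All pixel coordinates in outputs are 0-based (row,
col), origin top-left.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import io as sio
from scipy import sparse

from .imaging import ChannelImage
from .qpcr import CT_COLUMNS
from .sc import CountMatrix

__all__ = [
    "FormatError",
    "read_image",
    "write_image",
    "read_counts",
    "write_counts",
    "read_ct_table",
    "write_csv",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as its declared format."""


def read_image(path: str | os.PathLike, channels: Sequence[str] | None = None) -> list[ChannelImage]:
    """Load a single- or multi-page TIFF as one ChannelImage per page.

    Channel labels follow ``channels`` in page order; with none given,
    pages are labeled GENERIC.  Intensities are preserved exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            pages = [p.asarray() for p in tf.pages]
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if not pages:
        raise FormatError(f"TIFF {path} contains no pages")
    if channels is not None and len(channels) != len(pages):
        raise FormatError(
            f"{path}: {len(pages)} pages but {len(channels)} channel labels given"
        )
    labels = list(channels) if channels is not None else ["GENERIC"] * len(pages)
    return [ChannelImage(np.asarray(p, dtype=float), channel=lab) for p, lab in zip(pages, labels)]


def write_image(path: str | os.PathLike, images: Sequence[ChannelImage]) -> None:
    """Write channels as a multi-page 16-bit TIFF (values rounded and clipped)."""
    stack = np.stack(
        [np.clip(np.rint(im.pixels), 0, np.iinfo(np.uint16).max).astype(np.uint16) for im in images]
    )
    tifffile.imwrite(Path(path), stack)


def _read_features(path: Path) -> list[str]:
    """Features TSV with 1-3 columns (id, symbol, type); prefer the symbol column."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] == 0 or df.shape[1] > 3:
        raise FormatError(f"{path}: expected 1-3 tab-separated columns, got {df.shape[1]}")
    col = 1 if df.shape[1] >= 2 else 0
    symbols = df.iloc[:, col].tolist()
    if len(set(symbols)) != len(symbols):
        # symbol collisions are common in real annotations; disambiguate with the id
        symbols = [
            s if symbols.count(s) == 1 else f"{s}__{df.iloc[i, 0]}" for i, s in enumerate(symbols)
        ]
    return symbols


def read_counts(
    mtx_path: str | os.PathLike,
    features_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
) -> CountMatrix:
    """Load a MatrixMarket triple (genes x cells, Cell Ranger orientation)."""
    mtx_path, features_path, barcodes_path = Path(mtx_path), Path(features_path), Path(barcodes_path)
    try:
        m = sio.mmread(mtx_path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read MatrixMarket file {mtx_path}: {exc}") from exc
    m = sparse.csr_matrix(m)
    symbols = _read_features(features_path)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str).iloc[:, 0].tolist()
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"{barcodes_path}: duplicate barcodes")
    if m.shape != (len(symbols), len(barcodes)):
        raise FormatError(
            f"{mtx_path}: matrix is {m.shape} but features/barcodes give "
            f"({len(symbols)}, {len(barcodes)})"
        )
    if not np.allclose(m.data, np.rint(m.data)):
        raise FormatError(f"{mtx_path}: expected integer counts")
    return CountMatrix(counts=m.astype(np.int64), gene_symbols=symbols, cell_barcodes=barcodes)


def write_counts(out_dir: str | os.PathLike, counts: CountMatrix) -> None:
    """Write matrix.mtx, features.tsv and barcodes.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(out / "matrix.mtx", sparse.coo_matrix(counts.counts))
    pd.DataFrame({0: counts.gene_symbols, 1: counts.gene_symbols, 2: "Gene Expression"}).to_csv(
        out / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(counts.cell_barcodes).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)


def read_ct_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a long-format Ct CSV with columns sample,group,gene,replicate,ct."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read Ct table {path}: {exc}") from exc
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_csv(path: str | os.PathLike, frame: pd.DataFrame, sort_by: Sequence[str] | None = None) -> None:
    """Write a CSV with stable row order so runs are checksum-comparable."""
    if sort_by:
        frame = frame.sort_values(list(sort_by), kind="stable")
    frame.to_csv(Path(path), index=False)
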