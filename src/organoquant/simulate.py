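"""Ground-truthed synthetic data for every stage of the pipeline.

Three generators, one per assay: fluorescence fields with circular lipid
droplets and nuclei, negative-binomial single-cell count matrices with
planted differential expression and a mitochondrial gene block, and qPCR
Ct tables with planted fold changes against an ACTB reference.  Each is a
pure function of its config (including the seed), and each returns the
exact list of planted objects or effects so downstream recovery can be
scored against truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import ChannelImage

__all__ = [
    "ImageSimConfig",
    "GroundTruth",
    "CountsSimConfig",
    "CtSimConfig",
    "generate_droplet_image",
    "generate_count_matrix",
    "generate_ct_table",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fluorescence fields


@dataclass(frozen=True)
class ImageSimConfig:
    """Parameters of a simulated two-channel field (DAPI + droplet stain).

    Intensities are arbitrary units on top of ``background_level``; the
    invariant ``droplet_intensity > background_level + 3 * noise_sd``
    guarantees the planted objects are detectable by construction.
    """

    height_px: int = 256
    width_px: int = 256
    n_nuclei: int = 8
    droplets_per_cell_mean: float = 4.0
    radius_range_px: tuple[float, float] = (3.0, 8.0)
    droplet_intensity: float = 600.0
    nucleus_intensity: float = 400.0
    background_level: float = 100.0
    noise_sd: float = 20.0
    allow_overlap: bool = False
    nucleus_radius_range_px: tuple[float, float] = (6.0, 9.0)
    droplet_channel: str = "LIPIDTOX"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_nuclei < 0 or self.droplets_per_cell_mean < 0:
            raise ValueError("n_nuclei and droplets_per_cell_mean must be nonnegative")
        r_lo, r_hi = self.radius_range_px
        if not (0 < r_lo <= r_hi):
            raise ValueError("radius_range_px must satisfy 0 < r_lo <= r_hi")
        for name in ("droplet_intensity", "nucleus_intensity", "background_level", "noise_sd"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")
        if self.droplet_intensity <= self.background_level + 3 * self.noise_sd:
            raise ValueError(
                "droplet_intensity must exceed background_level + 3*noise_sd "
                "so planted droplets are detectable"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Planted objects of one simulated field: (center_row, center_col, radius_px)."""

    droplets: tuple[tuple[float, float, float], ...]
    nuclei: tuple[tuple[float, float, float], ...]

    def to_frame(self, which: str = "droplets") -> pd.DataFrame:
        objs = getattr(self, which)
        return pd.DataFrame(objs, columns=["center_row", "center_col", "radius_px"])


def _place_disks(
    rng: np.random.Generator,
    n: int,
    radii: np.ndarray,
    shape: tuple[int, int],
    existing: list[tuple[float, float, float]],
    allow_overlap: bool,
    max_attempts: int = 500,
) -> list[tuple[float, float, float]]:
    """Rejection-sample disk centers fully inside the field.

    Without ``allow_overlap`` a candidate is also rejected when it
    intersects an already placed disk (center distance < r_i + r_j + 1).
    A disk that cannot be placed after ``max_attempts`` tries is skipped
    and the event logged, so truth never contains clipped objects.
    """
    placed = list(existing)
    out: list[tuple[float, float, float]] = []
    h, w = shape
    for i in range(n):
        r = float(radii[i])
        ok = False
        for _ in range(max_attempts):
            cr = rng.uniform(r, h - 1 - r)
            cc = rng.uniform(r, w - 1 - r)
            if not allow_overlap:
                clash = any(
                    (cr - pr) ** 2 + (cc - pc) ** 2 < (r + prad + 1.0) ** 2
                    for pr, pc, prad in placed
                )
                if clash:
                    continue
            ok = True
            break
        if not ok:
            logger.warning("could not place disk %d (radius %.1f) without overlap; skipped", i, r)
            continue
        placed.append((cr, cc, r))
        out.append((cr, cc, r))
    return out


def _render(
    shape: tuple[int, int],
    disks: Sequence[tuple[float, float, float]],
    amplitude: float,
    background: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    img = np.full(shape, background, dtype=float)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cr, ccenter, r in disks:
        img[(rr - cr) ** 2 + (cc - ccenter) ** 2 <= r * r] = background + amplitude
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    return np.clip(img, 0.0, None)


def generate_droplet_image(
    config: ImageSimConfig,
) -> tuple[dict[str, ChannelImage], GroundTruth]:
    """Simulate one field: a DAPI nucleus channel and a droplet channel.

    Droplet count is a Poisson draw per nucleus (the assay reports only
    per-cell averages).  Returns the channels keyed by label and the exact
    ground truth of what was planted.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.height_px, config.width_px)

    nr_lo, nr_hi = config.nucleus_radius_range_px
    nucleus_radii = rng.uniform(nr_lo, nr_hi, size=config.n_nuclei)
    nuclei = _place_disks(rng, config.n_nuclei, nucleus_radii, shape, [], allow_overlap=False)

    n_droplets = int(rng.poisson(config.droplets_per_cell_mean * len(nuclei)))
    r_lo, r_hi = config.radius_range_px
    droplet_radii = rng.uniform(r_lo, r_hi, size=n_droplets)
    droplets = _place_disks(rng, n_droplets, droplet_radii, shape, [], config.allow_overlap)

    dapi = ChannelImage(
        _render(shape, nuclei, config.nucleus_intensity, config.background_level, config.noise_sd, rng),
        channel="DAPI",
    )
    droplet_img = ChannelImage(
        _render(shape, droplets, config.droplet_intensity, config.background_level, config.noise_sd, rng),
        channel=config.droplet_channel,
    )
    truth = GroundTruth(droplets=tuple(droplets), nuclei=tuple(nuclei))
    return {"DAPI": dapi, config.droplet_channel: droplet_img}, truth


# ---------------------------------------------------------------------------
# single-cell counts


@dataclass(frozen=True)
class CountsSimConfig:
    """Negative-binomial count matrix with cell types, a mito block and planted DE.

    ``de_genes`` entries are (gene_index, log2_fold_change, affected_type):
    in cells of the affected type the gene's NB mean is multiplied by
    ``2**log2_fold_change``.  Mitochondrial genes are a dedicated block of
    ``n_mito_genes`` symbols prefixed ``MT-`` that receives the type's
    ``mito_fraction`` share of each cell's expected total.
    """

    n_genes: int = 1000
    n_mito_genes: int = 13
    cells_per_type: Mapping[str, int] = field(default_factory=lambda: {"typeA": 200, "typeB": 200})
    nb_mean: float = 2.0
    nb_dispersion: float = 0.1
    mito_fraction_per_type: Mapping[str, float] = field(default_factory=dict)
    de_genes: tuple[tuple[int, float, str], ...] = ()
    gene_symbols: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_mito_genes <= 0:
            raise ValueError("n_genes and n_mito_genes must be positive")
        if self.n_mito_genes >= self.n_genes:
            raise ValueError("n_mito_genes must be smaller than n_genes")
        if not self.cells_per_type:
            raise ValueError("cells_per_type must not be empty")
        if any(n <= 0 for n in self.cells_per_type.values()):
            raise ValueError("cell counts per type must be positive")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")
        for t, f in self.mito_fraction_per_type.items():
            if not (0 <= f < 1):
                raise ValueError(f"mito fraction for {t!r} must be in [0, 1)")
        for idx, _lfc, t in self.de_genes:
            if not (0 <= idx < self.n_genes):
                raise ValueError(f"de gene index {idx} out of range")
            if t not in self.cells_per_type:
                raise ValueError(f"de affected type {t!r} not in cells_per_type")
        if self.gene_symbols is not None and len(self.gene_symbols) != self.n_genes:
            raise ValueError("gene_symbols must have length n_genes")

    def symbols(self) -> list[str]:
        if self.gene_symbols is not None:
            return list(self.gene_symbols)
        n_regular = self.n_genes - self.n_mito_genes
        syms = [f"GENE{i:05d}" for i in range(n_regular)]
        syms += [f"MT-G{i}" for i in range(self.n_mito_genes)]
        return syms

    @property
    def mito_gene_indices(self) -> np.ndarray:
        return np.arange(self.n_genes - self.n_mito_genes, self.n_genes)


def generate_count_matrix(config: CountsSimConfig):
    """Draw a genes x cells integer count matrix with known structure.

    Returns ``(counts, labels, de_truth)`` where ``counts`` is a
    :class:`~organoquant.sc.CountMatrix`, ``labels`` a pandas Series of
    cell-type labels per barcode, and ``de_truth`` a DataFrame listing the
    planted DE genes (gene index, symbol, log2 fold change, affected type).
    """
    from .sc import CountMatrix  # local import: sc depends on nothing here

    rng = np.random.default_rng(config.seed)
    types = list(config.cells_per_type)
    n_cells = sum(config.cells_per_type.values())
    symbols = config.symbols()
    mito_idx = config.mito_gene_indices
    regular_idx = np.setdiff1d(np.arange(config.n_genes), mito_idx)

    # per-type mean vector: regular genes at nb_mean, mito block sized so its
    # expected share of the cell total equals the type's mito fraction
    mean_by_type: dict[str, np.ndarray] = {}
    for t in types:
        mu = np.zeros(config.n_genes)
        mu[regular_idx] = config.nb_mean
        f = config.mito_fraction_per_type.get(t, 0.0)
        regular_total = config.nb_mean * regular_idx.size
        mito_total = f / (1.0 - f) * regular_total if f > 0 else 0.0
        mu[mito_idx] = mito_total / mito_idx.size
        for idx, lfc, affected in config.de_genes:
            if affected == t:
                mu[idx] *= 2.0**lfc
        mean_by_type[t] = mu

    counts = np.zeros((config.n_genes, n_cells), dtype=np.int64)
    labels = np.empty(n_cells, dtype=object)
    col = 0
    nb_n = 1.0 / config.nb_dispersion  # var = mu + dispersion * mu^2
    for t in types:
        k = config.cells_per_type[t]
        mu = mean_by_type[t]
        nonzero = mu > 0
        p = nb_n / (nb_n + mu[nonzero])
        block = np.zeros((config.n_genes, k), dtype=np.int64)
        block[nonzero, :] = rng.negative_binomial(nb_n, p[:, None], size=(nonzero.sum(), k))
        counts[:, col : col + k] = block
        labels[col : col + k] = t
        col += k

    barcodes = [f"CELL{i:05d}" for i in range(n_cells)]
    matrix = CountMatrix(counts=counts, gene_symbols=symbols, cell_barcodes=barcodes)
    label_series = pd.Series(labels, index=barcodes, name="cell_type")
    de_truth = pd.DataFrame(
        [
            {"gene_index": idx, "gene": symbols[idx], "log2_fold_change": lfc, "affected_type": t}
            for idx, lfc, t in config.de_genes
        ],
        columns=["gene_index", "gene", "log2_fold_change", "affected_type"],
    )
    return matrix, label_series, de_truth


# ---------------------------------------------------------------------------
# qPCR Ct tables


@dataclass(frozen=True)
class CtSimConfig:
    """Ct table with planted fold changes for a treated vs control design.

    In the treated group a gene with fold change F has its mean Ct lowered
    by log2(F) (one cycle per doubling of template); the reference gene
    keeps fold change 1.  Gaussian cycle noise is added per technical
    replicate measurement.
    """

    genes: tuple[str, ...] = ("ACTB", "SLC17A7", "TBR1")
    true_fold_change: Mapping[str, float] = field(default_factory=dict)
    base_ct: float = 22.0
    replicates_per_group: int = 6
    technical_replicates: int = 2
    noise_sd: float = 0.1
    reference_gene: str = "ACTB"
    control_group: str = "control"
    treated_group: str = "treated"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_gene not in self.genes:
            raise ValueError(f"reference gene {self.reference_gene!r} missing from genes")
        if self.replicates_per_group <= 0 or self.technical_replicates <= 0:
            raise ValueError("replicate counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for g, fc in self.true_fold_change.items():
            if g not in self.genes:
                raise ValueError(f"fold change given for unknown gene {g!r}")
            if fc <= 0:
                raise ValueError("fold changes must be positive")


def generate_ct_table(config: CtSimConfig) -> pd.DataFrame:
    """Simulate a long-format Ct table: sample, group, gene, replicate, ct."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for group in (config.control_group, config.treated_group):
        for s in range(config.replicates_per_group):
            sample = f"{group}_{s + 1}"
            for gene in config.genes:
                fc = config.true_fold_change.get(gene, 1.0)
                if gene == config.reference_gene:
                    fc = 1.0
                mean_ct = config.base_ct
                if group == config.treated_group:
                    mean_ct -= math.log2(fc)
                for rep in range(1, config.technical_replicates + 1):
                    ct = mean_ct + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
                    rows.append(
                        {"sample": sample, "group": group, "gene": gene, "replicate": rep, "ct": ct}
                    )
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])
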