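"""Single-cell RNA-seq quantification: QC, composition, signatures, DEG filtering.

The cell-level quality-control rules and downstream filters follow the
conventions of droplet-based organoid studies: cells are discarded when
their UMI total is above 25,000 or below 5,000, when fewer than 200 genes
are detected, or when mitochondrial reads exceed 12% — all strict
inequalities, so boundary-equal cells are kept.  Differentially expressed
genes are kept at Bonferroni-corrected p < 0.05 and |log2 fold change|
> 0.25.  Cell-type labels are an input (from any clustering); clustering
itself is out of scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "CompositionTable",
    "CORTICAL_SIGNATURE",
    "HIPPOCAMPAL_SIGNATURE",
    "SIGNATURE_SETS",
    "compute_cell_metrics",
    "qc_filter",
    "compute_cdr",
    "composition",
    "signature_score",
    "deg_filter",
    "two_group_gene_test",
]

#: Cortical-identity signature genes (13 symbols).
CORTICAL_SIGNATURE: tuple[str, ...] = (
    "TNNC1", "MYL4", "CALB2", "RELN", "LHX1", "LHX5", "EBF3",
    "SATB2", "DOK5", "EMX1", "TIAM2", "TBR1", "FOXG1",
)

#: Hippocampal-identity signature genes (13 symbols).
HIPPOCAMPAL_SIGNATURE: tuple[str, ...] = (
    "ZBTB20", "GLIS3", "DCX", "NRP2", "GRIA1", "PROX1", "NEUROD1",
    "C1QL2", "ELAVL2", "ELAVL4", "DKK3", "POU3F1", "SPOCK1",
)

SIGNATURE_SETS: dict[str, tuple[str, ...]] = {
    "cortical": CORTICAL_SIGNATURE,
    "hippocampal": HIPPOCAMPAL_SIGNATURE,
}


@dataclass
class CountMatrix:
    """Genes x cells nonnegative integer counts with identifiers.

    ``counts`` may be dense or ``scipy.sparse``; it is stored as CSR.
    ``sample_of_cell`` and ``group_of_sample`` are optional maps used by
    :func:`composition`.
    """

    counts: object
    gene_symbols: Sequence[str]
    cell_barcodes: Sequence[str]
    sample_of_cell: Mapping[str, str] | None = None
    group_of_sample: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        m = self.counts
        if not sparse.issparse(m):
            m = sparse.csr_matrix(np.asarray(m))
        else:
            m = m.tocsr()
        if (m.data < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = m
        self.gene_symbols = list(self.gene_symbols)
        self.cell_barcodes = list(self.cell_barcodes)
        if m.shape != (len(self.gene_symbols), len(self.cell_barcodes)):
            raise ValueError(
                f"counts shape {m.shape} inconsistent with {len(self.gene_symbols)} genes "
                f"x {len(self.cell_barcodes)} cells"
            )
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError("gene symbols must be unique")
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise ValueError("cell barcodes must be unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, barcodes: Iterable[str]) -> "CountMatrix":
        wanted = list(barcodes)
        pos = {b: i for i, b in enumerate(self.cell_barcodes)}
        idx = [pos[b] for b in wanted]
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_symbols=self.gene_symbols,
            cell_barcodes=wanted,
            sample_of_cell=self.sample_of_cell,
            group_of_sample=self.group_of_sample,
        )


@dataclass(frozen=True)
class QCThresholds:
    """Cell-discard thresholds; the defaults are the study conventions."""

    max_umi: float = 25_000
    min_umi: float = 5_000
    min_features: int = 200
    max_mito_percent: float = 12.0

    def __post_init__(self) -> None:
        if self.min_umi >= self.max_umi:
            raise ValueError("require min_umi < max_umi")


def default_mito_predicate(symbol: str) -> bool:
    """Default mitochondrial-gene predicate: symbol prefix ``MT-``."""
    return symbol.upper().startswith("MT-")


def compute_cell_metrics(
    counts: CountMatrix,
    mito_gene_predicate: Callable[[str], bool] = default_mito_predicate,
) -> pd.DataFrame:
    """Per-cell QC metrics: total UMI, detected genes, mitochondrial percent.

    Cells with zero total UMI get ``mito_percent`` 0 and ``zero_umi`` True.
    If no gene matches the mitochondrial predicate a warning is issued and
    every ``mito_percent`` is 0.
    """
    m = counts.counts
    total_umi = np.asarray(m.sum(axis=0)).ravel()
    n_features = np.asarray((m > 0).sum(axis=0)).ravel()
    mito_rows = np.fromiter(
        (mito_gene_predicate(s) for s in counts.gene_symbols), dtype=bool, count=counts.n_genes
    )
    if not mito_rows.any():
        warnings.warn("no gene matches the mitochondrial predicate; mito_percent set to 0")
        mito_counts = np.zeros(counts.n_cells)
    else:
        mito_counts = np.asarray(m[mito_rows].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_percent = np.where(total_umi > 0, 100.0 * mito_counts / total_umi, 0.0)
    return pd.DataFrame(
        {
            "total_umi": total_umi.astype(np.int64),
            "n_features": n_features.astype(np.int64),
            "mito_percent": mito_percent,
            "zero_umi": total_umi == 0,
        },
        index=pd.Index(counts.cell_barcodes, name="barcode"),
    )


def qc_filter(metrics: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> pd.Series:
    """Boolean keep-mask per cell under the discard rules.

    A cell is discarded iff total_umi > max_umi, total_umi < min_umi,
    n_features < min_features, or mito_percent > max_mito_percent.  All
    comparisons are strict, so cells exactly on a boundary are kept.
    """
    discard = (
        (metrics["total_umi"] > thresholds.max_umi)
        | (metrics["total_umi"] < thresholds.min_umi)
        | (metrics["n_features"] < thresholds.min_features)
        | (metrics["mito_percent"] > thresholds.max_mito_percent)
    )
    return ~discard


def compute_cdr(metrics: pd.DataFrame) -> pd.Series:
    """Cellular detection rate: z-scaled number of detected genes per cell.

    Uses the sample standard deviation (n-1 denominator).  If every cell
    detects the same number of genes the CDR is all zeros.
    """
    x = metrics["n_features"].to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError("compute_cdr requires at least 2 cells")
    sd = x.std(ddof=1)
    if sd == 0:
        z = np.zeros_like(x)
    else:
        z = (x - x.mean()) / sd
    return pd.Series(z, index=metrics.index, name="cdr")


@dataclass
class CompositionTable:
    """Per-sample cell-type fractions and per-type group comparisons.

    ``fractions``: DataFrame samples x types, rows sum to 1.
    ``comparisons``: one row per type with group means, SEMs, t and p from
    a two-sided unpaired equal-variance t test on per-sample fractions
    (the sample, i.e. the pooled-organoid dissociate, is the replicate unit).
    """

    fractions: pd.DataFrame
    comparisons: pd.DataFrame


def composition(
    labels: Mapping[str, str] | pd.Series,
    sample_of_cell: Mapping[str, str] | pd.Series,
    group_of_sample: Mapping[str, str] | pd.Series,
) -> CompositionTable:
    """Cell-type composition per sample, compared between two groups per type."""
    from .qpcr import two_sided_t_test

    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    sample_of_cell = pd.Series(dict(sample_of_cell)) if not isinstance(sample_of_cell, pd.Series) else sample_of_cell
    group_of_sample = pd.Series(dict(group_of_sample)) if not isinstance(group_of_sample, pd.Series) else group_of_sample

    missing = labels.index.difference(sample_of_cell.index)
    if len(missing):
        raise ValueError(f"{len(missing)} labeled cells have no sample assignment")
    df = pd.DataFrame({"cell_type": labels, "sample": sample_of_cell.reindex(labels.index)})
    table = pd.crosstab(df["sample"], df["cell_type"])
    fractions = table.div(table.sum(axis=1), axis=0)

    groups = group_of_sample.reindex(fractions.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    group_names = sorted(groups.unique())
    rows = []
    if len(group_names) == 2:
        g1, g2 = group_names
        a_idx, b_idx = fractions.index[groups == g1], fractions.index[groups == g2]
        for ct in fractions.columns:
            a = fractions.loc[a_idx, ct].to_numpy()
            b = fractions.loc[b_idx, ct].to_numpy()
            row = {
                "cell_type": ct,
                f"mean_{g1}": a.mean(),
                f"sem_{g1}": a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else 0.0,
                f"mean_{g2}": b.mean(),
                f"sem_{g2}": b.std(ddof=1) / np.sqrt(len(b)) if len(b) > 1 else 0.0,
            }
            if len(a) >= 2 and len(b) >= 2:
                t, p = two_sided_t_test(a, b)
                row["t"], row["p"] = t, p
            else:
                warnings.warn(f"group with < 2 samples; t test omitted for {ct!r}")
                row["t"], row["p"] = np.nan, np.nan
            rows.append(row)
    else:
        warnings.warn(
            f"composition comparison requires exactly 2 groups, found {len(group_names)}; "
            "fractions computed, comparison omitted"
        )
    comparisons = pd.DataFrame(rows)
    return CompositionTable(fractions=fractions, comparisons=comparisons)


def _log_normalize(counts: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """Counts-per-``scale`` normalisation followed by log1p; dense genes x cells."""
    m = counts.counts.astype(float)
    totals = np.asarray(m.sum(axis=0)).ravel()
    totals[totals == 0] = 1.0
    dense = np.asarray(m.todense())
    return np.log1p(dense / totals[None, :] * scale)


def signature_score(counts: CountMatrix, gene_set: Sequence[str]) -> np.ndarray:
    """Per-cell score of a gene set on log-normalised expression.

    Counts are normalised per cell to 10,000, log1p-transformed, each
    signature gene z-scored across cells (zero-variance genes dropped),
    and the score is the mean z-score over the retained genes.
    """
    present = [g for g in gene_set if g in counts.gene_symbols]
    if not present:
        raise ValueError("no gene of the signature set is present in the matrix")
    pos = {g: i for i, g in enumerate(counts.gene_symbols)}
    idx = [pos[g] for g in present]
    expr = _log_normalize(counts)[idx, :]
    sd = expr.std(axis=1, ddof=1) if expr.shape[1] > 1 else np.zeros(expr.shape[0])
    keep = sd > 0
    if not keep.any():
        warnings.warn("all signature genes have zero variance; scores set to 0")
        return np.zeros(counts.n_cells)
    z = (expr[keep] - expr[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return z.mean(axis=0)


def deg_filter(
    records: pd.DataFrame | Sequence[tuple[str, float, float]],
    n_tests: int,
    alpha: float = 0.05,
    min_abs_log2fc: float = 0.25,
) -> pd.DataFrame:
    """Bonferroni-correct raw p-values and flag significant DE genes.

    ``significant`` iff ``min(1, p_raw * n_tests) < alpha`` and
    ``|log2_fold_change| > min_abs_log2fc`` — both strict, so records on a
    boundary are not called.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records, columns=["gene", "log2_fold_change", "p_raw"])
    records = records.copy()
    p = records["p_raw"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p_raw values must lie in [0, 1]")
    if n_tests < len(records):
        raise ValueError("n_tests must be at least the number of records")
    records["p_bonferroni"] = np.minimum(1.0, p * n_tests)
    records["significant"] = (records["p_bonferroni"] < alpha) & (
        records["log2_fold_change"].abs() > min_abs_log2fc
    )
    return records


def _ranksum_gene(x: np.ndarray, n1: int) -> tuple[float, float]:
    """Tie-corrected two-sided rank-sum z test; first n1 entries are group 1."""
    n = x.size
    n2 = n - n1
    ranks = stats.rankdata(x)
    r1 = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values tied: no information
        return 0.0, 1.0
    z = (r1 - mu) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def two_group_gene_test(
    counts: CountMatrix, groups: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test between two cell groups.

    Uses the normal approximation with tie correction on log-normalised
    expression; also reports a log2 fold change of mean normalised
    expression (+1 pseudocount).  Returns a DataFrame with columns
    ``gene, statistic, p_raw, log2_fold_change``.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    groups = groups.reindex(counts.cell_barcodes)
    names = sorted(groups.dropna().unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, found {len(names)}")
    mask1 = (groups == names[0]).to_numpy()
    mask2 = (groups == names[1]).to_numpy()
    if mask1.sum() == 0 or mask2.sum() == 0:
        raise ValueError("both groups must be nonempty")

    expr = _log_normalize(counts)
    x1, x2 = expr[:, mask1], expr[:, mask2]
    n1 = x1.shape[1]
    stacked = np.concatenate([x1, x2], axis=1)

    stats_out = np.empty(counts.n_genes)
    pvals = np.empty(counts.n_genes)
    for g in range(counts.n_genes):
        stats_out[g], pvals[g] = _ranksum_gene(stacked[g], n1)

    cpk = np.expm1(expr)  # back to counts-per-10k scale
    lfc = np.log2((cpk[:, mask1].mean(axis=1) + 1.0) / (cpk[:, mask2].mean(axis=1) + 1.0))
    return pd.DataFrame(
        {
            "gene": list(counts.gene_symbols),
            "statistic": stats_out,
            "p_raw": pvals,
            "log2_fold_change": lfc,
        }
    )
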