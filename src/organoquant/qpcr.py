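"""Relative qPCR quantification by the 2^-ddCt method and summary statistics.

Technical replicates are averaged on the Ct scale, each gene is normalised
to a reference gene (ACTB by default) within the sample, and the resulting
dCt is referenced to the arithmetic-mean dCt of the control group.  The
amplification efficiency is fixed at 2 (no standard-curve correction).
Group summaries are mean +/- SEM with a two-sided unpaired equal-variance
Student's t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RelExpression", "delta_delta_ct", "group_stats", "two_sided_t_test"]

CT_COLUMNS = ["sample", "group", "gene", "replicate", "ct"]


@dataclass
class RelExpression:
    """2^-ddCt fold changes per sample x gene and group-level summaries.

    ``per_sample``: columns sample, group, gene, delta_ct, delta_delta_ct,
    fold_change.  ``per_group``: per group x gene mean, sem and, for the
    non-control group, t and p against the control group.
    """

    per_sample: pd.DataFrame
    per_group: pd.DataFrame
    reference_gene: str
    control_group: str


def _validate_ct_table(table: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    ct = table["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)) or (ct <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    for sample, sub in table.groupby("sample"):
        if reference_gene not in set(sub["gene"]):
            raise ValueError(f"reference gene {reference_gene!r} not measured in sample {sample!r}")
    return table


def delta_delta_ct(
    table: pd.DataFrame,
    reference_gene: str = "ACTB",
    control_group: str = "control",
) -> RelExpression:
    """Relative expression per sample and gene by 2^-ddCt.

    dCt = Ct(gene) - Ct(reference) per sample (technical replicates
    averaged first); ddCt = dCt - mean dCt of the control group for that
    gene; fold change = 2^-ddCt.
    """
    table = _validate_ct_table(table, reference_gene)
    if control_group not in set(table["group"]):
        raise ValueError(f"control group {control_group!r} not present in table")

    mean_ct = (
        table.groupby(["sample", "group", "gene"], sort=True)["ct"].mean().reset_index()
    )
    ref = (
        mean_ct[mean_ct["gene"] == reference_gene]
        .set_index("sample")["ct"]
        .rename("ref_ct")
    )
    merged = mean_ct.join(ref, on="sample")
    merged["delta_ct"] = merged["ct"] - merged["ref_ct"]

    control_baseline = (
        merged[merged["group"] == control_group].groupby("gene")["delta_ct"].mean()
    )
    merged = merged.join(control_baseline.rename("control_mean_delta_ct"), on="gene")
    merged["delta_delta_ct"] = merged["delta_ct"] - merged["control_mean_delta_ct"]
    merged["fold_change"] = 2.0 ** (-merged["delta_delta_ct"])

    per_sample = merged[
        ["sample", "group", "gene", "delta_ct", "delta_delta_ct", "fold_change"]
    ].sort_values(["gene", "group", "sample"], kind="stable").reset_index(drop=True)

    rows = []
    control_fc = per_sample[per_sample["group"] == control_group]
    for (group, gene), sub in per_sample.groupby(["group", "gene"], sort=True):
        fc = sub["fold_change"].to_numpy()
        mean, sem = group_stats(fc)
        row = {"group": group, "gene": gene, "n": len(fc), "mean": mean, "sem": sem}
        if group != control_group:
            ctrl = control_fc.loc[control_fc["gene"] == gene, "fold_change"].to_numpy()
            if len(fc) >= 2 and len(ctrl) >= 2:
                t, p = two_sided_t_test(fc, ctrl)
                row["t"], row["p"] = t, p
            else:
                warnings.warn(f"group with < 2 samples; t test omitted for gene {gene!r}")
                row["t"], row["p"] = np.nan, np.nan
        else:
            row["t"], row["p"] = np.nan, np.nan
        rows.append(row)
    per_group = pd.DataFrame(rows)
    return RelExpression(
        per_sample=per_sample,
        per_group=per_group,
        reference_gene=reference_gene,
        control_group=control_group,
    )


def group_stats(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sample sd / sqrt(n))."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("group_stats requires at least one value")
    if x.size == 1:
        warnings.warn("single observation; SEM reported as 0")
        return float(x[0]), 0.0
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))


def two_sided_t_test(group1, group2) -> tuple[float, float]:
    """Two-sided unpaired equal-variance Student's t test (df = n1 + n2 - 2)."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two_sided_t_test requires n >= 2 per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate pooled variance: no evidence either way when means agree
        return (0.0, 1.0) if a.mean() == b.mean() else (float(np.inf) * np.sign(a.mean() - b.mean()), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
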