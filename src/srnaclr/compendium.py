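"""Expression-matrix IO and compendium statistics.

The universal currency of the pipeline is a log2 expression matrix with
genes on the rows and arrays (hybridizations) on the columns, stored as a
:class:`pandas.DataFrame`.  Matrices must be complete (no missing values)
and carry unique identifiers on both axes.  This module reads and writes
them as TSV, merges experiment arrays into a reference compendium,
computes the per-gene standard deviation sigma that anchors the
compendium-referenced z statistic, and provides the row standardization
plus complete-linkage ordering used for heatmap-style reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "CompendiumStats",
    "read_expression_matrix",
    "write_expression_matrix",
    "validate_matrix",
    "merge_arrays",
    "per_gene_sd",
    "standardize_rows",
    "heatmap_order",
]


@dataclass(frozen=True)
class CompendiumStats:
    """Per-gene mean and sample standard deviation across a compendium.

    ``sigma`` uses the n-1 denominator.  Genes with zero variance are
    flagged: their sigma cannot serve as a z-score denominator and they
    are excluded (never silently dropped) from differential calling.
    """

    mean: pd.Series
    sigma: pd.Series
    zero_variance: pd.Index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.mean,
                "sigma": self.sigma,
                "zero_variance_flag": self.mean.index.isin(self.zero_variance),
            }
        ).rename_axis("gene_id")


def validate_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants; return the matrix unchanged."""
    dup_genes = m.index[m.index.duplicated()].unique().tolist()
    if dup_genes:
        raise ValueError(f"duplicate gene ids: {dup_genes}")
    dup_arrays = m.columns[m.columns.duplicated()].unique().tolist()
    if dup_arrays:
        raise ValueError(f"duplicate array ids: {dup_arrays}")
    if m.isna().any().any():
        bad = m.isna().stack()
        loc = bad[bad].index[0]
        raise ValueError(f"missing value at gene {loc[0]!r}, array {loc[1]!r}")
    non_numeric = [c for c in m.columns if not np.issubdtype(m[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric columns: {non_numeric}")
    return m


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-arrays TSV (first column gene id, header = array ids)."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    for col in m.columns:
        if not np.issubdtype(m[col].dtype, np.number):
            coerced = pd.to_numeric(m[col], errors="coerce")
            bad_rows = m.index[coerced.isna() & m[col].notna()].tolist()
            raise ValueError(
                f"non-numeric value in array {col!r} at gene(s) {bad_rows}"
            )
    return validate_matrix(m)


def write_expression_matrix(m: pd.DataFrame, path: str | Path) -> None:
    validate_matrix(m)
    m.rename_axis("gene_id").to_csv(path, sep="\t")


def merge_arrays(
    experiment: pd.DataFrame, compendium: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Concatenate experiment arrays onto a compendium.

    The merged gene set is the intersection of the two gene sets, in
    compendium order.  Returns ``(merged, dropped)`` where ``dropped``
    lists gene ids present in only one input.

    Raises on overlapping array ids or an empty gene intersection.
    """
    overlap = experiment.columns.intersection(compendium.columns)
    if len(overlap):
        raise ValueError(f"overlapping array ids: {overlap.tolist()}")
    shared = compendium.index[compendium.index.isin(experiment.index)]
    if shared.empty:
        raise ValueError("no genes shared between experiment and compendium")
    dropped = sorted(
        set(experiment.index).symmetric_difference(compendium.index)
    )
    merged = pd.concat(
        [compendium.loc[shared], experiment.loc[shared]], axis=1
    )
    return validate_matrix(merged), dropped


def per_gene_sd(m: pd.DataFrame) -> CompendiumStats:
    """Per-gene mean and sample SD (sigma) across all arrays of ``m``."""
    if m.shape[1] < 2:
        raise ValueError("sigma needs at least 2 arrays")
    values = m.to_numpy(dtype=float)
    mean = pd.Series(values.mean(axis=1), index=m.index)
    sd = values.std(axis=1, ddof=1)
    # a constant row has sigma exactly 0 by definition; float summation
    # of identical values can otherwise leave ~1e-15 residue
    sd[np.ptp(values, axis=1) == 0.0] = 0.0
    sigma = pd.Series(sd, index=m.index)
    zero = m.index[sigma == 0.0]
    return CompendiumStats(mean=mean, sigma=sigma, zero_variance=zero)


def standardize_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to mean 0 and unit sample variance.

    Constant rows cannot be standardized; they raise with the offending
    gene ids listed.
    """
    values = m.to_numpy(dtype=float)
    raw = values.std(axis=1, ddof=1)
    raw[np.ptp(values, axis=1) == 0.0] = 0.0
    sd = pd.Series(raw, index=m.index)
    constant = m.index[(sd == 0.0) | sd.isna()].tolist()
    if constant:
        raise ValueError(f"constant rows cannot be standardized: {constant}")
    return m.sub(m.mean(axis=1), axis=0).div(sd, axis=0)


def heatmap_order(m: pd.DataFrame) -> tuple[list[int], list[int]]:
    """Leaf orders of complete-linkage dendrograms on Euclidean distances.

    Rows are standardized (zero mean, unit variance per row) before
    either axis is clustered; columns are clustered on the
    row-standardized values without any column-wise scaling.  Returns
    ``(row_order, col_order)`` as permutations of the input indices.
    """
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("heatmap ordering needs at least 2 rows and 2 columns")
    z = standardize_rows(m).to_numpy()
    row_order = leaves_list(linkage(pdist(z), method="complete")).tolist()
    col_order = leaves_list(linkage(pdist(z.T), method="complete")).tolist()
    return row_order, col_order
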