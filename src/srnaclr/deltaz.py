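"""Compendium-referenced differential expression (the delta-Z statistic).

For a gene g with mean expression Xt over treatment arrays and Xc over
control arrays, dz_g = (Xt_g - Xc_g) / sigma_g, where sigma_g is the
gene's standard deviation across the entire reference compendium.  A
gene is called up when dz > tau and down when dz < -tau (strictly; the
default tau is 1 SD unit).  Genes whose compendium variance is zero are
reported as ``excluded`` rather than dropped.

The experiment contrasts a wild-type strain with a ybeY deletion, each
untreated or hydroxyurea (HU) treated, giving four standard comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compendium import CompendiumStats

__all__ = [
    "ComparisonDesign",
    "STANDARD_COMPARISONS",
    "condition_mean",
    "delta_z",
    "call_differential",
    "run_comparisons",
    "summarize_calls",
]

#: Labels of the four genotype-by-treatment contrasts, in canonical order:
#: knockout baseline effect, HU response per genotype, genotype contrast
#: under HU.
STANDARD_COMPARISONS = (
    "dYbeY-Unt_vs_WT-Unt",
    "WT-HU_vs_WT-Unt",
    "dYbeY-HU_vs_dYbeY-Unt",
    "dYbeY-HU_vs_WT-HU",
)

CALL_CATEGORIES = ("up", "down", "ns", "excluded")


@dataclass(frozen=True)
class ComparisonDesign:
    """Named treatment/control split of array ids for one contrast."""

    label: str
    treatment_arrays: tuple[str, ...]
    control_arrays: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.treatment_arrays or not self.control_arrays:
            raise ValueError(f"{self.label}: empty treatment or control set")
        if set(self.treatment_arrays) & set(self.control_arrays):
            raise ValueError(f"{self.label}: treatment and control overlap")

    def swapped(self) -> "ComparisonDesign":
        return ComparisonDesign(
            label=f"{self.label}:swapped",
            treatment_arrays=self.control_arrays,
            control_arrays=self.treatment_arrays,
        )


def condition_mean(m: pd.DataFrame, ids) -> pd.Series:
    """Arithmetic per-gene mean over the named arrays (replicate average)."""
    ids = list(ids)
    if not ids:
        raise ValueError("empty array id set")
    unknown = [a for a in ids if a not in m.columns]
    if unknown:
        raise ValueError(f"unknown array ids: {unknown}")
    return m[ids].mean(axis=1)


def delta_z(
    t_mean: pd.Series, c_mean: pd.Series, stats: CompendiumStats
) -> pd.Series:
    """dz = (Xt - Xc) / sigma per gene; NaN where sigma is zero."""
    if not t_mean.index.equals(c_mean.index):
        raise ValueError("treatment and control gene sets differ")
    if not t_mean.index.equals(stats.sigma.index):
        raise ValueError("gene set does not match compendium stats")
    with np.errstate(divide="ignore", invalid="ignore"):
        dz = (t_mean - c_mean) / stats.sigma.replace(0.0, np.nan)
    return dz


def call_differential(dz: pd.Series, tau: float = 1.0) -> pd.Series:
    """Strict-threshold calls: up iff dz > tau, down iff dz < -tau.

    dz exactly equal to tau is not significant.  NaN dz (zero-sigma
    genes) map to ``excluded``.
    """
    calls = pd.Series("ns", index=dz.index, dtype=object)
    calls[dz > tau] = "up"
    calls[dz < -tau] = "down"
    calls[dz.isna()] = "excluded"
    return pd.Categorical(calls, categories=CALL_CATEGORIES)


def run_comparisons(
    m: pd.DataFrame,
    stats: CompendiumStats,
    designs: list[ComparisonDesign],
    tau: float = 1.0,
) -> pd.DataFrame:
    """Score every gene in every comparison.

    Returns a long-form table with one row per (gene, comparison):
    columns ``gene_id``, ``comparison``, ``dz``, ``call``.
    """
    frames = []
    for design in designs:
        t = condition_mean(m, design.treatment_arrays)
        c = condition_mean(m, design.control_arrays)
        dz = delta_z(t, c, stats)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": m.index,
                    "comparison": design.label,
                    "dz": dz.to_numpy(),
                    "call": call_differential(dz, tau=tau),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def summarize_calls(dz_table: pd.DataFrame) -> pd.DataFrame:
    """Per-comparison up/down/ns/excluded counts (summary-table shape).

    ``n_total`` counts significant genes only (up + down), mirroring the
    convention of reporting totals of differentially regulated genes.
    """
    rows = []
    for label, grp in dz_table.groupby("comparison", sort=False, observed=True):
        counts = grp["call"].value_counts()
        up = int(counts.get("up", 0))
        down = int(counts.get("down", 0))
        rows.append(
            {
                "comparison": label,
                "n_up": up,
                "n_down": down,
                "n_total": up + down,
                "n_ns": int(counts.get("ns", 0)),
                "n_excluded": int(counts.get("excluded", 0)),
            }
        )
    return pd.DataFrame(rows)
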