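"""Synthetic expression compendia with planted, signed sRNA regulons.

The generator emulates the data the pipeline was designed for: a large
RMA-like log2 compendium collected across heterogeneous conditions, and
a small controlled experiment contrasting wild type with a ybeY
knockout, untreated vs hydroxyurea (HU) treated, in replicate.

Generative model (all on the log2 scale)
----------------------------------------
sRNA s in compendium array a:
    x_sa = b_s + c_sa + e_sa,      c ~ N(0, condition_factor_sd),
                                   e ~ N(0, noise_sd)
target gene g with planted regulators R(g):
    x_ga = b_g + sum_{s in R(g)} sign_sg * beta_sg * (x_sa - b_s) + e_ga
unregulated gene g:
    x_ga = b_g + c_ga + e_ga

sRNA expression is generated first; targets are linear functions of the
realized sRNA deviations, which makes correlation/MI recovery of the
planted edges analyzable.  YbeY dependence is modeled as a genotype x
treatment interaction: in knockout+HU arrays a YbeY-dependent sRNA's
mean is shifted by +-``interaction_shift``, and the shift propagates to
its targets through the planted edges.  Hfq labels are decorative truth
metadata for partition testing.

A single master seed drives everything; the edge structure, the
compendium and the experiment each consume an independent sub-stream,
so regenerating the experiment never perturbs the compendium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .deltaz import ComparisonDesign, STANDARD_COMPARISONS

__all__ = [
    "SyntheticTruth",
    "generate_compendium",
    "generate_experiment",
    "truth_edge_table",
    "write_truth",
]

GENOTYPES = ("WT", "dYbeY")
TREATMENTS = ("Unt", "HU")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset.

    ``edges`` holds (srna_id, gene_id, sign, beta) for every planted
    interaction, sign +1 = activation, -1 = repression.  Baselines and
    interaction signs are retained so the experiment can be regenerated
    deterministically from the same config.
    """

    edges: list[tuple[str, str, int, float]]
    ybey_dependent_srnas: set[str]
    hfq_dependent_srnas: set[str]
    condition_assignments: dict[str, tuple[str, str]] = field(default_factory=dict)
    baselines: pd.Series | None = None
    interaction_signs: dict[str, int] = field(default_factory=dict)
    srna_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)


def _streams(cfg: GeneratorConfig) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(cfg.rng_seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _plant_structure(cfg: GeneratorConfig, rng: np.random.Generator) -> SyntheticTruth:
    width = max(4, len(str(cfg.n_genes)))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    srna_ids = [f"srna{i:03d}" for i in range(1, cfg.n_srnas + 1)]

    baselines = pd.Series(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes + cfg.n_srnas),
        index=gene_ids + srna_ids,
    )

    lo, hi = cfg.targets_per_srna
    edges: list[tuple[str, str, int, float]] = []
    for s in srna_ids:
        k = int(rng.integers(lo, hi + 1))
        k = min(k, cfg.n_genes)
        targets = rng.choice(cfg.n_genes, size=k, replace=False)
        for t in targets:
            sign = 1 if rng.random() < cfg.activation_fraction else -1
            edges.append((s, gene_ids[t], sign, cfg.effect_size_beta))

    ybey = {s for s in srna_ids if rng.random() < cfg.ybey_dependent_srna_fraction}
    hfq = {s for s in srna_ids if rng.random() < cfg.hfq_dependent_srna_fraction}
    interaction_signs = {s: (1 if rng.random() < 0.5 else -1) for s in srna_ids}

    return SyntheticTruth(
        edges=edges,
        ybey_dependent_srnas=ybey,
        hfq_dependent_srnas=hfq,
        baselines=baselines,
        interaction_signs=interaction_signs,
        srna_ids=srna_ids,
        gene_ids=gene_ids,
    )


def _assemble_matrix(
    cfg: GeneratorConfig,
    truth: SyntheticTruth,
    srna_expr: np.ndarray,
    gene_condition: np.ndarray,
    gene_noise: np.ndarray,
    array_ids: list[str],
) -> pd.DataFrame:
    """Build the full matrix given realized sRNA rows and per-gene terms.

    ``gene_condition`` supplies the condition effect for unregulated
    genes; regulated genes replace it with the propagated sRNA signal.
    """
    b = truth.baselines
    srna_index = {s: i for i, s in enumerate(truth.srna_ids)}
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}

    srna_dev = srna_expr - b[truth.srna_ids].to_numpy()[:, None]
    genes = b[truth.gene_ids].to_numpy()[:, None] + gene_condition + gene_noise
    regulated = np.zeros(cfg.n_genes, dtype=bool)
    signal = np.zeros_like(gene_condition)
    for s, g, sign, beta in truth.edges:
        gi = gene_index[g]
        regulated[gi] = True
        signal[gi] += sign * beta * srna_dev[srna_index[s]]
    # planted targets carry the propagated signal in place of their own
    # condition effect
    genes[regulated] = (
        b[truth.gene_ids].to_numpy()[regulated, None]
        + signal[regulated]
        + gene_noise[regulated]
    )
    values = np.vstack([genes, srna_expr])
    return pd.DataFrame(values, index=truth.gene_ids + truth.srna_ids, columns=array_ids)


def generate_compendium(cfg: GeneratorConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the reference compendium and its ground truth.

    Returns a (n_genes + n_srnas) x n_compendium_arrays log2 matrix and
    the :class:`SyntheticTruth` describing every planted edge.  Output
    is bit-identical for identical config (the seed is part of it).
    """
    structure_rng, comp_rng, _ = _streams(cfg)
    truth = _plant_structure(cfg, structure_rng)

    n_arr = cfg.n_compendium_arrays
    array_ids = [f"comp{i:04d}" for i in range(1, n_arr + 1)]
    b_srna = truth.baselines[truth.srna_ids].to_numpy()[:, None]
    srna_expr = (
        b_srna
        + comp_rng.normal(0.0, cfg.condition_factor_sd, (cfg.n_srnas, n_arr))
        + comp_rng.normal(0.0, cfg.noise_sd, (cfg.n_srnas, n_arr))
    )
    gene_condition = comp_rng.normal(0.0, cfg.condition_factor_sd, (cfg.n_genes, n_arr))
    gene_noise = comp_rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, n_arr))
    matrix = _assemble_matrix(cfg, truth, srna_expr, gene_condition, gene_noise, array_ids)
    return matrix, truth


def generate_experiment(
    truth: SyntheticTruth, cfg: GeneratorConfig
) -> tuple[pd.DataFrame, list[ComparisonDesign]]:
    """Generate the 2 genotype x 2 treatment x n_replicates experiment.

    Every sRNA receives a random HU response (shared by both genotypes);
    sRNAs flagged YbeY-dependent receive an additional genotype x
    treatment interaction shift of magnitude ``cfg.interaction_shift``
    in knockout+HU arrays only.  Both propagate to targets through the
    planted edges.  Unregulated genes vary only by replicate noise.

    Returns the experiment matrix and the four standard comparisons.
    """
    if cfg.n_replicates < 2:
        warnings.warn(
            "n_replicates < 2: replicate means degenerate to single arrays",
            stacklevel=2,
        )
    _, _, exp_rng = _streams(cfg)

    array_ids: list[str] = []
    assignments: dict[str, tuple[str, str]] = {}
    for geno in GENOTYPES:
        for trt in TREATMENTS:
            for rep in range(1, cfg.n_replicates + 1):
                aid = f"{geno}_{trt}_r{rep}"
                array_ids.append(aid)
                assignments[aid] = (geno, trt)
    n_arr = len(array_ids)

    hu_response = exp_rng.normal(0.0, cfg.condition_factor_sd, cfg.n_srnas)
    is_hu = np.array([assignments[a][1] == "HU" for a in array_ids])
    is_ko_hu = np.array(
        [assignments[a] == ("dYbeY", "HU") for a in array_ids]
    )

    b_srna = truth.baselines[truth.srna_ids].to_numpy()[:, None]
    srna_expr = b_srna + np.zeros((cfg.n_srnas, n_arr))
    srna_expr += np.outer(hu_response, is_hu.astype(float))
    for i, s in enumerate(truth.srna_ids):
        if s in truth.ybey_dependent_srnas:
            shift = truth.interaction_signs[s] * cfg.interaction_shift
            srna_expr[i, is_ko_hu] += shift
    srna_expr += exp_rng.normal(0.0, cfg.noise_sd, (cfg.n_srnas, n_arr))

    gene_condition = np.zeros((cfg.n_genes, n_arr))
    gene_noise = exp_rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, n_arr))
    matrix = _assemble_matrix(cfg, truth, srna_expr, gene_condition, gene_noise, array_ids)

    truth.condition_assignments = assignments

    def cell(geno: str, trt: str) -> tuple[str, ...]:
        return tuple(a for a in array_ids if assignments[a] == (geno, trt))

    designs = [
        ComparisonDesign(STANDARD_COMPARISONS[0], cell("dYbeY", "Unt"), cell("WT", "Unt")),
        ComparisonDesign(STANDARD_COMPARISONS[1], cell("WT", "HU"), cell("WT", "Unt")),
        ComparisonDesign(STANDARD_COMPARISONS[2], cell("dYbeY", "HU"), cell("dYbeY", "Unt")),
        ComparisonDesign(STANDARD_COMPARISONS[3], cell("dYbeY", "HU"), cell("WT", "HU")),
    ]
    return matrix, designs


def truth_edge_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Planted edges as a signed target catalog (source = 'synthetic')."""
    return pd.DataFrame(
        [
            {
                "srna_name": s,
                "target_gene": g,
                "sign": "activation" if sign > 0 else "repression",
                "source": "synthetic",
            }
            for s, g, sign, _beta in truth.edges
        ],
        columns=["srna_name", "target_gene", "sign", "source"],
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write the truth edge table plus per-sRNA flags as TSV."""
    table = truth_edge_table(truth)
    table["ybey_dependent"] = table["srna_name"].isin(truth.ybey_dependent_srnas)
    table["hfq_dependent"] = table["srna_name"].isin(truth.hfq_dependent_srnas)
    table.to_csv(path, sep="\t", index=False)
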