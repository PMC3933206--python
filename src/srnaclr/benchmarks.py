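"""Benchmark scenarios on synthetic data with planted regulons.

These are the package's standing evaluation harnesses: a null
compendium for false-discovery control of the CLR network, a planted
genome-scale regulon for edge recovery and sign concordance, and a
four-condition experiment for YbeY-dependence classification recall.
Scenario parameters are fixed study conditions, not tuning knobs: 20
sRNAs against a genome-scale mRNA background, 100 compendium arrays,
log2 effect sizes at a signal-to-noise ratio of about 4 against
measurement noise (beta = 1, noise_sd = 0.25), and 2x2x3 experiments.

Every function takes a seed and returns plain dictionaries of metrics,
so the same scenarios back both the test suite and the acceptance
report.
"""

from __future__ import annotations

import numpy as np

from . import catalog as cat
from . import clr
from . import compendium as comp
from . import deltaz as dz
from . import synthetic as syn
from .config import GeneratorConfig

__all__ = [
    "null_network_fraction",
    "planted_recovery",
    "classification_recall",
]


def _null_config(seed: int) -> GeneratorConfig:
    return GeneratorConfig(
        n_genes=200,
        n_srnas=20,
        n_compendium_arrays=100,
        targets_per_srna=(0, 0),
        rng_seed=seed,
    )


def _planted_config(seed: int) -> GeneratorConfig:
    # all sRNAs YbeY-dependent so every regulon is perturbed in the
    # experiment; genome-scale background keeps regulon overlap rare
    return GeneratorConfig(
        n_genes=2000,
        n_srnas=20,
        n_compendium_arrays=100,
        targets_per_srna=(10, 10),
        effect_size_beta=1.0,
        noise_sd=0.25,
        condition_factor_sd=1.0,
        ybey_dependent_srna_fraction=1.0,
        rng_seed=seed,
    )


def _experiment_config(seed: int) -> GeneratorConfig:
    return GeneratorConfig(
        n_genes=200,
        n_srnas=20,
        n_compendium_arrays=100,
        targets_per_srna=(1, 10),
        ybey_dependent_srna_fraction=0.5,
        rng_seed=seed,
    )


def null_network_fraction(seed: int, n_perm: int = 20, q_threshold: float = 0.005) -> float:
    """Fraction of candidate edges called at q < threshold on a null compendium.

    No edges are planted, so every call is a false discovery; under
    honest FDR control the fraction should be near zero.
    """
    cfg = _null_config(seed)
    m, truth = syn.generate_compendium(cfg)
    net = clr.build_network(
        m, truth.srna_ids, n_perm=n_perm, seed=seed + 1, q_threshold=q_threshold
    )
    return float(net["significant"].mean())


def planted_recovery(
    seed: int,
    n_perm: int = 10,
    q_threshold: float = 0.005,
    include_network: bool = True,
) -> dict:
    """Recover a planted 20-sRNA x 10-target regulon at genome scale.

    Returns AUPR/precision/recall of the CLR network against the
    planted edges, the candidate-pair prevalence, and the
    sign-concordance recall (planted pairs scored concordant in at
    least one of the four comparisons).  ``include_network=False``
    skips the CLR stage and reports concordance only.
    """
    cfg = _planted_config(seed)
    m, truth = syn.generate_compendium(cfg)
    exp, designs = syn.generate_experiment(truth, cfg)
    merged, _ = comp.merge_arrays(exp, m)
    stats = comp.per_gene_sd(merged)
    dzt = dz.run_comparisons(merged[list(exp.columns)], stats, designs)

    metrics: dict = {}
    if include_network:
        net = clr.build_network(
            merged, truth.srna_ids, n_perm=n_perm, seed=seed + 1, q_threshold=q_threshold
        )
        metrics = clr.evaluate_recovery(net, truth.edges, q_threshold=q_threshold)

    conc = cat.sign_concordance(dzt, syn.truth_edge_table(truth))
    metrics["concordance_recall"] = cat.concordant_pair_count(conc) / len(truth.edges)
    return metrics


def classification_recall(seeds: list[int]) -> float:
    """Recall of planted YbeY-dependent flags by the call-table classifier.

    Each seed generates a fresh compendium + experiment; the classifier
    sees only the four-comparison dz call table.
    """
    hits = total = 0
    for seed in seeds:
        cfg = _experiment_config(seed)
        m, truth = syn.generate_compendium(cfg)
        exp, designs = syn.generate_experiment(truth, cfg)
        merged, _ = comp.merge_arrays(exp, m)
        stats = comp.per_gene_sd(merged)
        dzt = dz.run_comparisons(merged[list(exp.columns)], stats, designs)
        cls = cat.classify_ybey_dependence(dzt, truth.srna_ids)
        planted = cls["srna"].isin(truth.ybey_dependent_srnas).to_numpy()
        hits += int(((cls["category"] == "ybey_dependent").to_numpy() & planted).sum())
        total += int(planted.sum())
    return hits / total if total else float("nan")
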