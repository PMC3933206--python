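"""End-to-end orchestration: data -> sigma -> dz -> classification -> network.

One :class:`~srnaclr.config.PipelineConfig` drives the whole analysis:
generate (or load) an expression compendium and a four-condition
experiment, merge them, compute per-gene sigma, score the four
genotype x treatment comparisons, classify sRNA YbeY dependence,
infer the CLR network with permutation FDR, extract per-Hfq-partition
seed subnetworks, and score sign concordance of cataloged pairs.  All
stage outputs are written as TSV under one output directory together
with a checksum manifest and the resolved config, so a run is fully
reproducible and each stage is re-runnable from its intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import catalog as cat
from . import clr
from . import compendium as comp
from . import deltaz as dz
from . import synthetic as syn
from .config import PipelineConfig

__all__ = ["ReportBundle", "run_pipeline", "export_tables"]

log = logging.getLogger("srnaclr")


@dataclass
class ReportBundle:
    """Paths and in-memory results of one pipeline run."""

    outdir: Path
    config: PipelineConfig
    deltaz_table: pd.DataFrame
    summary: pd.DataFrame
    srna_summary: pd.DataFrame
    classification: pd.DataFrame
    network: pd.DataFrame
    concordance: pd.DataFrame
    recovery: dict | None
    files: dict[str, Path] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: PipelineConfig):
    """Return (experiment, compendium, designs, srna_ids, target_catalog, truth)."""
    if cfg.mode == "synthetic":
        gen = cfg.generator
        compendium, truth = syn.generate_compendium(gen)
        experiment, designs = syn.generate_experiment(truth, gen)
        target_catalog = syn.truth_edge_table(truth)
        srna_ids = list(truth.srna_ids)
        return experiment, compendium, designs, srna_ids, target_catalog, truth

    experiment = comp.read_expression_matrix(cfg.expression_path)
    compendium = comp.read_expression_matrix(cfg.compendium_path)
    design_df = pd.read_csv(cfg.design_path, sep="\t", dtype=str)
    designs = []
    for label, grp in design_df.groupby("comparison", sort=False):
        designs.append(
            dz.ComparisonDesign(
                label=label,
                treatment_arrays=tuple(grp.loc[grp["role"] == "treatment", "array_id"]),
                control_arrays=tuple(grp.loc[grp["role"] == "control", "array_id"]),
            )
        )
    if cfg.srna_catalog_path:
        records = cat.read_srna_catalog(cfg.srna_catalog_path)
        alias_table = {r.canonical_name: set(r.aliases) for r in records}
        mapped, unmapped = cat.resolve_srna_names(
            list(alias_table), alias_table, experiment
        )
        if unmapped:
            log.info("undetectable sRNAs (no matrix id): %s", unmapped)
        srna_ids = [r.gene_id for r in mapped]
    else:
        srna_ids = []
    target_catalog = (
        cat.read_target_catalog(cfg.target_catalog_path)
        if cfg.target_catalog_path
        else pd.DataFrame(columns=["srna_name", "target_gene", "sign", "source"])
    )
    return experiment, compendium, designs, srna_ids, target_catalog, None


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute every stage and write the report bundle to ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def save(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        files[name] = path
        return path

    experiment, compendium, designs, srna_ids, target_catalog, truth = _load_inputs(cfg)
    log.info(
        "inputs: experiment %s, compendium %s, %d sRNAs, %d catalog pairs",
        experiment.shape, compendium.shape, len(srna_ids), len(target_catalog),
    )
    save("experiment.tsv", lambda p: comp.write_expression_matrix(experiment, p))
    save("compendium.tsv", lambda p: comp.write_expression_matrix(compendium, p))
    save(
        "design.tsv",
        lambda p: pd.DataFrame(
            [
                {"comparison": d.label, "role": role, "array_id": a}
                for d in designs
                for role, ids in (
                    ("treatment", d.treatment_arrays),
                    ("control", d.control_arrays),
                )
                for a in ids
            ]
        ).to_csv(p, sep="\t", index=False),
    )
    if truth is not None:
        save("truth_edges.tsv", lambda p: syn.write_truth(truth, p))

    # sigma over the combined compendium + experiment arrays
    merged, dropped = comp.merge_arrays(experiment, compendium)
    if dropped:
        log.info("genes dropped in merge: %d", len(dropped))
    stats = comp.per_gene_sd(merged)
    if len(stats.zero_variance):
        log.info("zero-variance genes excluded from calling: %d", len(stats.zero_variance))
    save("compendium_stats.tsv", lambda p: stats.to_frame().to_csv(p, sep="\t"))

    dz_table = dz.run_comparisons(merged.loc[:, experiment.columns], stats, designs, tau=cfg.tau)
    summary = dz.summarize_calls(dz_table)
    save("deltaz.tsv", lambda p: dz_table.to_csv(p, sep="\t", index=False))
    save("deltaz_summary.tsv", lambda p: summary.to_csv(p, sep="\t", index=False))
    log.info("differential calls per comparison:\n%s", summary)

    srna_ids = [s for s in srna_ids if s in merged.index]
    srna_dz = dz_table[dz_table["gene_id"].isin(srna_ids)]
    srna_summary = dz.summarize_calls(srna_dz)
    save("srna_summary.tsv", lambda p: srna_summary.to_csv(p, sep="\t", index=False))

    classification = cat.classify_ybey_dependence(dz_table, srna_ids)
    if truth is not None:
        classification["planted_ybey_dependent"] = classification["srna"].isin(
            truth.ybey_dependent_srnas
        )
    save("ybey_classification.tsv", lambda p: classification.to_csv(p, sep="\t", index=False))

    if srna_ids:
        network = clr.build_network(
            merged,
            srna_ids,
            n_perm=cfg.n_permutations,
            seed=cfg.rng_seed,
            bins=cfg.mi_bins,
            q_threshold=cfg.q_threshold,
        )
    else:
        log.info("no resolvable sRNA regulators; network stage skipped")
        network = pd.DataFrame(
            {
                "srna": pd.Series(dtype=str),
                "gene": pd.Series(dtype=str),
                **{
                    c: pd.Series(dtype=float)
                    for c in ("mi", "z_reg", "z_tgt", "score", "p", "q")
                },
                "significant": pd.Series(dtype=bool),
            }
        )
    network = clr.annotate_validated(network, target_catalog)
    significant = network[network["significant"]]
    log.info("network: %d candidate edges, %d at q < %g",
             len(network), len(significant), cfg.q_threshold)
    save("network_edges.tsv", lambda p: clr.write_edge_list(significant, p))
    save("network.sif", lambda p: clr.write_sif(significant, p))
    save("network.graphml", lambda p: clr.write_graphml(significant, p))

    # seed subnetworks per Hfq partition (synthetic truth supplies flags)
    if truth is not None:
        dep_seeds = [s for s in srna_ids if s in truth.hfq_dependent_srnas]
        indep_seeds = [s for s in srna_ids if s not in truth.hfq_dependent_srnas]
        save(
            "subnetwork_hfq_dependent.tsv",
            lambda p: clr.write_edge_list(
                clr.extract_seed_subnetwork(significant, dep_seeds), p
            ),
        )
        save(
            "subnetwork_hfq_independent.tsv",
            lambda p: clr.write_edge_list(
                clr.extract_seed_subnetwork(significant, indep_seeds), p
            ),
        )

    concordance = cat.sign_concordance(
        dz_table,
        target_catalog,
        cat.ConcordancePolicy(tau_srna=cfg.tau, tau_target=cfg.tau),
    )
    save("concordance.tsv", lambda p: concordance.to_csv(p, sep="\t", index=False))
    log.info("concordant unique pairs: %d", cat.concordant_pair_count(concordance))

    recovery = None
    if truth is not None and truth.edges:
        recovery = clr.evaluate_recovery(network, truth.edges, q_threshold=cfg.q_threshold)
        save(
            "recovery.json",
            lambda p: p.write_text(json.dumps(recovery, indent=2) + "\n"),
        )
        log.info("planted-edge recovery: %s", recovery)

    # heatmap row/column orders for the sRNA block of the experiment
    srna_block = experiment.loc[[s for s in srna_ids if s in experiment.index]]
    variable = srna_block.index[srna_block.std(axis=1, ddof=1) > 0]
    if len(variable) >= 2 and srna_block.shape[1] >= 2:
        row_order, col_order = comp.heatmap_order(srna_block.loc[variable])
        save(
            "heatmap_orders.tsv",
            lambda p: pd.DataFrame(
                {
                    "axis": ["row"] * len(row_order) + ["col"] * len(col_order),
                    "position": list(range(len(row_order))) + list(range(len(col_order))),
                    "index": row_order + col_order,
                }
            ).to_csv(p, sep="\t", index=False),
        )

    save(
        "config.json",
        lambda p: p.write_text(json.dumps(cfg.to_dict(), indent=2, default=str) + "\n"),
    )

    manifest = {name: _sha256(path) for name, path in sorted(files.items())}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    files["manifest.json"] = manifest_path

    return ReportBundle(
        outdir=outdir,
        config=cfg,
        deltaz_table=dz_table,
        summary=summary,
        srna_summary=srna_summary,
        classification=classification,
        network=network,
        concordance=concordance,
        recovery=recovery,
        files=files,
        manifest=manifest,
    )


def export_tables(bundle: ReportBundle, formats: list[str] | None = None) -> dict[str, Path]:
    """Re-export the two summary tables (and network formats) on demand.

    The gene-level summary has one row per comparison with columns
    (comparison, n_up, n_down, n_total), total = up + down; the sRNA
    summary is the same shape restricted to mapped sRNAs.
    """
    formats = formats or ["tsv"]
    unknown = [f for f in formats if f not in ("tsv", "sif", "graphml")]
    if unknown:
        raise ValueError(f"unknown export formats: {unknown}")
    out: dict[str, Path] = {}
    if "tsv" in formats:
        for name, frame in (
            ("summary_genes.tsv", bundle.summary),
            ("summary_srnas.tsv", bundle.srna_summary),
        ):
            path = bundle.outdir / name
            frame[["comparison", "n_up", "n_down", "n_total"]].to_csv(
                path, sep="\t", index=False
            )
            out[name] = path
    significant = bundle.network[bundle.network["significant"]]
    if "sif" in formats:
        path = bundle.outdir / "network_export.sif"
        clr.write_sif(significant, path)
        out["network_export.sif"] = path
    if "graphml" in formats:
        path = bundle.outdir / "network_export.graphml"
        clr.write_graphml(significant, path)
        out["network_export.graphml"] = path
    return out
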