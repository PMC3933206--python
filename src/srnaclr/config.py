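"""Configuration objects for the synthetic generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["GeneratorConfig", "PipelineConfig"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic compendium/experiment generator.

    Defaults emulate the scale of the real study: a reference compendium
    of 759 heterogeneous arrays over an E. coli-sized gene complement,
    54 detectable sRNAs, and a 2-genotype x 2-treatment x 3-replicate
    experiment.  All expression values are on the log2 scale.

    Parameters
    ----------
    n_genes
        Number of mRNA rows.
    n_srnas
        Number of sRNA rows (regulators); must be < ``n_genes``.
    n_compendium_arrays
        Columns of the reference compendium.
    n_replicates
        Biological replicates per genotype-by-treatment cell.
    targets_per_srna
        (min, max) of the per-sRNA target count, drawn uniformly.
    activation_fraction
        Probability a planted edge is activating (+1); the remainder
        repress (-1).  Bacterial sRNAs mostly repress, hence < 0.5.
    effect_size_beta
        log2 change in a target per unit deviation of its sRNA.
    noise_sd
        Measurement noise SD, log2 units.
    baseline_mean, baseline_sd
        Distribution of per-row baseline log2 intensity.
    condition_factor_sd
        SD of the per-(row, array) condition effect in the compendium,
        i.e. biological variability across heterogeneous conditions.
    ybey_dependent_srna_fraction
        Probability an sRNA's HU response requires YbeY (modeled as a
        genotype-by-treatment interaction on the sRNA mean).
    hfq_dependent_srna_fraction
        Probability an sRNA is labeled Hfq-dependent (a decorative
        truth label used for partition testing; does not alter the
        generative model).
    ybey_interaction_shift
        Magnitude (log2) of the interaction shift applied to
        YbeY-dependent sRNAs in knockout+HU arrays; defaults to
        3 * ``effect_size_beta`` when None.
    rng_seed
        Master seed; compendium and experiment use independent
        sub-streams derived from it.
    """

    n_genes: int = 4300
    n_srnas: int = 54
    n_compendium_arrays: int = 759
    n_replicates: int = 3
    targets_per_srna: tuple[int, int] = (1, 10)
    activation_fraction: float = 0.3
    effect_size_beta: float = 1.0
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    condition_factor_sd: float = 1.0
    ybey_dependent_srna_fraction: float = 0.5
    hfq_dependent_srna_fraction: float = 0.43
    ybey_interaction_shift: Optional[float] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_srnas", "n_compendium_arrays", "n_replicates"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "activation_fraction",
            "ybey_dependent_srna_fraction",
            "hfq_dependent_srna_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("noise_sd", "baseline_sd", "condition_factor_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.targets_per_srna
        if lo < 0 or hi < lo:
            raise ValueError("targets_per_srna must satisfy 0 <= min <= max")
        if self.n_srnas >= self.n_genes:
            raise ValueError("n_srnas must be < n_genes")
        if self.ybey_interaction_shift is not None and self.ybey_interaction_shift < 0:
            raise ValueError("ybey_interaction_shift must be >= 0")

    @property
    def interaction_shift(self) -> float:
        if self.ybey_interaction_shift is not None:
            return self.ybey_interaction_shift
        return 3.0 * self.effect_size_beta

    def to_dict(self) -> dict:
        d = asdict(self)
        d["targets_per_srna"] = list(self.targets_per_srna)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "targets_per_srna" in d:
            d["targets_per_srna"] = tuple(d["targets_per_srna"])
        return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration.

    Exactly one input mode: ``synthetic`` (the generator supplies the
    compendium, experiment and truth catalogs) or ``files`` (paths to
    pre-normalized TSV matrices and catalogs).
    """

    mode: str = "synthetic"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    expression_path: Optional[str] = None
    compendium_path: Optional[str] = None
    design_path: Optional[str] = None
    srna_catalog_path: Optional[str] = None
    target_catalog_path: Optional[str] = None
    tau: float = 1.0
    q_threshold: float = 0.005
    mi_bins: int = 10
    n_permutations: int = 10
    rng_seed: int = 0
    outdir: str = "srnaclr_out"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files":
            missing = [
                n
                for n in ("expression_path", "compendium_path", "design_path")
                if getattr(self, n) is None
            ]
            if missing:
                raise ValueError(f"files mode requires: {missing}")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must be in (0, 1]")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
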