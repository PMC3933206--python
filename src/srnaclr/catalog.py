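"""sRNA identity resolution, dependence classification and concordance.

Bacterial sRNA nomenclature is not standardized (the signal-recognition
particle RNA, for example, is listed both as Ffs and 4.5S), so catalog
names are matched onto expression-matrix identifiers case-insensitively
through an alias table.  Resolved sRNAs are classified as YbeY-dependent
from their differential-expression calls across the four genotype x
treatment comparisons, partitioned by Hfq dependence, and known signed
sRNA->target pairs are scored for sign concordance against the dz
table: a repressed target should move opposite to its sRNA, an
activated target in the same direction.

The packaged reference tables transcribe the published per-comparison
sRNA lists and Hfq classifications for this study system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .deltaz import STANDARD_COMPARISONS

__all__ = [
    "SrnaRecord",
    "ConcordancePolicy",
    "read_srna_catalog",
    "read_target_catalog",
    "load_reported_srna_calls",
    "load_hfq_classes",
    "load_srnas_with_targets",
    "resolve_srna_names",
    "classify_ybey_dependence",
    "partition_by_hfq",
    "sign_concordance",
    "concordant_pair_count",
]


@dataclass(frozen=True)
class SrnaRecord:
    """One sRNA: canonical name, aliases, matrix id (if detectable), Hfq flag."""

    canonical_name: str
    aliases: frozenset[str] = frozenset()
    gene_id: Optional[str] = None
    hfq_dependent: Optional[bool] = None


@dataclass(frozen=True)
class ConcordancePolicy:
    """Gating policy for sign-concordance scoring.

    Both the sRNA and the target must exceed their |dz| thresholds for a
    pair to be scored (``require_both_significant``); pairs failing the
    gate are reported as not counted rather than discordant.
    """

    tau_srna: float = 1.0
    tau_target: float = 1.0
    require_both_significant: bool = True


def _parse_hfq(v) -> Optional[bool]:
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    return None


def read_srna_catalog(path) -> list[SrnaRecord]:
    """Read an sRNA catalog TSV: canonical_name, aliases (;-sep), hfq_dependent."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        aliases = frozenset(
            a.strip() for a in row.get("aliases", "").split(";") if a.strip()
        )
        records.append(
            SrnaRecord(
                canonical_name=row["canonical_name"],
                aliases=aliases,
                hfq_dependent=_parse_hfq(row.get("hfq_dependent", "")),
            )
        )
    _check_alias_collisions(records)
    return records


def read_target_catalog(path) -> pd.DataFrame:
    """Read a signed target catalog TSV (srna_name, target_gene, sign, source)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    bad = df[~df["sign"].isin(["activation", "repression"])]
    if len(bad):
        raise ValueError(f"invalid sign values: {bad['sign'].unique().tolist()}")
    if df.duplicated(["srna_name", "target_gene"]).any():
        raise ValueError("duplicate (srna, target) pairs in catalog")
    return df


def _packaged(name: str):
    return resources.files("srnaclr.data").joinpath(name)


def load_reported_srna_calls() -> pd.DataFrame:
    """Published per-comparison sRNA up/down lists (comparison, direction, srna)."""
    with resources.as_file(_packaged("reported_srna_calls.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_hfq_classes() -> list[SrnaRecord]:
    """Published Hfq classification of the YbeY-dependent sRNAs."""
    with resources.as_file(_packaged("srna_hfq_classes.tsv")) as p:
        return read_srna_catalog(p)


def load_srnas_with_targets() -> pd.DataFrame:
    """Published list of differentially expressed sRNAs with known targets."""
    with resources.as_file(_packaged("srna_with_targets.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def _check_alias_collisions(records: Iterable[SrnaRecord]) -> None:
    claimed: dict[str, str] = {}
    for rec in records:
        for name in {rec.canonical_name.lower()} | {a.lower() for a in rec.aliases}:
            owner = claimed.get(name)
            if owner is not None and owner != rec.canonical_name:
                raise ValueError(
                    f"alias collision: {name!r} claimed by both "
                    f"{owner!r} and {rec.canonical_name!r}"
                )
            claimed[name] = rec.canonical_name


def resolve_srna_names(
    names: Iterable[str],
    alias_table: dict[str, Iterable[str]],
    m: pd.DataFrame,
) -> tuple[list[SrnaRecord], list[str]]:
    """Map sRNA names onto matrix gene ids, case-insensitively via aliases.

    ``alias_table`` maps canonical names to alternate names.  A query
    name may be a canonical name or an alias; its whole synonym group is
    tried against the matrix index.  Every input name lands in exactly
    one of (mapped, unmapped); the mapped count is the number of
    "detectable" sRNAs.
    """
    records = [
        SrnaRecord(canonical_name=c, aliases=frozenset(alias_table.get(c, ())))
        for c in alias_table
    ]
    _check_alias_collisions(records)

    to_canonical: dict[str, str] = {}
    group: dict[str, set[str]] = {}
    for rec in records:
        synonyms = {rec.canonical_name} | set(rec.aliases)
        group[rec.canonical_name] = synonyms
        for s in synonyms:
            to_canonical[s.lower()] = rec.canonical_name

    by_lower = {g.lower(): g for g in m.index}

    mapped: list[SrnaRecord] = []
    unmapped: list[str] = []
    for name in names:
        canonical = to_canonical.get(name.lower(), name)
        candidates = group.get(canonical, {name})
        hit = next(
            (by_lower[c.lower()] for c in sorted(candidates) if c.lower() in by_lower),
            None,
        )
        if hit is None:
            unmapped.append(name)
        else:
            mapped.append(
                SrnaRecord(
                    canonical_name=canonical,
                    aliases=frozenset(candidates - {canonical}),
                    gene_id=hit,
                )
            )
    return mapped, unmapped


def _calls_by_comparison(
    dz_table: pd.DataFrame, gene_id: str
) -> dict[str, str]:
    sub = dz_table[dz_table["gene_id"] == gene_id]
    return dict(zip(sub["comparison"], sub["call"].astype(str)))


def classify_ybey_dependence(
    dz_table: pd.DataFrame, srna_gene_ids: Iterable[str]
) -> pd.DataFrame:
    """Classify each sRNA from its calls in the four standard comparisons.

    Rule: an sRNA differentially expressed in at least one comparison is
    YbeY-dependent iff it is significant in either genotype contrast
    (knockout vs WT, untreated or under HU) OR its HU-response calls
    differ between the two genotypes.  sRNAs significant nowhere are
    reported as ``not_differential``.

    Returns a frame with columns ``srna``, ``category`` in
    {ybey_dependent, not_ybey_dependent, not_differential}.
    """
    present = set(dz_table["comparison"].unique())
    missing = [c for c in STANDARD_COMPARISONS if c not in present]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    c1, c2, c3, c4 = STANDARD_COMPARISONS

    rows = []
    for gid in srna_gene_ids:
        calls = _calls_by_comparison(dz_table, gid)
        sig = {c for c in STANDARD_COMPARISONS if calls.get(c) in ("up", "down")}
        if not sig:
            category = "not_differential"
        elif c1 in sig or c4 in sig or calls.get(c2) != calls.get(c3):
            category = "ybey_dependent"
        else:
            category = "not_ybey_dependent"
        rows.append({"srna": gid, "category": category})
    return pd.DataFrame(rows, columns=["srna", "category"])


def partition_by_hfq(
    srnas: Iterable[SrnaRecord],
) -> tuple[set[str], set[str], set[str]]:
    """Split sRNAs into (Hfq-dependent, Hfq-independent, unknown) name sets."""
    dep, indep, unknown = set(), set(), set()
    for rec in srnas:
        if rec.hfq_dependent is True:
            dep.add(rec.canonical_name)
        elif rec.hfq_dependent is False:
            indep.add(rec.canonical_name)
        else:
            unknown.add(rec.canonical_name)
    return dep, indep, unknown


def sign_concordance(
    dz_table: pd.DataFrame,
    catalog: pd.DataFrame,
    policy: ConcordancePolicy = ConcordancePolicy(),
    srna_gene_map: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Score each cataloged (sRNA, target) pair in each comparison.

    A repression pair is concordant when sRNA and target move in
    opposite directions (dz_s * dz_t < 0); an activation pair when they
    move together.  Under the default policy both members must pass
    their |dz| gates for the pair to be counted.  Catalog rows whose
    sRNA or target is absent from the dz table are skipped with a
    warning.

    Returns a long frame: srna, target, comparison, dz_s, dz_t, sign,
    counted, concordant.
    """
    srna_gene_map = srna_gene_map or {}
    dz_wide = dz_table.pivot(index="gene_id", columns="comparison", values="dz")
    comparisons = [c for c in STANDARD_COMPARISONS if c in dz_wide.columns]
    if not comparisons:
        comparisons = list(dz_wide.columns)

    rows = []
    for _, entry in catalog.iterrows():
        srna_name = entry["srna_name"]
        gid = srna_gene_map.get(srna_name, srna_name)
        target = entry["target_gene"]
        if gid not in dz_wide.index or target not in dz_wide.index:
            warnings.warn(
                f"catalog pair ({srna_name}, {target}) not in dz table; skipped",
                stacklevel=2,
            )
            continue
        for comp in comparisons:
            dz_s = dz_wide.at[gid, comp]
            dz_t = dz_wide.at[target, comp]
            if pd.isna(dz_s) or pd.isna(dz_t):
                counted = False
                concordant = False
            else:
                gate_s = abs(dz_s) > policy.tau_srna
                gate_t = abs(dz_t) > policy.tau_target
                counted = (
                    (gate_s and gate_t)
                    if policy.require_both_significant
                    else (gate_s or gate_t)
                )
                product = dz_s * dz_t
                concordant = counted and (
                    product < 0
                    if entry["sign"] == "repression"
                    else product > 0
                )
            rows.append(
                {
                    "srna": srna_name,
                    "target": target,
                    "comparison": comp,
                    "dz_s": dz_s,
                    "dz_t": dz_t,
                    "sign": entry["sign"],
                    "counted": counted,
                    "concordant": concordant,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "srna", "target", "comparison", "dz_s", "dz_t",
            "sign", "counted", "concordant",
        ],
    )


def concordant_pair_count(concordance: pd.DataFrame) -> int:
    """Unique (sRNA, target) pairs concordant in at least one comparison."""
    if concordance.empty:
        return 0
    hits = concordance[concordance["concordant"]]
    return int(hits.drop_duplicates(["srna", "target"]).shape[0])
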