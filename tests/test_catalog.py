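"""Name resolution, YbeY/Hfq classification and sign concordance."""

import numpy as np
import pandas as pd
import pytest

from srnaclr.catalog import (
    ConcordancePolicy,
    classify_ybey_dependence,
    concordant_pair_count,
    load_hfq_classes,
    load_reported_srna_calls,
    load_srnas_with_targets,
    partition_by_hfq,
    resolve_srna_names,
    sign_concordance,
    SrnaRecord,
)
from srnaclr.deltaz import STANDARD_COMPARISONS

C1, C2, C3, C4 = STANDARD_COMPARISONS


def _matrix(gene_ids):
    return pd.DataFrame(
        np.zeros((len(gene_ids), 2)), index=gene_ids, columns=["a1", "a2"]
    )


def test_resolve_via_alias():
    """The SRP RNA appears as '4.5S' in catalogs but 'ffs' on arrays."""
    mapped, unmapped = resolve_srna_names(
        ["4.5S"], {"Ffs": ["4.5S"]}, _matrix(["ffs", "g1"])
    )
    assert unmapped == []
    assert mapped[0].canonical_name == "Ffs"
    assert mapped[0].gene_id == "ffs"


def test_resolve_case_insensitive_and_unmapped():
    mapped, unmapped = resolve_srna_names(
        ["ryeB", "NoSuch"], {"RyeB": []}, _matrix(["RyeB", "g1"])
    )
    assert [r.gene_id for r in mapped] == ["RyeB"]
    assert unmapped == ["NoSuch"]


def test_resolve_is_a_partition(rng):
    names = [f"s{i}" for i in range(10)]
    table = {n: [] for n in names[:6]}
    m = _matrix([n.upper() for n in names[:4]] + ["other"])
    mapped, unmapped = resolve_srna_names(names, table, m)
    assert len(mapped) + len(unmapped) == len(names)
    resolved = {r.canonical_name for r in mapped} | set(unmapped)
    assert len(resolved) == len(names)


def test_alias_collision_error():
    with pytest.raises(ValueError, match="collision"):
        resolve_srna_names(
            ["x"], {"A": ["shared"], "B": ["SHARED"]}, _matrix(["g"])
        )


def _call_table(gene_calls: dict[str, dict[str, str]]) -> pd.DataFrame:
    rows = []
    for gid, calls in gene_calls.items():
        for comp in STANDARD_COMPARISONS:
            call = calls.get(comp, "ns")
            dz = {"up": 2.0, "down": -2.0, "ns": 0.1}[call]
            rows.append(
                {"gene_id": gid, "comparison": comp, "dz": dz, "call": call}
            )
    return pd.DataFrame(rows)


def test_classification_rules():
    table = _call_table(
        {
            # up under HU in both genotypes, nothing genotype-specific
            "independent": {C2: "up", C3: "up"},
            # HU response only when YbeY present
            "dependent_hu": {C2: "up"},
            # significant only in the genotype contrast under HU
            "dependent_c4": {C4: "down"},
            # never significant
            "silent": {},
        }
    )
    result = classify_ybey_dependence(
        table, ["independent", "dependent_hu", "dependent_c4", "silent"]
    )
    by = dict(zip(result["srna"], result["category"]))
    assert by["independent"] == "not_ybey_dependent"
    assert by["dependent_hu"] == "ybey_dependent"
    assert by["dependent_c4"] == "ybey_dependent"
    assert by["silent"] == "not_differential"


def test_classification_requires_all_comparisons():
    table = _call_table({"g": {}})
    table = table[table["comparison"] != C3]
    with pytest.raises(ValueError, match=C3):
        classify_ybey_dependence(table, ["g"])


def test_classification_ignores_gene_order():
    table = _call_table({"a": {C4: "up"}, "b": {C2: "up", C3: "up"}})
    shuffled = table.sample(frac=1.0, random_state=1)
    r1 = classify_ybey_dependence(table, ["a", "b"])
    r2 = classify_ybey_dependence(shuffled, ["a", "b"])
    pd.testing.assert_frame_equal(r1, r2)


def test_partition_by_hfq_fixture_sizes():
    """The published Hfq classification of the YbeY-dependent sRNAs:
    12 Hfq-dependent, 16 Hfq-independent, none unknown."""
    dep, indep, unknown = partition_by_hfq(load_hfq_classes())
    assert (len(dep), len(indep), len(unknown)) == (12, 16, 0)


def test_partition_all_unknown_and_exhaustive():
    records = [SrnaRecord(canonical_name=f"s{i}") for i in range(5)]
    dep, indep, unknown = partition_by_hfq(records)
    assert (len(dep), len(indep), len(unknown)) == (0, 0, 5)
    mixed = records + [SrnaRecord(canonical_name="h", hfq_dependent=True)]
    parts = partition_by_hfq(mixed)
    assert sum(map(len, parts)) == len(mixed)
    assert not (parts[0] & parts[1]) and not (parts[0] & parts[2])


def _pair_catalog(sign: str) -> pd.DataFrame:
    return pd.DataFrame(
        [{"srna_name": "s", "target_gene": "t", "sign": sign, "source": "db"}]
    )


def _pair_dz(dz_s: float, dz_t: float) -> pd.DataFrame:
    rows = []
    for comp in STANDARD_COMPARISONS:
        sval = dz_s if comp == C2 else 0.0
        tval = dz_t if comp == C2 else 0.0
        rows += [
            {"gene_id": "s", "comparison": comp, "dz": sval,
             "call": "up" if sval > 1 else "ns"},
            {"gene_id": "t", "comparison": comp, "dz": tval,
             "call": "down" if tval < -1 else "ns"},
        ]
    return pd.DataFrame(rows)


@pytest.mark.parametrize(
    "sign,dz_s,dz_t,expected_concordant,expected_counted",
    [
        ("repression", 1.5, -1.2, True, True),
        ("repression", 1.5, 1.2, False, True),
        ("activation", 1.5, 1.2, True, True),
        ("activation", 1.5, -0.5, False, False),  # target fails the gate
    ],
)
def test_concordance_rules(sign, dz_s, dz_t, expected_concordant, expected_counted):
    result = sign_concordance(_pair_dz(dz_s, dz_t), _pair_catalog(sign))
    row = result[result["comparison"] == C2].iloc[0]
    assert bool(row["counted"]) is expected_counted
    assert bool(row["concordant"]) is expected_concordant


def test_concordance_sign_flip_inverts(small_dataset):
    """Flipping every catalog sign turns counted concordant pairs
    discordant and vice versa (under both-significant gating)."""
    from srnaclr.compendium import merge_arrays, per_gene_sd
    from srnaclr.deltaz import run_comparisons
    from srnaclr.synthetic import truth_edge_table

    m, truth, exp, designs = small_dataset
    merged, _ = merge_arrays(exp, m)
    table = run_comparisons(merged[list(exp.columns)], per_gene_sd(merged), designs)
    catalog = truth_edge_table(truth)
    flipped = catalog.copy()
    flipped["sign"] = flipped["sign"].map(
        {"activation": "repression", "repression": "activation"}
    )
    a = sign_concordance(table, catalog)
    b = sign_concordance(table, flipped)
    counted = a["counted"] & (a["dz_s"] * a["dz_t"] != 0)
    assert (a.loc[counted, "concordant"] ^ b.loc[counted, "concordant"]).all()


def test_concordance_skips_unknown_pairs():
    catalog = pd.DataFrame(
        [{"srna_name": "ghost", "target_gene": "t", "sign": "repression",
          "source": "db"}]
    )
    with pytest.warns(UserWarning, match="ghost"):
        result = sign_concordance(_pair_dz(2.0, -2.0), catalog)
    assert result.empty
    assert concordant_pair_count(result) == 0


def test_reported_lists_internally_consistent():
    """The packaged per-comparison lists reproduce the published sRNA
    summary: 5/17/13/17 differential sRNAs, 30 unique overall."""
    calls = load_reported_srna_calls()
    totals = calls.groupby("comparison")["srna"].count().to_dict()
    assert totals == {C1: 5, C2: 17, C3: 13, C4: 17}
    assert calls["srna"].str.lower().nunique() == 30
    with_targets = load_srnas_with_targets()
    assert len(with_targets) == 17
    assert int(with_targets["hfq_dependent"].sum()) == 11
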