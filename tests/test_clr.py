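"""Mutual information, CLR scoring, permutation FDR and recovery metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from srnaclr.clr import (
    annotate_validated,
    clr_scores,
    edge_significance,
    evaluate_recovery,
    extract_seed_subnetwork,
    mi_matrix,
    mutual_information,
    permutation_null,
)


def oracle_mi(x, y, bins):
    """Exhaustive plug-in joint-histogram MI, coded independently."""
    def bin_of(v, vals):
        lo, hi = min(vals), max(vals)
        if hi == lo:
            return 0
        edges = [lo + (hi - lo) * k / bins for k in range(bins + 1)]
        for k in range(bins):
            if edges[k] <= v < edges[k + 1]:
                return k
        return bins - 1

    n = len(x)
    joint: dict[tuple[int, int], int] = {}
    for xv, yv in zip(x, y):
        key = (bin_of(xv, x), bin_of(yv, y))
        joint[key] = joint.get(key, 0) + 1
    px: dict[int, float] = {}
    py: dict[int, float] = {}
    for (i, j), c in joint.items():
        px[i] = px.get(i, 0) + c / n
        py[j] = py.get(j, 0) + c / n
    return sum(
        (c / n) * math.log2((c / n) / (px[i] * py[j]))
        for (i, j), c in joint.items()
    )


def test_mi_identity_uniform_diagonal():
    x = np.arange(1.0, 11.0)
    assert mutual_information(x, x, bins=10) == pytest.approx(np.log2(10), abs=1e-12)


def test_mi_two_state_cases():
    a = np.array([0.0, 0.0, 1.0, 1.0])
    b = np.array([0.0, 1.0, 0.0, 1.0])
    assert mutual_information(a, b, bins=2) == 0.0
    assert mutual_information(a, a, bins=2) == pytest.approx(1.0, abs=1e-12)


def test_mi_constant_vector_is_zero():
    x = np.full(30, 3.5)
    y = np.arange(30.0)
    assert mutual_information(x, y) == 0.0


def test_mi_length_mismatch():
    with pytest.raises(ValueError):
        mutual_information(np.arange(30.0), np.arange(31.0))


def test_mi_matches_brute_force_oracle(rng):
    for _ in range(20):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        for bins in (2, 5, 10):
            assert mutual_information(x, y, bins=bins) == pytest.approx(
                oracle_mi(x, y, bins), abs=1e-12
            )


@settings(derandomize=True, max_examples=40)
@given(st.integers(0, 2**31 - 1), st.sampled_from([2, 5, 10]))
def test_mi_symmetry_and_nonnegativity(seed, bins):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=25)
    y = rng.normal(size=25)
    mxy = mutual_information(x, y, bins=bins)
    assert mxy == mutual_information(y, x, bins=bins)
    assert mxy >= 0.0


def test_mi_invariant_to_monotone_rescaling(rng):
    """Affine rescaling preserves equal-width bin assignments exactly."""
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    base = mutual_information(x, y)
    assert mutual_information(3.0 * x + 7.0, y) == pytest.approx(base, abs=1e-12)


def _toy_matrix(rng, n_genes=5, n_arrays=30):
    m = pd.DataFrame(
        rng.normal(size=(n_genes, n_arrays)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"a{i}" for i in range(n_arrays)],
    )
    return m


def test_mi_matrix_excludes_self_pairs(rng):
    m = _toy_matrix(rng)
    mm = mi_matrix(m, ["g0", "g1"])
    assert mm.shape == (2, 5)
    assert np.isnan(mm.at["g0", "g0"]) and np.isnan(mm.at["g1", "g1"])
    assert mm.notna().sum().sum() == 8


def test_mi_matrix_array_order_free(rng):
    m = _toy_matrix(rng)
    perm = list(rng.permutation(m.columns))
    a = mi_matrix(m, ["g0", "g1"])
    b = mi_matrix(m[perm], ["g0", "g1"])
    pd.testing.assert_frame_equal(a, b)


def test_mi_matrix_spot_checks_scalar_path(rng):
    m = _toy_matrix(rng, n_genes=8)
    mm = mi_matrix(m, ["g0", "g3", "g7"])
    for reg in ("g0", "g3", "g7"):
        for gene in rng.choice(m.index, size=4, replace=False):
            if gene == reg:
                continue
            direct = mutual_information(m.loc[reg], m.loc[gene])
            assert mm.at[reg, gene] == pytest.approx(direct, abs=1e-15)


def test_mi_matrix_unknown_regulator(rng):
    with pytest.raises(ValueError, match="ghost"):
        mi_matrix(_toy_matrix(rng), ["ghost"])


def test_clr_score_arithmetic():
    """Background row (0.1, 0.1, 0.1, 0.7): mean 0.25, sample SD 0.3,
    so the outlying cell carries z_reg = 1.5."""
    mm = pd.DataFrame(
        [[0.1, 0.1, 0.1, 0.7]],
        index=pd.Index(["r"], name="srna"),
        columns=["t1", "t2", "t3", "t4"],
    )
    edges = clr_scores(mm)
    big = edges[edges["gene"] == "t4"].iloc[0]
    assert big["z_reg"] == pytest.approx(1.5)
    # single-regulator columns have zero-variance backgrounds -> z_tgt 0
    assert big["z_tgt"] == 0.0
    assert big["score"] == pytest.approx(1.5)


def test_clr_clipping_below_background():
    mm = pd.DataFrame(
        [[0.9, 0.1, 0.5, 0.5], [0.1, 0.9, 0.5, 0.5]],
        index=pd.Index(["r1", "r2"], name="srna"),
        columns=["t1", "t2", "t3", "t4"],
    )
    edges = clr_scores(mm)
    low = edges[(edges["srna"] == "r1") & (edges["gene"] == "t2")].iloc[0]
    assert low["z_reg"] == 0.0 and low["score"] >= 0.0


def test_clr_shift_invariance(rng):
    """Adding a constant to every MI value leaves all z-scores unchanged."""
    mi = np.abs(rng.normal(size=(4, 20)))
    cols = [f"g{i}" for i in range(20)]
    a = clr_scores(pd.DataFrame(mi, index=list("wxyz"), columns=cols))
    b = clr_scores(pd.DataFrame(mi + 5.0, index=list("wxyz"), columns=cols))
    assert np.allclose(a["score"], b["score"])


def test_permutation_null_count_and_determinism(rng):
    m = _toy_matrix(rng, n_genes=12, n_arrays=40)
    regs = ["g0", "g1", "g2"]
    n1 = permutation_null(m, regs, n_perm=2, seed=3)
    n2 = permutation_null(m, regs, n_perm=2, seed=3)
    assert n1.shape == (2 * 3 * 11,)
    assert np.array_equal(n1, n2)
    assert not np.array_equal(n1, permutation_null(m, regs, n_perm=2, seed=4))


def test_add_one_p_value():
    edges = pd.DataFrame({"srna": ["s"], "gene": ["g"], "score": [10.0]})
    null = np.linspace(0, 5, 999)
    out = edge_significance(edges, null)
    assert out["p"].iloc[0] == pytest.approx(1 / 1000)


def test_bh_hand_run():
    edges = pd.DataFrame(
        {"srna": list("abc"), "gene": list("xyz"), "score": [3.0, 2.0, 1.0]}
    )
    # choose a null that yields p = (0.001, 0.02, 0.9)
    null = np.concatenate(
        [np.full(19, 2.5), np.full(880, 1.5), np.full(100, 0.5)]
    )
    out = edge_significance(edges, null)
    assert np.allclose(out["p"], [0.001, 0.02, 0.9])
    assert np.allclose(out["q"], [0.003, 0.03, 0.9])


def test_all_observed_below_null():
    edges = pd.DataFrame(
        {"srna": list("ab"), "gene": list("xy"), "score": [0.0, 0.1]}
    )
    null = np.full(50, 1.0)
    out = edge_significance(edges, null)
    assert (out["p"] == 1.0).all()
    assert not out["significant"].any()


def _network_fixture():
    return pd.DataFrame(
        {
            "srna": ["s1"] * 3 + ["s2"] * 3,
            "gene": ["a", "b", "c", "a", "b", "d"],
            "score": [5.0, 4.0, 3.0, 2.0, 1.0, 0.5],
            "q": [0.001, 0.001, 0.5, 0.001, 0.9, 0.9],
            "significant": [True, True, False, True, False, False],
        }
    )


def test_seed_subnetwork_extraction():
    net = _network_fixture()
    assert extract_seed_subnetwork(net, {"s1", "s2"}).shape[0] == 6
    assert extract_seed_subnetwork(net, set()).empty
    only_s1 = extract_seed_subnetwork(net, {"s1"})
    assert set(only_s1["gene"]) == {"a", "b", "c"}
    with pytest.warns(UserWarning, match="ghost"):
        sub = extract_seed_subnetwork(net, {"s1", "ghost"})
    assert (sub["srna"] == "s1").all()


def test_annotate_validated_counts():
    net = _network_fixture()
    empty = pd.DataFrame(columns=["srna_name", "target_gene", "sign", "source"])
    assert (annotate_validated(net, empty)["status"] == "predicted").all()
    catalog = pd.DataFrame(
        {
            "srna_name": ["s1", "s1", "s2"],
            "target_gene": ["a", "c", "d"],
            "sign": ["repression"] * 3,
            "source": ["db"] * 3,
        }
    )
    out = annotate_validated(net, catalog)
    assert (out["status"] == "validated").sum() == 3
    full = net.rename(columns={"srna": "srna_name", "gene": "target_gene"})
    full = full.assign(sign="repression", source="db")
    assert (annotate_validated(net, full)["status"] == "validated").all()


def test_recovery_perfect_ranking():
    net = _network_fixture()
    truth = [("s1", "a"), ("s1", "b")]
    metrics = evaluate_recovery(net, truth)
    assert metrics["aupr"] == pytest.approx(1.0)
    assert metrics["recall"] == 1.0


def test_recovery_nothing_significant_is_nan_precision():
    net = _network_fixture()
    net["significant"] = False
    metrics = evaluate_recovery(net, [("s1", "a")])
    assert metrics["recall"] == 0.0
    assert math.isnan(metrics["precision"])
    with pytest.raises(ValueError):
        evaluate_recovery(net, [])


def test_recovery_random_scores_aupr_near_prevalence(rng):
    """Uninformative scores: AUPR concentrates near prevalence (0.1)."""
    auprs = []
    for _ in range(20):
        n = 2000
        truth_flags = rng.random(n) < 0.1
        edges = pd.DataFrame(
            {
                "srna": ["s"] * n,
                "gene": [f"g{i}" for i in range(n)],
                "score": rng.random(n),
                "significant": np.zeros(n, dtype=bool),
            }
        )
        truth = [("s", f"g{i}") for i in np.flatnonzero(truth_flags)]
        auprs.append(evaluate_recovery(edges, truth)["aupr"])
    assert abs(float(np.mean(auprs)) - 0.10) < 0.03
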