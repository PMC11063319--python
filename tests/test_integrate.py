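"""Sample matching, CpG-gene correlation, and driver-pair calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

from methdriver import (
    ValidationError,
    call_driver_pairs,
    compare_gene_sets,
    correlate_pairs,
    match_samples,
    spearman_pair,
)


def _sheet(n, prefix, season="pollen", start=0):
    idx = [f"{prefix}{i}" for i in range(start, start + n)]
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(start, start + n)],
            "season": [season] * n,
            "group": ["AR"] * n,
            "sex": ["F"] * n,
            "symptom_score": [0.0] * n,
        },
        index=idx,
    )


def test_match_fifteen_shared_patients():
    meth = _sheet(16, "M")          # patients P0..P15
    expr = _sheet(19, "E", start=1)  # patients P1..P19 -> 15 shared
    match = match_samples(meth, expr)
    assert match.n_pairs == 15
    assert len(match.unmatched_meth) == 1
    assert len(match.unmatched_expr) == 4


def test_match_disjoint_patients_empty():
    match = match_samples(_sheet(4, "M"), _sheet(4, "E", start=10))
    assert match.n_pairs == 0


def test_match_identical_sheets_is_identity():
    sheet = _sheet(6, "S")
    match = match_samples(sheet, sheet)
    assert (match.pairs["meth_sample"] == match.pairs["expr_sample"]).all()
    assert match.n_pairs == 6


def test_match_duplicate_patient_season_raises():
    meth = _sheet(4, "M")
    meth.loc["M3", "patient_id"] = "P0"
    with pytest.raises(ValidationError):
        match_samples(meth, _sheet(4, "E"))


def test_spearman_exact_extremes():
    x = np.arange(8, dtype=float)
    rho, p, n = spearman_pair(x, -x)
    assert rho == pytest.approx(-1.0)
    assert n == 8
    rho2, _, _ = spearman_pair(x, x**3)  # monotone transform
    assert rho2 == pytest.approx(1.0)


def test_spearman_tied_data_matches_rank_formula():
    # explicit average-rank + Pearson-by-hand oracle, n = 15 with ties
    rng = np.random.default_rng(5)
    for _ in range(20):
        x = rng.integers(0, 5, 15).astype(float)
        y = rng.integers(0, 4, 15).astype(float) + 0.5 * x
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        num = np.sum((rx - rx.mean()) * (ry - ry.mean()))
        den = np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
        expected = num / den
        rho, _, _ = spearman_pair(x, y, exact_max_n=0)
        assert rho == pytest.approx(expected, abs=1e-12)


def test_spearman_exact_permutation_p_small_n():
    # n = 5: compare against direct enumeration of all orderings
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
    rho, p, _ = spearman_pair(x, y, exact_max_n=9)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = np.corrcoef(rx, ry)[0, 1]
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(np.corrcoef(rx, perm)[0, 1]) >= abs(obs) - 1e-12:
            count += 1
    assert rho == pytest.approx(obs)
    assert p == pytest.approx(count / total)


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(-100, 100), min_size=6, max_size=12, unique=True))
def test_spearman_invariant_under_monotone_transform(xs):
    x = np.array(xs)
    tx = np.exp(x / 100.0)  # strictly increasing map
    assume(len(np.unique(tx)) == len(x))  # no collisions at float precision
    rng = np.random.default_rng(42)
    y = rng.permutation(len(xs)).astype(float)
    rho1, _, _ = spearman_pair(x, y)
    rho2, _, _ = spearman_pair(tx, y)
    assert rho1 == pytest.approx(rho2, abs=1e-12)


def _scored(rows):
    return pd.DataFrame(rows, columns=["probe", "gene", "rho", "p", "n"])


def test_call_driver_pairs_class_and_boundary():
    scored = _scored(
        [
            ("c1", "g1", -0.5, 0.03, 15),
            ("c2", "g2", -0.39, 0.01, 15),  # rho boundary: excluded
            ("c3", "g3", -0.8, 0.2, 15),    # p too large
            ("c4", "g4", -0.9, 0.001, 15),  # inconsistent directions
        ]
    )
    dmps = {"c1": "hyper", "c2": "hypo", "c3": "hyper", "c4": "hyper"}
    degs = {"g1": "down", "g2": "up", "g3": "down", "g4": "up"}
    out = call_driver_pairs(scored, dmps, degs)
    assert list(out["probe"]) == ["c1"]
    assert out.loc[0, "regulation_class"] == "hyper_low"


def test_call_driver_pairs_requires_membership():
    scored = _scored([("c1", "g1", -0.9, 0.001, 15)])
    out = call_driver_pairs(scored, {}, {"g1": "down"})
    assert len(out) == 0


def test_disabled_thresholds_return_all_consistent_candidates():
    rows = [(f"c{i}", f"g{i}", rho, 0.5, 10) for i, rho in enumerate([-0.9, 0.0, 0.7])]
    scored = _scored(rows)
    dmps = {f"c{i}": "hyper" for i in range(3)}
    degs = {f"g{i}": "down" for i in range(3)}
    out = call_driver_pairs(scored, dmps, degs, rho_max=2.0, alpha=2.0)
    assert len(out) == 3


def test_correlate_pairs_complete_cases_and_min_n():
    probes = ["c1", "c2"]
    samples = [f"m{i}" for i in range(6)]
    esamples = [f"e{i}" for i in range(6)]
    beta = pd.DataFrame(
        [np.linspace(0.1, 0.9, 6), [0.2, np.nan, np.nan, np.nan, 0.4, 0.5]],
        index=probes,
        columns=samples,
    )
    expr = pd.DataFrame(
        [np.linspace(9, 5, 6), np.linspace(5, 9, 6)],
        index=["g1", "g2"],
        columns=esamples,
    )
    matched = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(6)],
            "season": ["pollen"] * 6,
            "meth_sample": samples,
            "expr_sample": esamples,
        }
    )
    out = correlate_pairs(beta, expr, {"c1": "g1", "c2": "g2"}, matched)
    assert set(out["probe"]) == {"c1"}  # c2 has only 3 complete cases
    assert out.loc[out["probe"] == "c1", "rho"].iloc[0] == pytest.approx(-1.0)


def test_compare_gene_sets_counts():
    shared = {"s1", "s2", "s3", "s4"}
    a = {"a", "b", "c", "d"} | shared
    b = {"e", "f"} | shared
    rep = compare_gene_sets(a, b, labels=("pollen", "non-pollen"))
    assert rep.counts == {
        "unique_pollen": 4,
        "unique_non-pollen": 2,
        "intersection": 4,
    }
    same = compare_gene_sets(a, a)
    assert not same.unique_a and not same.unique_b
    empty = compare_gene_sets(set(), b)
    assert set(empty.unique_b) == b and not empty.intersection
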