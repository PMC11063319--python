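"""Methylation QC: beta computation, missing filters, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methdriver import (
    DimensionError,
    EmptyResultError,
    ValidationError,
    apply_probe_blacklist,
    compute_beta,
    filter_missing,
    normalize_probe_types,
)
from methdriver.datatypes import MethylationSet, SampleSheet


def _matrix(values, probes=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=probes, columns=samples)


@pytest.mark.parametrize(
    "m, u, expected",
    [(100.0, 0.0, 0.5), (0.0, 400.0, 0.0), (1900.0, 0.0, 0.95)],
)
def test_compute_beta_worked_values(m, u, expected):
    out = compute_beta(np.array([[m]]), np.array([[u]]))
    assert out[0, 0] == pytest.approx(expected, abs=0.0)


def test_compute_beta_errors():
    with pytest.raises(DimensionError):
        compute_beta(np.ones((2, 2)), np.ones((3, 2)))
    with pytest.raises(ValidationError):
        compute_beta(np.array([[-1.0]]), np.array([[1.0]]))


def test_compute_beta_propagates_missing():
    out = compute_beta(np.array([[np.nan, 100.0]]), np.array([[50.0, 100.0]]))
    assert np.isnan(out[0, 0]) and np.isfinite(out[0, 1])


@settings(max_examples=50, deadline=None)
@given(
    m=st.floats(0, 1e5),
    u=st.floats(0, 1e5),
    dm=st.floats(0.1, 1e4),
)
def test_compute_beta_monotone(m, u, dm):
    base = compute_beta(np.array([[m]]), np.array([[u]]))[0, 0]
    more_m = compute_beta(np.array([[m + dm]]), np.array([[u]]))[0, 0]
    more_u = compute_beta(np.array([[m]]), np.array([[u + dm]]))[0, 0]
    assert more_m > base or np.isclose(more_m, base)
    assert more_u < base or np.isclose(more_u, base)
    assert more_m >= base >= more_u


def test_filter_missing_drops_half_missing_probe():
    mat = _matrix(np.ones((10, 4)))
    mat.iloc[0, :2] = np.nan  # 50% missing
    out, report = filter_missing(mat, max_rate=0.10)
    assert "p0" in report.dropped_features
    assert out.shape == (9, 4)


def test_filter_missing_identity_without_missing():
    mat = _matrix(np.ones((5, 3)))
    out, report = filter_missing(mat)
    pd.testing.assert_frame_equal(out, mat)
    assert not report.dropped_features and not report.dropped_samples


def test_filter_missing_second_pass_drops_sample():
    # the sample's missing cells are spread thin over probes, so every
    # probe survives pass 1 and the sample falls in pass 2
    mat = _matrix(np.ones((10, 20)))
    mat.iloc[:3, 0] = np.nan  # s0 misses 30% of probes; probes miss 5%
    out, report = filter_missing(mat, max_rate=0.10)
    assert "s0" in report.dropped_samples
    assert out.shape == (10, 19)


def test_filter_missing_boundary_rate_kept():
    # exactly 10% missing is kept ("under 10%" describes what is dropped)
    mat = _matrix(np.ones((5, 10)))
    mat.iloc[0, 0] = np.nan
    out, _ = filter_missing(mat, max_rate=0.10)
    assert "p0" in out.index


def test_filter_missing_idempotent_on_random_masks():
    rng = np.random.default_rng(7)
    for _ in range(10):
        mat = _matrix(rng.random((30, 12)))
        mask = rng.random(mat.shape) < 0.15
        mat = mat.mask(mask)
        once, _ = filter_missing(mat)
        twice, rep = filter_missing(once)
        pd.testing.assert_frame_equal(once, twice)
        assert not rep.dropped_features and not rep.dropped_samples


def test_filter_missing_all_dropped_raises():
    mat = _matrix(np.full((3, 3), np.nan))
    with pytest.raises(EmptyResultError):
        filter_missing(mat)


def _tiny_mset(n_probes=6, n_samples=4):
    probes = [f"p{i}" for i in range(n_probes)]
    samples = [f"s{j}" for j in range(n_samples)]
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "patient_id": [f"P{j}" for j in range(n_samples)],
                "group": ["AR", "AR", "HC", "HC"][:n_samples],
                "season": ["pollen"] * n_samples,
                "sex": ["F"] * n_samples,
                "symptom_score": [1.0] * n_samples,
            },
            index=samples,
        )
    )
    ann = pd.DataFrame(
        {
            "gene": ["G1"] * n_probes,
            "feature": ["TSS200"] * n_probes,
            "island": ["Island"] * n_probes,
            "design_type": ["I"] * n_probes,
        },
        index=probes,
    )
    beta = pd.DataFrame(np.full((n_probes, n_samples), 0.5), index=probes, columns=samples)
    return MethylationSet(beta=beta, annotation=ann, samples=sheet)


def test_blacklist_removes_only_listed_probes():
    mset = _tiny_mset()
    out = apply_probe_blacklist(mset, ["p1", "p2", "not_on_array"])
    assert out.beta.shape[0] == 4
    assert "p1" not in out.beta.index and "p0" in out.beta.index


def test_blacklist_empty_is_identity():
    mset = _tiny_mset()
    out = apply_probe_blacklist(mset, [])
    pd.testing.assert_frame_equal(out.beta, mset.beta)


def test_blacklist_can_empty_the_array():
    mset = _tiny_mset()
    out = apply_probe_blacklist(mset, [f"p{i}" for i in range(6)])
    assert out.beta.shape[0] == 0


def test_normalize_all_type_one_is_identity():
    rng = np.random.default_rng(0)
    beta = _matrix(rng.random((20, 3)))
    design = pd.Series("I", index=beta.index)
    out = normalize_probe_types(beta, design)
    pd.testing.assert_frame_equal(out, beta)


def test_normalize_preserves_type_two_rank_order():
    rng = np.random.default_rng(1)
    beta = _matrix(rng.random((200, 2)))
    design = pd.Series(["I"] * 100 + ["II"] * 100, index=beta.index)
    out = normalize_probe_types(beta, design)
    for j in range(2):
        before = beta.iloc[100:, j].rank()
        after = out.iloc[100:, j].rank()
        assert stats.spearmanr(before, after).statistic == pytest.approx(1.0)
    # Type-I values untouched
    pd.testing.assert_frame_equal(out.iloc[:100], beta.iloc[:100])


def test_normalize_matched_distributions_is_near_identity():
    # Type-II values already distributed as Type I -> mapping ~ identity
    rng = np.random.default_rng(2)
    n = 10_000
    vals = np.concatenate([rng.beta(2, 5, n), rng.beta(2, 5, n)])
    beta = _matrix(vals[:, None])
    design = pd.Series(["I"] * n + ["II"] * n, index=beta.index)
    out = normalize_probe_types(beta, design)
    ks = stats.ks_2samp(out.iloc[n:, 0], beta.iloc[n:, 0]).statistic
    assert ks < 0.05
    assert out.to_numpy().min() >= 0 and out.to_numpy().max() <= 1


def test_normalize_missing_design_type_raises():
    beta = _matrix(np.random.default_rng(3).random((4, 2)))
    design = pd.Series(["I", "II", "I"], index=beta.index[:3])
    with pytest.raises(ValidationError):
        normalize_probe_types(beta, design)
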