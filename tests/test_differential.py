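"""Moderated two-group testing and adaptive-threshold calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methdriver import (
    AdaptiveThreshold,
    ValidationError,
    adaptive_threshold,
    call_degs,
    call_dmps,
    moderated_ttest,
)
from methdriver.differential import fit_variance_prior, trigamma_inverse


def _frame(values):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"f{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )


def test_adaptive_threshold_worked_values():
    t = adaptive_threshold([1, 1, 1, 1])
    assert t.tau == pytest.approx(1.0)
    t = adaptive_threshold([0, 2])
    assert t.mean_abs == pytest.approx(1.0)
    assert t.sd_abs == pytest.approx(np.sqrt(2))
    assert t.tau == pytest.approx(1 + 2 * np.sqrt(2))


def test_adaptive_threshold_needs_two_values():
    with pytest.raises(ValidationError):
        adaptive_threshold([1.0])


@settings(max_examples=40, deadline=None)
@given(
    effects=st.lists(st.floats(-50, 50), min_size=2, max_size=20),
    c=st.floats(0.01, 10),
)
def test_adaptive_threshold_homogeneous_and_permutation_invariant(effects, c):
    base = adaptive_threshold(effects)
    scaled = adaptive_threshold([c * e for e in effects])
    assert scaled.tau == pytest.approx(c * base.tau, rel=1e-9, abs=1e-9)
    shuffled = adaptive_threshold(list(reversed(effects)))
    assert shuffled.tau == pytest.approx(base.tau, rel=1e-12, abs=1e-12)


def test_trigamma_inverse_round_trip():
    from scipy.special import polygamma

    for x in (0.1, 1.0, 4.0, 50.0):
        y = float(polygamma(1, x))
        assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


def test_identical_groups_give_null_results():
    rng = np.random.default_rng(0)
    half = rng.normal(size=(50, 6))
    mat = _frame(np.hstack([half, half]))
    groups = ["AR"] * 6 + ["HC"] * 6
    res = moderated_ttest(mat, groups)
    assert np.allclose(res["effect"], 0)
    assert (res["p"] >= 0.99).all()


def test_prior_df_zero_equals_ordinary_t():
    rng = np.random.default_rng(1)
    mat = _frame(rng.normal(size=(300, 14)))
    groups = ["AR"] * 7 + ["HC"] * 7
    res = moderated_ttest(mat, groups, prior_df=0.0)
    t_ref, p_ref = stats.ttest_ind(
        mat.iloc[:, :7], mat.iloc[:, 7:], axis=1, equal_var=True
    )
    np.testing.assert_allclose(res["t"], t_ref, atol=1e-10)
    np.testing.assert_allclose(res["p"], p_ref, atol=1e-10)


def test_moderation_shrinks_toward_ordinary_t_range():
    rng = np.random.default_rng(2)
    mat = _frame(rng.normal(size=(500, 10)))
    groups = ["AR"] * 5 + ["HC"] * 5
    fitted = moderated_ttest(mat, groups)
    assert fitted.attrs["prior_df"] > 0
    # moderated |t| has less extreme tails than the ordinary t under the null
    plain = moderated_ttest(mat, groups, prior_df=0.0)
    assert np.abs(fitted["t"]).max() <= np.abs(plain["t"]).max() + 1e-9


def test_zero_variance_zero_effect_feature():
    mat = _frame(np.vstack([np.zeros(8), np.random.default_rng(3).normal(size=(20, 8))]))
    groups = ["AR"] * 4 + ["HC"] * 4
    res = moderated_ttest(mat, groups, prior_df=0.0)
    assert res.loc["f0", "t"] == 0.0
    assert res.loc["f0", "p"] == 1.0


def test_too_few_samples_per_group_raises():
    mat = _frame(np.ones((3, 3)))
    with pytest.raises(ValidationError):
        moderated_ttest(mat, ["AR", "HC", "HC"])


def test_nan_aware_effects():
    mat = _frame(np.tile([1.0, 1.0, 1.0, 0.0, 0.0, 0.0], (4, 1)))
    mat.iloc[0, 0] = np.nan
    res = moderated_ttest(mat, ["AR"] * 3 + ["HC"] * 3)
    assert res.loc["f0", "n_case"] == 2
    assert res.loc["f0", "effect"] == pytest.approx(1.0)


def _annotation(features):
    return pd.DataFrame(
        {
            "gene": ["G"] * len(features),
            "feature": features,
            "island": ["Island"] * len(features),
            "design_type": ["II"] * len(features),
        },
        index=[f"f{i}" for i in range(len(features))],
    )


def _results(effects, ps):
    n = len(effects)
    return pd.DataFrame(
        {
            "effect": effects,
            "t": np.zeros(n),
            "p": ps,
            "p_adj": ps,
            "direction": ["up" if e > 0 else "down" for e in effects],
        },
        index=[f"f{i}" for i in range(n)],
    )


def test_call_dmps_promoter_restriction_and_boundaries():
    thr = AdaptiveThreshold(tau=0.1, mean_abs=0.05, sd_abs=0.025, n_features=4)
    res = _results([0.11, 0.5, 0.11, 0.1], [0.01, 0.001, 0.01, 0.01])
    ann = _annotation(["TSS200", "Body", "1stExon", "TSS1500"])
    called = call_dmps(res, ann, threshold=thr)
    assert "f0" in called.index  # promoter, beyond tau, significant
    assert "f1" not in called.index  # excluded by the promoter criterion
    assert "f2" in called.index
    assert "f3" not in called.index  # |effect| == tau, strict >
    assert (called["direction"] == "hyper").all()


def test_call_dmps_unannotated_significant_probe_excluded():
    thr = AdaptiveThreshold(tau=0.1, mean_abs=0.05, sd_abs=0.025, n_features=2)
    res = _results([0.3, 0.3], [0.001, 0.001])
    ann = _annotation(["TSS200"]).iloc[:1]
    called = call_dmps(res, ann, threshold=thr)
    assert list(called.index) == ["f0"]


def test_call_degs_boundary_and_partition():
    thr = AdaptiveThreshold(tau=1.0, mean_abs=0.5, sd_abs=0.25, n_features=3)
    res = _results([1.2, -1.5, 1.0], [0.04, 0.04, 0.04])
    called = call_degs(res, threshold=thr)
    assert set(called.index) == {"f0", "f1"}  # |effect| == tau excluded
    up = set(called.index[called["direction"] == "up"])
    down = set(called.index[called["direction"] == "down"])
    assert up == {"f0"} and down == {"f1"}
    assert up.isdisjoint(down) and up | down == set(called.index)


def test_variance_prior_infinite_for_common_variance():
    rng = np.random.default_rng(4)
    s2 = np.full(200, 2.0) * rng.chisquare(10, 200) / 10
    d0, s0 = fit_variance_prior(s2, np.full(200, 10.0))
    assert d0 > 10  # little extra spread beyond chi-square noise
    assert s0 == pytest.approx(2.0, rel=0.3)
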