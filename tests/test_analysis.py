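"""Inferential layer: Welch contrasts, OLS fits, BIC Bayes factors, diagnostics."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

import namingnorms as nn


def _norms_frame(rng=None, n=60):
    rng = rng or np.random.default_rng(0)
    kind = np.array(["natural", "artefact"])[np.arange(n) % 2]
    return pd.DataFrame(
        {
            "kind": kind,
            "object_id": [f"o{i // 4}" for i in range(n)],
            "agreement_pct": rng.uniform(20, 100, n),
        }
    )


# ---------------------------------------------------------------------------
# Welch contrasts
# ---------------------------------------------------------------------------

def test_identical_groups_are_not_significant():
    values = list(np.tile([1.0, 2.0, 3.0, 4.0], 2))
    norms = pd.DataFrame(
        {"kind": ["natural"] * 4 + ["artefact"] * 4, "v": values}
    )
    (c,) = nn.welch_contrasts(norms, ["v"], family_alpha=0.05, n_tests=8)
    assert c.t == pytest.approx(0.0, abs=1e-12)
    assert not c.significant


def test_bonferroni_alpha_reporting():
    norms = pd.DataFrame(
        {"kind": ["natural"] * 3 + ["artefact"] * 3, "v": [1.0, 2, 3, 4, 5, 6]}
    )
    (c,) = nn.welch_contrasts(norms, ["v"], family_alpha=0.05, n_tests=8)
    assert c.alpha_adjusted == 0.05 / 8
    assert c.alpha_adjusted_reported == 0.006


def test_welch_hand_computed_fixture():
    """Groups {1,2,3} vs {4,5,6}: t = -3.674, Welch df = 4."""
    norms = pd.DataFrame(
        {"kind": ["artefact"] * 3 + ["natural"] * 3,
         "v": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}
    )
    (c,) = nn.welch_contrasts(norms, ["v"])
    assert c.t == pytest.approx(-3.674, abs=5e-4)
    assert c.df == pytest.approx(4.0, abs=1e-9)


def test_welch_reduces_to_student_for_equal_variances_and_sizes():
    a = np.array([3.0, 5.0, 7.0, 9.0, 11.0])
    b = a + 2.0  # identical sample variance, identical n
    welch = sps.ttest_ind(a, b, equal_var=False)
    student = sps.ttest_ind(a, b, equal_var=True)
    assert abs(welch.statistic - student.statistic) <= 1e-10
    assert abs(welch.df - (len(a) + len(b) - 2)) <= 1e-10


def test_tiny_group_raises():
    norms = pd.DataFrame({"kind": ["natural", "artefact", "artefact"],
                          "v": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match=">= 2"):
        nn.welch_contrasts(norms, ["v"])


# ---------------------------------------------------------------------------
# OLS fits and Bayes factors
# ---------------------------------------------------------------------------

def test_exact_linear_relation_is_recovered():
    df = pd.DataFrame({"x": np.arange(10.0)})
    df["y"] = 2.0 * df["x"] + 1.0
    fit = nn.fit_linear(df, "y", ["x"])
    assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-10)
    assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-10)
    assert fit.df_resid == 8 and fit.n == 10


def test_rank_deficient_design_names_columns():
    df = pd.DataFrame({"x1": np.arange(10.0)})
    df["x2"] = 2.0 * df["x1"]
    df["y"] = df["x1"] + np.random.default_rng(0).normal(size=10)
    with pytest.raises(ValueError, match="x1.*x2|x2.*x1"):
        nn.fit_linear(df, "y", ["x1", "x2"])


def test_bf_from_bic_closed_forms():
    assert nn.bf_from_bic(100.0, 100.0) == pytest.approx(1.0, abs=1e-12)
    assert nn.bf_from_bic(2 * math.log(10), 0.0) == pytest.approx(10.0, rel=1e-12)
    assert nn.bf_from_bic(-2 * math.log(10), 0.0) == pytest.approx(0.1, rel=1e-12)


@given(st.floats(-500, 500), st.floats(-500, 500))
@settings(max_examples=200, derandomize=True, deadline=None)
def test_bf_identity_matches_direct_exponentiation(b0, b1):
    assert abs(nn.bf_from_bic(b0, b1) - math.exp((b0 - b1) / 2.0)) <= max(
        1e-10, 1e-10 * math.exp((b0 - b1) / 2.0)
    )


# ---------------------------------------------------------------------------
# Hierarchical comparison
# ---------------------------------------------------------------------------

def _comparison_frame(n=200, seed=0, weighted_drives_rt=False):
    rng = np.random.default_rng(seed)
    mz = rng.normal(4.0, 0.8, n)
    ml = rng.normal(6.0, 2.0, n)
    wz = mz + rng.normal(0.0, 0.3, n)
    wl = ml + rng.normal(0.0, 0.5, n)
    driver = wz if weighted_drives_rt else mz
    rt = 1500.0 - 140.0 * driver + rng.normal(0.0, 60.0, n)
    return pd.DataFrame(
        {
            "mean_rt_ms": rt,
            "modal_zipf": mz,
            "modal_length_letters": ml,
            "weighted_zipf": wz,
            "weighted_length_letters": wl,
        }
    )


def test_identical_modal_and_weighted_values_give_bf_one():
    df = _comparison_frame()
    df["weighted_zipf"] = df["modal_zipf"]
    df["weighted_length_letters"] = df["modal_length_letters"]
    result = nn.hierarchical_comparison(df)
    assert result.nonnested_bf == pytest.approx(1.0, abs=1e-9)


def test_comparison_prefers_the_generating_predictor():
    result = nn.hierarchical_comparison(_comparison_frame(weighted_drives_rt=True))
    assert result.nonnested_bf > 1 and result.winner == "weighted"
    result2 = nn.hierarchical_comparison(_comparison_frame(weighted_drives_rt=False))
    assert result2.nonnested_bf < 1 and result2.winner == "modal"


def test_comparison_drops_incomplete_cases_from_all_models():
    df = _comparison_frame()
    df.loc[:10, "weighted_zipf"] = np.nan
    result = nn.hierarchical_comparison(df)
    assert result.n_dropped == 11
    assert all(f.n == result.n for f in result.fits.values())


def test_step_bfs_multiply_to_final_bf():
    result = nn.hierarchical_comparison(_comparison_frame())
    for label in ("modal", "weighted"):
        prod = (
            result.step_bfs[f"{label}_step1_vs_null"]
            * result.step_bfs[f"{label}_step2_vs_step1"]
        )
        assert prod == pytest.approx(result.final_bf_vs_null[label], rel=1e-9)
    # non-nested BF equals the ratio of the two final BFs
    assert result.nonnested_bf == pytest.approx(
        result.final_bf_vs_null["weighted"] / result.final_bf_vs_null["modal"],
        rel=1e-9,
    )


# ---------------------------------------------------------------------------
# Suppression diagnostic
# ---------------------------------------------------------------------------

def test_orthogonal_predictors_are_never_flagged():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"x1": rng.normal(size=300), "x2": rng.normal(size=300)})
    df["y"] = df["x1"] + df["x2"] + rng.normal(scale=0.1, size=300)
    fit = nn.fit_linear(df, "y", ["x1", "x2"])
    rep = nn.suppression_check(df, "y", "x1", "x2", fit)
    assert rep.flagged == []


def test_classical_suppression_construction_is_flagged():
    """y depends on x1 only; x2 = x1 + noise gets a sign-flipped coefficient."""
    rng = np.random.default_rng(2)
    x1 = rng.normal(size=400)
    x2 = x1 + rng.normal(scale=0.4, size=400)
    y = 2.0 * x1 - 1.0 * x2 + rng.normal(scale=0.05, size=400)
    df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    fit = nn.fit_linear(df, "y", ["x1", "x2"])
    rep = nn.suppression_check(df, "y", "x1", "x2", fit)
    assert rep.flagged == ["x2"]
    assert rep.r_x1_x2 > 0.5 and rep.r_y_x2 > 0  # positive r, negative coefficient


# ---------------------------------------------------------------------------
# Within-object consistency
# ---------------------------------------------------------------------------

def test_zero_variance_consistency_is_missing_with_diagnostic():
    norms = pd.DataFrame(
        {
            "object_id": ["a", "a", "b", "b"],
            "h_normalised": [0.5, 0.5, 0.5, 0.5],
            "modal_name": ["x", "x", "y", "y"],
        }
    )
    res = nn.within_object_consistency(norms)
    assert math.isnan(res.r_min_max)
    assert "zero variance" in res.diagnostic
    assert res.n_single_modal == 2 and res.pct_single_modal == 100.0


def test_single_image_objects_are_excluded():
    norms = pd.DataFrame(
        {
            "object_id": ["a", "a", "b"],
            "h_normalised": [0.1, 0.4, 0.9],
            "modal_name": ["x", "z", "y"],
        }
    )
    res = nn.within_object_consistency(norms)
    assert res.n_objects == 1 and res.n_excluded_single_image == 1
    assert res.n_single_modal == 0


def test_synthetic_objects_show_strong_min_max_correlation(default_norms):
    """Estimated normalised H is consistent within objects (r >= .8)."""
    res = nn.within_object_consistency(default_norms["norms"])
    assert res.r_min_max >= 0.8
    assert 0 < res.n_single_modal <= res.n_objects == 200
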