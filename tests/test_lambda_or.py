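"""Misclassification correction, λ search, variance components, inference."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrdscreen.lambda_or import (
    LambdaORResult,
    MisclassSpec,
    NoisyTable,
    build_stratified_table,
    correct_table,
    exposure_prevalence,
    extra_variance,
    find_min_lambda,
    label_prevalence,
    lambda_or,
    misclassification_matrix,
    naive_log_or,
    propagated_variance,
    volcano_table,
)


def test_misclassification_matrix_values():
    assert np.array_equal(misclassification_matrix(1, 1), np.eye(2))
    assert np.allclose(
        misclassification_matrix(0.9, 0.95), [[0.9, 0.1], [0.05, 0.95]]
    )


def test_misclassification_matrix_degenerate_warns_spec_refuses():
    with pytest.warns(UserWarning, match="singular"):
        misclassification_matrix(0.6, 0.4)
    with pytest.raises(ValueError, match="singular"):
        MisclassSpec(0.6, 0.4)
    with pytest.raises(ValueError):
        misclassification_matrix(0.0, 0.9)
    with pytest.raises(ValueError):
        MisclassSpec(0.9, 0.9, n_val=1)


def test_correct_table_identity_when_noiseless():
    table = NoisyTable(13, 7, 5, 20)
    assert np.allclose(correct_table(table, MisclassSpec(1, 1), 0.0), table.as_matrix())


def test_correct_table_hand_inverse():
    T = correct_table(NoisyTable(90, 10, 10, 90), MisclassSpec(0.9, 0.9), 0.0)
    assert np.allclose(T, [[100, 0], [0, 100]], atol=1e-9)


def test_correct_table_asymmetric_noise_recovers_truth():
    # true T = diag(100, 100) pushed through K with p=0.9, q=0.8
    T = correct_table(NoisyTable(90, 10, 20, 80), MisclassSpec(0.9, 0.8), 0.0)
    assert np.allclose(T, [[100, 0], [0, 100]], atol=1e-9)


def test_correct_table_large_lambda_shrinks_to_zero():
    table = NoisyTable(90, 10, 10, 90)
    T = correct_table(table, MisclassSpec(0.9, 0.9), 1e9)
    assert np.all(np.abs(T) < 1e-6)


def grid_oracle(table, spec, epsilon, lam_max, stages=3, points=2001):
    """Multi-stage dense λ-grid sweep: the independent reference for λ*."""
    from adrdscreen.lambda_or import _cells_vs_lambda

    lo, hi = 0.0, lam_max
    best = None
    for _ in range(stages):
        grid = np.linspace(lo, hi, points)
        cells = _cells_vs_lambda(table, spec, grid)
        ok = np.all(cells >= epsilon, axis=1)
        if not ok.any():
            return None
        i = int(np.argmax(ok))
        best = grid[i]
        lo = grid[i - 1] if i > 0 else 0.0
        hi = grid[i]
    return best


def test_find_min_lambda_zero_when_feasible():
    # T(0) = [[87.5, 12.5], [12.5, 87.5]]: already above the 0.5 floor
    assert find_min_lambda(NoisyTable(80, 20, 20, 80), MisclassSpec(0.9, 0.9)) == 0.0


def test_find_min_lambda_matches_grid_oracle():
    rng = np.random.default_rng(42)
    spec_grid = [(0.75, 0.9), (0.85, 0.8), (0.9, 0.95)]
    checked = 0
    while checked < 50:
        p, q = spec_grid[checked % len(spec_grid)]
        spec = MisclassSpec(p, q)
        table = NoisyTable(*rng.integers(0, 25, size=4))
        if find_min_lambda(table, spec) == 0.0:
            continue
        lam = find_min_lambda(table, spec, epsilon=0.5)
        oracle = grid_oracle(table, spec, 0.5, 10.0 * max(table.a, table.b, table.c, table.d))
        if lam is None or oracle is None:
            assert lam is None and oracle is None
        else:
            assert lam == pytest.approx(oracle, rel=1e-4, abs=1e-6)
        checked += 1


def test_find_min_lambda_all_zero_table_infeasible():
    assert find_min_lambda(np.zeros((2, 2)), MisclassSpec(0.9, 0.9)) is None


@pytest.mark.parametrize(
    "cells, expected_log_or, expected_var",
    [
        ((10, 10, 10, 10), 0.0, 0.4),
        ((20, 10, 5, 10), math.log(4), 0.45),
    ],
)
def test_naive_log_or_hand_values(cells, expected_log_or, expected_var):
    log_or, var = naive_log_or(NoisyTable(*cells))
    assert log_or == pytest.approx(expected_log_or)
    assert var == pytest.approx(expected_var)


def test_naive_log_or_published_comorbidity_table():
    # type 2 diabetes 2x2 assembled from printed cohort margins:
    # 177,240 of 484,721 cases and 2,543,094 of 12,384,759 controls exposed
    table = NoisyTable(177240, 2543094, 484721 - 177240, 12384759 - 2543094)
    log_or, _ = naive_log_or(table)
    assert math.exp(log_or) == pytest.approx(2.23, abs=0.01)


def test_naive_log_or_zero_cell_rejected():
    with pytest.raises(ValueError):
        naive_log_or(NoisyTable(10, 0, 5, 5))


def test_extra_variance_limits_and_value():
    assert extra_variance(MisclassSpec(1, 1, n_val=500)) == 0.0
    assert extra_variance(MisclassSpec(0.9, 0.9)) == 0.0  # known p, q
    small = extra_variance(MisclassSpec(0.9, 0.9, n_val=10**9))
    assert small < 1e-10
    # frozen hand evaluation at p=q=0.9, n_val=1000:
    # ((0.1/0.64)^2 * 2*0.9*0.1/1000) * 2 = 8.789e-6
    assert extra_variance(MisclassSpec(0.9, 0.9, n_val=1000)) == pytest.approx(
        8.789e-6, rel=1e-3
    )


def test_propagated_variance_reduces_to_classical_when_noiseless():
    table = NoisyTable(20, 10, 5, 10)
    _, var = naive_log_or(table)
    assert propagated_variance(table, MisclassSpec(1, 1), 0.0) == pytest.approx(var)


def test_lambda_or_noiseless_symmetric_table():
    r = lambda_or(NoisyTable(10, 10, 10, 10), MisclassSpec(1, 1))
    assert r.feasible and r.lam == 0.0
    assert r.log_or == pytest.approx(0.0)
    assert r.z == pytest.approx(0.0)
    assert r.p_two_sided == pytest.approx(1.0)
    assert r.ci_low <= r.log_or <= r.ci_high


@settings(deadline=None, derandomize=True)
@given(st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500))
def test_reduction_to_naive_or_property(a, b, c, d):
    """p = q = 1 and λ = 0 reproduce the classical estimator exactly."""
    table = NoisyTable(a, b, c, d)
    r = lambda_or(table, MisclassSpec(1, 1))
    log_or, var = naive_log_or(table)
    assert r.lam == 0.0
    assert r.log_or == pytest.approx(log_or, abs=1e-12)
    assert r.var_naive == pytest.approx(var, abs=1e-12)
    assert r.var_extra == 0.0


@settings(deadline=None, derandomize=True)
@given(st.integers(1, 300), st.integers(1, 300), st.integers(1, 300), st.integers(1, 300))
def test_exposure_swap_symmetry(a, b, c, d):
    """Swapping exposure rows negates the log OR and preserves the p-value."""
    spec = MisclassSpec(0.9, 0.95)
    table = NoisyTable(a, b, c, d)
    r1 = lambda_or(table, spec)
    r2 = lambda_or(table.swapped_exposure(), spec)
    if r1.feasible and r2.feasible:
        assert r2.log_or == pytest.approx(-r1.log_or, rel=1e-9, abs=1e-12)
        assert r2.p_two_sided == pytest.approx(r1.p_two_sided, rel=1e-9)


def test_var_total_decomposition():
    table = NoisyTable(120, 60, 40, 200)
    known = lambda_or(table, MisclassSpec(0.9, 0.9))
    estimated = lambda_or(table, MisclassSpec(0.9, 0.9, n_val=500))
    assert known.var_total == pytest.approx(known.var_naive)
    assert estimated.var_total == pytest.approx(
        estimated.var_naive + estimated.var_extra
    )
    assert estimated.var_total > estimated.var_naive


def test_lambda_or_recovers_planted_effect():
    from adrdscreen.simulate import simulate_noisy_table

    true_log_or = math.log(3)
    table, _ = simulate_noisy_table(true_log_or, 50_000, 0.9, 0.95, seed=77)
    r = lambda_or(table, MisclassSpec(0.9, 0.95))
    assert r.feasible
    assert abs(r.log_or - true_log_or) < 3 * math.sqrt(r.var_total)
    # the uncorrected estimate is attenuated toward the null
    naive, _ = naive_log_or(table)
    assert abs(naive - true_log_or) > abs(r.log_or - true_log_or)


def test_build_stratified_table_hand_fixture():
    scores = [0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1]
    exposed = [True, True, False, True, False, True, False, False]
    table = build_stratified_table(scores, exposed, risk_threshold=0.5)
    # high-risk = score >= 0.5: patients 0-3
    assert (table.a, table.b, table.c, table.d) == (3, 1, 1, 3)


def test_build_stratified_table_degenerate_stratum_warns():
    with pytest.warns(UserWarning):
        build_stratified_table([0.9, 0.8], [True, False], risk_threshold=0.1)


def test_exposure_and_label_prevalence():
    table = NoisyTable(177240, 2543094, 307481, 9841665)
    case_frac, ctrl_frac = exposure_prevalence(table)
    assert case_frac == pytest.approx(0.366, abs=5e-4)
    assert ctrl_frac == pytest.approx(0.205, abs=5e-4)
    small = NoisyTable(2914 * 0.5, 100, 2914 * 0.5, 72650 - 2914 - 100)
    assert label_prevalence(small) == pytest.approx(2914 / 72650)


def test_volcano_table_single_and_direction():
    spec = MisclassSpec(0.95, 0.95)
    risk = lambda_or(NoisyTable(60, 20, 20, 60), spec)
    prot = lambda_or(NoisyTable(20, 60, 60, 20), spec)
    df = volcano_table({"I10": risk})
    assert len(df) == 1 and df.loc[0, "direction"] == "risk"
    df2 = volcano_table({"I10": risk, "N80": prot})
    assert set(df2["direction"]) == {"risk", "protective"}


def test_volcano_bh_adjustment_matches_hand_computation():
    # BH on p = (0.01, 0.02, 0.04) -> q = (0.03, 0.03, 0.04)
    def fake(p):
        return LambdaORResult(
            corrected_table=np.eye(2), lam=0.0, epsilon=0.5, feasible=True,
            log_or=1.0, var_naive=0.1, var_extra=0.0, var_total=0.1,
            z=1.0, p_two_sided=p, ci_low=0.5, ci_high=1.5,
        )

    df = volcano_table({"A": fake(0.01), "B": fake(0.02), "C": fake(0.04)})
    by_code = dict(zip(df["code"], df["q_bh"]))
    assert by_code["A"] == pytest.approx(0.03)
    assert by_code["B"] == pytest.approx(0.03)
    assert by_code["C"] == pytest.approx(0.04)
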