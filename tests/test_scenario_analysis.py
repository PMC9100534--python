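"""Projection, classification, zonal overlap, and MESS novelty analysis."""

import numpy as np
import pandas as pd
import pytest

from cnm import synthetic_data as sd
from cnm.evaluation_ensemble import EnsembleConfig, run_ensemble
from cnm.grids import EmptyDomainError, GridStack
from cnm.scenario_analysis import (
    HIGH, MODERATE, UNSUITABLE,
    analyse_scenario,
    class_fractions,
    classify,
    integrate_mess,
    mess,
    project,
    scenario_summary,
    suitable_negative_overlap,
    zonal_overlap,
)
from conftest import make_grid


def brute_force_mess(reference: pd.DataFrame, stack: GridStack) -> np.ndarray:
    """Naive per-cell, per-variable MESS loops (independent oracle)."""
    variables = list(reference.columns)
    nr, nc = stack.shape
    out = np.full((nr, nc), np.nan)
    mask = stack.combined_mask()
    for r in range(nr):
        for c in range(nc):
            if mask[r, c]:
                continue
            sims = []
            for v in variables:
                ref = reference[v].to_numpy()
                p = stack[v].values[r, c]
                n = len(ref)
                f = 100.0 * sum(x < p for x in ref) / n
                lo, hi = ref.min(), ref.max()
                if f == 0:
                    s = (p - lo) / (hi - lo) * 100
                elif f <= 50:
                    s = 2 * f
                elif f < 100:
                    s = 2 * (100 - f)
                else:
                    s = (hi - p) / (hi - lo) * 100
                sims.append(s)
            out[r, c] = min(sims)
    return out


# -- classification and cover -------------------------------------------------


def test_classify_threshold_semantics():
    probs = make_grid(np.array([[0.05, 0.1, 0.3], [0.5, 0.51, 0.7]]))
    cls = classify(probs)
    expected = np.array([[UNSUITABLE, MODERATE, MODERATE],
                         [MODERATE, HIGH, HIGH]], dtype=float)
    np.testing.assert_array_equal(cls.values, expected)
    with pytest.raises(ValueError):
        classify(probs, t_low=0.5, t_high=0.1)


def test_class_fractions_counts():
    cls = make_grid(np.array([[2.0, 2.0], [1.0, 0.0]]))
    f = class_fractions(cls)
    assert f == {"high": 50.0, "moderate": 25.0, "unsuitable": 25.0}
    assert sum(f.values()) == pytest.approx(100.0, abs=1e-9)
    all_high = make_grid(np.full((3, 3), 2.0))
    assert class_fractions(all_high)["high"] == 100.0
    empty_mask = np.ones((2, 2), dtype=bool)
    with pytest.raises(EmptyDomainError):
        class_fractions(make_grid(np.full((2, 2), np.nan), mask=empty_mask))


def test_class_fractions_invariant_to_permutation():
    rng = np.random.default_rng(0)
    vals = rng.integers(0, 3, (6, 6)).astype(float)
    f1 = class_fractions(make_grid(vals))
    f2 = class_fractions(make_grid(rng.permutation(vals.ravel()).reshape(6, 6)))
    assert f1 == f2


def test_zonal_overlap_single_zone_equals_global():
    rng = np.random.default_rng(1)
    cls = make_grid(rng.integers(0, 3, (5, 5)).astype(float))
    zones = make_grid(np.ones((5, 5)))
    table = zonal_overlap(cls, zones)
    assert len(table) == 1
    f = class_fractions(cls)
    assert table.loc[0, "high_pct"] == pytest.approx(f["high"])
    assert table.loc[0, "moderate_pct"] == pytest.approx(f["moderate"])


def test_zonal_overlap_rows_sum_and_conserve_counts():
    rng = np.random.default_rng(2)
    cls = make_grid(rng.integers(0, 3, (10, 10)).astype(float))
    zones = sd.make_zones(10, 10, 4, seed=0, origin_lon=-110.0, origin_lat=30.0)
    table = zonal_overlap(cls, zones)
    for _, row in table.iterrows():
        assert row["high_pct"] + row["moderate_pct"] + row["unsuitable_pct"] \
            == pytest.approx(100.0, abs=1e-9)
    # zone counts per class sum to the global class counts
    for code, frac_col in ((HIGH, "high_pct"), (MODERATE, "moderate_pct")):
        total = sum(row[frac_col] / 100 * row["n_cells"]
                    for _, row in table.iterrows())
        assert total == pytest.approx(float((cls.values == code).sum()))


def test_zonal_overlap_pure_zone_row():
    cls = make_grid(np.full((4, 4), 2.0))
    zones = make_grid(np.ones((4, 4)))
    row = zonal_overlap(cls, zones).iloc[0]
    assert (row["high_pct"], row["moderate_pct"], row["unsuitable_pct"]) \
        == (100.0, 0.0, 0.0)


# -- MESS ---------------------------------------------------------------------


def test_mess_formula_branches():
    ref = pd.DataFrame({"x": np.arange(1.0, 11.0)})  # 1..10
    vals = np.array([[5.5, 1.0, 0.0, 12.0]])
    stack = GridStack({"x": make_grid(vals)})
    m = mess(ref, stack)
    # median (5 of 10 strictly below) -> 2*50 = 100
    assert m.values[0, 0] == pytest.approx(100.0)
    # at the reference minimum: f=0, p=min -> 0
    assert m.values[0, 1] == pytest.approx(0.0)
    # below the minimum -> negative, proportional to the shortfall
    assert m.values[0, 2] == pytest.approx((0.0 - 1.0) / 9.0 * 100)
    # above the maximum -> negative
    assert m.values[0, 3] == pytest.approx((10.0 - 12.0) / 9.0 * 100)


def test_mess_equals_brute_force_oracle():
    rng = np.random.default_rng(3)
    for trial in range(5):
        ref = pd.DataFrame({
            "a": rng.normal(size=12),
            "b": rng.normal(size=12),
        })
        stack = GridStack({
            "a": make_grid(rng.normal(scale=2, size=(8, 8))),
            "b": make_grid(rng.normal(scale=2, size=(8, 8))),
        })
        m = mess(ref, stack)
        oracle = brute_force_mess(ref, stack)
        np.testing.assert_allclose(m.values, oracle, atol=1e-10)


def test_mess_reference_cells_nonnegative():
    rng = np.random.default_rng(4)
    vals = rng.normal(size=(6, 6))
    stack = GridStack({"x": make_grid(vals)})
    ref = pd.DataFrame({"x": vals.ravel()})
    m = mess(ref, stack)
    assert np.all(m.values >= 0)


def test_mess_constant_reference_rejected():
    ref = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
    stack = GridStack({"x": make_grid(np.ones((2, 2)))})
    with pytest.raises(ValueError, match="constant"):
        mess(ref, stack)


def test_integrate_mess_mean_and_sign():
    a = make_grid(np.full((2, 2), 10.0))
    b = make_grid(np.full((2, 2), -10.0))
    mean, sign = integrate_mess([a, b])
    np.testing.assert_array_equal(mean.values, 0.0)
    np.testing.assert_array_equal(sign.values, 0.0)  # boundary: non-negative
    mean1, sign1 = integrate_mess([b])
    np.testing.assert_array_equal(mean1.values, b.values)
    np.testing.assert_array_equal(sign1.values, 1.0)


def test_suitable_negative_overlap_counts():
    cls = make_grid(np.array([[2.0, 1.0], [1.0, 0.0]]))
    all_pos = make_grid(np.zeros((2, 2)))
    assert suitable_negative_overlap(cls, all_pos) == 0.0
    all_neg = make_grid(np.ones((2, 2)))
    assert suitable_negative_overlap(cls, all_neg) == 100.0
    one_neg = make_grid(np.array([[1.0, 0.0], [0.0, 0.0]]))
    assert suitable_negative_overlap(cls, one_neg) == pytest.approx(100 / 3)
    no_suitable = make_grid(np.zeros((2, 2)))
    assert np.isnan(suitable_negative_overlap(no_suitable, all_pos))


# -- projection ---------------------------------------------------------------


@pytest.fixture(scope="module")
def fitted(small_world):
    cfg = EnsembleConfig(n_runs=2, background_n=800)
    ens = run_ensemble(
        small_world.occurrences, small_world.current,
        ["temp_range", "prec_season"], cfg, seed=21,
    )
    return ens, small_world


def test_project_training_stack_reproduces_integration(fitted):
    ens, world = fitted
    proj = project(ens, world.current.subset(ens.variables))
    np.testing.assert_allclose(proj.values, ens.integrated.values, atol=1e-12)


def test_project_missing_layer_raises(fitted):
    ens, world = fitted
    partial = GridStack({"temp_range": world.current["temp_range"]})
    with pytest.raises(KeyError):
        project(ens, partial)


def test_analyse_scenario_structure(fitted):
    ens, world = fitted
    delta, stack = world.futures[0]
    res = analyse_scenario(ens, stack.subset(ens.variables),
                           delta.label, delta.forcing)
    assert sum(res.fractions.values()) == pytest.approx(100.0, abs=1e-9)
    assert res.mess_sign is not None
    assert res.negative_overlap_pct is not None
    table = scenario_summary([res])
    assert table.loc[0, "scenario"] == delta.label


def test_favorable_ladder_non_decreasing_high_fraction(fitted):
    ens, world = fitted
    base = analyse_scenario(ens, world.current.subset(ens.variables),
                            "current", run_mess=False)
    fracs = [base.fractions["high"]]
    for mag in (0.3, 0.6, 0.9, 1.2):
        delta = sd.ScenarioDelta(
            f"+{mag}", {"temp_range": mag, "prec_season": -mag}, 4.5
        )
        stack = sd.make_future_stack(world.current, delta)
        res = analyse_scenario(ens, stack.subset(ens.variables),
                               delta.label, run_mess=False)
        fracs.append(res.fractions["high"])
    assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))
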