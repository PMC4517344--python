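"""Agreement statistics: ICC, two-way ANOVA, Dunnett, CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdtsim.stats import (
    coefficient_of_variation,
    dunnett_vs_control,
    icc,
    rdt_table,
    two_way_anova,
)

from .oracles import icc_oracle


# ---------------------------------------------------------------------------
# coefficient of variation


def test_cv_constant_is_zero():
    assert coefficient_of_variation([7.0, 7.0, 7.0]) == 0.0


def test_cv_hand_computed():
    assert coefficient_of_variation([90.0, 100.0, 110.0]) == pytest.approx(0.1)


def test_cv_zero_mean_rejected():
    with pytest.raises(ZeroDivisionError):
        coefficient_of_variation([-1.0, 1.0])


@settings(derandomize=True, max_examples=30)
@given(c=st.floats(0.1, 100.0))
def test_cv_scale_invariant(c):
    base = np.array([80.0, 95.0, 130.0, 110.0])
    assert coefficient_of_variation(c * base) == pytest.approx(
        coefficient_of_variation(base), rel=1e-9
    )


# ---------------------------------------------------------------------------
# ICC


def test_icc_identical_columns_is_one():
    t = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [5.0, 5.0]])
    assert icc(t, "consistency").icc_value == pytest.approx(1.0)
    assert icc(t, "absolute").icc_value == pytest.approx(1.0)


def test_icc_additive_bias_property():
    """A constant shift leaves consistency at 1 but lowers absolute
    agreement."""
    a = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
    t = np.column_stack([a, a + 2.0])
    assert icc(t, "consistency").icc_value == pytest.approx(1.0)
    assert icc(t, "absolute").icc_value < 1.0


@pytest.mark.parametrize("shape", [(6, 2), (10, 3)])
def test_icc_matches_sums_of_squares_oracle(shape):
    rng = np.random.default_rng(42)
    t = 100.0 + 15.0 * rng.standard_normal(shape)
    for model in ("consistency", "absolute"):
        assert icc(t, model).icc_value == pytest.approx(icc_oracle(t, model))


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(7)
    t = 100.0 + 15.0 * rng.standard_normal((8, 2))
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(8), 2),
            "rater": np.tile(["A", "B"], 8),
            "score": t.ravel(),
        }
    )
    res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    res = res.set_index("Type")["ICC"]
    assert icc(t, "consistency").icc_value == pytest.approx(res["ICC(C,1)"], abs=1e-9)
    assert icc(t, "absolute").icc_value == pytest.approx(res["ICC(A,1)"], abs=1e-9)


def test_icc_invalid_tables_rejected():
    with pytest.raises(ValueError):
        icc(np.ones((1, 2)))
    with pytest.raises(ValueError):
        icc(np.full((4, 2), 3.0))  # zero total variance
    bad = np.ones((4, 2))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        icc(bad)


# ---------------------------------------------------------------------------
# two-way ANOVA


def _records(values_by_cell, n_rep):
    rows = []
    for (m, d), vals in values_by_cell.items():
        for i, v in enumerate(vals[:n_rep]):
            rows.append({"phantom_id": f"P{i}", "method": m, "depth_mm": d, "rdt_um": v})
    return pd.DataFrame(rows)


def test_anova_all_equal_data_has_zero_ss():
    df = _records(
        {(m, d): [5.0] * 4 for m in ("3D", "Pa", "An") for d in (3.0, 5.0)}, 4
    )
    res = two_way_anova(df)
    assert res.table.loc["method", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
    assert np.isnan(res.table.loc["method", "F"])


def test_anova_pure_main_effect_closed_form():
    """Injected method offsets with no noise: SS_method = r*nb*sum(effect^2)."""
    effects = {"3D": -10.0, "Pa": 10.0, "An": 0.0}
    df = _records(
        {(m, d): [100.0 + effects[m]] * 5 for m in effects for d in (3.0, 5.0)}, 5
    )
    res = two_way_anova(df)
    expected = 5 * 2 * sum(e**2 for e in effects.values())
    assert res.table.loc["method", "sum_sq"] == pytest.approx(expected)
    assert res.table.loc["depth_mm", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
    assert res.table.loc["method:depth_mm", "sum_sq"] == pytest.approx(0.0, abs=1e-9)


def test_anova_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    from statsmodels.formula.api import ols

    rng = np.random.default_rng(3)
    df = _records(
        {
            (m, d): list(100 + 10 * rng.standard_normal(6))
            for m in ("3D", "Pa", "An")
            for d in (3.0, 5.0)
        },
        6,
    )
    mine = two_way_anova(df).table
    fit = ols("rdt_um ~ C(method) * C(depth_mm)", data=df).fit()
    ref = sm.stats.anova_lm(fit, typ=2)
    assert mine.loc["method", "sum_sq"] == pytest.approx(ref.loc["C(method)", "sum_sq"])
    assert mine.loc["depth_mm", "sum_sq"] == pytest.approx(
        ref.loc["C(depth_mm)", "sum_sq"]
    )
    assert mine.loc["method:depth_mm", "sum_sq"] == pytest.approx(
        ref.loc["C(method):C(depth_mm)", "sum_sq"]
    )
    assert mine.loc["method", "p"] == pytest.approx(ref.loc["C(method)", "PR(>F)"])


def test_anova_row_order_invariant():
    rng = np.random.default_rng(5)
    df = _records(
        {
            (m, d): list(100 + 10 * rng.standard_normal(4))
            for m in ("3D", "Pa")
            for d in (3.0, 5.0)
        },
        4,
    )
    shuffled = df.sample(frac=1.0, random_state=1)
    pd.testing.assert_frame_equal(
        two_way_anova(df).table, two_way_anova(shuffled).table
    )


def test_anova_invalid_designs_rejected():
    df = _records({("3D", 3.0): [1.0, 2.0], ("Pa", 3.0): [1.0, 2.0]}, 2)
    with pytest.raises(ValueError):
        two_way_anova(df)  # single depth level
    df2 = _records(
        {(m, d): [1.0, 2.0] for m in ("3D", "Pa") for d in (3.0, 5.0)}, 2
    )
    with pytest.raises(ValueError):
        two_way_anova(df2.iloc[:-1])  # unbalanced


# ---------------------------------------------------------------------------
# Dunnett


def test_dunnett_identical_groups_not_significant():
    rng = np.random.default_rng(11)
    base = 100 + 10 * rng.standard_normal(12)
    df = pd.DataFrame(
        {
            "method": np.repeat(["3D", "Pa", "An"], 12),
            "rdt_um": np.concatenate([base, base, base]),
        }
    )
    res = dunnett_vs_control(df)
    assert not res["significant"].any()


def test_dunnett_huge_shift_is_significant():
    rng = np.random.default_rng(12)
    base = 100 + 1.0 * rng.standard_normal(12)
    df = pd.DataFrame(
        {
            "method": np.repeat(["3D", "Pa", "An"], 12),
            "rdt_um": np.concatenate([base, base + 10.0, base]),
        }
    )
    res = dunnett_vs_control(df).set_index("comparison")
    assert bool(res.loc["Pa vs 3D", "significant"])
    assert not bool(res.loc["An vs 3D", "significant"])


def test_dunnett_single_comparison_reduces_to_t_test():
    from scipy import stats as sps

    rng = np.random.default_rng(13)
    a = 100 + 10 * rng.standard_normal(10)
    b = 108 + 10 * rng.standard_normal(10)
    df = pd.DataFrame(
        {"method": np.repeat(["3D", "Pa"], 10), "rdt_um": np.concatenate([a, b])}
    )
    res = dunnett_vs_control(df)
    t_p = sps.ttest_ind(b, a).pvalue
    assert res["p_adjusted"].iloc[0] == pytest.approx(t_p, abs=1e-3)


def test_dunnett_missing_control_rejected():
    df = pd.DataFrame({"method": ["Pa"] * 3, "rdt_um": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError):
        dunnett_vs_control(df)


def test_rdt_table_requires_completeness():
    df = pd.DataFrame(
        {
            "phantom_id": ["P0", "P0", "P1"],
            "method": ["3D", "Pa", "3D"],
            "depth_mm": [3.0, 3.0, 3.0],
            "rdt_um": [1.0, 2.0, 3.0],
        }
    )
    with pytest.raises(ValueError):
        rdt_table(df)
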