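"""Agreement statistics for the RDT comparison.

The per-tooth minimum-RDT values, organised as phantoms × (measurement
method × fragment depth), are analysed the way the radiographic-agreement
literature does: a balanced two-way fixed-effects ANOVA (method × depth),
Dunnett-style multiple comparisons of each radiographic method against the
3D standard, two-way single-measure intraclass correlation coefficients
between each radiographic method and the 3D measurement, and the
coefficient of variation of the 3D values.

The ANOVA sums of squares and the ICC mean-square formulas are computed
in-package; F and Dunnett p-values come from scipy's distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ICCResult:
    """Two-way single-measure intraclass correlation."""

    icc_value: float
    model_tag: str  # "consistency" (ICC(3,1)) or "absolute" (ICC(2,1))
    n_subjects: int
    n_raters: int


@dataclass
class AnovaResult:
    """Balanced two-way ANOVA decomposition with interaction."""

    table: pd.DataFrame  # rows: factor A, factor B, A:B, residual, total
    factor_a: str
    factor_b: str


def coefficient_of_variation(values) -> float:
    """Sample standard deviation over mean (dimensionless)."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        raise ZeroDivisionError("coefficient of variation undefined for zero mean")
    if v.size < 2:
        return 0.0
    return float(v.std(ddof=1) / m)


# ---------------------------------------------------------------------------
# two-way ANOVA from sums of squares


def _mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """Row, column and residual mean squares of a complete two-way layout
    (one observation per cell): the ICC building blocks."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_err


def icc(table, model_tag: str = "consistency") -> ICCResult:
    """Single-measure ICC from two-way ANOVA mean squares.

    ``table`` is subjects × raters (complete, no missing cells).
    ``"consistency"`` is ICC(3,1) — insensitive to an additive rater bias;
    ``"absolute"`` is ICC(2,1) — absolute agreement, penalising bias.

    Raises on an incomplete table or zero total variance.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a 2D table with >= 2 subjects and >= 2 raters")
    if np.any(~np.isfinite(t)):
        raise ValueError("table must be complete (no missing cells)")
    if model_tag not in ("consistency", "absolute"):
        raise ValueError("model_tag must be 'consistency' or 'absolute'")
    n, k = t.shape
    if np.allclose(t, t.flat[0]):
        raise ValueError("zero total variance: ICC undefined")
    ms_r, ms_c, ms_e = _mean_squares(t)
    if model_tag == "consistency":
        denom = ms_r + (k - 1) * ms_e
        value = (ms_r - ms_e) / denom if denom > 0 else 0.0
    else:
        denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
        value = (ms_r - ms_e) / denom if denom > 0 else 0.0
    return ICCResult(float(value), model_tag, n, k)


def two_way_anova(
    records: pd.DataFrame,
    value: str = "rdt_um",
    factor_a: str = "method",
    factor_b: str = "depth_mm",
) -> AnovaResult:
    """Balanced two-way fixed-effects ANOVA with interaction.

    Every (A, B) cell must hold the same number of replicates (here, one
    reading per phantom).  F statistics use the residual mean square; with a
    zero residual or zero factor variance the F and p are reported as NaN.
    """
    df = pd.DataFrame(records)
    for col in (value, factor_a, factor_b):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    a_levels = np.unique(df[factor_a])
    b_levels = np.unique(df[factor_b])
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("each factor needs >= 2 levels")
    counts = df.groupby([factor_a, factor_b], observed=True)[value].count()
    if counts.nunique() != 1 or len(counts) != len(a_levels) * len(b_levels):
        raise ValueError("design must be complete and balanced")
    r = int(counts.iloc[0])

    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    a_means = df.groupby(factor_a, observed=True)[value].mean()
    b_means = df.groupby(factor_b, observed=True)[value].mean()
    cell_means = df.groupby([factor_a, factor_b], observed=True)[value].mean()
    nb, na = len(b_levels), len(a_levels)
    ss_a = float(r * nb * np.sum((a_means - grand) ** 2))
    ss_b = float(r * na * np.sum((b_means - grand) ** 2))
    ss_cells = float(r * np.sum((cell_means - grand) ** 2))
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ss_total - ss_cells

    df_a = na - 1
    df_b = nb - 1
    df_ab = df_a * df_b
    df_err = na * nb * (r - 1)

    def _row(ss, dof):
        ms = ss / dof if dof > 0 else np.nan
        return ss, dof, ms

    rows = {}
    rows[factor_a] = _row(ss_a, df_a)
    rows[factor_b] = _row(ss_b, df_b)
    rows[f"{factor_a}:{factor_b}"] = _row(ss_ab, df_ab)
    rows["residual"] = _row(ss_err, df_err)
    ms_err = rows["residual"][2]

    out = []
    for name, (ss, dof, ms) in rows.items():
        if name == "residual" or not np.isfinite(ms_err) or ms_err <= 0:
            f = p = np.nan
        else:
            f = ms / ms_err
            p = float(sps.f.sf(f, dof, df_err)) if np.isfinite(f) else np.nan
        out.append((name, ss, dof, ms, f, p))
    out.append(("total", ss_total, len(y) - 1, np.nan, np.nan, np.nan))
    table = pd.DataFrame(
        out, columns=["source", "sum_sq", "df", "mean_sq", "F", "p"]
    ).set_index("source")
    return AnovaResult(table=table, factor_a=factor_a, factor_b=factor_b)


def dunnett_vs_control(
    records: pd.DataFrame,
    value: str = "rdt_um",
    group: str = "method",
    control: str = "3D",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dunnett many-to-one comparisons against the 3D standard.

    Returns one row per non-control group with the Dunnett statistic, the
    family-wise adjusted p-value and a significance flag at ``alpha``.
    """
    df = pd.DataFrame(records)
    levels = list(pd.unique(df[group]))
    if control not in levels:
        raise ValueError(f"control level {control!r} not present")
    others = [g for g in levels if g != control]
    if not others:
        raise ValueError("no comparison groups besides the control")
    samples = [df.loc[df[group] == g, value].to_numpy(dtype=float) for g in others]
    ctrl = df.loc[df[group] == control, value].to_numpy(dtype=float)
    res = sps.dunnett(*samples, control=ctrl)
    return pd.DataFrame(
        {
            "comparison": [f"{g} vs {control}" for g in others],
            "statistic": res.statistic,
            "p_adjusted": res.pvalue,
            "significant": res.pvalue < alpha,
        }
    )


def rdt_table(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy RDT records into phantoms × (method, depth) — the complete
    table feeding the ICC."""
    df = pd.DataFrame(records)
    wide = df.pivot_table(
        index="phantom_id",
        columns=["method", "depth_mm"],
        values="rdt_um",
        aggfunc="first",
    )
    if wide.isna().any().any():
        raise ValueError("incomplete RDT table: every phantom needs all cells")
    return wide
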