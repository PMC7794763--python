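"""Factorial group statistics: ordinary one-/two-way ANOVA, Bonferroni
post-hoc comparisons, unpaired t-tests, and a factorial ANOVA computed
directly from printed per-group summary statistics (mean, SEM, n).

The summary-statistics route exists because published tables report only
(mean, SEM, n) per cell; those are sufficient statistics for the
fixed-effects decomposition, so the summary ANOVA is *exactly* equal to the
ANOVA on any raw sample realising the summaries — balanced or not.  Raw-data
ANOVAs delegate to statsmodels OLS; the summary route is an independent
weighted-model-comparison implementation, and the two are cross-checked in
the test suite.

Unbalanced designs default to Type II sums of squares (interaction tested
from the full model); Types I and III are switchable.  Degenerate
zero-variance inputs return SS=0, F=NaN (undefined marker) and p=1 with a
warning instead of raising, so simulation sweeps never crash.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

_ZERO_SS = 1e-12


@dataclass(frozen=True)
class SummaryCell:
    """One factor cell of a printed summary table."""

    mean: float
    sem: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("summary cell needs n >= 2")
        if self.sem <= 0:
            raise ValueError("summary cell needs sem > 0")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


@dataclass
class EffectRow:
    effect: str
    ss: float
    df: int
    F: float  # NaN marks "undefined" (zero residual variance)
    p: float


@dataclass
class PosthocRow:
    label: str
    diff: float
    t: float
    p_raw: float
    p_adj: float
    significant: bool


@dataclass
class AnovaResult:
    """Effect table plus the cell context needed for post-hoc comparisons."""

    effects: list[EffectRow]
    cell_means: dict[tuple, float]
    cell_ns: dict[tuple, int]
    mse: float
    df_resid: int
    posthoc: list[PosthocRow] = field(default_factory=list)

    def effect(self, name: str) -> EffectRow:
        for row in self.effects:
            if row.effect == name:
                return row
        raise KeyError(name)

    def p(self, name: str) -> float:
        return self.effect(name).p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"effect": e.effect, "ss": e.ss, "df": e.df, "F": e.F, "p": e.p} for e in self.effects]
        )


def significance_stars(p: float, alpha: float = 0.05) -> str:
    """Legend convention: */**/***/**** at 0.05/0.01/0.001/0.0001."""
    if np.isnan(p) or p >= alpha:
        return "ns"
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2)):
        if p < cut:
            return stars
    return "*"


def _design_columns(
    levels_a: list, levels_b: list | None, coding: str = "effect"
) -> dict[str, list]:
    """Effect-coded (sum-to-zero) design columns per effect, as cell-level rows.

    Returns {"intercept": ..., "A": cols, "B": cols, "A:B": cols} where each
    entry is a list of column vectors over the cell grid (row-major A×B).
    """
    a = len(levels_a)
    cells = list(itertools.product(range(a), range(len(levels_b)))) if levels_b else [
        (i, 0) for i in range(a)
    ]
    b = len(levels_b) if levels_b else 1

    def code(idx: int, nlev: int) -> list[float]:
        # sum-to-zero contrast columns for one factor level index
        out = []
        for j in range(nlev - 1):
            if idx == j:
                out.append(1.0)
            elif idx == nlev - 1:
                out.append(-1.0)
            else:
                out.append(0.0)
        return out

    cols: dict[str, list] = {"intercept": [np.ones(len(cells))]}
    cols["A"] = [np.array([code(i, a)[j] for i, _ in cells]) for j in range(a - 1)]
    if levels_b:
        cols["B"] = [np.array([code(k, b)[j] for _, k in cells]) for j in range(b - 1)]
        cols["A:B"] = [
            ca * cb for ca in cols["A"] for cb in cols["B"]
        ]
    return cols


def _weighted_rss(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Residual sum of squares of the weighted LS fit of y on X (weights w)."""
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)
    resid = y - X @ coef
    return float(np.sum(w * resid**2))


def _model_rss(cols: dict[str, list], terms: list[str], means: np.ndarray, ns: np.ndarray) -> float:
    X = np.column_stack(sum((cols[t] for t in terms), []))
    return _weighted_rss(X, means, ns.astype(float))


def _anova_from_cells(
    cell_index: list[tuple],
    means: np.ndarray,
    ns: np.ndarray,
    ss_within: float,
    levels_a: list,
    levels_b: list | None,
    ss_type: int = 2,
) -> AnovaResult:
    """Fixed-effects decomposition from cell means/sizes + pooled within-SS.

    Works for one factor (levels_b=None) or a full two-factor crossing.
    """
    N = int(ns.sum())
    n_cells = len(cell_index)
    df_resid = N - n_cells
    mse = ss_within / df_resid if df_resid > 0 else np.nan
    cols = _design_columns(levels_a, levels_b)
    effects: list[EffectRow] = []

    if levels_b is None:
        ss_a = _model_rss(cols, ["intercept"], means, ns)  # full model is saturated
        rows = [("factor", ss_a, len(levels_a) - 1)]
    else:
        full = ["intercept", "A", "B", "A:B"]
        rss = {
            tuple(t): _model_rss(cols, list(t), means, ns)
            for t in [
                ("intercept",),
                ("intercept", "A"),
                ("intercept", "B"),
                ("intercept", "A", "B"),
                ("intercept", "A", "A:B"),
                ("intercept", "B", "A:B"),
                ("intercept", "A", "B", "A:B"),
                ("intercept", "B", "A:B"),
            ]
        }
        df_a, df_b = len(levels_a) - 1, len(levels_b) - 1
        if ss_type == 1:
            ss_a = rss[("intercept",)] - rss[("intercept", "A")]
            ss_b = rss[("intercept", "A")] - rss[("intercept", "A", "B")]
        elif ss_type == 2:
            ss_a = rss[("intercept", "B")] - rss[("intercept", "A", "B")]
            ss_b = rss[("intercept", "A")] - rss[("intercept", "A", "B")]
        elif ss_type == 3:
            ss_a = rss[("intercept", "B", "A:B")] - rss[tuple(full)]
            ss_b = rss[("intercept", "A", "A:B")] - rss[tuple(full)]
        else:
            raise ValueError("ss_type must be 1, 2 or 3")
        ss_ab = rss[("intercept", "A", "B")] - rss[tuple(full)]
        rows = [
            ("factor_a", max(ss_a, 0.0), df_a),
            ("factor_b", max(ss_b, 0.0), df_b),
            ("interaction", max(ss_ab, 0.0), df_a * df_b),
        ]

    grand = float(np.sum(ns * means) / N)
    ss_total = float(np.sum(ns * (means - grand) ** 2)) + ss_within
    degenerate = ss_total < _ZERO_SS or mse < _ZERO_SS
    if degenerate:
        warnings.warn("zero-variance input: F undefined, p set to 1", stacklevel=3)
    for name, ss, df in rows:
        if degenerate or np.isnan(mse):
            effects.append(EffectRow(name, max(ss, 0.0), df, np.nan, 1.0))
        else:
            F = (ss / df) / mse
            effects.append(EffectRow(name, ss, df, F, float(sstats.f.sf(F, df, df_resid))))
    effects.append(EffectRow("residual", ss_within, df_resid, np.nan, np.nan))

    return AnovaResult(
        effects=effects,
        cell_means=dict(zip(cell_index, means.tolist())),
        cell_ns=dict(zip(cell_index, ns.astype(int).tolist())),
        mse=mse,
        df_resid=df_resid,
    )


def _cells_from_raw(values, level_cols):
    df = pd.DataFrame(values)
    grouped = df.groupby(level_cols, sort=True)["value"]
    means = grouped.mean()
    ns = grouped.size()
    ss_within = float(((df["value"] - grouped.transform("mean")) ** 2).sum())
    return means, ns, ss_within


def _degenerate(df: pd.DataFrame) -> bool:
    v = df["value"].to_numpy(float)
    return float(np.sum((v - v.mean()) ** 2)) < _ZERO_SS


def two_way_anova(
    values: pd.DataFrame,
    value_col: str = "value",
    a_col: str = "factor_a",
    b_col: str = "factor_b",
    ss_type: int = 2,
) -> AnovaResult:
    """Ordinary fixed-effects two-way ANOVA with interaction on raw data.

    Requires a full crossing with >= 2 observations per cell.  The fit is an
    OLS factorial model (statsmodels) summarised by the requested
    sum-of-squares type; Type III uses sum-to-zero contrasts.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = values.rename(columns={value_col: "value", a_col: "factor_a", b_col: "factor_b"})
    levels_a = sorted(df["factor_a"].unique())
    levels_b = sorted(df["factor_b"].unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs >= 2 levels")
    counts = df.groupby(["factor_a", "factor_b"]).size()
    for cell in itertools.product(levels_a, levels_b):
        if counts.get(cell, 0) < 2:
            raise ValueError(f"cell {cell} is empty or has < 2 observations")
    means, ns, ss_within = _cells_from_raw(df, ["factor_a", "factor_b"])
    cell_index = [tuple(k) for k in means.index]
    if _degenerate(df):
        return _anova_from_cells(
            cell_index, means.to_numpy(float), ns.to_numpy(float), ss_within,
            levels_a, levels_b, ss_type=ss_type,
        )
    contrast = ", Sum" if ss_type == 3 else ""
    model = smf.ols(
        f"value ~ C(factor_a{contrast}) * C(factor_b{contrast})", data=df
    ).fit()
    tbl = anova_lm(model, typ=ss_type)
    name_a = f"C(factor_a{contrast})"
    name_b = f"C(factor_b{contrast})"
    name_ab = f"{name_a}:{name_b}"
    mapping = [("factor_a", name_a), ("factor_b", name_b), ("interaction", name_ab)]
    effects = []
    for out_name, key in mapping:
        row = tbl.loc[key]
        effects.append(
            EffectRow(out_name, float(row["sum_sq"]), int(row["df"]),
                      float(row["F"]), float(row["PR(>F)"]))
        )
    resid = tbl.loc["Residual"]
    effects.append(EffectRow("residual", float(resid["sum_sq"]), int(resid["df"]), np.nan, np.nan))
    df_resid = int(resid["df"])
    return AnovaResult(
        effects=effects,
        cell_means=dict(zip(cell_index, means.to_numpy(float).tolist())),
        cell_ns=dict(zip(cell_index, ns.to_numpy(int).tolist())),
        mse=float(resid["sum_sq"]) / df_resid,
        df_resid=df_resid,
    )


def one_way_anova(
    values: pd.DataFrame, value_col: str = "value", level_col: str = "level"
) -> AnovaResult:
    """Ordinary one-way fixed-effects ANOVA on raw data (statsmodels OLS fit)."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = values.rename(columns={value_col: "value", level_col: "factor_a"})
    levels = sorted(df["factor_a"].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    counts = df.groupby("factor_a").size()
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 observations")
    means, ns, ss_within = _cells_from_raw(df, ["factor_a"])
    cell_index = [(k,) for k in means.index]
    if _degenerate(df):
        return _anova_from_cells(
            cell_index, means.to_numpy(float), ns.to_numpy(float), ss_within, levels, None
        )
    model = smf.ols("value ~ C(factor_a)", data=df).fit()
    tbl = anova_lm(model, typ=1)
    row = tbl.loc["C(factor_a)"]
    resid = tbl.loc["Residual"]
    df_resid = int(resid["df"])
    effects = [
        EffectRow("factor", float(row["sum_sq"]), int(row["df"]),
                  float(row["F"]), float(row["PR(>F)"])),
        EffectRow("residual", float(resid["sum_sq"]), df_resid, np.nan, np.nan),
    ]
    return AnovaResult(
        effects=effects,
        cell_means=dict(zip(cell_index, means.to_numpy(float).tolist())),
        cell_ns=dict(zip(cell_index, ns.to_numpy(int).tolist())),
        mse=float(resid["sum_sq"]) / df_resid,
        df_resid=df_resid,
    )


def summary_stats_anova(
    cells: dict[tuple[str, str], SummaryCell], ss_type: int = 2
) -> AnovaResult:
    """Two-way ANOVA computed directly from per-cell (mean, SEM, n).

    Within-cell SS is reconstructed as Σ(nᵢ−1)·(semᵢ·√nᵢ)²; between-effect
    SS come from weighted model comparisons on the cell means.  Exactly
    equal to :func:`two_way_anova` on any raw sample with these summaries.
    """
    levels_a = sorted({a for a, _ in cells})
    levels_b = sorted({b for _, b in cells})
    wanted = set(itertools.product(levels_a, levels_b))
    if set(cells) != wanted:
        from .io import IncompleteCrossingError

        raise IncompleteCrossingError("summary cells do not form a full crossing")
    index = sorted(cells)
    means = np.array([cells[k].mean for k in index], float)
    ns = np.array([cells[k].n for k in index], float)
    ss_within = float(sum((c.n - 1) * c.sd**2 for c in cells.values()))
    return _anova_from_cells(index, means, ns, ss_within, levels_a, levels_b, ss_type=ss_type)


def bonferroni_posthoc(
    result: AnovaResult,
    comparisons: list[tuple[tuple, tuple]] | None = None,
    alpha: float = 0.05,
) -> list[PosthocRow]:
    """Pairwise cell comparisons using the ANOVA residual mean square.

    Adjusted p = min(1, m·p) with m the number of comparisons.  The default
    family is the four within-row/within-column contrasts of a 2×2 design
    (factor-A effect within each B level, factor-B effect within each A
    level); the family size is recorded implicitly by the list length.
    """
    if comparisons is None:
        comparisons = default_2x2_comparisons(result)
    m = len(comparisons)
    rows = []
    for c1, c2 in comparisons:
        for c in (c1, c2):
            if c not in result.cell_means:
                raise KeyError(f"unknown cell {c}")
        diff = result.cell_means[c1] - result.cell_means[c2]
        se = np.sqrt(result.mse * (1 / result.cell_ns[c1] + 1 / result.cell_ns[c2]))
        if se < np.sqrt(_ZERO_SS):
            t, p = (np.nan, 1.0)
        else:
            t = diff / se
            p = float(2 * sstats.t.sf(abs(t), result.df_resid))
        p_adj = min(1.0, m * p)
        rows.append(
            PosthocRow(f"{c1} vs {c2}", float(diff), float(t), p, p_adj, p_adj < alpha)
        )
    result.posthoc = rows
    return rows


def default_2x2_comparisons(result: AnovaResult) -> list[tuple[tuple, tuple]]:
    levels_a = sorted({k[0] for k in result.cell_means})
    levels_b = sorted({k[1] for k in result.cell_means})
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise ValueError("default comparison family requires a 2x2 design")
    comps = []
    for b in levels_b:  # factor-A effect within each B level
        comps.append(((levels_a[0], b), (levels_a[1], b)))
    for a in levels_a:  # factor-B effect within each A level
        comps.append(((a, levels_b[0]), (a, levels_b[1])))
    return comps


def unpaired_t(values_a, values_b, welch: bool = False) -> tuple[float, float, float]:
    """Unpaired two-sample t-test; pooled variance by default, Welch optional.

    Returns (t, df, p).  Degenerate zero-variance input gives t=0, p=1 when
    the group means agree and t=±inf, p=0 otherwise.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va + vb < _ZERO_SS:
        warnings.warn("zero-variance t-test input", stacklevel=2)
        if abs(a.mean() - b.mean()) < np.sqrt(_ZERO_SS):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), float(len(a) + len(b) - 2), 0.0
    res = sstats.ttest_ind(a, b, equal_var=not welch)
    df = len(a) + len(b) - 2 if not welch else res.df
    return float(res.statistic), float(df), float(res.pvalue)
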