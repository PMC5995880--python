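"""Group-level inference on the long-format metrics table.

The inferential layer mirrors the panel statistics of a two-genotype,
four-session open-field design: Mann-Whitney U tests for behavioral
medians, two-way genotype x session ANOVA (Type-II sums of squares, since
cell counts per design cell are unbalanced) with Bonferroni-corrected
pairwise contrasts, and mean +/- SEM panel summaries.

Observations are treated as independent cells/fields; ``aggregate_animals``
collapses to per-animal means first, the statistically conservative
alternative when cells within an animal are correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

EXACT_MW_MAX_PRODUCT = 400


@dataclass(frozen=True)
class TestResult:
    test: str                      # mann_whitney_u | anova2 | bonferroni_pair
    effect: str                    # e.g. "genotype", "WT-KO @ session 1"
    statistic: float               # U or F or t
    df: tuple[float, float] | None
    p: float
    n: tuple[int, ...]

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass(frozen=True)
class PanelSummary:
    """Per-(genotype, session) n / mean / SEM table."""

    table: pd.DataFrame            # columns: group cols + n, mean, sem


def mann_whitney_u(a, b, effect: str = "") -> TestResult:
    """Two-tailed Mann-Whitney U with midrank tie handling.

    Reports U = min(U1, U2), the classical tabled statistic. The p-value is
    exact (permutation distribution) when n1*n2 <= 400 and the pooled
    sample is tie-free, otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) * len(b) <= EXACT_MW_MAX_PRODUCT and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, len(a) * len(b) - u1)
    return TestResult("mann_whitney_u", effect, u, None, float(res.pvalue),
                      (len(a), len(b)))


@dataclass(frozen=True)
class AnovaFit:
    """Two-way ANOVA results plus the residual variance for post-hocs."""

    genotype: TestResult
    session: TestResult
    interaction: TestResult
    mse: float
    df_resid: float
    cell_stats: pd.DataFrame       # per (genotype, session): n, mean


def anova2(table: pd.DataFrame, metric: str,
           factor_a: str = "genotype", factor_b: str = "session_index",
           aggregate_animals: bool = False) -> AnovaFit:
    """Two-way factor_a x factor_b ANOVA with Type-II sums of squares.

    Type-II SS is appropriate for the unbalanced cell counts that arise
    when different numbers of cells are recorded per session. dfs are
    reported as (effect df, residual df). Raises if any design cell is
    empty or either factor has a single level.
    """
    df = table[table["metric_name"] == metric].dropna(subset=["value"]).copy()
    if aggregate_animals:
        df = (df.groupby(["animal_id", factor_a, factor_b], as_index=False)
              ["value"].mean())
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    if df[factor_a].nunique() < 2 or df[factor_b].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    full = pd.MultiIndex.from_product(
        [df[factor_a].unique(), df[factor_b].unique()])
    missing = full.difference(counts.index)
    if len(missing):
        raise ValueError(f"empty design cell(s): {list(missing)}")
    df = df.rename(columns={factor_a: "A", factor_b: "B"})
    cell_stats = (df.groupby(["A", "B"], observed=True)["value"]
                  .agg(n="size", mean="mean").reset_index()
                  .rename(columns={"A": factor_a, "B": factor_b}))
    if df["value"].nunique() == 1:
        # no variance anywhere: every effect is exactly null
        a_lv, b_lv = df["A"].nunique(), df["B"].nunique()
        n_obs = len(df)
        df_resid = float(n_obs - a_lv * b_lv)
        zero = lambda effect, d1: TestResult(
            "anova2", effect, 0.0, (float(d1), df_resid), 1.0, (n_obs,))
        return AnovaFit(
            genotype=zero(factor_a, a_lv - 1),
            session=zero(factor_b, b_lv - 1),
            interaction=zero(f"{factor_a} x {factor_b}",
                             (a_lv - 1) * (b_lv - 1)),
            mse=0.0, df_resid=df_resid, cell_stats=cell_stats)
    model = smf.ols("value ~ C(A) * C(B)", data=df).fit()
    tab = anova_lm(model, typ=2)
    df_resid = float(tab.loc["Residual", "df"])
    mse = float(tab.loc["Residual", "sum_sq"] / df_resid)
    n_total = (len(df),)

    def row(name, effect):
        F = float(tab.loc[name, "F"])
        p = float(tab.loc[name, "PR(>F)"])
        if not np.isfinite(F):
            # zero residual variance: F is 0/0 for a null effect
            if abs(float(tab.loc[name, "sum_sq"])) <= 1e-12:
                F, p = 0.0, 1.0
            else:
                F, p = float("inf"), 0.0
        return TestResult("anova2", effect, F,
                          (float(tab.loc[name, "df"]), df_resid), p, n_total)

    return AnovaFit(
        genotype=row("C(A)", factor_a),
        session=row("C(B)", factor_b),
        interaction=row("C(A):C(B)", f"{factor_a} x {factor_b}"),
        mse=mse, df_resid=df_resid, cell_stats=cell_stats)


def bonferroni_pairs(table: pd.DataFrame, metric: str,
                     comparisons: list[tuple[tuple[str, str], object]] | None = None,
                     factor_a: str = "genotype",
                     factor_b: str = "session_index") -> list[TestResult]:
    """Pairwise factor_a contrasts within strata of factor_b.

    Each contrast uses the pooled residual variance of the two-way ANOVA
    (a protected-t / Fisher LSD statistic); p-values are multiplied by the
    number of comparisons and capped at 1. By default every stratum is
    tested with the two genotype levels.
    """
    fit = anova2(table, metric, factor_a, factor_b)
    df = table[table["metric_name"] == metric].dropna(subset=["value"])
    if comparisons is None:
        levels = sorted(df[factor_a].unique())
        if len(levels) != 2:
            raise ValueError("default comparisons need exactly 2 groups")
        comparisons = [((levels[0], levels[1]), s)
                       for s in sorted(df[factor_b].unique())]
    m = len(comparisons)
    out = []
    for (g1, g2), stratum in comparisons:
        sub = df[df[factor_b] == stratum]
        if len(sub) == 0:
            raise ValueError(f"unknown stratum {stratum!r}")
        x1 = sub.loc[sub[factor_a] == g1, "value"].to_numpy()
        x2 = sub.loc[sub[factor_a] == g2, "value"].to_numpy()
        n1, n2 = len(x1), len(x2)
        if n1 == 0 or n2 == 0:
            raise ValueError(f"empty group in stratum {stratum!r}")
        se = np.sqrt(fit.mse * (1.0 / n1 + 1.0 / n2))
        tstat = float((x1.mean() - x2.mean()) / se)
        raw = 2.0 * sps.t.sf(abs(tstat), fit.df_resid)
        out.append(TestResult(
            "bonferroni_pair", f"{g1}-{g2} @ {factor_b}={stratum}",
            tstat, (1.0, fit.df_resid), float(min(1.0, raw * m)), (n1, n2)))
    return out


def panel_summary(table: pd.DataFrame, metric: str,
                  group_by: tuple[str, ...] = ("genotype", "session_index")
                  ) -> PanelSummary:
    """n, mean, SEM per design cell; missing values dropped and counted."""
    df = table[table["metric_name"] == metric]
    grouped = df.groupby(list(group_by), observed=True)["value"]

    def sem(x):
        x = x.dropna()
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    out = grouped.agg(
        n=lambda x: int(x.notna().sum()),
        mean=lambda x: x.dropna().mean(),
        sem=sem,
    ).reset_index()
    return PanelSummary(out)


def results_table(results: list[TestResult]) -> pd.DataFrame:
    """Flatten test results to one CSV-ready row per test."""
    rows = []
    for r in results:
        rows.append({
            "test": r.test, "effect": r.effect, "statistic": r.statistic,
            "df1": r.df[0] if r.df else np.nan,
            "df2": r.df[1] if r.df else np.nan,
            "p": r.p, "n": "x".join(str(k) for k in r.n),
        })
    return pd.DataFrame(rows)
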