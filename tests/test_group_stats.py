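"""Mann-Whitney, two-way Type-II ANOVA and Bonferroni post-hocs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placecell import (anova2, bonferroni_pairs, mann_whitney_u,
                       new_metrics_table, panel_summary)


def mw_u_oracle(a, b):
    """Brute-force pair counting: #(a < b) + half ties, min of both sides."""
    u1 = sum(0.5 if x == y else float(x < y) for x in a for y in b)
    return min(u1, len(a) * len(b) - u1)


def mw_exact_p_oracle(a, b):
    """Full enumeration of group labelings (tie-free samples)."""
    pooled = list(a) + list(b)
    n1 = len(a)
    u_obs = mw_u_oracle(a, b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if mw_u_oracle(ga, gb) <= u_obs + 1e-9:
            count += 1
    return count / total


def metrics_from_values(values_by_cell, metric="m"):
    rows = []
    for (genotype, session), values in values_by_cell.items():
        for i, v in enumerate(values):
            rows.append(dict(animal_id=f"{genotype}1", genotype=genotype,
                             experiment_index=1, session_index=session,
                             cue_condition="full", unit_id=f"u{session}_{i}",
                             metric_name=metric, value=v))
    return new_metrics_table(rows)


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p == pytest.approx(1 / 3)

    def test_interleaved_samples_match_pair_counting(self):
        # perfectly interleaved groups: U = min(3, 1) = 1, p = 1
        res = mann_whitney_u([1, 3], [2, 4])
        assert res.statistic == mw_u_oracle([1, 3], [2, 4])
        assert res.p == pytest.approx(mw_exact_p_oracle([1, 3], [2, 4]))

    def test_smallest_case(self):
        res = mann_whitney_u([5], [7])
        assert res.statistic == 0
        assert res.p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_matches_pair_counting_oracle_random_samples(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            n1, n2 = rng.integers(1, 9, size=2)
            a = rng.integers(0, 10, n1).astype(float)  # ties likely
            b = rng.integers(0, 10, n2).astype(float)
            res = mann_whitney_u(a, b)
            assert res.statistic == pytest.approx(mw_u_oracle(a, b))

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(15):
            n1, n2 = rng.integers(2, 7, size=2)
            pooled = rng.permutation(np.arange(n1 + n2, dtype=float) + 1)
            a, b = pooled[:n1], pooled[n1:]
            res = mann_whitney_u(a, b)
            # P(min-U <= observed) under the permutation null is already
            # two-tailed: both directions shrink min(U1, U2)
            assert res.p == pytest.approx(mw_exact_p_oracle(a, b), abs=1e-9)


def balanced_ss_oracle(values):
    """Classical balanced two-way SS decomposition.

    ``values[(i, j)]`` holds the replicate list of cell (i, j).
    Returns (SS_A, SS_B, SS_AB, SS_E) with textbook formulas.
    """
    levels_a = sorted({i for i, _ in values})
    levels_b = sorted({j for _, j in values})
    n = len(next(iter(values.values())))
    all_vals = np.concatenate([np.asarray(v, float) for v in values.values()])
    grand = all_vals.mean()
    mean_a = {i: np.mean([v for j in levels_b for v in values[(i, j)]])
              for i in levels_a}
    mean_b = {j: np.mean([v for i in levels_a for v in values[(i, j)]])
              for j in levels_b}
    mean_ab = {k: np.mean(v) for k, v in values.items()}
    ss_a = n * len(levels_b) * sum((mean_a[i] - grand) ** 2 for i in levels_a)
    ss_b = n * len(levels_a) * sum((mean_b[j] - grand) ** 2 for j in levels_b)
    ss_ab = n * sum((mean_ab[(i, j)] - mean_a[i] - mean_b[j] + grand) ** 2
                    for i in levels_a for j in levels_b)
    ss_e = sum(((np.asarray(values[(i, j)]) - mean_ab[(i, j)]) ** 2).sum()
               for i in levels_a for j in levels_b)
    return ss_a, ss_b, ss_ab, ss_e


class TestAnova2:
    def test_constant_values_all_f_zero(self):
        table = metrics_from_values({
            ("WT", 1): [2.0, 2.0], ("WT", 2): [2.0, 2.0],
            ("KO", 1): [2.0, 2.0], ("KO", 2): [2.0, 2.0]})
        fit = anova2(table, "m")
        assert fit.genotype.statistic == 0 and fit.genotype.p == 1.0
        assert fit.interaction.statistic == 0

    def test_balanced_design_matches_hand_computed_ss(self):
        rng = np.random.default_rng(21)
        cells = {(g, s): list(rng.normal(loc + s, 1.0, 6))
                 for g, loc in (("WT", 0.0), ("KO", 1.2))
                 for s in (1, 2, 3, 4)}
        ss_a, ss_b, ss_ab, ss_e = balanced_ss_oracle(cells)
        df_a, df_b = 1, 3
        df_ab, df_e = 3, 8 * 6 - 8
        table = metrics_from_values(cells)
        fit = anova2(table, "m")
        assert fit.genotype.statistic == pytest.approx(
            (ss_a / df_a) / (ss_e / df_e), abs=1e-10)
        assert fit.session.statistic == pytest.approx(
            (ss_b / df_b) / (ss_e / df_e), abs=1e-10)
        assert fit.interaction.statistic == pytest.approx(
            (ss_ab / df_ab) / (ss_e / df_e), abs=1e-10)
        assert fit.genotype.df == (df_a, df_e)

    def test_empty_cell_rejected(self):
        table = metrics_from_values({
            ("WT", 1): [1.0, 2.0], ("WT", 2): [2.0, 1.5],
            ("KO", 1): [1.0, 3.0]})
        with pytest.raises(ValueError, match="empty design cell"):
            anova2(table, "m")

    def test_detects_strong_genotype_effect(self):
        rng = np.random.default_rng(22)
        cells = {(g, s): list(rng.normal(mu, 1.0, 20))
                 for g, mu in (("WT", 0.0), ("KO", 2.0)) for s in (1, 2)}
        fit = anova2(metrics_from_values(cells), "m")
        assert fit.genotype.p < 1e-6
        assert fit.interaction.p > 0.001


class TestBonferroni:
    def _table(self, seed=31, shift=0.0):
        rng = np.random.default_rng(seed)
        cells = {(g, s): list(rng.normal(shift * (g == "KO") * (s == 2),
                                         1.0, 15))
                 for g in ("WT", "KO") for s in (1, 2)}
        return metrics_from_values(cells)

    def test_single_comparison_unadjusted(self):
        table = self._table()
        (one,) = bonferroni_pairs(table, "m",
                                  comparisons=[(("WT", "KO"), 1)])
        many = bonferroni_pairs(table, "m")  # two strata -> factor 2
        same = [r for r in many if "=1" in r.effect][0]
        assert same.p == pytest.approx(min(1.0, one.p * 2), rel=1e-9)

    def test_adjusted_capped_at_one(self):
        table = self._table()
        results = bonferroni_pairs(table, "m")
        assert all(r.p <= 1.0 for r in results)

    def test_adjusted_at_least_raw(self):
        table = self._table(shift=1.0)
        (one,) = bonferroni_pairs(table, "m",
                                  comparisons=[(("WT", "KO"), 2)])
        both = bonferroni_pairs(table, "m")
        two = [r for r in both if "=2" in r.effect][0]
        assert two.p >= one.p - 1e-12

    def test_unknown_stratum_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_pairs(self._table(), "m",
                             comparisons=[(("WT", "KO"), 99)])

    def test_crossover_interaction_detected_with_one_contrast(self):
        # KO differs only in stratum 2: interaction + a single significant pair
        rng = np.random.default_rng(33)
        cells = {("WT", 1): list(rng.normal(0.5, 0.12, 40)),
                 ("WT", 2): list(rng.normal(0.43, 0.12, 40)),
                 ("KO", 1): list(rng.normal(0.30, 0.12, 40)),
                 ("KO", 2): list(rng.normal(0.49, 0.12, 40))}
        table = metrics_from_values(cells)
        fit = anova2(table, "m")
        assert fit.interaction.p < 0.05
        pairs = bonferroni_pairs(table, "m")
        sig = [r for r in pairs if r.p < 0.05]
        assert len(sig) == 1 and "=1" in sig[0].effect


class TestPanelSummary:
    def test_mean_and_sem_hand_computed(self):
        table = metrics_from_values({("WT", 1): [1.0, 2.0, 3.0]})
        row = panel_summary(table, "m").table.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(1.0 / np.sqrt(3))
        assert row["n"] == 3

    def test_single_value_sem_undefined(self):
        table = metrics_from_values({("WT", 1): [4.2]})
        row = panel_summary(table, "m").table.iloc[0]
        assert row["mean"] == pytest.approx(4.2)
        assert np.isnan(row["sem"])

    def test_all_missing_group_n_zero(self):
        table = metrics_from_values({("WT", 1): [np.nan, np.nan]})
        row = panel_summary(table, "m").table.iloc[0]
        assert row["n"] == 0
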