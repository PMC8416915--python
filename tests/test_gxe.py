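"""Two-way ANOVA partitioning, percentage bases, and Fisher's LSD letters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from anthoscan import (
    GxeDesign,
    anova_from_summaries,
    lsd_groups,
    lsd_groups_from_stats,
    percent_variation,
    simulate_gxe_table,
    summarize_table,
    two_way_anova,
)
from anthoscan.gxe import SOURCES, _stars


def random_balanced_table(rng, n_g=None, n_e=None, n=None):
    n_g = n_g or rng.integers(2, 6)
    n_e = n_e or rng.integers(2, 6)
    n = n or rng.integers(2, 7)
    rows = []
    for g in range(n_g):
        for e in range(n_e):
            cell = rng.normal(0, 2)
            for r in range(n):
                rows.append(
                    {"genotype": f"g{g}", "treatment": f"e{e}", "replicate": r + 1,
                     "value": cell + rng.normal(0, 0.5)}
                )
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        table = random_balanced_table(rng, n_g=4, n_e=4, n=4)
        ours = two_way_anova(table)

        fit = ols("value ~ C(genotype) * C(treatment)", table).fit()
        ref = sm.stats.anova_lm(fit, typ=1)
        assert ours["genotype"].ss == pytest.approx(ref.loc["C(genotype)", "sum_sq"])
        assert ours["environment"].ss == pytest.approx(ref.loc["C(treatment)", "sum_sq"])
        assert ours["gxe"].ss == pytest.approx(
            ref.loc["C(genotype):C(treatment)", "sum_sq"]
        )
        assert ours["residual"].ss == pytest.approx(ref.loc["Residual", "sum_sq"])
        assert ours["genotype"].p == pytest.approx(ref.loc["C(genotype)", "PR(>F)"])
        assert ours["gxe"].p == pytest.approx(
            ref.loc["C(genotype):C(treatment)", "PR(>F)"]
        )

    def test_hand_enumerable_2x2(self):
        """2x2 design with n=2, decomposed by hand from marginal means.

        Values: cell (a,x)={1,3}, (a,y)={2,4}, (b,x)={5,7}, (b,y)={10,12}.
        Grand mean 5.5; genotype means a=2.5, b=8.5; treatment x=4, y=7;
        cell means 2, 3, 6, 11.
        SS_G = 4*((2.5-5.5)^2+(8.5-5.5)^2) = 72
        SS_E = 4*((4-5.5)^2+(7-5.5)^2) = 18
        SS_GxE = 2*sum((cell - g - e + grand)^2) = 2*4*1 = 8
        SS_res = sum within-cell squares = 4 cells * 2*(1)^2 = 8
        """
        rows = []
        for g, t, vals in [("a", "x", (1, 3)), ("a", "y", (2, 4)),
                           ("b", "x", (5, 7)), ("b", "y", (10, 12))]:
            for r, v in enumerate(vals):
                rows.append({"genotype": g, "treatment": t, "replicate": r, "value": v})
        part = two_way_anova(pd.DataFrame(rows))
        assert part["genotype"].ss == pytest.approx(72.0)
        assert part["environment"].ss == pytest.approx(18.0)
        assert part["gxe"].ss == pytest.approx(8.0)
        assert part["residual"].ss == pytest.approx(8.0)
        assert part["genotype"].df == 1
        assert part["residual"].df == 4

    def test_all_observations_equal(self):
        rows = [
            {"genotype": g, "treatment": t, "replicate": r, "value": 2.5}
            for g in "ab" for t in "xy" for r in range(3)
        ]
        part = two_way_anova(pd.DataFrame(rows))
        for source in SOURCES:
            assert part[source].ss == pytest.approx(0.0)

    def test_pure_genotype_effect(self):
        design = GxeDesign(
            genotype_means={"g1": 1.0, "g2": 5.0, "g3": 9.0},
            environment_effects={"e1": 0.0, "e2": 0.0},
            replicate_sd=1e-9,
            seed=4,
        )
        part = two_way_anova(simulate_gxe_table(design))
        assert part["genotype"].percentage == pytest.approx(100.0, abs=1e-4)
        assert part["environment"].percentage == pytest.approx(0.0, abs=1e-4)
        assert part["gxe"].percentage == pytest.approx(0.0, abs=1e-4)

    def test_unbalanced_design_errors(self, rng):
        table = random_balanced_table(rng, n_g=2, n_e=2, n=3)
        with pytest.raises(ValueError, match="[Uu]nbalanced"):
            two_way_anova(table.iloc[:-1])

    def test_missing_cell_errors(self, rng):
        table = random_balanced_table(rng, n_g=2, n_e=2, n=3)
        dropped = table[~((table.genotype == "g0") & (table.treatment == "e0"))]
        with pytest.raises(ValueError):
            two_way_anova(dropped)

    def test_interaction_error_term_changes_main_effect_tests(self, rng):
        table = random_balanced_table(rng, n_g=3, n_e=3, n=4)
        fixed = two_way_anova(table, test_against="residual")
        mixed = two_way_anova(table, test_against="interaction")
        # Same decomposition, different denominators for the main effects.
        assert fixed["genotype"].ss == mixed["genotype"].ss
        assert fixed["gxe"].p == mixed["gxe"].p
        expected_f = mixed["genotype"].ms / mixed["gxe"].ms
        assert mixed["genotype"].f == pytest.approx(expected_f)


class TestSummariesEquivalence:
    def test_identical_to_raw_anova(self, rng):
        for _ in range(20):
            table = random_balanced_table(rng)
            raw = two_way_anova(table)
            from_sum = anova_from_summaries(summarize_table(table))
            for source in SOURCES:
                assert from_sum[source].ss == pytest.approx(
                    raw[source].ss, rel=1e-10, abs=1e-12
                )
                assert from_sum[source].df == raw[source].df

    def test_equal_cell_means_zero_effects(self):
        cells = [
            {"genotype": g, "treatment": t, "mean": 3.0, "sd": 0.4, "n": 4}
            for g in "ab" for t in "xy"
        ]
        part = anova_from_summaries(pd.DataFrame(cells))
        for source in ("genotype", "environment", "gxe"):
            assert part[source].percentage == pytest.approx(0.0)
        assert part["residual"].percentage == pytest.approx(100.0)

    def test_unequal_n_errors(self):
        cells = pd.DataFrame(
            [
                {"genotype": "a", "treatment": "x", "mean": 1, "sd": 0.1, "n": 4},
                {"genotype": "a", "treatment": "y", "mean": 1, "sd": 0.1, "n": 3},
                {"genotype": "b", "treatment": "x", "mean": 1, "sd": 0.1, "n": 4},
                {"genotype": "b", "treatment": "y", "mean": 1, "sd": 0.1, "n": 4},
            ]
        )
        with pytest.raises(ValueError, match="unbalanced"):
            anova_from_summaries(cells)


class TestPercentVariation:
    def test_identity_on_percent_inputs(self):
        ss = {"genotype": 77.7, "environment": 6.7, "gxe": 10.8, "residual": 4.8}
        assert percent_variation(ss) == pytest.approx(ss)

    def test_hand_arithmetic(self):
        out = percent_variation(
            {"genotype": 2.0, "environment": 1.0, "gxe": 1.0, "residual": 0.0}
        )
        assert out == {"genotype": 50.0, "environment": 25.0, "gxe": 25.0,
                       "residual": 0.0}

    def test_sums_to_100(self, rng):
        table = random_balanced_table(rng)
        for basis in ("ss", "variance_components"):
            part = two_way_anova(table, percent_of=basis)
            assert sum(part.percentages.values()) == pytest.approx(100.0)

    def test_partition_round_trip(self, rng):
        part = two_way_anova(random_balanced_table(rng))
        again = percent_variation(part)
        assert again.percentages == pytest.approx(part.percentages)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="zero"):
            percent_variation({"genotype": 0.0, "environment": 0.0,
                               "gxe": 0.0, "residual": 0.0})


def test_star_convention():
    assert _stars(0.2) == ""
    assert _stars(0.04) == "*"
    assert _stars(0.009) == "**"
    assert _stars(0.0009) == "***"


class TestLsdGroups:
    def test_two_well_separated_groups(self):
        rows = [
            {"genotype": g, "treatment": "t", "replicate": r, "value": v}
            for g, base in [("hi", 10.0), ("lo", 0.0)]
            for r, v in enumerate([base, base + 0.1, base - 0.1])
        ]
        grouping = lsd_groups(pd.DataFrame(rows), factor="genotype")
        assert grouping.letters["hi"] == "a"
        assert grouping.letters["lo"] == "b"

    def test_all_means_equal_share_a(self):
        rows = [
            {"genotype": g, "treatment": "t", "replicate": r, "value": v}
            for g in ("a", "b", "c")
            for r, v in enumerate([1.0, 1.2, 0.8])
        ]
        grouping = lsd_groups(pd.DataFrame(rows), factor="genotype")
        assert set(grouping.letters.values()) == {"a"}

    def test_matches_exhaustive_pairwise_oracle(self):
        """Letter sets must encode exactly the pairwise LSD comparisons."""
        means = {"g1": 0.0, "g2": 0.9, "g3": 1.7, "g4": 4.0}
        grouping = lsd_groups_from_stats(means, mse=1.0, df_residual=12,
                                         n_per_group=4, alpha=0.05)
        for a, b in itertools.combinations(means, 2):
            nonsig = abs(means[a] - means[b]) <= grouping.lsd
            shares = bool(set(grouping.letters[a]) & set(grouping.letters[b]))
            assert shares == nonsig, (a, b, grouping.letters, grouping.lsd)

    def test_chain_produces_overlapping_letters(self):
        # Adjacent means within LSD but extremes beyond it: middle gets "ab".
        means = {"hi": 2.0, "mid": 1.1, "lo": 0.0}
        grouping = lsd_groups_from_stats(means, mse=0.5, df_residual=9,
                                         n_per_group=3, alpha=0.05)
        assert grouping.lsd < 2.0
        assert grouping.letters["hi"] == "a"
        assert grouping.letters["lo"] == "b"
        assert set(grouping.letters["mid"]) == {"a", "b"}

    def test_row_shuffle_invariance(self, rng):
        table = random_balanced_table(rng, n_g=4, n_e=2, n=3)
        base = lsd_groups(table, factor="genotype")
        shuffled = lsd_groups(table.sample(frac=1, random_state=3), factor="genotype")
        assert base.letters == shuffled.letters
        assert base.lsd == pytest.approx(shuffled.lsd)

    def test_lsd_formula(self):
        from scipy import stats as sstats

        grouping = lsd_groups_from_stats({"a": 0.0, "b": 1.0}, mse=2.0,
                                         df_residual=10, n_per_group=5)
        expected = sstats.t.ppf(0.975, 10) * np.sqrt(2 * 2.0 / 5)
        assert grouping.lsd == pytest.approx(expected)

    def test_no_residual_df_errors(self):
        rows = [
            {"genotype": g, "treatment": "t", "replicate": 1, "value": 1.0}
            for g in "ab"
        ]
        with pytest.raises(ValueError, match="residual"):
            lsd_groups(pd.DataFrame(rows), factor="genotype")
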