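"""Richness/composition change statistics: Jaccard, G-tests, OLS, shares."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from insularis.change import (
    PeriodComparison,
    compare_periods,
    composition_shares,
    g_test,
    group_counts,
    interperiod_regression,
    jaccard_from_counts,
    pct_change,
    relative_change_by_area,
)
from insularis.errors import FormatError
from insularis.synthetic import ArchipelagoConfig, generate


class TestPeriodComparison:
    def test_jaccard_and_change_from_counts(self):
        comp = PeriodComparison.from_counts(1601, 1541, 1311)
        assert comp.jaccard == pytest.approx(1311 / (1601 + 1541 - 1311))
        assert round(comp.jaccard, 2) == 0.72
        assert comp.gained == 230
        assert comp.lost == 290
        assert comp.pct_change == pytest.approx(-3.7, abs=0.05)

    def test_identical_floras(self, tiny_occurrences, tiny_traits):
        comp = compare_periods(tiny_occurrences, "P1", "P1", traits=tiny_traits)
        assert comp.jaccard == 1.0
        assert comp.pct_change == 0.0

    def test_union_over_islands(self, tiny_occurrences, tiny_traits):
        comp = compare_periods(tiny_occurrences, "P1", "P2")
        assert comp.richness_p1 == 3  # sp1, sp2, sp3
        assert comp.richness_p2 == 3  # sp1, sp3, sp4
        assert comp.shared == 2
        assert comp.gained == 1 and comp.lost == 1

    def test_group_gains_partition_total(self):
        occ, islands, traits, _ = generate(ArchipelagoConfig(seed=3))
        total = compare_periods(occ, "P1", "P2")
        native = compare_periods(occ, "P1", "P2", traits=traits, origin="native")
        alien = compare_periods(occ, "P1", "P2", traits=traits, origin="alien")
        assert total.gained == native.gained + alien.gained
        assert total.lost == native.lost + alien.lost
        assert total.richness_p1 == native.richness_p1 + alien.richness_p1

    def test_pct_change_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            pct_change(0, 10)

    def test_jaccard_counts_validation(self):
        assert jaccard_from_counts(3, 5, 0) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            jaccard_from_counts(0, 0, 0)


class TestGTest:
    def test_origin_shift_reference_value(self):
        res = g_test([[1523, 78], [1360, 181]])
        assert res.g == pytest.approx(50.191, abs=0.1)
        assert res.df == 1
        assert res.p_value < 1e-4

    def test_perfect_independence(self):
        res = g_test([[10, 10], [10, 10]])
        assert res.g == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_log_likelihood_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            table = rng.integers(1, 200, size=(2, 3))
            res = g_test(table)
            g_ref, p_ref, df_ref, _ = chi2_contingency(
                table, correction=False, lambda_="log-likelihood")
            assert res.g == pytest.approx(g_ref)
            assert res.df == df_ref
            assert res.p_value == pytest.approx(p_ref)

    def test_invariant_to_permutations(self):
        table = np.array([[30, 12, 7], [8, 40, 22]])
        base = g_test(table).g
        assert g_test(table[::-1]).g == pytest.approx(base)
        assert g_test(table[:, ::-1]).g == pytest.approx(base)
        assert g_test(table.T).g == pytest.approx(base)

    def test_zero_cell_contributes_zero(self):
        res = g_test([[0, 50], [30, 20]])
        assert np.isfinite(res.g) and res.g > 0

    def test_zero_marginal_rejected(self):
        with pytest.raises(FormatError):
            g_test([[0, 0], [10, 20]])


class TestInterPeriodOLS:
    def test_identity_data(self):
        r = pd.Series([5.0, 10, 20, 40], index=list("abcd"))
        ols = interperiod_regression(r, r)
        assert ols.intercept == pytest.approx(0.0, abs=1e-10)
        assert ols.slope == pytest.approx(1.0)
        assert ols.r2 == pytest.approx(1.0)
        assert np.allclose(ols.residual_table["relative_residual"], 0.0, atol=1e-12)

    def test_matches_closed_form_slope(self):
        rng = np.random.default_rng(12)
        x = pd.Series(rng.uniform(5, 200, 10), index=[f"i{k}" for k in range(10)])
        y = 3.0 + 0.8 * x + pd.Series(rng.normal(0, 5, 10), index=x.index)
        ols = interperiod_regression(x, y)
        slope_cf = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert ols.slope == pytest.approx(slope_cf)
        assert ols.intercept == pytest.approx(y.mean() - slope_cf * x.mean())
        assert abs(ols.residual_table["residual"].mean()) < 1e-9

    def test_recovers_generating_line_within_two_se(self):
        # simulation property: coverage of the OLS estimator
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            x = pd.Series(rng.uniform(10, 300, 16))
            y = 10.0 + 0.8 * x + pd.Series(rng.normal(0, 8, 16))
            import statsmodels.api as sm
            model = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
            if abs(model.params[1] - 0.8) <= 2 * model.bse[1]:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_constant_predictor_rejected(self):
        r1 = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        r2 = pd.Series([4.0, 6.0, 5.0], index=list("abc"))
        with pytest.raises(FormatError):
            interperiod_regression(r1, r2)


class TestRelativeChange:
    def test_simple_percentages(self, tiny_islands):
        from insularis.core_data import OccurrenceTable
        rows = ([("s%d" % i, "big", "P1") for i in range(10)]
                + [("s%d" % i, "big", "P2") for i in range(25)]
                + [("x", "mid", "P1"), ("x", "mid", "P2")])
        occ = OccurrenceTable(records=pd.DataFrame(
            rows, columns=["species", "island", "period"]))
        table = relative_change_by_area(occ, tiny_islands, "P1", "P2")
        big = table.set_index("island").loc["big"]
        assert big["relative_change_pct"] == pytest.approx(150.0)
        mid = table.set_index("island").loc["mid"]
        assert mid["relative_change_pct"] == pytest.approx(0.0)
        small = table.set_index("island").loc["small"]
        assert bool(small["undefined"])

    def test_funnel_variance_shrinks_with_area(self):
        # occurrence-level turnover: small islands show more variable
        # relative change than large ones
        rel_by_half = {"small": [], "large": []}
        for seed in range(12):
            occ, islands, traits, _ = generate(ArchipelagoConfig(seed=seed))
            table = relative_change_by_area(occ, islands, "P1", "P2",
                                            traits=traits, origin="native")
            table = table[~table["undefined"]].sort_values("area_km2")
            half = len(table) // 2
            rel_by_half["small"].extend(table["relative_change_pct"].iloc[:half])
            rel_by_half["large"].extend(table["relative_change_pct"].iloc[half:])
        assert np.var(rel_by_half["small"]) > np.var(rel_by_half["large"])


class TestCompositionShares:
    def test_shares_sum_to_100(self, tiny_occurrences, tiny_traits):
        for classifier in ("origin", "functional_type"):
            shares = composition_shares(tiny_occurrences, tiny_traits, "P1",
                                        classifier=classifier)
            assert sum(shares["archipelago_pct"].values()) == pytest.approx(100.0)

    def test_single_class_dataset(self):
        from insularis.core_data import OccurrenceTable, SpeciesTraits
        occ = OccurrenceTable(records=pd.DataFrame(
            [("a", "i1", "P1"), ("b", "i1", "P1")],
            columns=["species", "island", "period"]))
        traits = SpeciesTraits(table=pd.DataFrame({
            "species": ["a", "b"], "origin": ["native", "native"],
            "functional_type": ["AH", "AH"]}))
        shares = composition_shares(occ, traits, "P1", classifier="origin")
        assert shares["archipelago_pct"]["native"] == pytest.approx(100.0)

    def test_alien_share_from_small_example(self, tiny_occurrences, tiny_traits):
        shares = composition_shares(tiny_occurrences, tiny_traits, "P1")
        assert shares["archipelago_pct"]["alien"] == pytest.approx(100 / 3)

    def test_group_counts_table(self, tiny_occurrences, tiny_traits):
        counts = group_counts(tiny_occurrences, tiny_traits, ["P1", "P2"])
        assert counts.loc["native", "P1"] == 2
        assert counts.loc["alien", "P1"] == 1
        assert counts.loc["native", "P2"] == 2
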