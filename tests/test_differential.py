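"""Differential screening: Welch statistic against its closed form and an
independent reference implementation, empirical-Bayes variance moderation
limits and parameter recovery, BH adjustment against brute force, and the
strict p < alpha DEG filter."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosstalk.containers import ExpressionMatrix
from crosstalk.differential import (
    DEGConfig,
    differential_expression,
    filter_degs,
    fit_variance_prior,
    moderated_t,
    volcano_annotations,
    welch_t,
)
from crosstalk.enrichment import bh_adjust
from crosstalk.errors import ParameterError
from crosstalk.synthetic import SyntheticConfig, generate_two_tissue_study

from conftest import make_matrix


class TestWelch:
    def test_closed_form_example(self):
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert abs(t - 3.674) < 1e-3
        assert abs(df - 4.0) < 1e-9
        assert abs(p - 0.0214) < 1e-3

    def test_matches_independent_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = rng.normal(size=rng.integers(3, 20))
            b = rng.normal(loc=rng.normal(), size=rng.integers(3, 20))
            t, df, p = welch_t(a, b)
            ref = stats.ttest_ind(b, a, equal_var=False)
            assert abs(t - ref.statistic) < 1e-10
            assert abs(p - ref.pvalue) < 1e-10
            assert abs(df - ref.df) < 1e-8

    def test_identical_groups_null(self):
        t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_antisymmetric_in_group_order(self):
        t1, df1, p1 = welch_t([1, 2, 4], [3, 6, 9])
        t2, df2, p2 = welch_t([3, 6, 9], [1, 2, 4])
        assert abs(t1 + t2) < 1e-12 and abs(p1 - p2) < 1e-12 and abs(df1 - df2) < 1e-12

    def test_shift_invariant_and_scale_equivariant(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=6), rng.normal(size=8)
        t0, _, p0 = welch_t(a, b)
        t1, _, p1 = welch_t(a + 5, b + 5)
        t2, _, p2 = welch_t(a * 3, b * 3)
        assert abs(t0 - t1) < 1e-10 and abs(p0 - p1) < 1e-10
        assert abs(t0 - t2) < 1e-10 and abs(p0 - p2) < 1e-10

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            welch_t([1.0], [1.0, 2.0])


class TestVariancePrior:
    def test_degenerate_equal_variances(self):
        d0, s0 = fit_variance_prior([2.5] * 50, residual_df=10)
        assert np.isinf(d0)
        assert abs(s0 - 2.5) < 1e-9

    def test_recovers_simulated_prior(self):
        """Variances from a scaled inverse chi-square (d0=4, s0^2=1) should be
        recovered within 20%."""
        rng = np.random.default_rng(5)
        d0_true, s0_true, df = 4.0, 1.0, 20
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=10000)
        s2 = sigma2 * rng.chisquare(df, size=10000) / df
        d0, s0 = fit_variance_prior(s2, residual_df=df)
        assert abs(d0 - d0_true) / d0_true < 0.20
        assert abs(s0 - s0_true) / s0_true < 0.20

    def test_too_few_variances_rejected(self):
        with pytest.raises(ParameterError):
            fit_variance_prior([1.0] * 9, residual_df=5)


class TestModerated:
    @pytest.fixture()
    def blocks(self):
        rng = np.random.default_rng(2)
        return rng.normal(size=(40, 6)), rng.normal(loc=0.3, size=(40, 8))

    def test_d0_zero_limit_is_pooled_t(self, blocks):
        hc, oa = blocks
        t, df, _, _, _ = moderated_t(hc, oa, d0=0.0, s0_sq=1.0)
        n1, n2 = 6, 8
        sp2 = ((n1 - 1) * hc.var(axis=1, ddof=1) + (n2 - 1) * oa.var(axis=1, ddof=1)) / (
            n1 + n2 - 2
        )
        expected = (oa.mean(axis=1) - hc.mean(axis=1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        np.testing.assert_allclose(t, expected, atol=1e-10)
        np.testing.assert_allclose(df, n1 + n2 - 2)

    def test_d0_infinite_limit_shares_prior_variance(self, blocks):
        hc, oa = blocks
        s0 = 0.8
        t, df, _, _, _ = moderated_t(hc, oa, d0=np.inf, s0_sq=s0)
        expected = (oa.mean(axis=1) - hc.mean(axis=1)) / np.sqrt(s0 * (1 / 6 + 1 / 8))
        np.testing.assert_allclose(t, expected, atol=1e-10)
        assert np.isinf(df).all()

    def test_moderation_shrinks_extreme_variances(self, blocks):
        hc, oa = blocks
        t, df, p, d0, s0 = moderated_t(hc, oa)
        assert d0 > 0 and s0 > 0
        assert (df > 12).all()  # gains d0 degrees of freedom over the pooled 12


class TestDifferentialExpression:
    def test_constant_matrix_is_all_null(self):
        mat = make_matrix(np.full((5, 8), 3.0))
        table = differential_expression(mat)
        assert (table["p_value"] == 1.0).all()
        assert (table["log2fc"] == 0.0).all()
        assert (table["adj_p"] >= table["p_value"]).all()

    def test_overwhelming_single_signal_ranks_first(self):
        rng = np.random.default_rng(3)
        values = rng.normal(8.0, 0.1, size=(50, 22))
        values[17, 11:] += 3.0  # planted gene, OA block
        mat = make_matrix(values)
        table = differential_expression(mat)
        assert table["p_value"].idxmin() == "G17"
        assert table.loc["G17", "direction"] == "up"

    def test_null_false_positive_rate_calibrated(self):
        cfg = SyntheticConfig(
            frac_de_ligands=0.0, frac_de_receptors=0.0, frac_de_background=0.0,
            effect_log2=0.0, seed=0,
        )
        blood, _, _ = generate_two_tissue_study(cfg)
        table = differential_expression(blood)
        frac = (table["p_value"] < 0.05).mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert 0.05 - half < frac < 0.05 + half

    def test_direction_consistent_with_fold_change(self, small_study):
        blood, _, _ = small_study
        table = differential_expression(blood)
        assert ((table["log2fc"] > 0) == (table["direction"] == "up")).all()

    def test_missing_group_rejected(self):
        mat = make_matrix(np.zeros((3, 4)), groups=["HC"] * 4)
        with pytest.raises(ParameterError):
            differential_expression(mat)

    def test_moderated_method_runs_and_orders_signal_first(self, small_study):
        blood, _, truth = small_study
        table = differential_expression(blood, DEGConfig(method="moderated"))
        degs = filter_degs(table, DEGConfig(method="moderated"))
        assert truth.de_genes("BL") <= degs.genes  # effect 2, sigma .5: all found


class TestFilterAndVolcano:
    def _table(self, p, fc):
        n = len(p)
        return pd.DataFrame(
            {
                "mean_hc": np.zeros(n), "mean_oa": fc, "log2fc": fc,
                "t_stat": np.zeros(n), "df": np.full(n, 10.0),
                "p_value": p, "adj_p": bh_adjust(p),
                "direction": np.where(np.asarray(fc) > 0, "up", "down"),
            },
            index=pd.Index([f"G{i:03d}" for i in range(n)], name="gene"),
        )

    def test_empty_table_gives_empty_set(self):
        table = self._table(np.array([]), np.array([]))
        assert len(filter_degs(table)) == 0

    def test_boundary_p_excluded_by_strict_inequality(self):
        table = self._table(np.array([0.05, 0.049]), np.array([1.0, -1.0]))
        degs = filter_degs(table, DEGConfig(alpha=0.05))
        assert degs.genes == {"G001"}
        assert degs.directions["G001"] == "down"

    def test_filter_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=300)
        fc = rng.normal(size=300)
        table = self._table(p, fc)
        for use_adj in (False, True):
            cfg = DEGConfig(alpha=0.1, use_adjusted=use_adj)
            expected = {
                g for g, row in table.iterrows()
                if (row["adj_p"] if use_adj else row["p_value"]) < 0.1
            }
            assert filter_degs(table, cfg).genes == expected

    def test_adjusted_filter_is_stricter(self, small_study):
        blood, _, _ = small_study
        table = differential_expression(blood)
        raw = filter_degs(table, DEGConfig(use_adjusted=False))
        adj = filter_degs(table, DEGConfig(use_adjusted=True))
        assert adj.genes <= raw.genes

    def test_volcano_clamps_when_a_side_runs_short(self):
        table = self._table(
            np.array([0.01, 0.02, 0.03, 0.04]), np.array([1.0, 2.0, 3.0, -1.0])
        )
        coords = volcano_annotations(table, top_n=20)
        assert coords["label"].sum() == 4

    def test_volcano_zero_labels(self):
        table = self._table(np.array([0.01, 0.5]), np.array([1.0, -1.0]))
        coords = volcano_annotations(table, top_n=0)
        assert coords["label"].sum() == 0
        np.testing.assert_allclose(coords["neg_log10_p"], -np.log10([0.01, 0.5]))

    def test_volcano_selection_matches_sort_oracle(self):
        rng = np.random.default_rng(6)
        p = np.round(rng.uniform(size=200), 2)  # heavy ties to exercise breaks
        fc = rng.normal(size=200)
        table = self._table(p, fc)
        coords = volcano_annotations(table, top_n=20)
        got = set(coords.index[coords["label"]])
        expected = set()
        for direction in ("up", "down"):
            rows = [
                (row["p_value"], -abs(row["log2fc"]), g)
                for g, row in table.iterrows() if row["direction"] == direction
            ]
            expected |= {g for _, _, g in sorted(rows)[:10]}
        assert got == expected


class TestBH:
    def test_hand_evaluated_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate_inputs(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 50))
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.5])
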