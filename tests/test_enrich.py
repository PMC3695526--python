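"""NB enrichment machinery: size factors, dispersions, exact test, BH, calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from sortmut.enrich import (
    MutationEnrichment,
    bh_adjust,
    enrichment_table,
    estimate_dispersions,
    nb_exact_test,
    size_factors,
)

ABC, DEF = list("abc"), list("def")


def nb_matrix(rng, mu, alpha, n_rows, n_cols):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu[:, None]), size=(n_rows, n_cols))


def null_matrix(rng, n_rows=474, lo=100, hi=3000, alpha=0.05):
    """Null count matrix at screen-like depth (means around the per-mutation
    coverage of a deeply sequenced pool)."""
    mu = 10 ** rng.uniform(np.log10(lo), np.log10(hi), n_rows)
    return pd.DataFrame(nb_matrix(rng, mu, alpha, n_rows, 6), columns=ABC + DEF), mu


class TestSizeFactors:
    def test_identical_columns_equal_factors(self):
        df = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2]})
        s = size_factors(df)
        assert s[0] == pytest.approx(s[1])

    def test_doubled_column_ratio_two(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        s = size_factors(df)
        assert s[1] / s[0] == pytest.approx(2.0)

    def test_single_sample_is_one(self):
        assert size_factors(pd.DataFrame({"a": [4, 7, 1]}))[0] == pytest.approx(1.0)

    def test_fallback_to_totals_when_no_positive_row(self):
        df = pd.DataFrame({"a": [0, 10], "b": [10, 0]})
        with pytest.warns(UserWarning, match="column-total"):
            s = size_factors(df)
        assert s[0] == pytest.approx(s[1])


class TestDispersions:
    def test_equal_replicates_clamped_to_floor(self):
        df = pd.DataFrame(np.full((10, 6), 50), columns=ABC + DEF)
        d = estimate_dispersions(df, ["A"] * 3 + ["B"] * 3, np.ones(6))
        assert (d["alpha_raw"] <= 0).all()
        assert (d["alpha"] >= 1e-8).all()
        assert d["alpha"].iloc[0] == pytest.approx(1e-8)

    def test_poisson_counts_near_floor(self):
        rng = np.random.default_rng(5)
        mu = 10 ** rng.uniform(2, 3, 474)
        df = pd.DataFrame(rng.poisson(mu[:, None], size=(474, 6)), columns=ABC + DEF)
        d = estimate_dispersions(df, ["A"] * 3 + ["B"] * 3, size_factors(df))
        assert 1e-8 <= np.nanmedian(d["alpha"]) <= 0.01

    def test_recovers_true_dispersion(self):
        rng = np.random.default_rng(6)
        mu = 10 ** rng.uniform(2.5, 3.5, 474)
        df = pd.DataFrame(nb_matrix(rng, mu, 0.1, 474, 6), columns=ABC + DEF)
        d = estimate_dispersions(df, ["A"] * 3 + ["B"] * 3, size_factors(df))
        assert 0.05 <= np.nanmedian(d["alpha"]) <= 0.2

    def test_all_zero_row_excluded(self):
        df = pd.DataFrame(np.vstack([[0] * 6, [9] * 6]), columns=ABC + DEF)
        d = estimate_dispersions(df, ["A"] * 3 + ["B"] * 3, np.ones(6))
        assert np.isnan(d["alpha"].iloc[0])
        assert np.isfinite(d["alpha"].iloc[1])


class TestNbExactTest:
    def test_balanced_counts_give_p_one(self):
        p = nb_exact_test([10, 10, 10], [10, 10, 10], np.ones(3), np.ones(3), 0.01)
        assert p == 1.0

    def test_symmetric_in_conditions(self):
        p1 = nb_exact_test([5, 7, 6], [20, 22, 18], np.ones(3), np.ones(3), 0.05)
        p2 = nb_exact_test([20, 22, 18], [5, 7, 6], np.ones(3), np.ones(3), 0.05)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_total_skipped(self):
        assert np.isnan(nb_exact_test([0], [0], np.ones(1), np.ones(1), 0.1))

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(0, 50, 3)
            b = rng.integers(0, 50, 3)
            if a.sum() + b.sum() == 0:
                continue
            p = nb_exact_test(a, b, np.ones(3), np.ones(3), 0.05)
            assert 0 < p <= 1

    def test_vanishing_dispersion_matches_exact_binomial(self):
        # oracle: conditioning Poisson sums on the total gives a binomial
        # law; scipy's two-sided exact binomial test is the reference
        for total in (1, 7, 30, 101, 200):
            for ka in range(0, total + 1, max(1, total // 10)):
                kb = total - ka
                p_nb = nb_exact_test([ka], [kb], np.ones(1), np.ones(1), 1e-8)
                p_bin = stats.binomtest(ka, total, 0.5).pvalue
                assert p_nb == pytest.approx(p_bin, abs=2e-3)

    def test_unequal_size_factors_shift_null(self):
        # with condition A sequenced twice as deep, a 2:1 count split is the
        # null expectation
        p = nb_exact_test([40], [20], np.array([2.0]), np.array([1.0]), 1e-8)
        assert p == 1.0


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        adj = bh_adjust([0.01, 0.02, 0.9])
        assert np.allclose(adj, [0.03, 0.03, 0.9])

    def test_equal_ps_unchanged(self):
        adj = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(adj, 0.2)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_hand_bh(self, ps):
        adj = bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        # hand step-up oracle
        p = np.asarray(ps)
        n = len(p)
        order = np.argsort(p, kind="stable")
        stepped = p[order] * n / np.arange(1, n + 1)
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(stepped, 1.0)
        assert np.allclose(adj, expected)


class TestEnrichmentModel:
    def test_null_type_one_error_within_band(self):
        rng = np.random.default_rng(123)
        reject = total = 0
        for _ in range(5):
            df, _ = null_matrix(rng)
            pv = MutationEnrichment(df, ABC, DEF).fit().table["p_value"].dropna()
            reject += (pv < 0.05).sum()
            total += len(pv)
        assert 0.03 <= reject / total <= 0.07

    def test_spiked_row_detected(self):
        # 8-fold enrichment at ~2000 reads/sample must be called
        rng = np.random.default_rng(9)
        mu = np.full(474, 2000.0)
        df = pd.DataFrame(nb_matrix(rng, mu, 0.02, 474, 6), columns=ABC + DEF)
        df.loc[7, ABC] = (df.loc[7, ABC] * 8).astype(int)
        res = MutationEnrichment(df, ABC, DEF).fit()
        assert res.table.loc[7, "call"] == "over"
        assert res.table.loc[7, "p_adjusted"] < 0.05

    def test_swapped_contrast_flips_calls(self):
        rng = np.random.default_rng(10)
        df, _ = null_matrix(rng)
        df.loc[0, ABC] *= 6
        df.loc[1, DEF] *= 6
        fwd = MutationEnrichment(df, ABC, DEF).fit().table
        rev = MutationEnrichment(df, DEF, ABC).fit().table
        flip = {"over": "under", "under": "over", "ns": "ns"}
        assert list(rev["call"]) == [flip[c] for c in fwd["call"]]
        assert np.allclose(
            rev["log2_ratio"], -fwd["log2_ratio"], equal_nan=True
        )

    def test_calls_consistent_with_padj_and_direction(self):
        rng = np.random.default_rng(11)
        df, _ = null_matrix(rng)
        res = MutationEnrichment(df, ABC, DEF).fit(alpha=0.2)
        t = res.table.dropna(subset=["p_value"])
        assert ((t["p_adjusted"] >= t["p_value"]) | np.isclose(t["p_adjusted"], t["p_value"])).all()
        sig = t[t["call"] != "ns"]
        assert (sig["p_adjusted"] < 0.2).all()
        assert ((sig["log2_ratio"] > 0) == (sig["call"] == "over")).all()

    def test_missing_condition_label_rejected(self, error_free_experiment):
        with pytest.raises(ValueError, match="no samples"):
            enrichment_table(error_free_experiment.matrix, ("srna:low", "srna:all"))

    def test_summary_mentions_counts(self):
        rng = np.random.default_rng(12)
        df, _ = null_matrix(rng, n_rows=50)
        res = MutationEnrichment(df, ABC, DEF).fit()
        s = res.summary()
        assert "over-represented" in s and "rows tested" in s


class TestFdrControl:
    def test_bh_keeps_fdr_in_spiked_simulation(self):
        rng = np.random.default_rng(77)
        tot_disc = tot_false = 0
        for _ in range(6):
            df, mu = null_matrix(rng)
            k = df.values.astype(float)
            spike = rng.choice(474, 40, replace=False)
            up, dn = spike[:20], spike[20:]
            r = 1 / 0.05
            k[up, :3] = rng.negative_binomial(
                r, r / (r + mu[up, None] * 8), size=(20, 3)
            )
            k[dn, :3] = rng.negative_binomial(
                r, r / (r + mu[dn, None] / 8), size=(20, 3)
            )
            df = pd.DataFrame(k, columns=ABC + DEF)
            res = MutationEnrichment(df, ABC, DEF).fit()
            sig = res.table["call"].values != "ns"
            truth = np.zeros(474, bool)
            truth[spike] = True
            tot_disc += int(sig.sum())
            tot_false += int((sig & ~truth).sum())
        fdr = tot_false / tot_disc
        assert fdr <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / tot_disc)
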