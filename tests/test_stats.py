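import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalfold.stats import (
    CohortTable,
    bh_fdr,
    fit_pad_regression,
    interaction_test,
    mode_continuous,
    run_association_suite,
)
from fetalfold.synthetic import synth_cohort_table


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """Closed-form OLS oracle: beta, SE, from (X'X)^-1."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    return beta, se


def bh_brute_force(p: np.ndarray, q: float):
    """Step-up definition: reject 1..k* where k* = max{k : p_(k) <= q k/m}."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestModeContinuous:
    def test_singleton(self):
        assert mode_continuous([5.0]) == 5.0

    def test_hand_traced_half_sample_recursion(self):
        # sorted [1,2,2,2,9]: shortest 3-interval is [2,2,2] -> mode 2
        assert mode_continuous([1, 2, 2, 2, 9]) == 2.0

    def test_two_values_mean(self):
        assert mode_continuous([1.0, 3.0]) == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mode_continuous([])

    def test_estimate_concentrates_near_true_mode_as_n_grows(self):
        """Skewed unimodal sample: the half-sample mode tracks the density
        peak and its error shrinks with sample size (~n^-1/3)."""
        errs = {}
        true_mode = 2.0  # Gamma(shape=3, scale=1) peaks at (k-1)*theta
        for n in (500, 50_000):
            vals = []
            for seed in range(8):
                rng = np.random.default_rng(seed)
                x = rng.gamma(3.0, 1.0, n)
                vals.append(abs(mode_continuous(x) - true_mode))
            errs[n] = np.mean(vals)
        assert errs[50_000] < errs[500]
        assert errs[50_000] < 0.25

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=40),
        st.floats(0.1, 5.0),
        st.floats(-10, 10),
    )
    @settings(max_examples=60, deadline=None)
    def test_translation_and_scale_equivariance(self, xs, a, b):
        x = np.asarray(xs)
        lhs = mode_continuous(a * x + b)
        rhs = a * mode_continuous(x) + b
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-7)


class TestPadRegression:
    def test_matches_normal_equations_oracle(self):
        for seed in range(5):
            df, _ = synth_cohort_table(n=60, gamma={"cerebral_volume": 0.4}, seed=seed)
            r = fit_pad_regression(CohortTable(df), "cerebral_volume")
            gw = df["gw"].to_numpy()
            x = df["cerebral_volume"].to_numpy()
            z = lambda v: (v - v.mean()) / v.std()
            X = np.column_stack([np.ones(len(df)), z(gw), z(x)])
            beta, se = ols_normal_equations(X, df["pad"].to_numpy())
            assert r.beta2 == pytest.approx(beta[2], abs=1e-8)
            assert r.se == pytest.approx(se[2], abs=1e-8)

    def test_recovers_generating_coefficient(self):
        hits = 0
        for seed in range(30):
            df, _ = synth_cohort_table(
                n=200, gamma={"cerebral_volume": 0.5}, sigma_pad=0.5, seed=seed
            )
            r = fit_pad_regression(CohortTable(df), "cerebral_volume")
            hits += abs(r.beta2 - 0.5) < 2 * r.se
        assert hits >= 27  # ~95% nominal

    def test_collinear_measure_rejected(self):
        df, _ = synth_cohort_table(n=50, seed=0)
        df["gw_copy"] = df["gw"]
        with pytest.raises(ValueError, match="collinear"):
            fit_pad_regression(CohortTable(df), "gw_copy")

    def test_small_cohort_rejected(self):
        df, _ = synth_cohort_table(n=20, seed=0)
        with pytest.raises(ValueError):
            fit_pad_regression(CohortTable(df.iloc[:3]), "cerebral_volume")


class TestInteraction:
    def test_sex_relabeling_flips_coefficient_sign(self):
        df, _ = synth_cohort_table(
            n=120,
            gamma={"cerebral_volume": 0.3},
            gamma_int=0.5,
            interaction_measure="cerebral_volume",
            seed=2,
        )
        r = interaction_test(CohortTable(df), "cerebral_volume")
        flipped = df.copy()
        flipped["sex"] = flipped["sex"].map({"M": "F", "F": "M", "unknown": "unknown"})
        rf = interaction_test(CohortTable(flipped), "cerebral_volume")
        assert rf.beta2 == pytest.approx(-r.beta2, abs=1e-8)

    def test_unknown_sex_dropped(self):
        df, _ = synth_cohort_table(n=120, seed=3)
        r = interaction_test(CohortTable(df), "cerebral_volume")
        assert r.n == (df["sex"] != "unknown").sum()

    def test_single_sex_rejected(self):
        df, _ = synth_cohort_table(n=60, seed=4)
        df["sex"] = "M"
        with pytest.raises(ValueError):
            interaction_test(CohortTable(df), "cerebral_volume")

    def test_detects_injected_interaction(self):
        rejections = 0
        for seed in range(20):
            df, _ = synth_cohort_table(
                n=99,
                gamma={"cerebral_volume": 0.3},
                gamma_int=0.8,
                interaction_measure="cerebral_volume",
                sigma_pad=0.7,
                seed=seed,
            )
            r = interaction_test(CohortTable(df), "cerebral_volume")
            rejections += r.pvalue < 0.05
        assert rejections / 20 > 0.5  # power above one half


class TestBhFdr:
    def test_hand_stepped_example(self):
        reject, _ = bh_fdr([0.001, 0.01, 0.02, 0.9], 0.05)
        np.testing.assert_array_equal(reject, [True, True, True, False])

    def test_nothing_rejected_when_all_p_large(self):
        reject, _ = bh_fdr([0.2, 0.4, 0.9], 0.05)
        assert not reject.any()

    def test_all_equal_p_at_threshold_rejected(self):
        reject, _ = bh_fdr([0.01] * 5, 0.05)
        assert reject.all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.2, 1.4])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_brute_force_step_up(self, pvals, q):
        p = np.asarray(pvals)
        reject, _ = bh_fdr(p, q)
        np.testing.assert_array_equal(reject, bh_brute_force(p, q))

    def test_adjusted_p_monotone_in_raw_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=9)
        _, p_adj = bh_fdr(p, 0.05)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)


class TestAssociationSuite:
    def test_single_signal_column_flagged(self):
        hits_signal = hits_null = 0
        n_seeds = 25
        for seed in range(n_seeds):
            df, _ = synth_cohort_table(
                n=115,
                gamma={"cerebral_volume": 0.6},
                sigma_pad=0.5,
                measures=("cerebral_volume", "surface_area", "gyrification_index"),
                ga_coupling=0.3,
                seed=seed,
            )
            res = run_association_suite(CohortTable(df))
            flags = {
                r["measure"]: r["significant_fdr"] for r in res["families"]["all"]
            }
            hits_signal += flags["cerebral_volume"]
            hits_null += flags["gyrification_index"]
        assert hits_signal / n_seeds >= 0.8
        assert hits_null / n_seeds <= 0.2

    def test_permuting_pad_destroys_signal(self):
        df, _ = synth_cohort_table(
            n=115, gamma={"cerebral_volume": 0.6}, sigma_pad=0.5, seed=0
        )
        rng = np.random.default_rng(1)
        df["pad"] = rng.permutation(df["pad"].to_numpy())
        res = run_association_suite(CohortTable(df))
        flags = [r["significant_fdr"] for r in res["families"]["all"]]
        assert sum(flags) <= 1  # at most a false positive

    def test_output_json_round_trips(self, tmp_path):
        df, _ = synth_cohort_table(n=60, seed=0)
        res = run_association_suite(CohortTable(df))
        path = tmp_path / "res.json"
        path.write_text(json.dumps(res))
        assert json.loads(path.read_text()) == res


class TestCohortTable:
    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            CohortTable(pd.DataFrame({"id": ["a"], "gw": [30.0]}))

    def test_out_of_range_gw_rejected(self):
        df, _ = synth_cohort_table(n=20, seed=0)
        df.loc[0, "gw"] = 55.0
        with pytest.raises(ValueError, match="gestational"):
            CohortTable(df)

    def test_csv_round_trip(self, tmp_path):
        df, _ = synth_cohort_table(n=12, seed=0)
        ct = CohortTable(df)
        ct.to_csv(tmp_path / "c.csv")
        back = CohortTable.from_csv(tmp_path / "c.csv")
        assert back.measures == ct.measures
        np.testing.assert_allclose(
            back.df["pad"].to_numpy(), ct.df["pad"].to_numpy(), rtol=1e-12
        )
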