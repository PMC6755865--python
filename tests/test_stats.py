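"""Correlation/FDR/partial-correlation/power/ANCOVA/mediation stage."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from binpsych.stats import (
    ancova_backward,
    by_adjust,
    correlation_matrix,
    mediation,
    moca_education_adjust,
    partial_correlation,
    power_pearson,
)


class TestByAdjust:
    def test_hand_computed_example(self):
        # m=3, c(3)=11/6; step-up: q3=.04*11/6=.0733, q2=min(q3,.02*5.5/2)
        q = by_adjust([0.01, 0.02, 0.04])
        assert q == pytest.approx([0.055, 0.055, 0.0733], abs=5e-4)

    def test_zeros_and_single(self):
        assert np.all(by_adjust([0.0, 0.0, 0.0]) == 0.0)
        assert by_adjust([0.03]) == pytest.approx([0.03])   # c(1)=1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            by_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_equals_bh_times_harmonic_factor(self, pvals):
        """BY equals BH scaled by c(m) = sum 1/i, capped at 1, and is
        monotone in the sorted p values."""
        from statsmodels.stats.multitest import multipletests

        q = by_adjust(pvals)
        bh = multipletests(pvals, method="fdr_bh")[1]
        cm = sum(1.0 / i for i in range(1, len(pvals) + 1))
        assert np.allclose(q, np.minimum(bh * cm, 1.0), atol=1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-12)


class TestCorrelationMatrix:
    def test_identical_columns(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        df["y"] = df.x
        rep = correlation_matrix(df)
        assert rep.r.loc["x", "y"] == pytest.approx(1.0)
        assert rep.p.loc["x", "y"] < 1e-6

    def test_five_point_hand_oracle(self):
        # r = sum(dx dy) / sqrt(sum dx^2 sum dy^2) = 8/10 = 0.8
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]},
                          dtype=float)
        rep = correlation_matrix(df)
        assert rep.r.loc["x", "y"] == pytest.approx(0.8)
        t = 0.8 * math.sqrt(3 / (1 - 0.64))
        assert rep.p.loc["x", "y"] == pytest.approx(2 * sps.t.sf(t, 3))

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((20_000, 2)), columns=["a", "b"])
        rep = correlation_matrix(df)
        assert abs(rep.r.loc["a", "b"]) < 0.03

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "c": [5.0, 5, 5, 5]})
        rep = correlation_matrix(df)
        assert rep.flags and np.isnan(rep.r.loc["x", "c"])

    def test_q_not_below_p(self, small_cohort):
        rep = correlation_matrix(small_cohort)
        iu = np.triu_indices(len(rep.p), k=1)
        p, q = rep.p.values[iu], rep.q.values[iu]
        ok = np.isfinite(p)
        assert np.all(q[ok] >= p[ok] - 1e-12)


class TestPartialCorrelation:
    def test_independent_controls_leave_r_unchanged(self):
        rng = np.random.default_rng(1)
        n = 20_000
        x = rng.standard_normal(n)
        y = 0.6 * x + 0.8 * rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y,
                           "c1": rng.standard_normal(n),
                           "c2": rng.standard_normal(n)})
        raw = np.corrcoef(x, y)[0, 1]
        r, p = partial_correlation(df, ("x", "y"), ("c1", "c2"))
        assert r == pytest.approx(raw, abs=0.02)

    def test_six_row_recursive_formula_oracle(self):
        df = pd.DataFrame({
            "x": [1.0, 2, 3, 4, 5, 6],
            "y": [2.0, 1, 4, 3, 7, 5],
            "z": [1.0, 1, 2, 2, 3, 4],
        })
        r_xy = np.corrcoef(df.x, df.y)[0, 1]
        r_xz = np.corrcoef(df.x, df.z)[0, 1]
        r_yz = np.corrcoef(df.y, df.z)[0, 1]
        expected = (r_xy - r_xz * r_yz) / math.sqrt(
            (1 - r_xz**2) * (1 - r_yz**2))
        r, p = partial_correlation(df, ("x", "y"), ("z",))
        assert r == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_pingouin(self, small_cohort):
        pingouin = pytest.importorskip("pingouin")
        from binpsych.stats import analysis_frame

        df = analysis_frame(small_cohort).reset_index(drop=True)
        r, p = partial_correlation(df, ("ipd_fl", "tmb_time"),
                                   ("age", "pta_lf"))
        ref = pingouin.partial_corr(df, x="ipd_fl", y="tmb_time",
                                    covar=["age", "pta_lf"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)

    def test_degenerate_and_rank_deficient(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 6, 7],
                           "y": [2.0, 4, 6, 8, 10, 12, 14]})
        df["c"] = df.y          # y == control exactly
        df["c2"] = 2 * df.y     # collinear controls
        r, p = partial_correlation(df, ("x", "y"), ("c",))
        assert np.isnan(r)
        with pytest.raises(ValueError):
            partial_correlation(df, ("x", "y"), ("c", "c2"))


class TestPowerPearson:
    def test_published_power_statement(self):
        # n = 20 gives 80% power for |r| >= .58
        assert round(power_pearson(0.58, 20), 1) == 0.8
        assert 0.78 <= round(power_pearson(0.58, 20), 2) <= 0.80

    def test_null_limit_tends_to_alpha(self):
        assert power_pearson(1e-6, 20) == pytest.approx(0.05, abs=0.001)

    def test_monotone_in_n_and_limits(self):
        powers = [power_pearson(0.4, n) for n in (10, 20, 40, 80, 160)]
        assert np.all(np.diff(powers) > 0)
        assert power_pearson(0.4, 10_000) > 0.999
        assert power_pearson(0.4, 20, alpha=0.9999) > 0.99

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_pearson(0.0, 20)
        with pytest.raises(ValueError):
            power_pearson(0.5, 3)


class TestAncovaBackward:
    def test_single_true_predictor_retained(self):
        """Response linear in one candidate + noise: backward
        elimination keeps that candidate in nearly all replicates."""
        hits, spurious = 0, 0
        n_rep = 50
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            n = 200
            df = pd.DataFrame(rng.standard_normal((n, 3)),
                              columns=["a", "b", "c"])
            df["y"] = 2.0 * df.a + rng.standard_normal(n)
            res = ancova_backward(df, "y", ["a", "b", "c"])
            if "a" in res.retained:
                hits += 1
            spurious += len(set(res.retained) - {"a"})
        assert hits >= int(0.95 * n_rep)
        assert spurious <= 0.25 * n_rep   # ~ family error rate

    def test_pure_noise_usually_empty(self):
        empties = 0
        n_rep = 40
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            df = pd.DataFrame(rng.standard_normal((100, 4)),
                              columns=["a", "b", "c", "y"])
            res = ancova_backward(df, "y", ["a", "b", "c"])
            empties += not res.retained
        # each candidate has ~5% chance to survive; most runs are empty
        assert empties >= int(0.75 * n_rep)

    def test_collinear_design_flagged(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.standard_normal(50)})
        df["y"] = df.a + 0.1 * rng.standard_normal(50)
        df["dup"] = df.y       # response duplicated as a candidate
        res = ancova_backward(df, "y", ["a", "dup"])
        assert res.collinear

    def test_reports_r_squared(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.standard_normal(100)})
        df["y"] = df.a + 0.5 * rng.standard_normal(100)
        res = ancova_backward(df, "y", ["a"])
        assert 0.5 < res.r_squared < 1.0
        assert res.anova is not None


class TestMediation:
    def test_constructed_perfect_mediation(self):
        rng = np.random.default_rng(4)
        n = 200
        x = rng.standard_normal(n)
        m = x + 0.1 * rng.standard_normal(n)
        y = m + 0.1 * rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        res = mediation(df, "x", "m", "y")
        assert res.classification == "perfect"
        assert res.path_a[1] < 0.05 and res.path_b[1] < 0.05

    def test_no_mediation_when_mediator_independent(self):
        rng = np.random.default_rng(5)
        n = 200
        x = rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "m": rng.standard_normal(n),
                           "y": x + 0.2 * rng.standard_normal(n)})
        res = mediation(df, "x", "m", "y")
        assert res.classification == "none"

    def test_degenerate_variance_rejected(self):
        df = pd.DataFrame({"x": np.ones(10), "m": np.arange(10.0),
                           "y": np.arange(10.0)})
        with pytest.raises(ValueError):
            mediation(df, "x", "m", "y")


def test_moca_education_adjustment():
    out = moca_education_adjust([22, 26, 30], [True, False, True])
    assert list(out) == [23.0, 26.0, 30.0]
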