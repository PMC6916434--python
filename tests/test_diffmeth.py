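import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special, stats

from methsig.core_io import ProbeMatrix
from methsig.diffmeth import (
    DesignMatrix,
    DiffMethResult,
    MethylationModel,
    ModerationParams,
    beta_to_m,
    bh_adjust,
    build_design,
    call_dmc,
    call_dmc_replicate_consistent,
    estimate_moderation,
    fit_linear_models,
    m_to_beta,
    moderated_t,
)

from conftest import make_sheet


class TestBetaMTransform:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)],
    )
    def test_exact_values(self, beta, expected):
        assert beta_to_m(beta) == pytest.approx(expected, abs=1e-12)

    def test_clamp_at_zero(self):
        eps = 1e-6
        assert beta_to_m(0.0, eps) == pytest.approx(np.log2(eps / (1 - eps)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            beta_to_m(1.5)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(1e-5, 1 - 1e-5))
    def test_inverse_and_monotone(self, b):
        m = beta_to_m(b)
        assert m_to_beta(m) == pytest.approx(b, rel=1e-9)
        assert beta_to_m(min(b + 1e-6, 1 - 1e-6)) >= m


def _two_group_design(n_a=5, n_b=5):
    rows = [{"sample_id": f"a{i}", "group": "HNM"} for i in range(n_a)]
    rows += [{"sample_id": f"b{i}", "group": "CIMP_CC"} for i in range(n_b)]
    sheet = make_sheet(rows)
    return sheet, build_design(sheet, ["HNM", "CIMP_CC"], covariates=())


class TestLinearFit:
    def test_exact_linear_probe_zero_residual(self):
        sheet, design = _two_group_design()
        y = design.values @ np.array([1.0, 2.0])
        M = ProbeMatrix(["p1"], design.sample_ids, y[None, :], "mvalue")
        fit = fit_linear_models(M, design)
        assert fit.s2[0] == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(fit.coef[0], [1.0, 2.0], atol=1e-12)

    def test_contrast_equals_group_mean_difference(self):
        rng = np.random.default_rng(0)
        sheet, design = _two_group_design(6, 4)
        y = rng.normal(size=10)
        M = ProbeMatrix(["p1"], design.sample_ids, y[None, :], "mvalue")
        fit = fit_linear_models(M, design)
        coef, _ = fit.contrast_stats(design.contrast("CIMP_CC", "HNM"))
        assert coef[0] == pytest.approx(y[6:].mean() - y[:6].mean())

    def test_matches_normal_equations_oracle(self):
        """20-probe fit equals a direct (X'X)^-1 X'y solve to 1e-10."""
        rng = np.random.default_rng(42)
        rows = [
            {"sample_id": f"s{i}", "group": g, "location": l, "batch": b}
            for i, (g, l, b) in enumerate(
                zip(
                    ["HNM"] * 10 + ["CIMP_CC"] * 10,
                    rng.choice(["proximal", "distal"], 20),
                    rng.choice(["B1", "B2"], 20),
                )
            )
        ]
        sheet = make_sheet(rows)
        design = build_design(sheet, ["HNM", "CIMP_CC"])
        Y = rng.normal(size=(20, 20))
        M = ProbeMatrix([f"p{i}" for i in range(20)], design.sample_ids, Y, "mvalue")
        fit = fit_linear_models(M, design)
        X = design.values
        oracle = np.linalg.inv(X.T @ X) @ X.T @ Y.T
        np.testing.assert_allclose(fit.coef, oracle.T, atol=1e-10)

    def test_probe_with_insufficient_samples_flagged(self):
        sheet, design = _two_group_design(2, 2)
        y = np.array([0.1, np.nan, np.nan, np.nan])
        M = ProbeMatrix(["p1"], design.sample_ids, y[None, :], "mvalue")
        fit = fit_linear_models(M, design)
        assert not fit.ok[0]
        assert np.isnan(fit.s2[0])


class TestModeration:
    def test_equal_variances_give_infinite_prior_df(self):
        """Zero between-probe spread in log variances: the prior is a point
        mass (d0 = +inf) and every posterior variance equals s0^2."""
        s2 = np.full(1000, 2.5)
        params = estimate_moderation(s2, 10.0)
        assert np.isinf(params.d0)
        res = moderated_t(np.ones(3), np.ones(3), np.array([0.1, 2.5, 9.0]), 10.0, params)
        assert len(set(np.round(res.t_mod, 12))) == 1

    def test_point_mass_prior_variance_recovered(self):
        """Variances drawn with a common true variance (d0 = inf regime):
        s0^2 is recovered within 5%."""
        rng = np.random.default_rng(8)
        d = 10
        s2 = 2.5 * rng.chisquare(d, 20_000) / d
        params = estimate_moderation(s2, float(d))
        assert params.d0 > 50 or np.isinf(params.d0)
        assert params.s0_sq == pytest.approx(2.5, rel=0.05)

    def test_recovers_scaled_f_hyperparameters(self):
        """s^2 ~ s0^2 d0 / chi^2_d0 scaled-F simulation: recover (d0, s0^2)
        within 10% at 50,000 probes."""
        rng = np.random.default_rng(11)
        d0, s0_sq, d_g = 4.0, 1.0, 10
        G = 50_000
        prior_var = s0_sq * d0 / rng.chisquare(d0, G)
        s2 = prior_var * rng.chisquare(d_g, G) / d_g
        params = estimate_moderation(s2, float(d_g))
        assert params.d0 == pytest.approx(d0, rel=0.10)
        assert params.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_matches_numeric_moment_equation_solve(self):
        """Hand-listed variances: closed-form estimates equal an independent
        root-finding solve of the two moment equations."""
        s2 = np.array([0.05, 0.2, 0.4, 1.0, 3.0, 8.0, 0.1, 0.6, 2.0, 5.0])
        d = 6.0
        params = estimate_moderation(s2, d)
        e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
        target_var = np.var(e, ddof=1) - special.polygamma(1, d / 2)

        sol = optimize.brentq(
            lambda x: special.polygamma(1, x / 2) - target_var, 0.1, 1e4
        )
        s0 = np.exp(e.mean() + special.digamma(sol / 2) - np.log(sol / 2))
        assert params.d0 == pytest.approx(sol, rel=1e-6)
        assert params.s0_sq == pytest.approx(s0, rel=1e-6)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(Exception):
            estimate_moderation(np.zeros(20), 5.0)


class TestModeratedT:
    def test_hand_example(self):
        """coef 2, su 0.5, s2 1, d 4, prior (4, 1): posterior variance 1,
        t = 4 on 8 df; p matches the t CDF directly."""
        res = moderated_t(2.0, 0.5, 1.0, 4.0, ModerationParams(4.0, 1.0))
        assert res.t_mod[0] == pytest.approx(4.0)
        assert res.df_total[0] == 8
        assert res.p_value[0] == pytest.approx(2 * stats.t.sf(4.0, 8), rel=1e-12)

    def test_zero_coef_gives_p_one(self):
        res = moderated_t(0.0, 0.5, 1.0, 4.0, ModerationParams(4.0, 1.0))
        assert res.t_mod[0] == 0.0
        assert res.p_value[0] == 1.0

    def test_d0_zero_limit_equals_ordinary_t(self):
        """With no prior weight the moderated pipeline reproduces per-probe
        ordinary t-tests (max |difference| < 1e-10, 200 probes)."""
        rng = np.random.default_rng(5)
        n_a = n_b = 8
        Y = rng.normal(size=(200, n_a + n_b))
        rows = [{"sample_id": f"s{i}", "group": "HNM"} for i in range(n_a)]
        rows += [{"sample_id": f"s{i + n_a}", "group": "CIMP_CC"} for i in range(n_b)]
        sheet = make_sheet(rows)
        design = build_design(sheet, ["HNM", "CIMP_CC"], covariates=())
        M = ProbeMatrix([f"p{i}" for i in range(200)], design.sample_ids, Y, "mvalue")
        fit = fit_linear_models(M, design)
        coef, su = fit.contrast_stats(design.contrast("CIMP_CC", "HNM"))
        res = moderated_t(coef, su, fit.s2, fit.df_resid, ModerationParams(1e-300, 1.0))
        t_ref = stats.ttest_ind(Y[:, n_a:], Y[:, :n_a], axis=1).statistic
        assert np.max(np.abs(res.t_mod - t_ref)) < 1e-10

    def test_infinite_prior_df_uses_prior_variance(self):
        res = moderated_t(1.0, 1.0, 5.0, 4.0, ModerationParams(np.inf, 4.0))
        assert res.t_mod[0] == pytest.approx(0.5)
        assert res.p_value[0] == pytest.approx(2 * stats.norm.sf(0.5), rel=1e-9)


def bh_bruteforce(p):
    """Independent O(n^2) step-up: adj_i = min over j with p_j >= p_i of
    min(1, n p_j / rank_j)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(n, int)
    ranks[order] = np.arange(1, n + 1)
    adj = np.empty(n)
    for i in range(n):
        candidates = [min(1.0, n * p[j] / ranks[j]) for j in range(n) if p[j] >= p[i]]
        adj[i] = min(candidates)
    return adj


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.random(rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _result_from_rows(rows):
    df = pd.DataFrame(rows).set_index("probe")
    df["mean_beta_a"] = 0.5
    df["mean_beta_b"] = 0.3
    df["df_total"] = 10.0
    df["t_mod"] = 1.0
    df["p_value"] = df["adj_p"]
    return DiffMethResult("a", "b", df)


class TestCallDmc:
    def test_threshold_logic(self):
        res = _result_from_rows(
            [
                {"probe": "hit", "adj_p": 1e-5, "logFC": 2.5, "delta_beta": 0.15},
                {"probe": "small_dbeta", "adj_p": 1e-5, "logFC": 2.5, "delta_beta": 0.08},
                {"probe": "down", "adj_p": 1e-5, "logFC": -2.5, "delta_beta": -0.15},
                {"probe": "ns", "adj_p": 0.2, "logFC": 2.5, "delta_beta": 0.15},
            ]
        )
        calls = call_dmc(res)
        assert calls.hyper == {"hit"}
        assert calls.hypo == {"down"}

    def test_matches_bruteforce_row_scan(self):
        rng = np.random.default_rng(3)
        rows = [
            {
                "probe": f"p{i}",
                "adj_p": rng.random() * 1e-3,
                "logFC": rng.normal(scale=3),
                "delta_beta": rng.normal(scale=0.2),
            }
            for i in range(1000)
        ]
        res = _result_from_rows(rows)
        calls = call_dmc(res)
        hyper = {
            r["probe"]
            for r in rows
            if r["adj_p"] < 1e-4 and r["logFC"] > 2 and r["delta_beta"] > 0.10
        }
        hypo = {
            r["probe"]
            for r in rows
            if r["adj_p"] < 1e-4 and r["logFC"] < -2 and r["delta_beta"] < -0.10
        }
        assert calls.hyper == hyper
        assert calls.hypo == hypo
        assert not (calls.hyper & calls.hypo)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(4)
        rows = [
            {
                "probe": f"p{i}",
                "adj_p": rng.random() * 1e-3,
                "logFC": rng.normal(scale=3),
                "delta_beta": rng.normal(scale=0.2),
            }
            for i in range(300)
        ]
        res = _result_from_rows(rows)
        strict = call_dmc(res, 1e-5, 2.5, 0.15)
        relaxed = call_dmc(res, 1e-4, 2.0, 0.10)
        assert strict.hyper <= relaxed.hyper
        assert strict.hypo <= relaxed.hypo


class TestReplicateConsistentDmc:
    @pytest.mark.parametrize(
        "deltas,expected",
        [
            ((0.06, 0.07), "hyper"),
            ((0.06, 0.03), "neither"),
            ((-0.06, -0.09), "hypo"),
        ],
    )
    def test_both_replicates_must_pass(self, deltas, expected):
        df = pd.DataFrame({"r1": [deltas[0]], "r2": [deltas[1]]}, index=["p1"])
        hyper, hypo = call_dmc_replicate_consistent(df, 0.05)
        assert ("p1" in hyper) == (expected == "hyper")
        assert ("p1" in hypo) == (expected == "hypo")

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            call_dmc_replicate_consistent(pd.DataFrame({"r1": [0.1]}), 0.05)


class TestNullBehaviour:
    def test_no_group_effect_rarely_yields_discoveries(self):
        """Null simulation (no group effect, 5,000 probes): adjusted p < 0.05
        finds nothing in at least 95% of 20 seeded runs."""
        clean = 0
        n_runs = 20
        rows = [{"sample_id": f"s{i}", "group": "HNM"} for i in range(10)]
        rows += [{"sample_id": f"s{i + 10}", "group": "CIMP_CC"} for i in range(10)]
        sheet = make_sheet(rows)
        design = build_design(sheet, ["HNM", "CIMP_CC"], covariates=())
        c = design.contrast("CIMP_CC", "HNM")
        for run in range(n_runs):
            rng = np.random.default_rng(100 + run)
            Y = rng.normal(size=(5000, 20))
            M = ProbeMatrix([f"p{i}" for i in range(5000)], design.sample_ids, Y, "mvalue")
            fit = fit_linear_models(M, design)
            params = estimate_moderation(fit.s2, fit.df_resid)
            coef, su = fit.contrast_stats(c)
            res = moderated_t(coef, su, fit.s2, fit.df_resid, params)
            adj = bh_adjust(res.p_value)
            if (adj < 0.05).sum() == 0:
                clean += 1
        assert clean >= int(0.95 * n_runs)


class TestMethylationModel:
    def test_logfc_sign_matches_delta_beta(self, default_cohort):
        matrix, sheet, _ = default_cohort
        model = MethylationModel(matrix, sheet, ["HNM", "nonCIMP_CC", "CIMP_CC"])
        res = model.contrast("CIMP_CC", "HNM").table.dropna()
        # below ~0.02 the Jensen gap between mean-logit and logit-mean can
        # flip the sign of a null probe; any material difference agrees
        sub = res[res["delta_beta"].abs() > 0.02]
        assert len(sub) > 300
        assert (np.sign(sub["logFC"]) == np.sign(sub["delta_beta"])).all()

    def test_result_round_trip(self, default_cohort, tmp_path):
        matrix, sheet, _ = default_cohort
        model = MethylationModel(matrix, sheet, ["HNM", "CIMP_CC"])
        res = model.contrast("CIMP_CC", "HNM")
        path = tmp_path / "res.tsv"
        res.write(path)
        back = DiffMethResult.read(path)
        pd.testing.assert_frame_equal(res.table, back.table, check_exact=False, rtol=1e-12)
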