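import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from assocnet.config import ModelSpec
from assocnet.lmm import (
    FIXED_TERMS,
    FitResult,
    VarianceComponents,
    fit,
    gaussian_loglik,
    make_design_frame,
    marginal_covariance,
    prepare_model_frame,
    simulate_response,
    standardize_covariate,
    transform_response,
    wald_tests,
)

IDENTITY_SPEC = ModelSpec(
    trait="strength", transform="identity", include_year_ar1=False
)
BETA = np.array([0.1, 0.2, 0.5, -0.1])


def oracle_covariance(comp, frame, spec):
    """Naive elementwise double-loop construction of the marginal covariance."""
    n = len(frame)
    ind = pd.factorize(frame["individual_id"])[0]
    x = frame["x"].to_numpy(float)
    yr = frame["year"].to_numpy(int)
    mo = frame["month"].to_numpy() if "month" in frame.columns else None
    if spec.random_structure == "intercept_only":
        v_slope, cov = 0.0, 0.0
    elif spec.random_structure == "zero_corr":
        v_slope, cov = comp.v_slope, 0.0
    else:
        v_slope, cov = comp.v_slope, comp.cov_int_slope
    V = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            if ind[s] == ind[t]:
                V[s, t] += comp.v_int + cov * (x[s] + x[t]) + v_slope * x[s] * x[t]
            if spec.include_year_ar1:
                V[s, t] += comp.v_year * comp.rho_year ** abs(yr[s] - yr[t])
            if spec.include_month_effect and mo[s] == mo[t]:
                V[s, t] += comp.v_month
            if s == t:
                V[s, t] += comp.v_resid
    return V


class TestStandardize:
    def test_printed_arithmetic(self):
        z, mean, sd = standardize_covariate(np.array([1.0, 2.0, 3.0]))
        assert z == pytest.approx([-1.2247448, 0.0, 1.2247448], abs=1e-6)
        assert mean == 2.0

    def test_idempotence(self, rng):
        z, _, _ = standardize_covariate(rng.normal(size=50))
        z2, _, _ = standardize_covariate(z)
        assert z2 == pytest.approx(z, abs=1e-12)

    def test_mean_zero_unit_sd(self, rng):
        z, _, _ = standardize_covariate(rng.gamma(2.0, 3.0, size=200))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_round_trip(self, rng):
        raw = rng.normal(3.0, 2.0, size=40)
        z, mean, sd = standardize_covariate(raw)
        assert z * sd + mean == pytest.approx(raw, abs=1e-10)

    def test_sample_convention(self):
        z, _, sd = standardize_covariate(np.array([1.0, 2.0, 3.0]), "sample")
        assert sd == pytest.approx(1.0)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize_covariate(np.full(5, 2.0))


class TestTransform:
    def test_log_and_logit_anchors(self):
        y, _, _ = transform_response(np.array([1.0]), "log")
        assert y[0] == pytest.approx(0.0)
        y, _, _ = transform_response(np.array([0.5]), "logit")
        assert y[0] == pytest.approx(0.0)
        y, _, _ = transform_response(np.array([0.75]), "logit")
        assert y[0] == pytest.approx(np.log(3.0))

    def test_domain_violations_dropped_and_counted(self):
        y, keep, n_dropped = transform_response(np.array([0.0, 0.4, 1.0]), "logit")
        assert n_dropped == 2
        assert keep.tolist() == [False, True, False]
        assert len(y) == 1

    def test_log_drops_nonpositive(self):
        _, keep, n_dropped = transform_response(np.array([-1.0, 0.0, 2.0]), "log")
        assert n_dropped == 2 and keep.tolist() == [False, False, True]

    def test_unknown_transform(self):
        with pytest.raises(ValueError):
            transform_response(np.array([1.0]), "sqrt")


class TestMarginalCovariance:
    def test_compound_symmetry_closed_form(self):
        frame = make_design_frame(3, 4, seed=0)
        comp = VarianceComponents(v_int=0.7, v_resid=0.4)
        spec = replace(IDENTITY_SPEC, random_structure="intercept_only")
        V = marginal_covariance(comp, frame, spec)
        ind = pd.factorize(frame["individual_id"])[0]
        same = ind[:, None] == ind[None, :]
        want = np.where(same, 0.7, 0.0) + 0.4 * np.eye(len(frame))
        assert V == pytest.approx(want)

    def test_rho_zero_year_block_diagonal(self):
        frame = make_design_frame(3, 4, seed=0)
        comp = VarianceComponents(v_int=0.1, v_year=0.5, rho_year=0.0, v_resid=0.2)
        spec = replace(IDENTITY_SPEC, include_year_ar1=True)
        V = marginal_covariance(comp, frame, spec)
        yr = frame["year"].to_numpy()
        across = yr[:, None] != yr[None, :]
        ind = pd.factorize(frame["individual_id"])[0]
        diff_ind = ind[:, None] != ind[None, :]
        assert np.all(V[across & diff_ind] == 0.0)

    def test_elementwise_oracle(self, rng):
        spec = ModelSpec(
            trait="strength", timescale="month", transform="identity",
            include_year_ar1=True,
        )
        frame = make_design_frame(4, 3, obs_per_individual_year=2, seed=1,
                                  monthly=True, months=(6, 7))
        comp = VarianceComponents(0.8, 0.3, -0.2, 0.4, 0.5, 0.2, 0.7)
        assert marginal_covariance(comp, frame, spec) == pytest.approx(
            oracle_covariance(comp, frame, spec)
        )

    def test_non_psd_rejected(self):
        frame = make_design_frame(3, 3, seed=0)
        comp = VarianceComponents(v_int=0.1, v_slope=0.1, cov_int_slope=0.5)
        with pytest.raises(ValueError):
            marginal_covariance(comp, frame, IDENTITY_SPEC)


class TestLikelihood:
    def test_matches_direct_mvn_density(self, rng):
        spec = ModelSpec(
            trait="strength", timescale="month", transform="identity",
            include_year_ar1=True,
        )
        for rep in range(5):
            frame = make_design_frame(
                5, 3, obs_per_individual_year=1, seed=rep, monthly=True, months=(6, 7)
            )
            comp = VarianceComponents(
                v_int=rng.uniform(0.2, 1.5),
                v_slope=rng.uniform(0.05, 0.6),
                cov_int_slope=0.0,
                v_year=rng.uniform(0.05, 0.5),
                rho_year=rng.uniform(-0.6, 0.6),
                v_month=rng.uniform(0.05, 0.4),
                v_resid=rng.uniform(0.3, 1.2),
            )
            comp.cov_int_slope = (
                rng.uniform(-0.9, 0.9) * np.sqrt(comp.v_int * comp.v_slope)
            )
            frame = simulate_response(frame, comp, BETA, spec, rng)
            V = oracle_covariance(comp, frame, spec)
            X = np.column_stack(
                [np.ones(len(frame)), frame.sex01, frame.x, frame.sex01 * frame.x]
            )
            want = stats.multivariate_normal(mean=X @ BETA, cov=V).logpdf(frame["y"])
            got = gaussian_loglik(comp, frame, spec, BETA)
            assert got == pytest.approx(want, abs=1e-8)


def anova_ml_components(frame):
    """Closed-form ML variance components for balanced intercept-only data."""
    g = frame.groupby("individual_id")["y"]
    means, counts = g.mean(), g.size()
    assert counts.nunique() == 1
    m = counts.iloc[0]
    a = len(means)
    ssw = ((frame["y"] - frame["individual_id"].map(means)) ** 2).sum()
    sigma_e = ssw / (a * (m - 1))
    tau = ((means - frame["y"].mean()) ** 2).sum() / a
    sigma_u = tau - sigma_e / m
    return float(sigma_u), float(sigma_e)


class TestFit:
    def test_balanced_anova_closed_form(self):
        rng = np.random.default_rng(42)
        frame = make_design_frame(50, 6, seed=3)
        truth = VarianceComponents(v_int=1.0, v_resid=1.0)
        spec = replace(IDENTITY_SPEC, random_structure="intercept_only")
        frame = simulate_response(frame, truth, np.zeros(4), spec, rng)
        res = fit(frame, spec, n_starts=1, fixed_terms=("intercept",))
        want_u, want_e = anova_ml_components(frame)
        assert res.components.v_int == pytest.approx(want_u, rel=0.01)
        assert res.components.v_resid == pytest.approx(want_e, rel=0.01)

    def test_ml_dominance_over_truth(self):
        rng = np.random.default_rng(5)
        truth = VarianceComponents(1.0, 0.25, -0.3, v_resid=1.0)
        frame = make_design_frame(40, 8, seed=5)
        frame = simulate_response(frame, truth, BETA, IDENTITY_SPEC, rng)
        res = fit(frame, IDENTITY_SPEC, seed=1)
        assert res.converged
        assert res.loglik >= gaussian_loglik(truth, frame, IDENTITY_SPEC, BETA)

    def test_reparameterization_invariance(self):
        rng = np.random.default_rng(6)
        truth = VarianceComponents(1.0, 0.25, -0.2, v_resid=0.8)
        frame = make_design_frame(40, 8, seed=6)
        frame = simulate_response(frame, truth, BETA, IDENTITY_SPEC, rng)
        res1 = fit(frame, IDENTITY_SPEC, seed=1)
        c = 2.0
        frame2 = frame.copy()
        frame2["x"] = frame2["x"] * c
        res2 = fit(frame2, IDENTITY_SPEC, seed=1)
        assert res2.beta[2] == pytest.approx(res1.beta[2] / c, rel=1e-3)
        assert res2.components.v_slope == pytest.approx(
            res1.components.v_slope / c**2, rel=5e-3
        )
        assert res2.loglik == pytest.approx(res1.loglik, abs=1e-4)

    def test_nested_loglik_monotone(self):
        rng = np.random.default_rng(7)
        truth = VarianceComponents(1.0, 0.3, -0.25, v_resid=1.0)
        frame = make_design_frame(30, 8, seed=7)
        frame = simulate_response(frame, truth, BETA, IDENTITY_SPEC, rng)
        lls = {}
        for rs in ("full", "zero_corr", "intercept_only"):
            lls[rs] = fit(frame, replace(IDENTITY_SPEC, random_structure=rs), seed=1).loglik
        assert lls["full"] >= lls["zero_corr"] - 1e-6
        assert lls["zero_corr"] >= lls["intercept_only"] - 1e-6

    def test_row_order_and_relabel_invariance(self):
        rng = np.random.default_rng(8)
        truth = VarianceComponents(0.8, 0.2, 0.1, v_resid=0.9)
        frame = make_design_frame(20, 6, seed=8)
        frame = simulate_response(frame, truth, BETA, IDENTITY_SPEC, rng)
        res1 = fit(frame, IDENTITY_SPEC, seed=1)
        shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabel = {f"ID{i:04d}": f"Z{i:04d}" for i in range(20)}
        shuffled["individual_id"] = shuffled["individual_id"].map(relabel)
        res2 = fit(shuffled, IDENTITY_SPEC, seed=1)
        assert res2.loglik == pytest.approx(res1.loglik, abs=1e-5)
        assert res2.beta == pytest.approx(res1.beta, abs=1e-4)

    def test_against_statsmodels_mixedlm(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        rng = np.random.default_rng(7)
        truth = VarianceComponents(1.0, 0.25, -0.3, v_resid=1.0)
        frame = make_design_frame(60, 8, seed=5)
        frame = simulate_response(frame, truth, BETA, IDENTITY_SPEC, rng)
        res = fit(frame, IDENTITY_SPEC, seed=1)
        md = smf.mixedlm(
            "y ~ sex01 * x", frame, groups=frame["individual_id"], re_formula="~x"
        ).fit(reml=False)
        assert res.loglik == pytest.approx(md.llf, abs=1e-4)
        assert res.components.v_int == pytest.approx(md.cov_re.iloc[0, 0], rel=1e-3, abs=1e-4)
        assert res.components.v_slope == pytest.approx(md.cov_re.iloc[1, 1], rel=1e-3, abs=1e-4)
        assert res.components.v_resid == pytest.approx(md.scale, rel=1e-3)

    def test_single_observation_individuals_fix_slopes(self):
        rng = np.random.default_rng(10)
        n = 15
        frame = pd.DataFrame(
            {
                "individual_id": [f"ID{i:04d}" for i in range(n)],
                "sex01": (rng.random(n) < 0.5).astype(float),
                "x": rng.normal(size=n),
                "year": rng.integers(2000, 2005, size=n),
            }
        )
        frame = simulate_response(
            frame, VarianceComponents(v_int=0.5, v_resid=1.0), BETA, IDENTITY_SPEC, rng
        )
        res = fit(frame, IDENTITY_SPEC, seed=1)
        assert not res.slope_estimable
        assert res.components.v_slope == 0.0
        assert res.components.cov_int_slope == 0.0


class TestWald:
    def _result(self, beta, se):
        return FitResult(
            spec=IDENTITY_SPEC,
            beta=np.asarray(beta, float),
            se=np.asarray(se, float),
            beta_names=FIXED_TERMS,
            components=VarianceComponents(v_resid=1.0),
            loglik=0.0,
            n_obs=10,
            n_individuals=5,
            converged=True,
        )

    def test_quantile_anchor(self):
        res = self._result([1.96, 0, 0, 0], [1.0, 1, 1, 1])
        w = wald_tests(res)
        assert w["chi2"].iloc[0] == pytest.approx(3.8416)
        assert w["p"].iloc[0] == pytest.approx(0.05, abs=1e-3)

    def test_zero_estimate_p_one(self):
        w = wald_tests(self._result([0, 0, 0, 0], [1, 1, 1, 1]))
        assert (w["p"] == 1.0).all()
        assert (w["df"] == 1).all()


class TestPrepareModelFrame:
    def _table(self):
        return pd.DataFrame(
            {
                "individual_id": ["A", "B", "C", "D", "E"],
                "window_year": [2000, 2000, 2001, 2001, 2002],
                "window_month": pd.NA,
                "strength": [1.0, 2.0, 0.0, 3.0, 1.5],
                "clustering": [0.5, 0.0, 0.3, 1.0, 0.7],
                "closeness": [0.2, 0.5, 0.1, 0.6, 0.4],
                "n_sightings": [6, 6, 6, 6, 6],
                "included": [True, True, True, True, False],
                "sex": ["F", "M", "F", "U", "M"],
                "covariate_raw": [1.0, 4.0, 2.0, 2.0, 3.0],
            }
        )

    def test_exclusions_and_domain_filter(self):
        spec = ModelSpec(trait="strength", transform="log")
        frame, info = prepare_model_frame(self._table(), spec)
        # E excluded (flag), D excluded (unknown sex), C dropped (log domain)
        assert set(frame["individual_id"]) == {"A", "B"}
        assert info["n_dropped_transform"] == 1

    def test_logit_domain_filter(self):
        spec = ModelSpec(trait="clustering", transform="logit")
        frame, info = prepare_model_frame(self._table(), spec)
        # B has clustering 0, D excluded by sex, E by flag; A and C remain
        assert set(frame["individual_id"]) == {"A", "C"}
        assert info["n_dropped_transform"] == 1

    def test_covariate_standardized_over_fit_rows(self):
        spec = ModelSpec(trait="closeness", transform="log")
        frame, _ = prepare_model_frame(self._table(), spec)
        x = frame["x"].to_numpy()
        assert x.mean() == pytest.approx(0.0, abs=1e-12)
        assert x.std() == pytest.approx(1.0, abs=1e-12)
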