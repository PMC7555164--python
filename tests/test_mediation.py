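"""Mediation decomposition, bootstrap CIs, model suite, and design power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agediff.mediation import (
    MODEL_SPECS,
    MediationModel,
    bootstrap_indirect,
    correlation_power,
    correlation_power_simulated,
    fit_paths,
    proportion_mediated,
    run_model_suite,
)


def _trivariate(n, a_path, b_path, direct, rng):
    """Standardized single-mediator chain with known population paths."""
    x = rng.standard_normal(n)
    m = a_path * x + np.sqrt(1 - a_path**2) * rng.standard_normal(n)
    resid = 1 - (b_path**2 + direct**2 + 2 * a_path * b_path * direct)
    y = b_path * m + direct * x + np.sqrt(resid) * rng.standard_normal(n)
    return x, m, y


class TestFitPaths:
    def test_near_noiseless_chain(self):
        # an exactly collinear chain (m = x) leaves the x/m split unidentified;
        # an epsilon-perturbed mediator pins the whole effect on the chain
        rng = np.random.default_rng(0)
        x = np.linspace(-2, 2, 50)
        m = x + 1e-6 * rng.standard_normal(50)
        res = fit_paths(x, m, m.copy())
        assert res.indirect_effects[0] == pytest.approx(1.0, abs=1e-4)
        assert res.direct_effect == pytest.approx(0.0, abs=1e-4)
        assert res.total_effect == pytest.approx(1.0, abs=1e-4)

    def test_population_path_arithmetic(self, rng):
        x, m, y = _trivariate(10_000, 0.5, 0.4, 0.2, rng)
        res = fit_paths(x, m, y)
        assert res.indirect_effects[0] == pytest.approx(0.20, abs=0.03)
        assert res.total_effect == pytest.approx(0.40, abs=0.03)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_decomposition_identity(self, seed):
        """c = c' + sum(a_i b_i) exactly, on arbitrary complete-case data."""
        rng = np.random.default_rng(seed)
        n, k = rng.integers(12, 60), rng.integers(1, 4)
        x = rng.standard_normal(n)
        M = rng.standard_normal((n, k)) + 0.3 * x[:, None]
        y = rng.standard_normal(n) + M @ rng.uniform(-1, 1, k)
        res = fit_paths(x, M, y)
        assert res.total_effect == pytest.approx(
            res.direct_effect + res.indirect_effects.sum(), abs=1e-10
        )

    def test_scaling_invariance(self, rng):
        x, m, y = _trivariate(200, 0.5, 0.4, 0.2, rng)
        base = fit_paths(x, m, y)
        scaled = fit_paths(3.7 * x, np.column_stack([m * 0.01]), 250.0 * y)
        np.testing.assert_allclose(scaled.alpha, base.alpha, atol=1e-12)
        np.testing.assert_allclose(scaled.beta, base.beta, atol=1e-12)
        assert scaled.total_effect == pytest.approx(base.total_effect, abs=1e-12)

    def test_listwise_deletion(self, rng):
        x, m, y = _trivariate(100, 0.5, 0.4, 0.2, rng)
        x2 = x.copy()
        x2[0] = np.nan
        res = fit_paths(x2, m, y)
        assert res.n == 99

    def test_collinear_mediators_named(self, rng):
        x = rng.standard_normal(50)
        m1 = rng.standard_normal(50)
        M = np.column_stack([m1, m1 * 2 + 1e-9])
        with pytest.raises(ValueError, match="collinear"):
            fit_paths(x, M, rng.standard_normal(50), mediator_names=["p", "q"])

    def test_minimum_n(self, rng):
        with pytest.raises(ValueError):
            fit_paths(np.arange(5.0), np.arange(5.0), np.arange(5.0) * 0 + rng.standard_normal(5))


class TestBootstrap:
    def test_seed_determinism(self, rng):
        x, m, y = _trivariate(123, 0.5, 0.4, 0.2, rng)
        r1 = bootstrap_indirect(x, m, y, n_boot=300, seed=9)
        r2 = bootstrap_indirect(x, m, y, n_boot=300, seed=9)
        np.testing.assert_array_equal(r1.ci_low, r2.ci_low)
        np.testing.assert_array_equal(r1.ci_high, r2.ci_high)

    def test_real_indirect_detected(self, rng):
        """Strong indirect effect at n=500: the 99.5% CI excludes zero."""
        x, m, y = _trivariate(500, 0.6, 0.5, 0.1, rng)
        res = bootstrap_indirect(x, m, y, n_boot=1000, seed=1)
        assert res.ci_low[0] > 0

    def test_null_indirect_covered(self, rng):
        """Mediator unrelated to x: CI straddles zero (checked across reps)."""
        excl = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            x = r.standard_normal(123)
            m = r.standard_normal(123)
            y = 0.4 * m + r.standard_normal(123)
            res = bootstrap_indirect(x, m, y, n_boot=500, conf=0.995, seed=rep)
            excl += res.ci_low[0] > 0 or res.ci_high[0] < 0
        assert excl <= 2

    def test_estimator_interface(self, rng):
        x, m, y = _trivariate(200, 0.5, 0.4, 0.2, rng)
        est = MediationModel(n_boot=200, seed=3).fit(np.column_stack([x, m]), y)
        assert est.ci_.shape == (1, 2)
        assert est.total_effect_ == pytest.approx(
            est.direct_effect_ + est.indirect_effects_.sum(), abs=1e-10
        )


class TestProportionMediated:
    def test_eighty_percent(self):
        res = fit_paths(np.arange(20.0), np.arange(20.0), np.arange(20.0))
        res.total_effect, res.direct_effect = 1.0, 0.2
        assert proportion_mediated(res) == pytest.approx(80.0)

    def test_no_mediation(self):
        res = fit_paths(np.arange(20.0), np.arange(20.0), np.arange(20.0))
        res.total_effect = res.direct_effect = 0.47
        assert proportion_mediated(res) == pytest.approx(0.0)

    def test_suppression_flagged_above_100(self, rng):
        x = rng.standard_normal(300)
        m = 0.7 * x + 0.4 * rng.standard_normal(300)
        y = -0.5 * m + 0.45 * x + 0.5 * rng.standard_normal(300)
        res = fit_paths(x, m, y)
        if res.total_effect * res.direct_effect < 0:
            assert res.suppression
            assert proportion_mediated(res) > 100.0

    def test_zero_total_effect_undefined(self):
        res = fit_paths(np.arange(20.0), np.arange(20.0), np.arange(20.0))
        res.total_effect = 1e-12
        with pytest.warns(UserWarning):
            assert np.isnan(proportion_mediated(res))


def _toy_composites(rng, n=123, with_age_effects=True):
    age = rng.uniform(18, 62, n)
    z = (age - age.mean()) / age.std()
    load = 0.55 if with_age_effects else 0.0
    t0 = load * z + np.sqrt(1 - load**2) * rng.standard_normal(n)
    a = (0.45 if with_age_effects else 0.0) * z + 0.9 * rng.standard_normal(n)
    v = rng.standard_normal(n)
    g = 0.55 * v - 0.55 * t0 + 0.5 * rng.standard_normal(n)
    logrt = 0.6 * t0 + 0.5 * a + 0.3 * rng.standard_normal(n)
    df = pd.DataFrame(
        {"age": age, "g": g, "processing_capacity": g + 0.3 * rng.standard_normal(n),
         "psychometric_speed": -0.7 * t0 + 0.6 * rng.standard_normal(n),
         "memory": g + 0.5 * rng.standard_normal(n),
         "comp_v": v, "comp_a": a, "comp_t0": t0, "comp_logrt": logrt}
    )
    for d in ("figural", "numeric", "verbal"):
        df[d] = g + 0.4 * rng.standard_normal(n)
        df[f"comp_v_{d}"] = v + 0.4 * rng.standard_normal(n)
        df[f"comp_a_{d}"] = a + 0.4 * rng.standard_normal(n)
        df[f"comp_t0_{d}"] = t0 + 0.4 * rng.standard_normal(n)
    return df


class TestModelSuite:
    def test_t0_mediation_recovered(self, rng):
        df = _toy_composites(rng)
        results = run_model_suite(df, n_boot=500, seed=0)
        assert set(results) == set(MODEL_SPECS)
        m2 = results["Model 2"]
        i_t0 = m2.mediators.index("comp_t0")
        assert m2.ci_high[i_t0] < 0  # negative indirect, CI excludes zero

    def test_global_null_quiet(self):
        rng = np.random.default_rng(99)
        df = _toy_composites(rng, with_age_effects=False)
        results = run_model_suite(df, n_boot=500, seed=0)
        n_flagged = sum(
            (r.ci_low[i] > 0 or r.ci_high[i] < 0)
            for r in results.values()
            for i in range(len(r.mediators))
        )
        assert n_flagged <= 2  # ~nominal at conf 0.995 over 22 intervals

    def test_missing_column_names_model(self, rng):
        df = _toy_composites(rng).drop(columns=["comp_t0"])
        with pytest.raises(KeyError, match="Model 2"):
            run_model_suite(df, n_boot=50)

    def test_pathway_without_outcome_link_gives_null_indirect(self):
        """Age moves boundary separation, but the outcome ignores it."""
        rng = np.random.default_rng(5)
        df = _toy_composites(rng)
        results = run_model_suite(df, n_boot=500, seed=1)
        m2 = results["Model 2"]
        i_a = m2.mediators.index("comp_a")
        assert m2.alpha[i_a] > 0.2  # age -> a path present
        assert m2.ci_low[i_a] < 0 < m2.ci_high[i_a]  # but indirect is null


class TestCorrelationPower:
    def test_design_value(self):
        assert correlation_power(0.25, 125, 0.05) == pytest.approx(0.81, abs=0.005)

    def test_size_equals_level(self):
        assert correlation_power(1e-9, 125, 0.05) == pytest.approx(0.05, abs=1e-3)

    def test_consistency(self):
        assert correlation_power(0.25, 100_000, 0.05) > 0.999999

    def test_simulation_cross_check(self):
        approx = correlation_power(0.25, 125, 0.05)
        sim = correlation_power_simulated(0.25, 125, 0.05, n_rep=20_000, seed=2)
        assert sim == pytest.approx(approx, abs=0.015)

    def test_domain_errors(self):
        for bad in ((1.2, 100, 0.05), (0.3, 3, 0.05), (0.3, 100, 1.2)):
            with pytest.raises(ValueError):
                correlation_power(*bad)
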