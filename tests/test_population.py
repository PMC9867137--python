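"""Synthetic-population generator and Laplace/FOCE estimation layer."""

import math

import numpy as np
import pytest
from scipy import integrate as sint

from fractalpk import (
    DoseEvent,
    ModelSpec,
    PopulationDesign,
    PopulationModel,
    PopulationPKEstimator,
    generate_population,
    robustify,
)
from fractalpk.population import evaluate_ofv, fit as fit_fn


@pytest.fixture(scope="module")
def bolus_model():
    spec = ModelSpec(n_compartments=1, absorption="bolus")
    return PopulationModel(
        spec=spec,
        theta={"CL": 1.0, "V1": 10.0},
        omega={"V1": 0.01},
        sigma_add=0.5,
    )


class TestGenerator:
    def test_same_seed_same_dataset(self, fractal_abs_truth, rich_times):
        design = PopulationDesign(
            model=fractal_abs_truth,
            n_subjects=5,
            doses=[DoseEvent(0.0, 100.0)],
            sampling_times=rich_times,
            seed=11,
        )
        a = generate_population(design)
        b = generate_population(design)
        assert a == b

    def test_different_seed_differs(self, fractal_abs_truth, rich_times):
        design = PopulationDesign(
            model=fractal_abs_truth,
            n_subjects=5,
            doses=[DoseEvent(0.0, 100.0)],
            sampling_times=rich_times,
        )
        a = generate_population(design, seed=1)
        b = generate_population(design, seed=2)
        assert not (a == b)

    def test_subject_count_matches_design(self, fractal_abs_truth, rich_times):
        design = PopulationDesign(
            model=fractal_abs_truth,
            n_subjects=18,
            doses=[DoseEvent(0.0, 100.0)],
            sampling_times=rich_times,
            seed=3,
        )
        data = generate_population(design)
        assert data.n_subjects == 18
        assert data.n_observations == 18 * len(rich_times)

    def test_noise_free_equals_population_prediction(self, rich_times):
        spec = ModelSpec(n_compartments=1, absorption="first_order")
        model = PopulationModel(
            spec=spec, theta={"Ka": 0.3, "CL": 0.5, "V1": 10.0}, omega={}, sigma_add=0.0
        )
        design = PopulationDesign(
            model=model,
            n_subjects=3,
            doses=[DoseEvent(0.0, 100.0)],
            sampling_times=rich_times,
            seed=5,
        )
        data = generate_population(design)
        obs = data.observations()
        for _, sub in obs.groupby("ID"):
            first = obs[obs["ID"] == obs["ID"].iloc[0]]
            assert np.allclose(sub["DV"].to_numpy(), first["DV"].to_numpy())

    def test_negative_observations_kept_by_default(self):
        spec = ModelSpec(n_compartments=1, absorption="first_order")
        model = PopulationModel(
            spec=spec,
            theta={"Ka": 0.3, "CL": 0.5, "V1": 10.0},
            sigma_add=5.0,  # large additive noise around small concentrations
        )
        design = PopulationDesign(
            model=model,
            n_subjects=20,
            doses=[DoseEvent(0.0, 1.0)],
            sampling_times=(1.0, 5.0, 20.0),
            seed=6,
        )
        assert (generate_population(design).observations()["DV"] < 0).any()
        design.truncate_negative = True
        assert not (generate_population(design).observations()["DV"] < 0).any()


class TestModelValidation:
    def test_h_bounds_enforced(self):
        spec = ModelSpec(n_compartments=1, fractal_on={"Ka": 0.5})
        with pytest.raises(ValueError, match="outside"):
            PopulationModel(
                spec=spec,
                theta={"Ka": 0.3, "CL": 0.5, "V1": 10.0, "h_Ka": 1.2},
            )

    def test_iiv_on_unknown_effect_rejected(self):
        spec = ModelSpec(n_compartments=1, absorption="bolus")
        with pytest.raises(ValueError, match="IIV"):
            PopulationModel(
                spec=spec, theta={"CL": 1.0, "V1": 10.0}, omega={"Ka": 0.1}
            )


class TestLaplaceObjective:
    def test_matches_quadrature_at_small_omega(self):
        """1-compartment bolus, IIV on V1, one sample per subject: the
        Laplace OFV agrees with brute-force quadrature of the marginal
        likelihood to 1e-4 when the random effect is nearly degenerate."""
        spec = ModelSpec(n_compartments=1, absorption="bolus")
        model = PopulationModel(
            spec=spec,
            theta={"CL": 1.0, "V1": 10.0},
            omega={"V1": 1e-5},
            sigma_add=0.5,
        )
        design = PopulationDesign(
            model=model,
            n_subjects=3,
            doses=[DoseEvent(0.0, 100.0)],
            sampling_times=(5.0,),
            seed=42,
        )
        data = generate_population(design)
        ofv, _ = evaluate_ofv(model, data)

        def f_eta(eta, t=5.0):
            v1 = 10.0 * math.exp(eta)
            return 100.0 * math.exp(-1.0 * t / v1) / v1

        quad_total = 0.0
        for _, sub in data.df.groupby("ID"):
            y = float(sub[sub["EVID"] == 0]["DV"].iloc[0])

            def integrand(eta):
                fy = f_eta(eta)
                return (
                    math.exp(-0.5 * (y - fy) ** 2 / 0.25)
                    / math.sqrt(2 * math.pi * 0.25)
                    * math.exp(-0.5 * eta**2 / 1e-5)
                    / math.sqrt(2 * math.pi * 1e-5)
                )

            lik, _ = sint.quad(integrand, -0.05, 0.05, epsabs=1e-16, epsrel=1e-13)
            quad_total += -2.0 * math.log(lik)
        assert abs(ofv - quad_total) < 1e-4

    def test_close_to_quadrature_at_moderate_omega(self, bolus_model):
        """At 10% IIV the Laplace approximation tracks quadrature closely
        (sparse single-observation design, the hardest case for it)."""
        design = PopulationDesign(
            model=bolus_model,
            n_subjects=3,
            doses=[DoseEvent(0.0, 100.0)],
            sampling_times=(5.0,),
            seed=42,
        )
        data = generate_population(design)
        ofv, _ = evaluate_ofv(bolus_model, data)

        def f_eta(eta, t=5.0):
            v1 = 10.0 * math.exp(eta)
            return 100.0 * math.exp(-t / v1) / v1

        quad_total = 0.0
        for _, sub in data.df.groupby("ID"):
            y = float(sub[sub["EVID"] == 0]["DV"].iloc[0])

            def integrand(eta):
                fy = f_eta(eta)
                return (
                    math.exp(-0.5 * (y - fy) ** 2 / 0.25)
                    / math.sqrt(2 * math.pi * 0.25)
                    * math.exp(-0.5 * eta**2 / 0.01)
                    / math.sqrt(2 * math.pi * 0.01)
                )

            lik, _ = sint.quad(integrand, -1.0, 1.0, epsabs=1e-14, epsrel=1e-12)
            quad_total += -2.0 * math.log(lik)
        assert abs(ofv - quad_total) < 0.1

    def test_fast_and_general_prediction_paths_agree(self, fractal_abs_truth, rich_times):
        from fractalpk.simulate import SolverOptions

        design = PopulationDesign(
            model=fractal_abs_truth,
            n_subjects=4,
            doses=[DoseEvent(0.0, 100.0)],
            sampling_times=rich_times,
            seed=9,
        )
        data = generate_population(design)
        o_fast, _ = evaluate_ofv(fractal_abs_truth, data)
        o_gen, _ = evaluate_ofv(
            fractal_abs_truth, data, solver=SolverOptions(method="LSODA")
        )
        assert o_fast == pytest.approx(o_gen, abs=1e-3)


@pytest.fixture(scope="module")
def noise_free_fit():
    """Degenerate recovery: noise-free data, near-zero Omega/sigma."""
    spec = ModelSpec(n_compartments=1, absorption="first_order")
    truth = PopulationModel(
        spec=spec,
        theta={"Ka": 0.3, "CL": 0.5, "V1": 10.0},
        omega={"CL": 1e-8},
        sigma_add=1e-4,
    )
    design = PopulationDesign(
        model=truth,
        n_subjects=4,
        doses=[DoseEvent(0.0, 100.0)],
        sampling_times=(0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0, 48.0),
        seed=0,
    )
    data = generate_population(design)
    init = truth.copy()
    init.theta.update({"Ka": 0.4, "CL": 0.4, "V1": 12.0})
    est = PopulationPKEstimator(init, free=["Ka", "CL", "V1"], maxfev=400)
    return truth, est.fit(data)


@pytest.fixture(scope="module")
def simple_fit():
    spec = ModelSpec(n_compartments=1, absorption="first_order")
    truth = PopulationModel(
        spec=spec,
        theta={"Ka": 0.3, "CL": 0.5, "V1": 10.0},
        omega={"CL": 0.04},
        sigma_prop=0.1,
    )
    design = PopulationDesign(
        model=truth,
        n_subjects=6,
        doses=[DoseEvent(0.0, 100.0)],
        sampling_times=(0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0, 48.0),
        seed=13,
    )
    data = generate_population(design)
    res = fit_fn(
        truth,
        data,
        options={"free": ["Ka", "CL", "V1", "omega_CL", "sigma_prop"], "maxfev": 300},
    )
    return data, res


class TestFitting:
    def test_noise_free_recovery(self, noise_free_fit):
        truth, est = noise_free_fit
        for name in ("Ka", "CL", "V1"):
            assert est.theta_[name] == pytest.approx(truth.theta[name], rel=1e-3)

    def test_fitted_attributes_present(self, noise_free_fit):
        _, est = noise_free_fit
        assert est.k_ == 3
        assert est.n_obs_ == 4 * 8
        assert math.isfinite(est.ofv_)
        assert set(est.ebes_) == {1, 2, 3, 4}

    def test_ofv_trace_monotone_non_increasing(self, noise_free_fit):
        _, est = noise_free_fit
        trace = np.asarray(est.ofv_trace_)
        assert len(trace) >= 1
        assert np.all(np.diff(trace) <= 0)

    def test_predict_requires_fit(self, bolus_model):
        est = PopulationPKEstimator(bolus_model)
        with pytest.raises(RuntimeError, match="not fitted"):
            est.predict(None)

    def test_sklearn_params_roundtrip(self, bolus_model):
        est = PopulationPKEstimator(bolus_model, maxfev=123)
        params = est.get_params()
        assert params["maxfev"] == 123
        est.set_params(maxfev=456)
        assert est.maxfev == 456

    def test_estimated_h_within_bounds(self, small_population, fractal_abs_truth):
        """The heterogeneity exponent always lands in [0, 1] (logit-bounded),
        even from a deliberately extreme start."""
        init = fractal_abs_truth.copy()
        init.theta["h_Ka"] = 0.95
        est = PopulationPKEstimator(
            init, free=["h_Ka"], maxfev=60
        )
        est.fit(small_population)
        assert 0.0 <= est.theta_["h_Ka"] <= 1.0


class TestRobustify:
    def test_restart_from_optimum_is_idempotent(self, simple_fit):
        data, res = simple_fit
        rob = robustify(
            res,
            data,
            n_perturb=2,
            seed=1,
            options={
                "free": ["Ka", "CL", "V1", "omega_CL", "sigma_prop"],
                "maxfev": 300,
            },
        )
        assert rob.ofv <= res.ofv + 1e-6
        assert rob.n_saddle_resets == 2

    def test_two_seeds_land_in_same_basin(self, simple_fit):
        data, res = simple_fit
        opts = {"free": ["Ka", "CL", "V1", "omega_CL", "sigma_prop"], "maxfev": 300}
        r1 = robustify(res, data, n_perturb=1, seed=101, options=opts)
        r2 = robustify(res, data, n_perturb=1, seed=202, options=opts)
        assert abs(r1.ofv - r2.ofv) < 0.1


class TestFitResultSerialization:
    def test_json_roundtrip(self, simple_fit_result=None):
        spec = ModelSpec(n_compartments=1, fractal_on={"Ka": 0.4})
        model = PopulationModel(
            spec=spec,
            theta={"Ka": 0.3, "CL": 0.5, "V1": 10.0, "h_Ka": 0.4},
            omega={"CL": 0.04},
            sigma_prop=0.1,
        )
        from fractalpk.population import FitResult

        res = FitResult(
            model=model,
            theta=dict(model.theta),
            omega=dict(model.omega),
            sigma_add=0.0,
            sigma_prop=0.1,
            ofv=123.456,
            k=5,
            n_obs=48,
            ebes={1: np.array([0.01]), 2: np.array([-0.02])},
            converged=True,
            n_iter=100,
        )
        text = res.to_json()
        back = FitResult.from_json(text)
        assert back.ofv == res.ofv
        assert back.theta == res.theta
        assert back.model.spec.fractal_on == {"Ka": 0.4}
        assert np.allclose(back.ebes["1"], [0.01])
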