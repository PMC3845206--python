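import numpy as np
import pytest

from attngain import comparison as cp
from attngain import inversion as inv
from attngain import observation as ob
from attngain import synthetic_data as sd
from attngain.network import BACKWARD_PAIRS, SOURCE_NAMES, build_posner_network

from conftest import EFFECT_LABELS, fit_scenario


class LinearForward:
    """A toy forward model linear in theta, for conjugate-oracle checks."""

    conditions = ("c",)

    def __init__(self, X):
        self.X = X

    def predict(self, thetas):
        T = np.atleast_2d(thetas)
        preds = (T @ self.X.T).reshape(T.shape[0], 1, 1, self.X.shape[0])
        return preds, np.ones(T.shape[0], dtype=bool)


@pytest.fixture(scope="module")
def linear_problem():
    rng = np.random.default_rng(0)
    P, N = 10, 40
    X = rng.standard_normal((N, P))
    theta = rng.standard_normal(P)
    lam = np.log(25.0)  # known noise precision (sd 0.2)
    y = X @ theta + np.exp(-lam / 2) * rng.standard_normal(N)
    priors = inv.PriorSpec([f"t{i}" for i in range(P)], np.zeros(P), np.full(P, 0.8))
    opts = inv.VLOptions(hyper_mean=lam, hyper_variance=0.0)
    fit = inv.variational_laplace({"c": y[None, :]}, LinearForward(X), priors, opts)
    return X, y, lam, priors, opts, fit


class TestLinearGaussianOracle:
    def closed_form(self, X, y, lam, priors):
        S0 = np.diag(priors.variance)
        Spost = np.linalg.inv(np.linalg.inv(S0) + np.exp(lam) * X.T @ X)
        mpost = Spost @ (np.exp(lam) * X.T @ y)
        N = y.size
        Sy = np.exp(-lam) * np.eye(N) + X @ S0 @ X.T
        logev = (
            -0.5 * N * np.log(2 * np.pi)
            - 0.5 * np.linalg.slogdet(Sy)[1]
            - 0.5 * y @ np.linalg.solve(Sy, y)
        )
        return mpost, Spost, logev

    def test_posterior_matches_conjugate_solution(self, linear_problem):
        X, y, lam, priors, _, fit = linear_problem
        mpost, Spost, _ = self.closed_form(X, y, lam, priors)
        assert np.abs(fit.posterior.mean - mpost).max() < 1e-6
        assert np.abs(fit.posterior.cov - Spost).max() < 1e-6

    def test_free_energy_equals_log_evidence(self, linear_problem):
        X, y, lam, priors, _, fit = linear_problem
        _, _, logev = self.closed_form(X, y, lam, priors)
        assert abs(fit.free_energy - logev) < 1e-6

    def test_free_energy_is_last_trace_value(self, linear_problem):
        *_, fit = linear_problem
        assert inv.free_energy(fit) == fit.trace[-1]

    def test_trace_monotone_nondecreasing(self, linear_problem):
        *_, fit = linear_problem
        assert all(b >= a for a, b in zip(fit.trace, fit.trace[1:]))


class TestDefaultPriors:
    def test_full_model_frees_all_condition_effects(self):
        priors = inv.default_priors(build_posner_network(), cp.ModelSpec(True, True, True))
        for name in EFFECT_LABELS:
            assert priors.variance[priors.index(name)] == 0.25

    def test_null_model_fixes_every_condition_effect_at_zero(self):
        priors = inv.default_priors(build_posner_network(), cp.ModelSpec(False, False, False))
        for name in priors.names:
            if name.startswith(("dg_", "dM_", "dB_")):
                assert priors.variance[priors.index(name)] == 0.0
                assert priors.mean[priors.index(name)] == 0.0

    def test_model_101_frees_extrastriate_not_parietal(self):
        priors = inv.default_priors(build_posner_network(), cp.ModelSpec(True, False, True))
        assert priors.variance[priors.index("dg_V2L")] == 0.25
        assert priors.variance[priors.index("dg_V3R")] == 0.25
        assert priors.variance[priors.index("dg_PCL")] == 0.0
        assert priors.variance[priors.index("dM_V3L->V2L")] == 0.25

    def test_structural_scalings_and_stimulus_prior(self):
        priors = inv.default_priors(build_posner_network(), cp.ModelSpec(True, True, True))
        assert priors.variance[priors.index("lnA_f_V2L->V3L")] == 1 / 16
        assert priors.mean[priors.index("stim_peak")] == 120.0
        assert priors.variance[priors.index("stim_peak")] == 256.0

    def test_fixed_parameters_invisible_to_optimizer(self):
        priors = inv.default_priors(build_posner_network(), cp.ModelSpec(False, False, False))
        free_names = [priors.names[i] for i in np.flatnonzero(priors.free)]
        assert not any(n.startswith(("dg_", "dM_", "dB_")) for n in free_names)
        assert priors.n_free == len(free_names)


class TestPredictResponse:
    def test_truth_parameters_reproduce_noiseless_modes(self):
        spec = sd.default_validity_scenario(seed=0, snr_db=np.inf)
        ds, truth = sd.generate_dataset(spec)
        basis = ob.canonical_modes(ds, ds.lead_field, 8)
        modes = ob.reduce_to_modes(ds, basis)
        net = build_posner_network()
        priors = inv.default_priors(net, cp.ModelSpec(True, True, True))
        fwd = inv.ForwardModel(net, ds.lead_field, basis, priors)
        theta = priors.mean.copy()
        tv = truth.effect_vector()
        for name, value in zip(EFFECT_LABELS, tv):
            theta[priors.index(name)] = value
        pred = inv.predict_response(theta, fwd)
        for c in modes:
            assert np.allclose(pred[c], modes[c], atol=1e-8)

    def test_prediction_condition_identical_without_effects(self):
        spec = sd.default_validity_scenario(seed=0)
        ds, _ = sd.generate_dataset(spec)
        basis = ob.canonical_modes(ds, ds.lead_field, 8)
        net = build_posner_network()
        priors = inv.default_priors(net, cp.ModelSpec(True, True, True))
        fwd = inv.ForwardModel(net, ds.lead_field, basis, priors)
        pred = inv.predict_response(priors.mean, fwd)
        assert np.array_equal(pred["valid"], pred["invalid"])

    def test_theta_to_network_round_trip_of_effects(self):
        net = build_posner_network()
        priors = inv.default_priors(net, cp.ModelSpec(True, True, True))
        theta = priors.mean.copy()
        theta[priors.index("dg_V2L")] = -0.5
        theta[priors.index("dM_V3L->V2L")] = 0.3
        built = inv.theta_to_network(theta, priors, net)
        v3l, v2l = SOURCE_NAMES.index("V3L"), SOURCE_NAMES.index("V2L")
        assert built.effects.delta_gamma[SOURCE_NAMES.index("V2L")] == -0.5
        assert built.effects.delta_M[v2l, v3l] == 0.3


class TestObjectiveDiagnostics:
    def test_accuracy_term_falls_with_added_noise_at_fixed_theta(self):
        spec = sd.default_validity_scenario(seed=0, snr_db=np.inf)
        ds, _ = sd.generate_dataset(spec)
        basis = ob.canonical_modes(ds, ds.lead_field, 8)
        modes = ob.reduce_to_modes(ds, basis)
        net = build_posner_network()
        priors = inv.default_priors(net, cp.ModelSpec(True, True, True))
        fwd = inv.ForwardModel(net, ds.lead_field, basis, priors)
        rng = np.random.default_rng(0)
        noisier = {c: m + 0.05 * rng.standard_normal(m.shape) for c, m in modes.items()}
        lam = 4.0
        f_clean = inv.objective_at(priors.mean, modes, fwd, priors, lam)
        f_noisy = inv.objective_at(priors.mean, noisier, fwd, priors, lam)
        assert f_noisy < f_clean

    def test_internal_gradient_matches_directional_derivative(self):
        spec = sd.default_validity_scenario(seed=0)
        ds, _ = sd.generate_dataset(spec)
        basis = ob.canonical_modes(ds, ds.lead_field, 8)
        modes = ob.reduce_to_modes(ds, basis)
        net = build_posner_network()
        priors = inv.default_priors(net, cp.ModelSpec(True, True, True))
        fwd = inv.ForwardModel(net, ds.lead_field, basis, priors)
        lam = 4.0
        free_idx = np.flatnonzero(priors.free)
        g = inv.internal_gradient(priors.mean, modes, fwd, priors, lam)
        rng = np.random.default_rng(1)
        y = inv._stack_data(modes, fwd.conditions)

        def loss(theta):
            pred, _ = fwd.predict(theta[None])
            e = y - pred[0].ravel()
            d = theta[free_idx] - priors.mean[free_idx]
            P0 = np.diag(1.0 / priors.variance[free_idx])
            return -0.5 * np.exp(lam) * e @ e - 0.5 * d @ P0 @ d

        for _ in range(3):
            direction = rng.standard_normal(free_idx.size)
            direction /= np.linalg.norm(direction)
            h = 1e-4
            tp, tm = priors.mean.copy(), priors.mean.copy()
            tp[free_idx] += h * direction
            tm[free_idx] -= h * direction
            numeric = (loss(tp) - loss(tm)) / (2 * h)
            analytic = g @ direction
            assert abs(numeric - analytic) <= 0.01 * max(1.0, abs(numeric))


class TestCalibration:
    def test_effect_credible_intervals_cover_zero_on_null_data(self):
        # data generated at the prior mean with zero condition effects and
        # high SNR: 90% credible intervals should cover 0 for ~90% of the
        # effect parameters, pooled over seeds
        covered = total = 0
        for seed in range(3):
            out = fit_scenario(seed, null=True, snr_db=30.0)
            fit, priors = out["fit"], out["priors"]
            sds = fit.posterior.sd(priors)
            for name in EFFECT_LABELS:
                i = priors.index(name)
                half_width = 1.6449 * sds[i]
                covered += abs(fit.posterior.mean[i]) <= half_width
                total += 1
        assert covered / total >= 0.9


class TestComplexityPenalty:
    def test_irrelevant_free_effects_never_raise_evidence(self, null_fits):
        # on effect-free data the full model's F must not exceed any reduced
        # model's F obtained by fixing (truly irrelevant) effects at zero
        for out in null_fits:
            fit, priors = out["fit"], out["priors"]
            for model in (cp.ModelSpec(False, False, False), cp.ModelSpec(True, False, False)):
                reduced = cp.restrict_priors(priors, model)
                f_reduced = cp.reduce_evidence(fit, priors, reduced)
                assert fit.free_energy <= f_reduced
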