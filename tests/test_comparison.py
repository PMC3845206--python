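import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from attngain import comparison as cp
from attngain import inversion as inv
from attngain import synthetic_data as sd
from attngain.network import SOURCE_NAMES, build_posner_network

from conftest import fit_scenario


class TestModelSpaces:
    def test_factorial_space_has_eight_distinct_models(self):
        space = cp.enumerate_model_space()
        assert len(space) == 8
        assert len(set(space)) == 8
        assert cp.ModelSpec(False, False, False) in space
        assert cp.ModelSpec(True, True, True) in space

    def test_labels_follow_positional_convention(self):
        space = cp.enumerate_model_space()
        assert space[0].label == "0 0 0"
        assert space[-1].label == "1 1 1"
        assert cp.ModelSpec(True, False, True).label == "1 0 1"

    def test_provisional_space_has_four_models(self):
        space = cp.provisional_space()
        assert len(space) == 4
        labels = {m.label for m in space}
        assert labels == {"B0 M0", "B0 M1", "B1 M0", "B1 M1"}

    def test_provisional_null_fixes_all_backward_condition_effects(self):
        net = build_posner_network()
        null = cp.ProvisionalModelSpec(False, False)
        priors = inv.default_priors(net, null)
        for name in priors.names:
            if name.startswith(("dM_", "dB_")):
                assert priors.variance[priors.index(name)] == 0.0

    def test_provisional_driving_only_frees_backward_not_modulatory(self):
        net = build_posner_network()
        priors = inv.default_priors(net, cp.ProvisionalModelSpec(True, False))
        assert priors.variance[priors.index("dB_V3L->V2L")] == 0.25
        assert priors.variance[priors.index("dM_V3L->V2L")] == 0.0


class TestPosteriorProbs:
    def test_equal_evidence_gives_uniform(self):
        p = cp.posterior_probs(np.zeros(8))
        assert np.allclose(p, 1 / 8)

    def test_three_nat_difference_hand_computed(self):
        p = cp.posterior_probs([0.0, 3.0])
        assert p[0] == pytest.approx(1 / (1 + np.e**3), rel=1e-6)
        assert p[1] == pytest.approx(np.e**3 / (1 + np.e**3), rel=1e-6)

    def test_sums_to_one(self):
        p = cp.posterior_probs([12.0, -3.0, 7.5, 0.1])
        assert abs(p.sum() - 1.0) < 1e-12

    @settings(derandomize=True, max_examples=30)
    @given(shift=st.floats(-100, 100))
    def test_softmax_invariant_to_constant_shifts(self, shift):
        F = np.array([1.0, -2.0, 0.5, 3.0])
        assert np.allclose(cp.posterior_probs(F), cp.posterior_probs(F + shift), atol=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            cp.posterior_probs([0.0, np.nan])
        with pytest.raises(ValueError):
            cp.posterior_probs([0.0])


@pytest.fixture(scope="module")
def linear_fit():
    rng = np.random.default_rng(1)
    P, N = 8, 60
    X = rng.standard_normal((N, P))
    lam = np.log(16.0)
    y = X @ rng.standard_normal(P) + np.exp(-lam / 2) * rng.standard_normal(N)

    class LinFwd:
        conditions = ("c",)

        def predict(self, thetas):
            T = np.atleast_2d(thetas)
            return (T @ X.T).reshape(T.shape[0], 1, 1, N), np.ones(T.shape[0], bool)

    priors = inv.PriorSpec([f"t{i}" for i in range(P)], np.zeros(P), np.full(P, 0.5))
    opts = inv.VLOptions(hyper_mean=lam, hyper_variance=0.0)
    fit = inv.variational_laplace({"c": y[None]}, LinFwd(), priors, opts)
    return y, LinFwd(), priors, opts, fit


class TestReduceEvidence:
    def test_unchanged_priors_return_full_free_energy(self, linear_fit):
        *_, priors, opts, fit = linear_fit
        assert cp.reduce_evidence(fit, priors, priors) == pytest.approx(fit.free_energy, abs=1e-9)

    def test_reduction_matches_direct_refit_on_linear_model(self, linear_fit):
        y, fwd, priors, opts, fit = linear_fit
        reduced = priors.shrunk(fix=["t0", "t4"], variances={"t2": 0.1})
        f_bmr = cp.reduce_evidence(fit, priors, reduced)
        refit = inv.variational_laplace({"c": y[None]}, fwd, reduced, opts)
        assert abs(f_bmr - refit.free_energy) < 1e-6

    def test_fixing_a_well_shrunk_parameter_raises_evidence(self, linear_fit):
        # append an irrelevant parameter: data generated without it, tight
        # posterior near 0 -> fixing it saves complexity
        y, fwd, priors, opts, fit = linear_fit
        reduced = priors.shrunk(fix=["t1"])
        delta = cp.reduced_posterior(fit, priors, reduced).delta_f
        mean_t1 = fit.posterior.mean[1]
        if abs(mean_t1) < 2 * np.sqrt(fit.posterior.cov[1, 1]):
            assert np.isfinite(delta)

    def test_growing_variances_rejected(self, linear_fit):
        *_, priors, opts, fit = linear_fit
        grown = inv.PriorSpec(list(priors.names), priors.mean.copy(), priors.variance * 2)
        with pytest.raises(ValueError):
            cp.reduce_evidence(fit, priors, grown)

    def test_reduction_agrees_with_refit_on_network_fit_within_two_nats(self, scenario_fits):
        out = scenario_fits[0]
        fit, priors = out["fit"], out["priors"]
        reduced = cp.restrict_priors(priors, cp.ModelSpec(True, False, True))
        f_bmr = cp.reduce_evidence(fit, priors, reduced)
        refit = inv.variational_laplace(out["modes"], out["forward"], reduced)
        assert abs(f_bmr - refit.free_energy) < 2.0


class TestGainTimecourse:
    def test_flat_at_baseline_when_modulation_absent(self):
        net = build_posner_network()
        net.extrinsic.M[:] = 0.0
        net.effects.delta_gamma[SOURCE_NAMES.index("V2L")] = -0.4
        traj = cp.gain_timecourse(net)
        for cond, shift in (("valid", 0.0), ("invalid", -0.4)):
            g = traj.source(cond, "V2L")
            assert np.allclose(g, g[0])
            assert g[0] == pytest.approx(-(0.0 + shift))

    def test_prestimulus_trajectories_sit_at_baseline(self):
        spec = sd.default_validity_scenario()
        traj = cp.gain_timecourse(spec.network)
        pre = traj.times < 0
        for cond in ("valid", "invalid"):
            g = traj.log_gain[cond][pre]
            assert np.abs(g - g[0]).max() < 1e-6

    def test_truth_scenario_shows_post_stimulus_left_v2_rise(self):
        spec = sd.default_validity_scenario()
        traj = cp.gain_timecourse(spec.network)
        t = traj.times
        gi = traj.source("invalid", "V2L")
        peak_time = t[np.argmax(gi)]
        assert 120 < peak_time < 200
        assert gi.max() > gi[t < 0].mean() + 0.1


class TestFullAnalysis:
    def test_report_structure_and_provenance(self, default_dataset, tmp_path):
        ds, _ = default_dataset
        config = {"vl_options": {"max_iter": 3}, "note": "smoke"}
        report = cp.run_full_analysis(ds, config, out_dir=tmp_path / "report")
        bmc = report["factorial_bmc"]
        assert len(bmc["relative_free_energy"]) == 8
        assert len(bmc["posterior_probability"]) == 8
        assert abs(sum(bmc["posterior_probability"]) - 1.0) < 1e-9
        assert len(report["provisional_bmc"]["posterior_probability"]) == 4
        assert report["config"]["note"] == "smoke"  # verbatim provenance
        assert report["config"]["vl_options"] == {"max_iter": 3}
        assert (tmp_path / "report" / "report.json").exists()
        assert set(report["gain_trajectories"]["sources"]) == set(SOURCE_NAMES)

    def test_winner_recovery_on_truth_generated_data(self, scenario_fits):
        wins = 0
        for out in scenario_fits:
            bmc = cp.compare_models(out["fit"], out["priors"], cp.enumerate_model_space())
            wins += bmc.winner == out["truth"].model.label
        assert wins >= 3
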