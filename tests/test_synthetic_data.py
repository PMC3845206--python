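import numpy as np
import pytest

from attngain import io
from attngain.comparison import ModelSpec
from attngain.network import BACKWARD_PAIRS, SOURCE_NAMES, ConditionEffects
from attngain.preprocessing import robust_average
from attngain.synthetic_data import (
    ScenarioSpec,
    default_validity_scenario,
    generate_dataset,
    generate_raw_trials,
)

IDX = {lab: i for i, lab in enumerate(SOURCE_NAMES)}


class TestScenarioPattern:
    def test_left_v2_profoundly_disinhibited(self):
        spec = default_validity_scenario()
        assert spec.network.effects.delta_gamma[IDX["V2L"]] < 0
        assert spec.network.effects.delta_gamma[IDX["V2L"]] == pytest.approx(-np.log(2))

    def test_slight_extrastriate_effects_have_stated_signs(self):
        eff = default_validity_scenario().network.effects
        assert eff.delta_gamma[IDX["V3L"]] > 0  # left V3 gain slightly decreased
        assert eff.delta_gamma[IDX["V5R"]] < 0  # right V5 gain increased

    def test_modulation_positive_except_from_right_parietal(self):
        eff = default_validity_scenario().network.effects
        for s, t in BACKWARD_PAIRS:
            if SOURCE_NAMES[s] == "PCR":
                assert eff.delta_M[t, s] < 0
            else:
                assert eff.delta_M[t, s] >= 0

    def test_no_parietal_gain_difference(self):
        eff = default_validity_scenario().network.effects
        assert eff.delta_gamma[IDX["PCL"]] == 0.0
        assert eff.delta_gamma[IDX["PCR"]] == 0.0

    def test_input_targets_right_v2_for_left_hemifield_targets(self):
        spec = default_validity_scenario()
        assert spec.network.stimulus.target_source.label == "V2R"

    def test_generating_model_is_extrastriate_plus_modulation(self):
        _, truth = generate_dataset(default_validity_scenario())
        assert truth.model == ModelSpec(True, False, True)
        truth.check_model_consistency()

    def test_inconsistent_truth_record_detected(self):
        _, truth = generate_dataset(default_validity_scenario())
        truth.model = ModelSpec(True, True, True)  # claims parietal effects
        with pytest.raises(ValueError):
            truth.check_model_consistency()


class TestGenerateDataset:
    def test_same_spec_gives_byte_identical_datasets(self):
        a, _ = generate_dataset(default_validity_scenario(seed=7))
        b, _ = generate_dataset(default_validity_scenario(seed=7))
        for c in a.data:
            assert np.array_equal(a.data[c], b.data[c])

    def test_zero_effects_infinite_snr_conditions_identical(self):
        spec = default_validity_scenario(seed=0, snr_db=np.inf)
        spec.network.effects = ConditionEffects()
        ds, _ = generate_dataset(spec)
        assert np.array_equal(ds.data["valid"], ds.data["invalid"])

    def test_condition_contrast_energy_above_noise_floor(self, default_dataset):
        ds, truth = default_dataset
        contrast = ds.data["invalid"] - ds.data["valid"]
        clean_spec = default_validity_scenario(seed=0, snr_db=np.inf)
        clean, _ = generate_dataset(clean_spec)
        clean_contrast = clean.data["invalid"] - clean.data["valid"]
        noise_var = np.mean((ds.data["valid"] - clean.data["valid"]) ** 2)
        # the clean contrast alone must carry more energy than one noise draw
        assert np.mean(clean_contrast**2) > 0.5 * noise_var

    def test_window_and_rate_follow_study_design(self, default_dataset):
        ds, _ = default_dataset
        assert ds.sfreq == 200.0
        assert ds.window_ms == (-50.0, 400.0)
        assert ds.data["valid"].shape[1] == 91

    def test_invalid_outlier_fraction_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(network=default_validity_scenario().network, outlier_fraction=1.0)


class TestGenerateRawTrials:
    def test_no_jitter_no_noise_trials_identical(self):
        spec = default_validity_scenario(seed=1, snr_db=np.inf)
        spec.n_trials = 4
        spec.amplitude_jitter_sd = 0.0
        spec.latency_jitter_sd = 0.0
        trials, _ = generate_raw_trials(spec)
        for ts in trials.values():
            for tr in ts.trials[1:]:
                assert np.allclose(tr, ts.trials[0])

    def test_outliers_flagged_by_index(self):
        spec = default_validity_scenario(seed=2)
        spec.n_trials = 20
        spec.outlier_fraction = 0.2
        trials, truth = generate_raw_trials(spec)
        for cond in ("valid", "invalid"):
            assert len(truth.outlier_indices[cond]) == 4
            clean_amp = np.median([np.abs(t).max() for t in trials[cond].trials])
            for k in truth.outlier_indices[cond]:
                assert np.abs(trials[cond].trials[k]).max() > 3 * clean_amp

    def test_robust_average_of_trials_approaches_clean_average(self):
        spec = default_validity_scenario(seed=3)
        spec.n_trials = 48
        spec.amplitude_jitter_sd = 0.0
        spec.latency_jitter_sd = 0.0
        trials, _ = generate_raw_trials(spec)
        clean_spec = default_validity_scenario(seed=3, snr_db=np.inf)
        clean_spec.n_trials = 2
        clean_spec.amplitude_jitter_sd = 0.0
        clean_spec.latency_jitter_sd = 0.0
        clean, _ = generate_raw_trials(clean_spec)
        avg = robust_average(trials["valid"]).average
        ref = clean["valid"].trials[0]
        assert np.abs(avg - ref).max() < 0.25 * np.abs(ref).max()


class TestContainerRoundTrip:
    def test_sensor_dataset_lossless(self, tmp_path, default_dataset):
        ds, _ = default_dataset
        path = tmp_path / "ds.h5"
        io.save_sensor_dataset(path, ds)
        back = io.load_sensor_dataset(path)
        assert back.sfreq == ds.sfreq
        assert tuple(back.window_ms) == ds.window_ms
        for c in ds.data:
            assert np.array_equal(back.data[c], ds.data[c])
        assert np.array_equal(back.lead_field.gain, ds.lead_field.gain)

    def test_trial_sets_lossless(self, tmp_path):
        spec = default_validity_scenario(seed=4)
        spec.n_trials = 3
        trials, _ = generate_raw_trials(spec)
        path = tmp_path / "trials.h5"
        io.save_trial_sets(path, trials)
        back = io.load_trial_sets(path)
        for cond, ts in trials.items():
            assert back[cond].onset_index == ts.onset_index
            for a, b in zip(back[cond].trials, ts.trials):
                assert np.array_equal(a, b)

    def test_lead_field_csv_round_trip(self, tmp_path, default_dataset):
        ds, _ = default_dataset
        path = tmp_path / "lead.csv"
        io.lead_field_to_csv(path, ds.lead_field)
        back = io.lead_field_from_csv(path)
        assert np.allclose(back.gain, ds.lead_field.gain)
        assert tuple(back.source_names) == tuple(ds.lead_field.source_names)


class TestFlatConfigExport:
    def test_keys_namespaced_and_values_match(self, tmp_path):
        spec = default_validity_scenario()
        cfg = io.network_to_config(spec.network)
        assert cfg["V2L.superficial_pyramidal.gamma0"] == 0.0
        assert cfg["V2L.deep_pyramidal.kappa"] == pytest.approx(1 / 16)
        assert cfg["effects.delta_gamma.V2L"] == pytest.approx(-np.log(2))
        assert cfg["stimulus.target"] == "V2R"
        assert "forward.V2L->V3L" in cfg
        path = tmp_path / "net.yaml"
        io.save_config(path, cfg)
        assert io.load_config(path) == cfg
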