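"""Ground-truth scenarios and synthetic MEG-style datasets.

The default validity scenario reproduces the qualitative structure of the
attentional (cueing) effect for left-hemifield targets: exogenous input to
right V2 at ~120 ms; in the invalid condition the left V2 source is
strongly disinhibited (profoundly lower superficial-pyramidal
self-inhibition), left V3 gain is slightly decreased, right V5 gain is
slightly increased, backward modulation is strengthened on all edges
except those from right parietal cortex, and parietal gain itself does not
differ between conditions.  Every generated dataset carries a TruthRecord
so that recovery tests can compare estimates with the generating values.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .comparison import ModelSpec
from .network import (
    ConditionEffects,
    NetworkParameters,
    SOURCE_NAMES,
    build_posner_network,
    integrate_batch,
    integrate_network,
    numeric_params,
    stack_numeric,
)
from .observation import (
    ContributionWeights,
    LeadField,
    SensorDataset,
    add_sensor_noise,
    make_lead_field,
    project_to_sensors,
)
from .preprocessing import TrialSet

__all__ = [
    "ScenarioSpec",
    "TruthRecord",
    "default_validity_scenario",
    "generate_dataset",
    "generate_raw_trials",
]

_IDX = {lab: i for i, lab in enumerate(SOURCE_NAMES)}

#: Default condition-effect magnitudes (log scale).  Signs follow the
#: attended-hemisphere switch; magnitudes are declared package defaults:
#: ln 2 for the profound left-V2 disinhibition, ln 1.25 for slight effects,
#: ln 1.5 for the positive modulatory differences.
PROFOUND = float(np.log(2.0))
SLIGHT = float(np.log(1.25))
MODERATE = float(np.log(1.5))


@dataclass
class ScenarioSpec:
    """Everything needed to generate a synthetic dataset reproducibly."""

    network: NetworkParameters
    snr_db: float = 10.0
    n_trials: int = 128
    amplitude_jitter_sd: float = 0.1  # lognormal sd of per-trial stimulus gain
    latency_jitter_sd: float = 8.0  # ms, per-trial shift of the input peak
    outlier_fraction: float = 0.0
    seed: int = 0
    n_channels: int = 64
    lead_seed: int = 1234
    sfreq: float = 200.0
    window_ms: tuple[float, float] = (-50.0, 400.0)

    def __post_init__(self) -> None:
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials per condition")


@dataclass
class TruthRecord:
    """Ground truth retained alongside a generated dataset."""

    effects: ConditionEffects
    network: NetworkParameters
    model: ModelSpec
    seed: int
    snr_db: float
    outlier_indices: dict[str, list[int]] = field(default_factory=dict)

    def effect_vector(self) -> np.ndarray:
        """Concatenated (delta_gamma, delta_M on backward edges) truth vector."""
        from .network import BACKWARD_PAIRS

        dM = np.array([self.effects.delta_M[t, s] for s, t in BACKWARD_PAIRS])
        return np.concatenate([self.effects.delta_gamma, dM])

    def check_model_consistency(self) -> None:
        """The generating ModelSpec must match which effect entries are nonzero."""
        dg = self.effects.delta_gamma
        extrastriate = bool(np.any(dg[[_IDX[n] for n in SOURCE_NAMES if not n.startswith("PC")]]))
        parietal = bool(np.any(dg[[_IDX["PCL"], _IDX["PCR"]]]))
        modulation = bool(np.any(self.effects.delta_M))
        actual = ModelSpec(extrastriate, parietal, modulation)
        if actual != self.model:
            raise ValueError(
                f"TruthRecord model {self.model.label!r} inconsistent with "
                f"nonzero effects {actual.label!r}"
            )


def scenario_effects() -> ConditionEffects:
    """The default invalid-vs-valid effect pattern for left-hemifield targets."""
    dg = np.zeros(8)
    dg[_IDX["V2L"]] = -PROFOUND  # profound disinhibition of left V2
    dg[_IDX["V3L"]] = +SLIGHT  # slight gain decrease in left V3
    dg[_IDX["V5R"]] = -SLIGHT  # slight gain increase in right V5
    dM = np.zeros((8, 8))
    from .network import BACKWARD_PAIRS

    for s, t in BACKWARD_PAIRS:
        if SOURCE_NAMES[s] == "PCR":
            dM[t, s] = -SLIGHT  # backward modulation from right parietal weakens
        else:
            dM[t, s] = +MODERATE  # everywhere else it strengthens
    return ConditionEffects(delta_gamma=dg, delta_M=dM)


def default_validity_scenario(seed: int = 0, **overrides) -> ScenarioSpec:
    """The study-design scenario: left-hemifield targets, gain + modulation effects.

    Input is delivered to right V2 (contralateral to the target); condition
    effects are confined to extrastriate gain and backward modulation, so
    the generating model is (1, 0, 1) in the factorial space.
    """
    network = build_posner_network()
    network.effects = scenario_effects()
    return ScenarioSpec(network=network, seed=seed, **overrides)


def _truth(spec: ScenarioSpec) -> TruthRecord:
    eff = spec.network.effects
    dg = eff.delta_gamma
    record = TruthRecord(
        effects=eff,
        network=spec.network,
        model=ModelSpec(
            extrastriate_gain=bool(np.any(dg[:6])),
            parietal_gain=bool(np.any(dg[6:])),
            modulation=bool(np.any(eff.delta_M)),
        ),
        seed=spec.seed,
        snr_db=spec.snr_db,
    )
    record.check_model_consistency()
    return record


def _clean_sensors(spec: ScenarioSpec, lead: LeadField) -> dict[str, np.ndarray]:
    weights = ContributionWeights()
    out = {}
    for cond in ("valid", "invalid"):
        activity = integrate_network(
            spec.network, cond, window=spec.window_ms, dt=1.0
        )
        keep = slice(None, None, int(round(1000.0 / spec.sfreq)))
        sensors = project_to_sensors(activity, lead, weights)
        out[cond] = sensors[:, keep]
    return out


def generate_dataset(spec: ScenarioSpec) -> tuple[SensorDataset, TruthRecord]:
    """Integrate the truth network, project to sensors, add noise at snr_db.

    Returns the condition-averaged SensorDataset (standing in for robustly
    averaged grand-average evoked responses) and the ground-truth record.
    Byte-identical under identical specs.
    """
    lead = make_lead_field(spec.n_channels, seed=spec.lead_seed)
    clean = _clean_sensors(spec, lead)
    dataset = SensorDataset(
        data=clean, sfreq=spec.sfreq, window_ms=spec.window_ms, lead_field=lead
    )
    noisy = add_sensor_noise(dataset, spec.snr_db, seed=spec.seed)
    return noisy, _truth(spec)


def generate_raw_trials(
    spec: ScenarioSpec, raw_sfreq: float = 600.0
) -> tuple[dict[str, TrialSet], TruthRecord]:
    """Single-trial sensor data with latency/amplitude jitter and outliers.

    Trials are simulated at ``raw_sfreq`` on a padded window so the
    preprocessing chain (filter, downsample, epoch) has context; per-trial
    noise is scaled such that averaging ``n_trials`` recovers the
    dataset-level snr_db.  A seeded fraction of trials is corrupted with
    large smooth artifacts; their indices are recorded in the truth record.
    """
    rng = np.random.default_rng(spec.seed)
    lead = make_lead_field(spec.n_channels, seed=spec.lead_seed)
    weights = ContributionWeights()
    w = weights.as_vector()
    pad_window = (-250.0, 600.0)
    dt = 1000.0 / raw_sfreq / 2.0
    truth = _truth(spec)

    trial_snr_db = spec.snr_db - 10.0 * np.log10(spec.n_trials)
    out: dict[str, TrialSet] = {}
    for cond in ("valid", "invalid"):
        base = numeric_params(spec.network, cond)
        entries = []
        amp0 = float(base["stim_amp"][0])
        peak0 = float(base["stim_peak"][0])
        amps = amp0 * np.exp(spec.amplitude_jitter_sd * rng.standard_normal(spec.n_trials))
        peaks = peak0 + spec.latency_jitter_sd * rng.standard_normal(spec.n_trials)
        for k in range(spec.n_trials):
            e = {key: (val.copy() if isinstance(val, np.ndarray) else val) for key, val in base.items()}
            e["stim_amp"] = np.array([amps[k]])
            e["stim_peak"] = np.array([peaks[k]])
            entries.append(e)
        num = stack_numeric(entries)
        times, v, ok = integrate_batch(num, window=pad_window, dt=dt, sample_every=2)
        if not ok.all():
            from .network import IntegrationError

            raise IntegrationError("truth network unstable during trial simulation")
        x = np.einsum("bksp,p->bks", v, w)  # (trials, T, sources)
        sensors = np.einsum("cs,bks->bck", lead.gain, x)  # (trials, channels, T)

        signal_power = float(np.mean(sensors**2))
        noise_sd = np.sqrt(signal_power / 10 ** (trial_snr_db / 10)) if signal_power else 0.0
        sensors = sensors + noise_sd * rng.standard_normal(sensors.shape)

        n_out = int(round(spec.outlier_fraction * spec.n_trials))
        idx = sorted(rng.choice(spec.n_trials, size=n_out, replace=False).tolist())
        rms = np.sqrt(np.mean(sensors**2)) or 1.0
        for k in idx:
            # large in-band artifact (movement-like): 20x RMS oscillation at a
            # random frequency inside the analysis band, coherent over channels
            freq = rng.uniform(5.0, 25.0)
            phase = rng.uniform(0, 2 * np.pi)
            artifact = 20.0 * rms * np.sin(2 * np.pi * freq * times / 1000.0 + phase)
            sensors[k] += artifact[None, :]
        truth.outlier_indices[cond] = idx

        onset = int(np.argmin(np.abs(times)))
        out[cond] = TrialSet(
            trials=[sensors[k] for k in range(spec.n_trials)],
            sfreq=raw_sfreq,
            condition=cond,
            onset_index=onset,
        )
    return out, truth
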