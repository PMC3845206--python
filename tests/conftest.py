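import numpy as np
import pytest

from attngain import comparison as cp
from attngain import inversion as inv
from attngain import observation as ob
from attngain import synthetic_data as sd
from attngain.network import BACKWARD_PAIRS, SOURCE_NAMES, ConditionEffects, build_posner_network

EFFECT_LABELS = [f"dg_{l}" for l in SOURCE_NAMES] + [
    f"dM_{SOURCE_NAMES[s]}->{SOURCE_NAMES[t]}" for s, t in BACKWARD_PAIRS
]


def effect_estimates(fit, priors):
    """Posterior means of the condition-effect vector (delta_gamma, delta_M)."""
    return np.array([fit.posterior.mean[priors.index(n)] for n in EFFECT_LABELS])


def fit_scenario(seed, null=False, snr_db=None, opts=None):
    """Generate a default-scenario dataset and invert the full factorial model."""
    spec = sd.default_validity_scenario(seed=seed)
    if null:
        spec.network.effects = ConditionEffects()
    if snr_db is not None:
        spec.snr_db = snr_db
    ds, truth = sd.generate_dataset(spec)
    basis = ob.canonical_modes(ds, ds.lead_field, 8)
    modes = ob.reduce_to_modes(ds, basis)
    net = build_posner_network()
    priors = inv.default_priors(net, cp.ModelSpec(True, True, True))
    fwd = inv.ForwardModel(net, ds.lead_field, basis, priors)
    fit = inv.variational_laplace(modes, fwd, priors, opts)
    return {
        "fit": fit,
        "priors": priors,
        "truth": truth,
        "network": net,
        "dataset": ds,
        "modes": modes,
        "forward": fwd,
    }


@pytest.fixture(scope="session")
def scenario_fits():
    """Full-model inversions of the default validity scenario, seeds 0-4."""
    return [fit_scenario(seed) for seed in range(5)]


@pytest.fixture(scope="session")
def null_fits():
    """Full-model inversions of effect-free data, seeds 0-4."""
    return [fit_scenario(seed, null=True) for seed in range(5)]


@pytest.fixture(scope="session")
def default_dataset():
    spec = sd.default_validity_scenario(seed=0)
    ds, truth = sd.generate_dataset(spec)
    return ds, truth
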