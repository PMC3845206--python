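"""Single-source canonical microcircuit with precision encoded as
superficial-pyramidal self-inhibition.

The microcircuit has four neural-mass populations (spiny stellate,
superficial pyramidal, inhibitory interneuron, deep pyramidal), each with
second-order (alpha-function) convolution kinetics.  The log self-inhibition
``gamma`` of the superficial pyramidal population plays the role of negative
log precision in predictive coding: precision Pi = exp(-gamma), so lowering
self-inhibition raises the gain of the population reporting prediction
error.  Descending (modulatory) afferents shift gamma around its baseline
``gamma0`` in proportion to how far their firing rates sit above baseline.

A didactic single error-unit integrator is also provided; its steady state
realises the precision-weighted prediction error xi = Pi * (mu - prediction).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "PopulationLabel",
    "PopulationState",
    "SigmoidSpec",
    "SourceIntrinsics",
    "ErrorUnit",
    "sigmoid_rate",
    "precision_of",
    "precision_inverse",
    "effective_gamma",
    "population_derivative",
    "population_impulse_response",
    "error_unit_trajectory",
    "MODULATION_COEFFICIENT",
    "default_intrinsic_coupling",
    "default_kappa",
]

#: Default coefficient c in gamma = gamma0 - c * M . (sigma(V) - sigma0).
MODULATION_COEFFICIENT = 1.5


class PopulationLabel(Enum):
    """The four populations of the canonical microcircuit.

    The array order (ss, sp, ii, dp) is used throughout the package.
    Superficial pyramidal cells are the unique population whose
    self-inhibition is parameterised by gamma.
    """

    spiny_stellate = 0
    superficial_pyramidal = 1
    inhibitory_interneuron = 2
    deep_pyramidal = 3


SS = PopulationLabel.spiny_stellate.value
SP = PopulationLabel.superficial_pyramidal.value
II = PopulationLabel.inhibitory_interneuron.value
DP = PopulationLabel.deep_pyramidal.value


@dataclass(frozen=True)
class SigmoidSpec:
    """Logistic firing-rate nonlinearity sigma(v) in [0, 1].

    Parameters
    ----------
    slope : float
        Gain of the logistic, in 1/mV.
    threshold : float
        Depolarization at half-maximal rate, in mV.

    With the default centred sigmoid the baseline rate is
    ``sigma0 = sigma(0) = 0.5``, which makes the all-zero state an exact
    fixed point of the network when couplings act on rate deviations.
    """

    slope: float = 0.56
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope <= 0:
            raise ValueError("sigmoid slope must be finite and positive")
        if not np.isfinite(self.threshold):
            raise ValueError("sigmoid threshold must be finite")

    @property
    def sigma0(self) -> float:
        """Baseline firing rate sigma(0)."""
        return float(sigmoid_rate(0.0, self))


@dataclass
class PopulationState:
    """Second-order state of one population: depolarization and current."""

    v: float = 0.0  # mV
    i: float = 0.0  # mV/ms


def sigmoid_rate(v, spec: SigmoidSpec):
    """Firing rate sigma(v) in [0, 1] as a logistic function of depolarization.

    Strictly increasing in ``v``; saturates at 0 and 1; returns
    ``spec.sigma0`` at v = 0 for a centred sigmoid.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("depolarization must be finite")
    return 1.0 / (1.0 + np.exp(-spec.slope * (v - spec.threshold)))


def precision_of(gamma):
    """Precision Pi = exp(-gamma) of a prediction-error channel.

    gamma is the log strength of recurrent self-inhibition on superficial
    pyramidal cells, i.e. the negative log precision.
    """
    gamma = np.asarray(gamma, dtype=float)
    if not np.all(np.isfinite(gamma)):
        raise ValueError("gamma must be finite")
    return np.exp(-gamma)


def precision_inverse(pi):
    """Inverse of :func:`precision_of`: gamma = -ln(Pi), for Pi > 0."""
    pi = np.asarray(pi, dtype=float)
    if not np.all(np.isfinite(pi)) or np.any(pi <= 0):
        raise ValueError("precision must be finite and positive")
    return -np.log(pi)


def effective_gamma(
    gamma0: float,
    delta_gamma: float,
    condition: str,
    mod_row,
    afferent_rates,
    spec: SigmoidSpec,
    c: float = MODULATION_COEFFICIENT,
):
    """Instantaneous log self-inhibition of a superficial pyramidal population.

    gamma = gamma0 + [condition == invalid] * delta_gamma
            - c * sum_k mod_row[k] * (afferent_rates[k] - sigma0)

    The modulatory term vanishes when all afferents fire at baseline
    (sigma0), so gamma0 is by construction the self-inhibition at baseline
    firing.  Positive modulatory weight with above-baseline afferent firing
    suppresses self-inhibition, i.e. increases gain/precision.
    """
    mod_row = np.asarray(mod_row, dtype=float)
    afferent_rates = np.asarray(afferent_rates, dtype=float)
    if mod_row.shape != afferent_rates.shape:
        raise ValueError(
            f"mod_row {mod_row.shape} and afferent_rates "
            f"{afferent_rates.shape} must have the same shape"
        )
    if condition not in ("valid", "invalid"):
        raise ValueError("condition must be 'valid' or 'invalid'")
    base = gamma0 + (delta_gamma if condition == "invalid" else 0.0)
    return base - c * float(np.dot(mod_row, afferent_rates - spec.sigma0))


def population_derivative(state: PopulationState, presynaptic_input: float, kappa: float):
    """Time derivative of one population's second-order convolution kinetics.

    dv/dt = i
    di/dt = kappa * u - 2 kappa * i - kappa^2 * v

    which is the state-space form of the alpha-kernel kappa*t*exp(-kappa*t)
    convolved with the presynaptic drive u.  Steady state under constant
    drive is v = u / kappa.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if not (np.isfinite(state.v) and np.isfinite(state.i) and np.isfinite(presynaptic_input)):
        raise ValueError("state and input must be finite")
    dv = state.i
    di = kappa * presynaptic_input - 2.0 * kappa * state.i - kappa**2 * state.v
    return dv, di


def population_impulse_response(t, kappa: float):
    """Closed-form impulse response kappa * t * exp(-kappa t) (peak at 1/kappa)."""
    t = np.asarray(t, dtype=float)
    return kappa * t * np.exp(-kappa * t) * (t >= 0)


@dataclass
class ErrorUnit:
    """A single precision-weighted prediction-error unit.

    Integrates  d(xi)/dt = mu - prediction - exp(gamma) * xi,
    whose fixed point is xi = exp(-gamma) * (mu - prediction)
    = Pi * (mu - prediction).
    """

    mu: float = 0.0
    prediction: float = 0.0
    gamma: float = 0.0
    xi: float = 0.0


def error_unit_trajectory(unit: ErrorUnit, duration: float, dt: float) -> np.ndarray:
    """Integrate the error-unit ODE with classical RK4; returns the xi course.

    The returned array has ``round(duration/dt) + 1`` samples including the
    initial state.  Requires ``dt * exp(gamma) < 2`` (explicit-scheme
    stability for the linear decay term).
    """
    rate = np.exp(unit.gamma)
    if dt * rate >= 2.0:
        raise ValueError(
            f"dt={dt} is unstable for gamma={unit.gamma}: need dt*exp(gamma) < 2"
        )
    n = int(round(duration / dt))
    drive = unit.mu - unit.prediction

    def f(x):
        return drive - rate * x

    xi = np.empty(n + 1)
    xi[0] = unit.xi
    x = unit.xi
    for k in range(n):
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        x = x + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        xi[k + 1] = x
    return xi


def default_intrinsic_coupling() -> np.ndarray:
    """Default signed intrinsic coupling table C[target, source], order (ss, sp, ii, dp).

    Excitatory entries are positive, inhibitory negative.  The ascending
    intrinsic chain ss->sp->dp is excitatory; the interneuron pool is driven
    by spiny stellate and deep pyramidal cells and inhibits all three
    excitatory populations; spiny stellate and interneuron populations carry
    fixed self-inhibition.  The sp->sp entry is identically zero here: the
    superficial pyramidal self-inhibition is exclusively exp(gamma) and is
    applied by the integrator from the gain state, never stored in this
    table.
    """
    C = np.zeros((4, 4))
    C[SP, SS] = 4.0
    C[DP, SP] = 1.5
    C[II, SS] = 2.0
    C[II, DP] = 0.75
    C[SS, II] = -2.0
    C[SP, II] = -4.0
    C[DP, II] = -0.4
    C[SS, SS] = -2.0
    C[II, II] = -2.0
    return C


def default_kappa() -> np.ndarray:
    """Per-population rate constants (1/ms): 1/4 for ss, sp, ii; 1/16 for dp."""
    k = np.full(4, 0.25)
    k[DP] = 1.0 / 16.0
    return k


@dataclass
class SourceIntrinsics:
    """Intrinsic parameters of one cortical source.

    Attributes
    ----------
    intrinsic_coupling : (4, 4) array
        Signed population-to-population strengths C[target, source]; the
        (sp, sp) entry must be zero — that self-connection is always derived
        from gamma via exp(gamma).
    kappa : (4,) array
        Per-population rate constants in 1/ms.
    gamma0 : float
        Baseline log self-inhibition of the superficial pyramidal cells
        (negative log precision at baseline firing).
    sigmoid : SigmoidSpec
    """

    intrinsic_coupling: np.ndarray = field(default_factory=default_intrinsic_coupling)
    kappa: np.ndarray = field(default_factory=default_kappa)
    gamma0: float = 0.0
    sigmoid: SigmoidSpec = field(default_factory=SigmoidSpec)

    def __post_init__(self) -> None:
        self.intrinsic_coupling = np.asarray(self.intrinsic_coupling, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.intrinsic_coupling.shape != (4, 4):
            raise ValueError("intrinsic_coupling must be 4x4")
        if self.intrinsic_coupling[SP, SP] != 0.0:
            raise ValueError(
                "the sp->sp entry is derived from gamma and must not be stored"
            )
        if self.kappa.shape != (4,) or np.any(self.kappa <= 0):
            raise ValueError("kappa must be 4 positive rate constants")
        if not np.isfinite(self.gamma0):
            raise ValueError("gamma0 must be finite")
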