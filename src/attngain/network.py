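"""The 8-source Posner visual hierarchy and its coupled dynamics.

Two mirror-symmetric three-level hierarchies (V2 -> {V3, V5} -> PC per
hemisphere) are coupled by extrinsic forward connections (superficial
pyramidal -> spiny stellate, ascending), backward driving connections
(deep pyramidal -> superficial pyramidal and interneurons, descending) and
backward *modulatory* connections (deep pyramidal -> gamma of the target's
superficial pyramidal cells).  Homologous sources are linked by weak
interhemispheric (callosal) driving connections so that a stimulus
delivered to one hemisphere evokes activity in both, as observed
empirically for lateralised visual targets.

Condition (valid/invalid cueing) enters only through ConditionEffects:
an additive shift of the baseline gain parameter gamma0 (delta_gamma), a
log-scaling of the modulatory weights (delta_M) and, optionally, a
log-scaling of the backward driving weights (delta_B).  With all effects
zero the two conditions are computationally identical.

The integrator is a fixed-step classical Runge-Kutta (RK4) scheme over a
batch of parameter sets; batching is what makes finite-difference
Jacobians for model inversion affordable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .microcircuit import (
    DP,
    II,
    MODULATION_COEFFICIENT,
    SP,
    SS,
    SigmoidSpec,
    SourceIntrinsics,
)

__all__ = [
    "SourceNode",
    "SOURCES",
    "SOURCE_NAMES",
    "MIRROR_PERMUTATION",
    "ExtrinsicConnectivity",
    "ConditionEffects",
    "StimulusSpec",
    "NetworkParameters",
    "SourceActivity",
    "IntegrationError",
    "build_posner_network",
    "gaussian_input",
    "integrate_network",
    "resting_state",
    "linear_stability",
    "mirror_network",
]


@dataclass(frozen=True)
class SourceNode:
    """One cortical source: area name, hemisphere and hierarchical level."""

    name: str  # V2, V3, V5 or PC
    hemisphere: str  # L or R

    def __post_init__(self) -> None:
        if self.name not in ("V2", "V3", "V5", "PC"):
            raise ValueError(f"unknown source name {self.name!r}")
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"hemisphere must be L or R, got {self.hemisphere!r}")

    @property
    def level(self) -> int:
        return {"V2": 1, "V3": 2, "V5": 2, "PC": 3}[self.name]

    @property
    def label(self) -> str:
        return f"{self.name}{self.hemisphere}"


#: Canonical source order; L/R interleaved so that hemisphere mirroring is
#: the pairwise index swap MIRROR_PERMUTATION.
SOURCES: tuple[SourceNode, ...] = tuple(
    SourceNode(name, hemi) for name in ("V2", "V3", "V5", "PC") for hemi in ("L", "R")
)
SOURCE_NAMES: tuple[str, ...] = tuple(s.label for s in SOURCES)
MIRROR_PERMUTATION = np.array([1, 0, 3, 2, 5, 4, 7, 6])

_INDEX = {s.label: i for i, s in enumerate(SOURCES)}

# Within-hemisphere ascending edges of the hierarchy (source -> target).
_FORWARD_EDGES = [
    ("V2", "V3"),
    ("V2", "V5"),
    ("V3", "PC"),
    ("V5", "PC"),
]


def _forward_pairs() -> list[tuple[int, int]]:
    """(source_index, target_index) for all forward edges, both hemispheres."""
    pairs = []
    for lo, hi in _FORWARD_EDGES:
        for hemi in ("L", "R"):
            pairs.append((_INDEX[lo + hemi], _INDEX[hi + hemi]))
    return pairs


FORWARD_PAIRS = _forward_pairs()
BACKWARD_PAIRS = [(t, s) for (s, t) in FORWARD_PAIRS]
LATERAL_PAIRS = [(i, int(MIRROR_PERMUTATION[i])) for i in range(8)]


def _edge_matrix(pairs, value):
    A = np.zeros((8, 8))
    for s, t in pairs:
        A[t, s] = value
    return A


def _level_matrix(pairs, low_value, high_value, key):
    """Edge matrix with level-dependent default weights.

    ``key`` selects which endpoint decides "high": for forward edges the
    target (into PC vs into V3/V5), for backward/modulatory edges the
    source (from PC vs from V3/V5), for lateral edges the shared level.
    """
    A = np.zeros((8, 8))
    for s, t in pairs:
        ref = SOURCES[t] if key == "target" else SOURCES[s]
        A[t, s] = high_value if ref.name == "PC" else low_value
    return A


def _lateral_matrix(v2, mid, pc):
    A = np.zeros((8, 8))
    for s, t in LATERAL_PAIRS:
        A[t, s] = {"V2": v2, "V3": mid, "V5": mid, "PC": pc}[SOURCES[s].name]
    return A


@dataclass
class ExtrinsicConnectivity:
    """Extrinsic coupling matrices, all indexed [target, source].

    A_forward : sp of source -> ss of target, ascending one level.
    A_backward : dp of source -> sp (and, scaled, ii) of target, descending.
    M : dp of source -> gamma of sp in target, on the same edges as
        A_backward (every modulatory edge coincides with a backward edge).
    A_lateral : sp of source -> ss of the homologous source in the other
        hemisphere (interhemispheric driving).
    """

    A_forward: np.ndarray = field(
        default_factory=lambda: _level_matrix(FORWARD_PAIRS, 2.4, 3.2, "target")
    )
    A_backward: np.ndarray = field(
        default_factory=lambda: _level_matrix(BACKWARD_PAIRS, 0.12, 0.1, "source")
    )
    M: np.ndarray = field(
        default_factory=lambda: _level_matrix(BACKWARD_PAIRS, 1.8, 2.5, "source")
    )
    A_lateral: np.ndarray = field(default_factory=lambda: _lateral_matrix(3.5, 2.7, 1.7))

    def __post_init__(self) -> None:
        for name in ("A_forward", "A_backward", "M", "A_lateral"):
            A = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, A)
            if A.shape != (8, 8):
                raise ValueError(f"{name} must be 8x8")
            if np.any(A < 0):
                raise ValueError(f"{name} entries must be non-negative")
            if np.any(np.diag(A) != 0):
                raise ValueError(f"{name} must have zero diagonal")
        allowed_f = _edge_matrix(FORWARD_PAIRS, 1.0) > 0
        allowed_b = _edge_matrix(BACKWARD_PAIRS, 1.0) > 0
        allowed_l = _edge_matrix(LATERAL_PAIRS, 1.0) > 0
        if np.any((self.A_forward > 0) & ~allowed_f):
            raise ValueError("forward entries only on level-ascending within-hemisphere edges")
        if np.any((self.A_backward > 0) & ~allowed_b):
            raise ValueError("backward entries only on edges reciprocal to forward ones")
        if np.any((self.M > 0) & ~allowed_b):
            raise ValueError("modulatory entries only on backward edges")
        if np.any((self.A_lateral > 0) & ~allowed_l):
            raise ValueError("lateral entries only between homologous sources")


@dataclass
class ConditionEffects:
    """Differences between the invalid and the (baseline) valid condition.

    delta_gamma : (8,) additive increment to each source's gamma0.
    delta_M : (8, 8) log-scaling of modulatory weights, M_invalid = M * exp(delta_M).
    delta_B : (8, 8) log-scaling of backward driving weights (used by the
        provisional driving-vs-modulatory comparison; zero by default).
    """

    delta_gamma: np.ndarray = field(default_factory=lambda: np.zeros(8))
    delta_M: np.ndarray = field(default_factory=lambda: np.zeros((8, 8)))
    delta_B: np.ndarray = field(default_factory=lambda: np.zeros((8, 8)))

    def __post_init__(self) -> None:
        self.delta_gamma = np.asarray(self.delta_gamma, dtype=float)
        self.delta_M = np.asarray(self.delta_M, dtype=float)
        self.delta_B = np.asarray(self.delta_B, dtype=float)
        if self.delta_gamma.shape != (8,):
            raise ValueError("delta_gamma must have one entry per source")
        for name in ("delta_M", "delta_B"):
            if getattr(self, name).shape != (8, 8):
                raise ValueError(f"{name} must be 8x8")


@dataclass
class StimulusSpec:
    """Exogenous target-related input: a Gaussian bump of drive to one V2.

    Defaults follow the experimental prior: peak at 120 ms post-target with
    a 16 ms standard deviation, delivered to the V2 source contralateral to
    the target hemifield (right V2 for a left-hemifield target).
    """

    peak_time: float = 120.0  # ms
    width: float = 16.0  # ms (standard deviation)
    amplitude: float = 3.0  # a.u.
    target_source: SourceNode = field(default_factory=lambda: SourceNode("V2", "R"))

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("stimulus width must be positive")
        if self.target_source.name != "V2":
            raise ValueError("exogenous input must target a V2 source")

    @property
    def target_index(self) -> int:
        return _INDEX[self.target_source.label]


@dataclass
class NetworkParameters:
    """Complete parameter set of the 8-source network."""

    intrinsics: list[SourceIntrinsics] = field(
        default_factory=lambda: [SourceIntrinsics() for _ in range(8)]
    )
    extrinsic: ExtrinsicConnectivity = field(default_factory=ExtrinsicConnectivity)
    effects: ConditionEffects = field(default_factory=ConditionEffects)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    backward_ii_weight: float = 0.75
    modulation_coefficient: float = MODULATION_COEFFICIENT

    def __post_init__(self) -> None:
        if len(self.intrinsics) != 8:
            raise ValueError("need one SourceIntrinsics per source")

    @property
    def sigmoid(self) -> SigmoidSpec:
        return self.intrinsics[0].sigmoid

    def gamma0_vector(self) -> np.ndarray:
        return np.array([s.gamma0 for s in self.intrinsics])


class IntegrationError(RuntimeError):
    """Raised when the network dynamics diverge; names the first bad source."""


def gaussian_input(t, spec: StimulusSpec):
    """Exogenous drive amplitude * exp(-(t - peak)^2 / (2 width^2))."""
    if spec.width <= 0:
        raise ValueError("stimulus width must be positive")
    t = np.asarray(t, dtype=float)
    z = (t - spec.peak_time) / spec.width
    return spec.amplitude * np.exp(-0.5 * z * z)


def build_posner_network(overrides: dict | None = None) -> NetworkParameters:
    """Assemble the default 8-source Posner hierarchy, with optional overrides.

    Overrides are flat ``key: value`` pairs, e.g.::

        {"stimulus.amplitude": 2.0,
         "gamma0.V2L": 0.3,
         "forward.V2L->V3L": 1.5,
         "modulatory.PCL->V3L": 0.8,
         "effects.delta_gamma.V2L": -0.7}

    Overriding a structurally absent edge (e.g. ``forward.V2L->PCL``) or an
    unknown key raises ``KeyError``.
    """
    params = NetworkParameters()
    if not overrides:
        return params

    matrices = {
        "forward": (params.extrinsic.A_forward, set(FORWARD_PAIRS)),
        "backward": (params.extrinsic.A_backward, set(BACKWARD_PAIRS)),
        "modulatory": (params.extrinsic.M, set(BACKWARD_PAIRS)),
        "lateral": (params.extrinsic.A_lateral, set(LATERAL_PAIRS)),
        "effects.delta_M": (params.effects.delta_M, set(BACKWARD_PAIRS)),
        "effects.delta_B": (params.effects.delta_B, set(BACKWARD_PAIRS)),
    }
    for key, value in overrides.items():
        parts = key.split(".")
        if key.startswith(("effects.delta_M.", "effects.delta_B.")):
            kind, edge = key.rsplit(".", 1), None
            mat_key = ".".join(parts[:2])
            edge = parts[2]
            _set_edge(matrices[mat_key], mat_key, edge, value)
        elif parts[0] in ("forward", "backward", "modulatory", "lateral"):
            if len(parts) != 2:
                raise KeyError(f"malformed edge override {key!r}")
            _set_edge(matrices[parts[0]], parts[0], parts[1], value)
        elif parts[0] == "gamma0":
            idx = _source_index(parts[1], key)
            params.intrinsics[idx] = replace(params.intrinsics[idx], gamma0=float(value))
        elif parts[0] == "effects" and parts[1] == "delta_gamma":
            idx = _source_index(parts[2], key)
            params.effects.delta_gamma[idx] = float(value)
        elif parts[0] == "kappa":
            which = parts[1]
            if which == "dp":
                pops = [DP]
            elif which == "e":
                pops = [SS, SP, II]
            else:
                raise KeyError(f"unknown kappa group {key!r}")
            for i in range(8):
                kap = params.intrinsics[i].kappa.copy()
                kap[pops] = float(value)
                params.intrinsics[i] = replace(params.intrinsics[i], kappa=kap)
        elif parts[0] == "stimulus":
            if parts[1] == "target":
                params.stimulus = replace(
                    params.stimulus,
                    target_source=SourceNode(value[:2], value[2]),
                )
            elif parts[1] in ("peak_time", "width", "amplitude"):
                params.stimulus = replace(params.stimulus, **{parts[1]: float(value)})
            else:
                raise KeyError(f"unknown stimulus key {key!r}")
        elif key == "backward_ii_weight":
            params.backward_ii_weight = float(value)
        elif key == "modulation_coefficient":
            params.modulation_coefficient = float(value)
        else:
            raise KeyError(f"unknown override key {key!r}")
    return params


def _source_index(label: str, key: str) -> int:
    if label not in _INDEX:
        raise KeyError(f"unknown source {label!r} in override {key!r}")
    return _INDEX[label]


def _set_edge(entry, kind, edge, value):
    mat, allowed = entry
    try:
        src, tgt = edge.split("->")
    except ValueError as exc:
        raise KeyError(f"malformed edge {edge!r} for {kind}") from exc
    pair = (_source_index(src, edge), _source_index(tgt, edge))
    if pair not in allowed:
        raise KeyError(f"{kind} edge {edge!r} is structurally absent")
    mat[pair[1], pair[0]] = float(value)


# ---------------------------------------------------------------------------
# Numeric core: batched integration
# ---------------------------------------------------------------------------


def numeric_params(params: NetworkParameters, condition: str) -> dict:
    """Flatten a NetworkParameters + condition into plain arrays (batch of 1)."""
    if condition not in ("valid", "invalid"):
        raise ValueError("condition must be 'valid' or 'invalid'")
    inv = condition == "invalid"
    ext = params.extrinsic
    eff = params.effects
    gamma0 = params.gamma0_vector() + (eff.delta_gamma if inv else 0.0)
    M = ext.M * np.exp(eff.delta_M) if inv else ext.M
    A_b = ext.A_backward * np.exp(eff.delta_B) if inv else ext.A_backward
    return {
        "gamma0": gamma0[None],
        "A_f": ext.A_forward[None],
        "A_b": A_b[None],
        "M": M[None],
        "A_lat": ext.A_lateral[None],
        "C": np.stack([s.intrinsic_coupling for s in params.intrinsics])[None],
        "kappa": np.stack([s.kappa for s in params.intrinsics])[None],
        "stim_peak": np.array([params.stimulus.peak_time]),
        "stim_width": np.array([params.stimulus.width]),
        "stim_amp": np.array([params.stimulus.amplitude]),
        "stim_target": np.array([params.stimulus.target_index]),
        "slope": params.sigmoid.slope,
        "threshold": params.sigmoid.threshold,
        "sigma0": params.sigmoid.sigma0,
        "c_mod": params.modulation_coefficient,
        "bw_ii": params.backward_ii_weight,
    }


def stack_numeric(entries: list[dict]) -> dict:
    """Stack batch-of-1 numeric parameter dicts into one batched dict."""
    out = {}
    for key in entries[0]:
        if isinstance(entries[0][key], np.ndarray):
            out[key] = np.concatenate([e[key] for e in entries], axis=0)
        else:
            vals = {e[key] for e in entries}
            if len(vals) != 1:
                raise ValueError(f"cannot batch differing scalar {key}")
            out[key] = entries[0][key]
    return out


def integrate_batch(
    num: dict,
    window: tuple[float, float] = (-50.0, 400.0),
    dt: float = 1.0,
    sample_every: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate a batch of networks with fixed-step RK4.

    Parameters
    ----------
    num : dict
        Batched numeric parameters (see :func:`numeric_params` /
        :func:`stack_numeric`).
    window : (t0, t1) in ms; dt : step in ms; sample_every : store every
        k-th step.

    Returns
    -------
    times : (T,) sampled times in ms.
    v : (B, T, 8, 4) depolarization traces.
    ok : (B,) finite-trajectory mask (divergent batch entries are flagged,
        not raised, so an optimizer can reject the step).
    """
    t0, t1 = window
    n_steps = int(round((t1 - t0) / dt))
    B = num["gamma0"].shape[0]

    kappa = num["kappa"]
    kap2 = kappa * kappa
    C = num["C"]
    slope, thr, sigma0 = num["slope"], num["threshold"], num["sigma0"]
    c_mod, bw_ii = num["c_mod"], num["bw_ii"]
    A_f, A_b, A_lat, M = num["A_f"], num["A_b"], num["A_lat"], num["M"]
    gamma0 = num["gamma0"]
    peak, width, amp = num["stim_peak"], num["stim_width"], num["stim_amp"]
    target = num["stim_target"].astype(int)
    bidx = np.arange(B)

    v = np.zeros((B, 8, 4))
    cur = np.zeros((B, 8, 4))

    def deriv(v, cur, t):
        r = 1.0 / (1.0 + np.exp(-slope * (v - thr))) - sigma0
        gam = gamma0 - c_mod * np.einsum("bts,bs->bt", M, r[:, :, DP])
        u = np.einsum("bsjp,bsp->bsj", C, r)
        u[:, :, SP] -= np.exp(gam) * r[:, :, SP]
        u[:, :, SS] += np.einsum("bts,bs->bt", A_f, r[:, :, SP])
        u[:, :, SS] += np.einsum("bts,bs->bt", A_lat, r[:, :, SP])
        bwd = np.einsum("bts,bs->bt", A_b, r[:, :, DP])
        u[:, :, SP] += bwd
        u[:, :, II] += bw_ii * bwd
        z = (t - peak) / width
        u[bidx, target, SS] += amp * np.exp(-0.5 * z * z)
        return cur, kappa * u - 2.0 * kappa * cur - kap2 * v

    n_kept = n_steps // sample_every + 1
    out = np.empty((B, n_kept, 8, 4))
    times = t0 + dt * sample_every * np.arange(n_kept)
    out[:, 0] = v
    kept = 1
    with np.errstate(over="ignore", invalid="ignore"):
        for step in range(n_steps):
            t = t0 + step * dt
            dv1, di1 = deriv(v, cur, t)
            dv2, di2 = deriv(v + 0.5 * dt * dv1, cur + 0.5 * dt * di1, t + 0.5 * dt)
            dv3, di3 = deriv(v + 0.5 * dt * dv2, cur + 0.5 * dt * di2, t + 0.5 * dt)
            dv4, di4 = deriv(v + dt * dv3, cur + dt * di3, t + dt)
            v = v + dt * (dv1 + 2 * dv2 + 2 * dv3 + dv4) / 6.0
            cur = cur + dt * (di1 + 2 * di2 + 2 * di3 + di4) / 6.0
            if (step + 1) % sample_every == 0:
                out[:, kept] = v
                kept += 1
    ok = np.isfinite(out).all(axis=(1, 2, 3))
    return times, out, ok


def effective_gamma_trace(num: dict, v: np.ndarray) -> np.ndarray:
    """Instantaneous gamma per (batch, time, source) from stored depolarizations.

    Uses the same modulatory law as the integrator (deep-pyramidal rates of
    the modulating sources through M).
    """
    r_dp = 1.0 / (1.0 + np.exp(-num["slope"] * (v[..., DP] - num["threshold"]))) - num["sigma0"]
    return num["gamma0"][:, None, :] - num["c_mod"] * np.einsum(
        "bts,bks->bkt", num["M"], r_dp
    )


@dataclass
class SourceActivity:
    """Per-source, per-population depolarization traces on a time grid."""

    times: np.ndarray  # ms relative to target onset
    v: np.ndarray  # (T, 8, 4)
    gamma: np.ndarray  # (T, 8) instantaneous sp log self-inhibition
    condition: str

    def trace(self, source: str, population: int) -> np.ndarray:
        return self.v[:, _INDEX[source], population]

    def to_frame(self):
        """Tidy long-format table (time_ms, source, hemisphere, population, v)."""
        import pandas as pd

        pops = ["spiny_stellate", "superficial_pyramidal", "inhibitory_interneuron", "deep_pyramidal"]
        rows = []
        for si, src in enumerate(SOURCES):
            for pi, pop in enumerate(pops):
                rows.append(
                    pd.DataFrame(
                        {
                            "time_ms": self.times,
                            "source": src.name,
                            "hemisphere": src.hemisphere,
                            "population": pop,
                            "v": self.v[:, si, pi],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def integrate_network(
    params: NetworkParameters,
    condition: str,
    window: tuple[float, float] = (-50.0, 400.0),
    dt: float = 1.0,
) -> SourceActivity:
    """Integrate the full network for one condition.

    Deterministic given parameters; raises :class:`IntegrationError` naming
    the first divergent source if the dynamics blow up.
    """
    num = numeric_params(params, condition)
    times, v, ok = integrate_batch(num, window=window, dt=dt)
    if not ok[0]:
        bad = ~np.isfinite(v[0]).all(axis=(0, 2))
        first = SOURCE_NAMES[int(np.argmax(bad))]
        raise IntegrationError(f"dynamics diverged; first non-finite source: {first}")
    gamma = effective_gamma_trace(num, v)[0]
    return SourceActivity(times=times, v=v[0], gamma=gamma, condition=condition)


def _state_derivative(num: dict, v: np.ndarray, cur: np.ndarray, t: float):
    """Derivative of the (8, 4) state for a batch-of-1 numeric parameter set."""
    slope, thr, sigma0 = num["slope"], num["threshold"], num["sigma0"]
    r = 1.0 / (1.0 + np.exp(-slope * (v - thr))) - sigma0
    gam = num["gamma0"] - num["c_mod"] * np.einsum("bts,bs->bt", num["M"], r[:, :, DP])
    u = np.einsum("bsjp,bsp->bsj", num["C"], r)
    u[:, :, SP] -= np.exp(gam) * r[:, :, SP]
    u[:, :, SS] += np.einsum("bts,bs->bt", num["A_f"], r[:, :, SP])
    u[:, :, SS] += np.einsum("bts,bs->bt", num["A_lat"], r[:, :, SP])
    bwd = np.einsum("bts,bs->bt", num["A_b"], r[:, :, DP])
    u[:, :, SP] += bwd
    u[:, :, II] += num["bw_ii"] * bwd
    z = (t - num["stim_peak"]) / num["stim_width"]
    u[np.arange(v.shape[0]), num["stim_target"].astype(int), SS] += num["stim_amp"] * np.exp(
        -0.5 * z * z
    )
    kappa = num["kappa"]
    return cur, kappa * u - 2.0 * kappa * cur - kappa * kappa * v


def resting_state(
    params: NetworkParameters, condition: str = "valid", tol: float = 1e-9
) -> np.ndarray:
    """Fixed point of the autonomous dynamics (stimulus off), shape (2, 8, 4).

    With centred sigmoids the all-zero state is the exact fixed point; for
    perturbed parameterizations a Newton-Krylov style root solve is used.
    Raises RuntimeError if no fixed point is found.
    """
    num = numeric_params(params, condition)
    num = dict(num, stim_amp=np.array([0.0]))

    def fun(x):
        v = x[:32].reshape(1, 8, 4)
        cur = x[32:].reshape(1, 8, 4)
        dv, di = _state_derivative(num, v, cur, -1e6)
        return np.concatenate([dv.ravel(), di.ravel()])

    x0 = np.zeros(64)
    if np.max(np.abs(fun(x0))) < tol:
        return x0.reshape(2, 8, 4)
    sol = optimize.root(fun, x0, method="hybr", tol=1e-12)
    if not sol.success or np.max(np.abs(fun(sol.x))) > tol:
        raise RuntimeError("no resting fixed point found within iteration budget")
    return sol.x.reshape(2, 8, 4)


def linear_stability(params: NetworkParameters, condition: str = "valid") -> np.ndarray:
    """Eigenvalues of the numerical Jacobian at the resting fixed point."""
    num = numeric_params(params, condition)
    num = dict(num, stim_amp=np.array([0.0]))
    rest = resting_state(params, condition).ravel()

    def fun(x):
        v = x[:32].reshape(1, 8, 4)
        cur = x[32:].reshape(1, 8, 4)
        dv, di = _state_derivative(num, v, cur, -1e6)
        return np.concatenate([dv.ravel(), di.ravel()])

    eps = 1e-6
    J = np.empty((64, 64))
    for j in range(64):
        e = np.zeros(64)
        e[j] = eps
        J[:, j] = (fun(rest + e) - fun(rest - e)) / (2 * eps)
    return np.linalg.eigvals(J)


def mirror_network(params: NetworkParameters) -> NetworkParameters:
    """Swap the two hemispheres everywhere (parameters and stimulus target)."""
    p = MIRROR_PERMUTATION
    ext = params.extrinsic
    mirrored_ext = ExtrinsicConnectivity(
        A_forward=ext.A_forward[np.ix_(p, p)],
        A_backward=ext.A_backward[np.ix_(p, p)],
        M=ext.M[np.ix_(p, p)],
        A_lateral=ext.A_lateral[np.ix_(p, p)],
    )
    eff = params.effects
    mirrored_eff = ConditionEffects(
        delta_gamma=eff.delta_gamma[p],
        delta_M=eff.delta_M[np.ix_(p, p)],
        delta_B=eff.delta_B[np.ix_(p, p)],
    )
    tgt = params.stimulus.target_source
    mirrored_stim = replace(
        params.stimulus,
        target_source=SourceNode(tgt.name, "L" if tgt.hemisphere == "R" else "R"),
    )
    return NetworkParameters(
        intrinsics=[params.intrinsics[i] for i in p],
        extrinsic=mirrored_ext,
        effects=mirrored_eff,
        stimulus=mirrored_stim,
        backward_ii_weight=params.backward_ii_weight,
        modulation_coefficient=params.modulation_coefficient,
    )
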