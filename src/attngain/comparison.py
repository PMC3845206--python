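"""Model spaces, Bayesian model reduction and comparison, gain trajectories.

Two model spaces are declared.  The factorial space crosses three binary
factors — condition differences in extrastriate gain (delta_gamma on V2,
V3, V5), in parietal gain (delta_gamma on PC) and in backward modulation
(delta_M) — giving 8 models labelled "e p m" (e.g. "1 0 1").  The
provisional space crosses condition effects on backward *driving*
(delta_B) versus backward *modulatory* (delta_M) connections.

Reduced models are scored analytically by Bayesian model reduction from
the full model's posterior: for Gaussian priors and (locally) Gaussian
posteriors the evidence of a model whose priors only shrink — possibly to
zero variance — follows in closed form, without refitting.  Refitting is
available as an audit path.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import (
    NetworkParameters,
    SOURCE_NAMES,
    effective_gamma_trace,
    integrate_batch,
    numeric_params,
)

__all__ = [
    "ModelSpec",
    "ProvisionalModelSpec",
    "BMCResult",
    "GainTrajectory",
    "ReducedModelEvidence",
    "enumerate_model_space",
    "provisional_space",
    "reduce_evidence",
    "reduced_posterior",
    "posterior_probs",
    "gain_timecourse",
    "run_full_analysis",
]


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the factorial model space."""

    extrastriate_gain: bool
    parietal_gain: bool
    modulation: bool

    @property
    def label(self) -> str:
        return f"{int(self.extrastriate_gain)} {int(self.parietal_gain)} {int(self.modulation)}"

    @property
    def n_factors_on(self) -> int:
        return int(self.extrastriate_gain) + int(self.parietal_gain) + int(self.modulation)


@dataclass(frozen=True)
class ProvisionalModelSpec:
    """Driving-vs-modulatory backward condition effects (gain effects free)."""

    driving: bool
    modulation: bool

    @property
    def label(self) -> str:
        return f"B{int(self.driving)} M{int(self.modulation)}"

    @property
    def n_factors_on(self) -> int:
        return int(self.driving) + int(self.modulation)


def enumerate_model_space() -> list[ModelSpec]:
    """All 2^3 factorial models, in deterministic order null -> full."""
    return [
        ModelSpec(bool(e), bool(p), bool(m))
        for e, p, m in itertools.product((0, 1), repeat=3)
    ]


def provisional_space() -> list[ProvisionalModelSpec]:
    """The 2^2 driving/modulatory space: null, driving-only, modulatory-only, both."""
    return [
        ProvisionalModelSpec(bool(b), bool(m))
        for b, m in itertools.product((0, 1), repeat=2)
    ]


def restrict_priors(full_priors, model):
    """Reduced priors for a model: excluded condition effects get variance 0."""
    from .inversion import PriorSpec

    var = full_priors.variance.copy()
    extrastriate = bool(getattr(model, "extrastriate_gain", True))
    parietal = bool(getattr(model, "parietal_gain", True))
    modulation = bool(getattr(model, "modulation", True))
    driving = bool(getattr(model, "driving", False))
    if hasattr(model, "driving"):
        extrastriate = parietal = True
    for i, name in enumerate(full_priors.names):
        if name.startswith("dg_"):
            lab = name[3:]
            on = parietal if lab.startswith("PC") else extrastriate
            if not on:
                var[i] = 0.0
        elif name.startswith("dM_") and not modulation:
            var[i] = 0.0
        elif name.startswith("dB_") and not driving:
            var[i] = 0.0
    return PriorSpec(list(full_priors.names), full_priors.mean.copy(), var)


@dataclass
class ReducedModelEvidence:
    """Evidence and posterior of a reduced model, from Bayesian model reduction."""

    delta_f: float  # F_reduced - F_full
    free_energy: float  # F_reduced
    mean: np.ndarray  # reduced posterior mean over the FULL parameter vector
    cov: np.ndarray  # over the reduced model's free parameters
    free_names: list[str]


def _canonical_slice(P, mean, idx_B, idx_A, a):
    """Canonical form over theta_B of a Gaussian N(mean, P^-1) sliced at theta_A = a.

    Returns (P_BB, h, c) with density = exp(c + h'x - x'Px/2) including the
    Gaussian's own normalizer.
    """
    n = mean.size
    mu_B = mean[idx_B]
    d_A = a - mean[idx_A]
    P_BB = P[np.ix_(idx_B, idx_B)]
    P_AA = P[np.ix_(idx_A, idx_A)]
    P_BA = P[np.ix_(idx_B, idx_A)]
    h = P_BB @ mu_B - P_BA @ d_A
    c = (
        0.5 * np.linalg.slogdet(P)[1]
        - 0.5 * n * np.log(2 * np.pi)
        - 0.5 * float(d_A @ (P_AA @ d_A))
        + float(d_A @ (P_BA.T @ mu_B))
        - 0.5 * float(mu_B @ (P_BB @ mu_B))
    )
    return P_BB, h, c


def reduced_posterior(full_fit, full_priors, reduced_priors) -> ReducedModelEvidence:
    """Bayesian model reduction: evidence and posterior under shrunken priors.

    The reduced priors may only shrink variances relative to the full
    priors (possibly to exactly zero, which fixes the parameter at its
    prior mean).  For a linear-Gaussian model the result is exact; for the
    nonlinear network it inherits the Laplace approximation of the fit.
    """
    v_full = full_priors.variance
    v_red = reduced_priors.variance
    if list(full_priors.names) != list(reduced_priors.names):
        raise ValueError("full and reduced priors must describe the same parameters")
    if np.any(v_red > v_full + 1e-12):
        raise ValueError("reduced prior variances must not exceed the full ones")
    if not np.allclose(reduced_priors.mean, full_priors.mean):
        raise ValueError("reduced priors may differ only in their variances")

    free_full = np.flatnonzero(full_priors.free)
    # within the full free set, which stay free / become fixed in the reduction
    red_var_f = v_red[free_full]
    local_B = np.flatnonzero(red_var_f > 0)
    local_A = np.flatnonzero(red_var_f == 0)

    S = full_fit.posterior.cov
    m = full_fit.posterior.mean[free_full]
    mu0 = full_priors.mean[free_full]
    Pq = np.linalg.inv(S)
    Pp = np.diag(1.0 / v_full[free_full])
    a = mu0[local_A]

    Pq_BB, h_q, c_q = _canonical_slice(Pq, m, local_B, local_A, a)
    Pp_BB, h_p, c_p = _canonical_slice(Pp, mu0, local_B, local_A, a)

    if local_B.size:
        P_n = np.diag(1.0 / red_var_f[local_B])
        mu_n = mu0[local_B]
        h_n = P_n @ mu_n
        c_n = (
            0.5 * np.linalg.slogdet(P_n)[1]
            - 0.5 * local_B.size * np.log(2 * np.pi)
            - 0.5 * float(mu_n @ h_n)
        )
        P_t = Pq_BB + P_n - Pp_BB
        h_t = h_q + h_n - h_p
        c_t = c_q + c_n - c_p
        S_t = np.linalg.inv(P_t)
        m_B = S_t @ h_t
        delta_f = (
            c_t
            + 0.5 * float(h_t @ m_B)
            - 0.5 * np.linalg.slogdet(P_t)[1]
            + 0.5 * local_B.size * np.log(2 * np.pi)
        )
        mean_full = full_priors.mean.copy()
        mean_full[free_full[local_B]] = m_B
        cov = S_t
        names = [full_priors.names[free_full[i]] for i in local_B]
    else:
        delta_f = c_q - c_p
        mean_full = full_priors.mean.copy()
        cov = np.zeros((0, 0))
        names = []

    return ReducedModelEvidence(
        delta_f=float(delta_f),
        free_energy=full_fit.free_energy + float(delta_f),
        mean=mean_full,
        cov=cov,
        free_names=names,
    )


def reduce_evidence(full_fit, full_priors, reduced_priors) -> float:
    """Free energy of a reduced model from the full fit (no refitting)."""
    return reduced_posterior(full_fit, full_priors, reduced_priors).free_energy


@dataclass
class BMCResult:
    """Free energies and posterior probabilities over a declared model space."""

    labels: list[str]
    free_energy: np.ndarray  # relative to the space's minimum
    probability: np.ndarray
    winner: str

    def as_dict(self) -> dict:
        return {
            "labels": self.labels,
            "relative_free_energy": self.free_energy.tolist(),
            "posterior_probability": self.probability.tolist(),
            "winner": self.winner,
        }


def posterior_probs(free_energies, model_prior=None) -> np.ndarray:
    """Posterior model probabilities: softmax of F (+ log prior), normalized."""
    F = np.asarray(free_energies, float)
    if F.size < 2:
        raise ValueError("need at least two models to compare")
    if not np.all(np.isfinite(F)):
        raise ValueError("free energies must be finite")
    logp = F - F.max()
    if model_prior is not None:
        prior = np.asarray(model_prior, float)
        logp = logp + np.log(prior / prior.sum())
    w = np.exp(logp)
    return w / w.sum()


def compare_models(full_fit, full_priors, models) -> BMCResult:
    """Score every model in a space by reduction from one full fit."""
    Fs = []
    specs = list(models)
    for model in specs:
        reduced = restrict_priors(full_priors, model)
        Fs.append(reduce_evidence(full_fit, full_priors, reduced))
    Fs = np.asarray(Fs)
    probs = posterior_probs(Fs)
    best = Fs.max()
    # break exact ties toward the model with fewer free factors
    order = sorted(
        range(len(specs)),
        key=lambda i: (-(Fs[i]), specs[i].n_factors_on),
    )
    winner = specs[order[0]].label
    return BMCResult(
        labels=[m.label for m in specs],
        free_energy=Fs - Fs.min(),
        probability=probs,
        winner=winner,
    )


@dataclass
class GainTrajectory:
    """Time-resolved log gain (= -gamma = log precision) per source and condition."""

    times: np.ndarray
    log_gain: dict[str, np.ndarray]  # condition -> (T, 8)

    def source(self, condition: str, label: str) -> np.ndarray:
        return self.log_gain[condition][:, SOURCE_NAMES.index(label)]


def gain_timecourse(
    network: NetworkParameters,
    conditions=("valid", "invalid"),
    window: tuple[float, float] = (-50.0, 400.0),
    dt: float = 1.0,
) -> GainTrajectory:
    """Integrate the network and return -gamma(t) per source and condition.

    The instantaneous gamma is evaluated from the same deep-pyramidal
    afferent depolarizations the integrator uses, so with M = 0 the
    trajectories are flat at -(gamma0 + [invalid] * delta_gamma).
    """
    out = {}
    times = None
    for cond in conditions:
        num = numeric_params(network, cond)
        times, v, ok = integrate_batch(num, window=window, dt=dt)
        if not ok[0]:
            from .network import IntegrationError

            raise IntegrationError(f"integration unstable in condition {cond!r}")
        out[cond] = -effective_gamma_trace(num, v)[0]
    return GainTrajectory(times=times, log_gain=out)


def run_full_analysis(dataset, config: dict | None = None, out_dir=None) -> dict:
    """Full pipeline: modes -> full inversions -> both BMCs -> gain trajectories.

    ``dataset`` is a SensorDataset with 'valid' and 'invalid' conditions and
    an attached lead field.  Returns a report dict; if ``out_dir`` is given,
    JSON tables and figures are written there.  Any stage failure raises
    with the stage name in the message.
    """
    from . import inversion, observation
    from .network import build_posner_network

    config = dict(config or {})
    stage = "setup"
    report: dict = {"config": {k: v for k, v in config.items()}}
    try:
        stage = "canonical_modes"
        lead = dataset.lead_field
        if lead is None:
            raise ValueError("dataset has no lead field attached")
        n_modes = int(config.get("n_modes", 8))
        basis = observation.canonical_modes(dataset, lead, n=n_modes)
        modes = observation.reduce_to_modes(dataset, basis)

        stage = "full_model_inversion"
        base = build_posner_network(config.get("network_overrides"))
        opts = inversion.VLOptions(**config.get("vl_options", {}))
        full_spec = ModelSpec(True, True, True)
        priors = inversion.default_priors(base, full_spec)
        fwd = inversion.ForwardModel(base, lead, basis, priors)
        fit = inversion.variational_laplace(modes, fwd, priors, opts)
        report["full_fit"] = {
            "free_energy": fit.free_energy,
            "converged": fit.converged,
            "n_iter": fit.n_iter,
            "trace": fit.trace,
        }

        stage = "factorial_bmc"
        factorial = compare_models(fit, priors, enumerate_model_space())
        report["factorial_bmc"] = factorial.as_dict()

        stage = "provisional_bmc"
        prov_full = ProvisionalModelSpec(True, True)
        prov_priors = inversion.default_priors(base, prov_full)
        prov_fwd = inversion.ForwardModel(base, lead, basis, prov_priors)
        prov_fit = inversion.variational_laplace(modes, prov_fwd, prov_priors, opts)
        provisional = compare_models(prov_fit, prov_priors, provisional_space())
        report["provisional_bmc"] = provisional.as_dict()

        stage = "winning_model_parameters"
        winner_spec = next(
            m for m in enumerate_model_space() if m.label == factorial.winner
        )
        red = reduced_posterior(fit, priors, restrict_priors(priors, winner_spec))
        effects = {
            name: float(red.mean[priors.index(name)])
            for name in priors.names
            if name.startswith(("dg_", "dM_"))
        }
        report["winning_model"] = {"label": factorial.winner, "effects": effects}

        stage = "gain_trajectories"
        win_net = inversion.theta_to_network(red.mean, priors, base)
        traj = gain_timecourse(win_net)
        report["gain_trajectories"] = {
            "times_ms": traj.times.tolist(),
            "sources": list(SOURCE_NAMES),
            **{c: traj.log_gain[c].tolist() for c in traj.log_gain},
        }
    except Exception as exc:
        raise RuntimeError(f"analysis stage {stage!r} failed: {exc}") from exc

    report["fits"] = {"full": fit, "provisional_full": prov_fit}
    if out_dir is not None:
        _write_report(report, Path(out_dir), traj)
    return report


def _write_report(report: dict, out_dir: Path, traj: GainTrajectory) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    serializable = {k: v for k, v in report.items() if k != "fits"}
    (out_dir / "report.json").write_text(json.dumps(serializable, indent=2))
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        bmc = report["factorial_bmc"]
        axes[0].bar(bmc["labels"], bmc["relative_free_energy"])
        axes[0].set_ylabel("relative log evidence (nats)")
        axes[0].set_title("Factorial model space")
        axes[1].bar(bmc["labels"], bmc["posterior_probability"])
        axes[1].set_ylabel("posterior probability")
        for ax in axes:
            ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(out_dir / "model_comparison.svg")
        plt.close(fig)

        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, cond in zip(axes, ("valid", "invalid")):
            for lab in ("V2L", "V2R"):
                ax.plot(traj.times, traj.source(cond, lab), label=lab)
            ax.axvline(0, color="k", lw=0.5)
            ax.set_title(f"{cond} trials")
            ax.set_xlabel("peristimulus time (ms)")
            ax.legend()
        axes[0].set_ylabel("log gain (-gamma)")
        fig.tight_layout()
        fig.savefig(out_dir / "gain_trajectories.svg")
        plt.close(fig)
    except Exception:
        pass
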