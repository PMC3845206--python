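"""Container formats: HDF5 datasets, CSV lead fields, YAML configs, fit JSON.

Layout of the HDF5 container::

    /conditions/<name>/data      channels x time (or trials x channels x time)
    /lead_field                  channels x sources (optional)
    attrs: sfreq, window_ms, channel_names, source_names
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .network import SOURCE_NAMES
from .observation import LeadField, SensorDataset
from .preprocessing import TrialSet

__all__ = [
    "save_sensor_dataset",
    "load_sensor_dataset",
    "save_trial_sets",
    "load_trial_sets",
    "lead_field_to_csv",
    "lead_field_from_csv",
    "save_config",
    "load_config",
    "fit_to_json",
]


def save_sensor_dataset(path, dataset: SensorDataset) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sfreq"] = dataset.sfreq
        f.attrs["window_ms"] = list(dataset.window_ms)
        g = f.create_group("conditions")
        for cond, d in dataset.data.items():
            g.create_group(cond).create_dataset("data", data=d)
        if dataset.lead_field is not None:
            lf = f.create_dataset("lead_field", data=dataset.lead_field.gain)
            lf.attrs["channel_names"] = [str(c) for c in dataset.lead_field.channel_names]
            lf.attrs["source_names"] = list(dataset.lead_field.source_names)


def load_sensor_dataset(path) -> SensorDataset:
    with h5py.File(path, "r") as f:
        data = {cond: f["conditions"][cond]["data"][()] for cond in f["conditions"]}
        lead = None
        if "lead_field" in f:
            lf = f["lead_field"]
            lead = LeadField(
                gain=lf[()],
                channel_names=[str(c) for c in lf.attrs["channel_names"]],
                source_names=tuple(str(s) for s in lf.attrs["source_names"]),
            )
        return SensorDataset(
            data=data,
            sfreq=float(f.attrs["sfreq"]),
            window_ms=tuple(f.attrs["window_ms"]),
            lead_field=lead,
        )


def save_trial_sets(path, trial_sets: dict[str, TrialSet]) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("conditions")
        for cond, ts in trial_sets.items():
            gc = g.create_group(cond)
            gc.create_dataset("data", data=np.stack(ts.trials))
            gc.attrs["sfreq"] = ts.sfreq
            gc.attrs["onset_index"] = ts.onset_index


def load_trial_sets(path) -> dict[str, TrialSet]:
    out = {}
    with h5py.File(path, "r") as f:
        for cond in f["conditions"]:
            gc = f["conditions"][cond]
            stacked = gc["data"][()]
            out[cond] = TrialSet(
                trials=[stacked[i] for i in range(stacked.shape[0])],
                sfreq=float(gc.attrs["sfreq"]),
                condition=cond,
                onset_index=int(gc.attrs["onset_index"]),
            )
    return out


def lead_field_to_csv(path, lead: LeadField) -> None:
    pd.DataFrame(lead.gain, index=lead.channel_names, columns=list(lead.source_names)).to_csv(
        path, index_label="channel"
    )


def lead_field_from_csv(path) -> LeadField:
    df = pd.read_csv(path, index_col="channel")
    return LeadField(
        gain=df.to_numpy(float),
        channel_names=[str(c) for c in df.index],
        source_names=tuple(df.columns),
    )


_POPULATIONS = ("spiny_stellate", "superficial_pyramidal", "inhibitory_interneuron", "deep_pyramidal")


def network_to_config(params) -> dict:
    """Flatten NetworkParameters to a key/value config.

    Keys are namespaced ``source.population.parameter`` for intrinsic
    quantities and ``<kind>.<src>-><tgt>`` for extrinsic edges; suitable
    for YAML/JSON serialization via :func:`save_config`.
    """
    cfg: dict[str, float] = {}
    for si, lab in enumerate(SOURCE_NAMES):
        intr = params.intrinsics[si]
        cfg[f"{lab}.superficial_pyramidal.gamma0"] = float(intr.gamma0)
        for pi, pop in enumerate(_POPULATIONS):
            cfg[f"{lab}.{pop}.kappa"] = float(intr.kappa[pi])
            for pj, pop_from in enumerate(_POPULATIONS):
                c = float(intr.intrinsic_coupling[pi, pj])
                if c != 0.0:
                    cfg[f"{lab}.{pop}.coupling_from.{pop_from}"] = c
    ext = params.effects
    for kind, mat in (
        ("forward", params.extrinsic.A_forward),
        ("backward", params.extrinsic.A_backward),
        ("modulatory", params.extrinsic.M),
        ("lateral", params.extrinsic.A_lateral),
        ("effects.delta_M", ext.delta_M),
        ("effects.delta_B", ext.delta_B),
    ):
        for t, s in zip(*np.nonzero(mat)):
            cfg[f"{kind}.{SOURCE_NAMES[s]}->{SOURCE_NAMES[t]}"] = float(mat[t, s])
    for si, lab in enumerate(SOURCE_NAMES):
        if ext.delta_gamma[si] != 0.0:
            cfg[f"effects.delta_gamma.{lab}"] = float(ext.delta_gamma[si])
    cfg["stimulus.peak_time"] = float(params.stimulus.peak_time)
    cfg["stimulus.width"] = float(params.stimulus.width)
    cfg["stimulus.amplitude"] = float(params.stimulus.amplitude)
    cfg["stimulus.target"] = params.stimulus.target_source.label
    cfg["backward_ii_weight"] = float(params.backward_ii_weight)
    cfg["modulation_coefficient"] = float(params.modulation_coefficient)
    return cfg


def save_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def fit_to_json(path, fit) -> None:
    """Serialize a FitResult (posterior, noise hyperposterior, F, trace)."""
    payload = {
        "free_energy": fit.free_energy,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "trace": list(fit.trace),
        "log_precision": fit.log_precision,
        "log_precision_var": fit.log_precision_var,
        "parameter_names": list(fit.priors.names),
        "posterior_mean": fit.posterior.mean.tolist(),
        "free_names": list(fit.posterior.free_names),
        "posterior_cov": fit.posterior.cov.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
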