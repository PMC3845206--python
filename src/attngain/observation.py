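"""Forward observation model: sources -> sensors -> canonical modes.

Source depolarizations are mapped to MEG-style sensors through a lead
field, with the three excitatory populations contributing in fixed
proportion (superficial pyramidal cells dominating).  For fitting, sensor
data are compressed to a small number of canonical modes: the principal
components of the data restricted to the column space of the lead field.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .microcircuit import DP, SP, SS
from .network import SOURCE_NAMES, SourceActivity

__all__ = [
    "LeadField",
    "ContributionWeights",
    "SensorDataset",
    "ModeBasis",
    "make_lead_field",
    "project_to_sensors",
    "canonical_modes",
    "reduce_to_modes",
    "expand_from_modes",
    "add_sensor_noise",
]


@dataclass
class LeadField:
    """Linear gain from source depolarization (mV) to sensors (a.u.)."""

    gain: np.ndarray  # (channels, sources)
    channel_names: list[str]
    source_names: tuple[str, ...] = SOURCE_NAMES

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field must be finite")
        if np.any(np.all(self.gain == 0, axis=0)):
            raise ValueError("lead field has an all-zero source column")
        if self.gain.shape[1] != len(self.source_names):
            raise ValueError("lead field columns must match the source list")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]


@dataclass(frozen=True)
class ContributionWeights:
    """Relative sensor contribution of the excitatory populations.

    Superficial pyramidal cells must dominate; inhibitory interneurons
    contribute nothing to the measured field.
    """

    spiny_stellate: float = 0.2
    superficial_pyramidal: float = 1.0
    deep_pyramidal: float = 0.5

    def __post_init__(self) -> None:
        if not (
            self.superficial_pyramidal > self.spiny_stellate
            and self.superficial_pyramidal > self.deep_pyramidal
        ):
            raise ValueError("superficial pyramidal weight must be strictly greatest")

    def as_vector(self) -> np.ndarray:
        w = np.zeros(4)
        w[SS] = self.spiny_stellate
        w[SP] = self.superficial_pyramidal
        w[DP] = self.deep_pyramidal
        return w


@dataclass
class SensorDataset:
    """Condition-labelled channels x time evoked responses."""

    data: dict[str, np.ndarray]  # condition -> (channels, time)
    sfreq: float  # Hz
    window_ms: tuple[float, float]
    lead_field: LeadField | None = None

    def __post_init__(self) -> None:
        shapes = {cond: d.shape for cond, d in self.data.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"conditions must share a time axis, got {shapes}")

    @property
    def conditions(self) -> list[str]:
        return list(self.data)

    @property
    def times(self) -> np.ndarray:
        n = next(iter(self.data.values())).shape[1]
        return self.window_ms[0] + 1000.0 / self.sfreq * np.arange(n)

    def concatenated(self) -> np.ndarray:
        """Channels x (time * conditions) matrix, conditions in listed order."""
        return np.concatenate([self.data[c] for c in self.conditions], axis=1)


@dataclass
class ModeBasis:
    """Orthonormal sensor-space basis of canonical modes."""

    vectors: np.ndarray  # (channels, n_modes)
    variance_accounted: np.ndarray  # fraction of projected-data variance per mode

    def __post_init__(self) -> None:
        G = self.vectors.T @ self.vectors
        if not np.allclose(G, np.eye(self.vectors.shape[1]), atol=1e-8):
            raise ValueError("mode vectors must be orthonormal")

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[1]


def make_lead_field(
    n_channels: int = 64,
    between_source_correlation: float = 0.3,
    seed: int = 1234,
) -> LeadField:
    """Synthetic lead field: smooth random topographies, one per source.

    Channels are laid out on a ring; each source's topography is a smooth
    random field (Gaussian-kernel-smoothed white noise) with unit norm.
    A configurable correlation mixes a shared topography into every source
    to emulate MEG field spread.  Deterministic under ``seed``.
    """
    if not 0 <= between_source_correlation < 1:
        raise ValueError("between_source_correlation must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_sources = len(SOURCE_NAMES)
    # smooth white noise on a ring of channels with a circulant Gaussian kernel
    pos = np.arange(n_channels)
    dist = np.minimum(np.abs(pos[:, None] - pos[None, :]), n_channels - np.abs(pos[:, None] - pos[None, :]))
    kernel = np.exp(-0.5 * (dist / (n_channels / 12)) ** 2)
    raw = kernel @ rng.standard_normal((n_channels, n_sources + 1))
    raw /= np.linalg.norm(raw, axis=0, keepdims=True)
    shared = raw[:, -1]
    rho = between_source_correlation
    cols = np.sqrt(1 - rho**2) * raw[:, :n_sources] + rho * shared[:, None]
    cols /= np.linalg.norm(cols, axis=0, keepdims=True)
    names = [f"MEG{i:03d}" for i in range(n_channels)]
    return LeadField(gain=cols, channel_names=names)


def project_to_sensors(
    activity: SourceActivity,
    lead: LeadField,
    weights: ContributionWeights | None = None,
) -> np.ndarray:
    """Sensor traces (channels x time) for one condition's source activity.

    Each source contributes the weighted sum of its excitatory population
    depolarizations through its lead-field column; the map is linear in the
    activity.
    """
    if tuple(lead.source_names) != SOURCE_NAMES:
        raise ValueError("lead field source order does not match the network")
    weights = weights or ContributionWeights()
    w = weights.as_vector()
    x = activity.v @ w  # (T, sources)
    return lead.gain @ x.T


def canonical_modes(data: SensorDataset, lead: LeadField, n: int = 8) -> ModeBasis:
    """Top-n principal components of the data restricted to the lead field's range.

    The condition-concatenated data matrix is projected onto the column
    space of the lead field; the modes are the leading left singular
    vectors of that projection, ordered by decreasing variance.
    """
    if n > lead.n_channels:
        raise ValueError("cannot extract more modes than channels")
    rank = np.linalg.matrix_rank(lead.gain)
    if rank < n:
        raise ValueError(f"lead field rank {rank} < requested modes {n}")
    Q, _ = np.linalg.qr(lead.gain)
    projected = Q @ (Q.T @ data.concatenated())
    U, s, _ = np.linalg.svd(projected, full_matrices=False)
    var = s**2
    return ModeBasis(vectors=U[:, :n], variance_accounted=var[:n] / var.sum())


def reduce_to_modes(data: SensorDataset, basis: ModeBasis) -> dict[str, np.ndarray]:
    """Project each condition's channels x time matrix into mode space."""
    out = {}
    for cond, d in data.data.items():
        if d.shape[0] != basis.vectors.shape[0]:
            raise ValueError("channel dimension does not match the mode basis")
        out[cond] = basis.vectors.T @ d
    return out


def expand_from_modes(modes: dict[str, np.ndarray], basis: ModeBasis) -> dict[str, np.ndarray]:
    """Lift mode-space traces back to sensor space (basis @ modes)."""
    return {cond: basis.vectors @ m for cond, m in modes.items()}


def add_sensor_noise(data: SensorDataset, snr_db: float, seed: int) -> SensorDataset:
    """Add white Gaussian sensor noise at a prescribed dataset-level SNR.

    The noise variance is set from the mean signal power over all channels,
    samples and conditions so that 10*log10(signal power / noise power)
    equals ``snr_db``.  Reproducible under ``seed``.
    """
    if not np.isfinite(snr_db):
        if snr_db == np.inf:
            return SensorDataset(
                data={c: d.copy() for c, d in data.data.items()},
                sfreq=data.sfreq,
                window_ms=data.window_ms,
                lead_field=data.lead_field,
            )
        raise ValueError("snr_db must be finite or +inf")
    signal_power = float(np.mean([np.mean(d**2) for d in data.data.values()]))
    if signal_power == 0:
        raise ValueError("cannot scale noise against an all-zero signal")
    noise_sd = np.sqrt(signal_power / 10 ** (snr_db / 10))
    rng = np.random.default_rng(seed)
    noisy = {c: d + noise_sd * rng.standard_normal(d.shape) for c, d in data.data.items()}
    return SensorDataset(
        data=noisy, sfreq=data.sfreq, window_ms=data.window_ms, lead_field=data.lead_field
    )
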