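"""Forward simulator of epicortical potentials.

Patient ECoG cannot be shared, so the analyses here are exercised on a
synthetic forward model that reproduces the mechanisms thought to shape
inter-electrode similarity:

* shared narrow-band oscillations modelled as planar traveling waves,
  with phase lags set by a cortical conduction speed (2-6 m/s for short
  cortico-cortical connections);
* broadband 1/f^a activity with a finite spatial correlation length;
* passive volume conduction, modelled as an exponential distance decay
  ``exp(-d / lambda)`` from each source to each recording point;
* spatial averaging over the exposed electrode disc (larger contacts see
  the average of a larger neural population);
* independent per-electrode sensor noise.

The model is deliberately phenomenological: a single decay constant, a
flat cortex, no laminar structure.  It is sufficient to generate the
qualitative regimes the ndRMS analysis distinguishes (phase-lagged
oscillations, spatially decaying correlation, the white-noise floor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import ElectrodeLayout
from .preprocess import Recording

__all__ = [
    "Oscillation",
    "Broadband",
    "TaskModulation",
    "SimConfig",
    "SourceField",
    "default_config",
    "fine_grained_config",
    "conduction_weight",
    "source_grid",
    "simulate_source_field",
    "disc_subpoints",
    "sample_electrodes",
    "generate_dataset",
]


@dataclass(frozen=True)
class Oscillation:
    """A planar traveling wave: phase at position p (mm) is
    ``2*pi*f*(p . direction)/speed`` with speed in m/s."""

    freq_hz: float
    amplitude: float  # uV at the source
    propagation_speed_m_per_s: float = 2.5
    origin_mm: tuple[float, float] = (0.0, 0.0)
    direction_deg: float = 0.0


@dataclass(frozen=True)
class Broadband:
    """1/f^exponent broadband activity with spatial correlation.

    A config may carry several components with different correlation
    lengths (e.g. a mesoscale shared field plus fine sub-electrode
    structure); their series add.
    """

    amplitude: float = 0.0  # uV (per-source sd)
    power_law_exponent: float = 2.0
    spatial_correlation_length_mm: float = 2.0


@dataclass(frozen=True)
class TaskModulation:
    """Extra oscillation gated on during active trial windows, with a
    Gaussian spatial footprint (task-responsive patch)."""

    freq_hz: float = 80.0
    amplitude: float = 0.0
    center_mm: tuple[float, float] = (0.0, 0.0)
    radius_mm: float = 3.0


@dataclass(frozen=True)
class SimConfig:
    fs_hz: float = 2000.0
    duration_s: float = 10.0
    oscillations: tuple[Oscillation, ...] = ()
    broadband: Broadband | tuple[Broadband, ...] = field(default_factory=Broadband)
    conduction_lambda_mm: float = 1.0
    sensor_noise_sd: float = 1.0  # uV
    source_spacing_mm: float | None = None  # default: the layout pitch
    margin_mm: float | None = None  # default: 2 x source spacing
    n_subpoints: int = 16
    task: TaskModulation | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.broadband, Broadband):
            object.__setattr__(self, "broadband", (self.broadband,))
        else:
            object.__setattr__(self, "broadband", tuple(self.broadband))
        if self.fs_hz <= 0 or self.duration_s <= 0:
            raise ValueError("fs_hz and duration_s must be positive")
        fmax = max((o.freq_hz for o in self.oscillations), default=0.0)
        if self.task is not None:
            fmax = max(fmax, self.task.freq_hz)
        if self.fs_hz <= 2 * fmax:
            raise ValueError("fs_hz must exceed twice the highest oscillation frequency")
        if any(o.amplitude < 0 for o in self.oscillations) or any(
            b.amplitude < 0 for b in self.broadband
        ):
            raise ValueError("amplitudes must be non-negative")
        if self.conduction_lambda_mm <= 0:
            raise ValueError("conduction_lambda_mm must be positive")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["oscillations"] = tuple(
            Oscillation(**{**o, "origin_mm": tuple(o.get("origin_mm", (0.0, 0.0)))})
            for o in d.get("oscillations", ())
        )
        bb = d.get("broadband")
        if isinstance(bb, dict):
            d["broadband"] = Broadband(**bb)
        elif isinstance(bb, (list, tuple)):
            d["broadband"] = tuple(
                Broadband(**b) if isinstance(b, dict) else b for b in bb
            )
        if isinstance(d.get("task"), dict):
            t = d["task"]
            d["task"] = TaskModulation(**{**t, "center_mm": tuple(t.get("center_mm", (0.0, 0.0)))})
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_config(seed: int = 0, duration_s: float = 10.0) -> SimConfig:
    """Reference simulation: resting sensorimotor cortex.

    A theta, an alpha/mu and a beta traveling wave (speeds in the 2-3 m/s
    range of short cortico-cortical connections, distinct propagation
    directions), 1/f^2 broadband activity with a 2 mm correlation length,
    a 1 mm volume-conduction decay and moderate sensor noise.  Amplitudes
    follow the power-law fall-off of spectral amplitude with frequency.
    """
    return SimConfig(
        fs_hz=2000.0,
        duration_s=duration_s,
        oscillations=(
            Oscillation(5.0, 25.0, 2.0, (0.0, 0.0), 20.0),
            Oscillation(10.0, 15.0, 2.5, (5.0, 3.0), 135.0),
            Oscillation(22.0, 8.0, 3.0, (-4.0, 8.0), 260.0),
        ),
        broadband=Broadband(amplitude=10.0, power_law_exponent=2.0,
                            spatial_correlation_length_mm=2.0),
        conduction_lambda_mm=1.0,
        sensor_noise_sd=3.0,
        seed=seed,
    )


def fine_grained_config(seed: int = 0, duration_s: float = 2.0) -> SimConfig:
    """Configuration resolving sub-electrode spatial scale.

    Probing the effect of the exposed contact diameter requires a source
    field with structure finer than the disc radius.  The field has two
    broadband components — a mesoscale one (4 mm correlation length,
    shared between neighbouring electrodes) and a stronger fine-grained
    one (0.2 mm, uncorrelated across contacts) — on a 0.25 mm source
    lattice with a 0.3 mm volume-conduction decay and low sensor noise.  Disc
    averaging attenuates the fine (non-shared) component on large
    contacts, so larger electrodes yield lower ndRMS at matched IED.
    """
    return SimConfig(
        duration_s=duration_s,
        broadband=(
            Broadband(amplitude=10.0, power_law_exponent=2.0,
                      spatial_correlation_length_mm=4.0),
            Broadband(amplitude=25.0, power_law_exponent=2.0,
                      spatial_correlation_length_mm=0.2),
        ),
        conduction_lambda_mm=0.3,
        sensor_noise_sd=0.5,
        source_spacing_mm=0.25,
        margin_mm=1.0,
        n_subpoints=16,
        seed=seed,
    )


@dataclass
class SourceField:
    """Neural sources: positions (mm) and one time series per source."""

    positions: np.ndarray  # (m, 2)
    series: np.ndarray  # (m, n_samples), uV
    fs_hz: float

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.series):
            raise ValueError("one series per source required")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("source series must be finite")


def conduction_weight(distance_mm: float, lambda_mm: float) -> float:
    """Volume-conduction kernel ``exp(-d/lambda)``; 1 at the source,
    strictly decreasing with distance."""
    if lambda_mm <= 0:
        raise ValueError("lambda_mm must be positive")
    d = np.asarray(distance_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = np.exp(-d / lambda_mm)
    return float(out) if np.isscalar(distance_mm) else out


def source_grid(
    layout: ElectrodeLayout, spacing_mm: float, margin_mm: float
) -> tuple[np.ndarray, tuple[int, int]]:
    """Regular source lattice covering the layout bounding box plus margin.

    Returns the (m, 2) positions and the (nx, ny) lattice shape.  The
    spacing sets the finest spatial structure the field can contain: to
    probe electrode-size effects it must be smaller than the exposed disc
    radius.
    """
    lo = layout.positions.min(axis=0) - margin_mm
    hi = layout.positions.max(axis=0) + margin_mm
    xs = np.arange(lo[0], hi[0] + spacing_mm / 2, spacing_mm)
    ys = np.arange(lo[1], hi[1] + spacing_mm / 2, spacing_mm)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()]), (len(xs), len(ys))


def _seed_children(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Documented randomness split: child 0 drives broadband sources,
    child 1 drives sensor noise."""
    ss = np.random.SeedSequence(seed)
    c_broadband, c_noise = ss.spawn(2)
    return np.random.default_rng(c_broadband), np.random.default_rng(c_noise)


def _shape_spectrum(white: np.ndarray, fs: float, exponent: float) -> np.ndarray:
    """Impose a 1/f^exponent power spectrum (amplitude 1/f^(exponent/2)),
    then rescale each row to unit sd."""
    n = white.shape[-1]
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def simulate_source_field(
    config: SimConfig,
    layout: ElectrodeLayout,
    task_gate: np.ndarray | None = None,
    source_positions: np.ndarray | None = None,
) -> SourceField:
    """Generate the source field for a layout.

    Sources sit on a regular lattice covering the grid (spacing defaults
    to the layout pitch).  Each source carries the sum of the configured
    traveling waves evaluated at its position, plus spatially correlated
    1/f^a broadband noise.  ``task_gate`` (0/1 per sample) switches the
    task oscillation on during active windows.  Deterministic given the
    config seed.
    """
    spacing = config.source_spacing_mm or layout.pitch_mm
    margin = config.margin_mm if config.margin_mm is not None else 2 * spacing
    grid_shape: tuple[int, int] | None = None
    if source_positions is not None:
        pos = np.asarray(source_positions, dtype=float)
    else:
        pos, grid_shape = source_grid(layout, spacing, margin)
    m = len(pos)
    n = int(round(config.duration_s * config.fs_hz))
    t = np.arange(n) / config.fs_hz
    series = np.zeros((m, n))

    for osc in config.oscillations:
        series += _traveling_wave(osc, pos, t)

    if config.task is not None and config.task.amplitude > 0:
        if task_gate is None:
            task_gate = np.ones(n)
        d2 = ((pos - np.asarray(config.task.center_mm)) ** 2).sum(axis=1)
        w = np.exp(-d2 / (2.0 * config.task.radius_mm**2))
        carrier = np.sin(2 * np.pi * config.task.freq_hz * t) * task_gate
        series += config.task.amplitude * w[:, None] * carrier[None, :]

    rng_bb, _ = _seed_children(config.seed)
    for bb in config.broadband:
        if bb.amplitude <= 0:
            continue
        ell = bb.spatial_correlation_length_mm
        if ell > 0:
            shaped = _planewave_broadband(rng_bb, pos, n, config.fs_hz, ell,
                                          bb.power_law_exponent)
        else:
            # zero correlation length: independent noise per source
            shaped = _shape_spectrum(rng_bb.standard_normal((m, n)),
                                     config.fs_hz, bb.power_law_exponent)
        series += bb.amplitude * shaped

    return SourceField(positions=pos, series=series, fs_hz=config.fs_hz)


#: spatial modes per broadband component; finite-mode error on pair
#: correlations scales as 1/sqrt(K)
_N_SPATIAL_MODES = 256


def _planewave_broadband(
    rng: np.random.Generator,
    pos: np.ndarray,
    n: int,
    fs: float,
    ell: float,
    exponent: float,
) -> np.ndarray:
    """Stationary Gaussian random field by random plane-wave synthesis.

    Wave vectors are drawn from the spectral density of the Gaussian
    covariance exp(-d^2 / (2 ell^2)), i.e. k ~ Normal(0, 1/ell^2) per
    axis, each mode carrying an independent 1/f^a time series.  The
    field's second-order statistics are domain-independent, unlike
    lattice smoothing which distorts near boundaries.
    """
    K = _N_SPATIAL_MODES
    k = rng.normal(0.0, 1.0 / ell, (K, 2))
    phase = rng.uniform(0.0, 2.0 * np.pi, K)
    amps = _shape_spectrum(rng.standard_normal((K, n)), fs, exponent)
    G = np.cos(pos @ k.T + phase)  # (m, K)
    return np.sqrt(2.0 / K) * (G @ amps)


def _traveling_wave(osc: Oscillation, pos: np.ndarray, t: np.ndarray) -> np.ndarray:
    theta = np.deg2rad(osc.direction_deg)
    dhat = np.array([np.cos(theta), np.sin(theta)])
    # delay in seconds: positions are mm, speed m/s
    delay = ((pos - np.asarray(osc.origin_mm)) @ dhat) / (1000.0 * osc.propagation_speed_m_per_s)
    return osc.amplitude * np.sin(2 * np.pi * osc.freq_hz * (t[None, :] - delay[:, None]))


def disc_subpoints(center: np.ndarray, diameter_mm: float, n: int) -> np.ndarray:
    """Fixed sunflower pattern of n points on the exposed disc, so the
    electrode-size effect is deterministic (seed-independent)."""
    if n < 1:
        raise ValueError("n_subpoints must be >= 1")
    if n == 1:
        return np.asarray(center, dtype=float)[None, :]
    k = np.arange(n)
    r = (diameter_mm / 2.0) * np.sqrt((k + 0.5) / n)
    phi = k * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    return np.asarray(center) + np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def sample_electrodes(
    field: SourceField,
    layout: ElectrodeLayout,
    config: SimConfig,
    n_subpoints: int | None = None,
) -> Recording:
    """Project the source field onto the electrodes.

    Each electrode signal is the mean, over sub-points on its exposed
    disc, of the conduction-weighted sum of all source series, plus
    independent white sensor noise (sd ``config.sensor_noise_sd`` uV).
    """
    n_sub = n_subpoints if n_subpoints is not None else config.n_subpoints
    if layout.exposed_diameter_mm > layout.pitch_mm:
        raise ValueError("exposed disc larger than the electrode pitch")
    n_el = layout.n_electrodes
    pts = np.concatenate(
        [disc_subpoints(layout.positions[i], layout.exposed_diameter_mm, n_sub)
         for i in range(n_el)]
    )  # (n_el * n_sub, 2)
    d = np.sqrt(((pts[:, None, :] - field.positions[None, :, :]) ** 2).sum(-1))
    W = conduction_weight(d, config.conduction_lambda_mm)
    mixed = (W @ field.series).reshape(n_el, n_sub, -1).mean(axis=1)
    if config.sensor_noise_sd > 0:
        _, rng_noise = _seed_children(config.seed)
        mixed = mixed + rng_noise.normal(0.0, config.sensor_noise_sd, mixed.shape)
    return Recording(data=mixed, fs_hz=field.fs_hz, channel_id=layout.electrode_id)


def generate_dataset(
    config: SimConfig,
    layout: ElectrodeLayout,
    n_trials: int = 0,
    isi_s: float = 3.0,
    seed: int | None = None,
) -> tuple[Recording, pd.DataFrame]:
    """Simulate a continuous recording plus a BIDS-style events table.

    Stimulus events are placed at regular onsets ``isi_s, 2*isi_s, ...``;
    the recording must be long enough for ``n_trials`` events plus the
    trailing half interval.  With ``n_trials == 0`` an event-free stream
    is produced (anesthesia-style recording).  Fully reproducible from
    the seed.
    """
    if seed is not None:
        config = SimConfig(**{**config.to_dict(), "seed": seed,
                              "oscillations": config.oscillations,
                              "broadband": config.broadband, "task": config.task})
    n = int(round(config.duration_s * config.fs_hz))
    gate = None
    if n_trials > 0:
        needed = isi_s * (n_trials + 0.5)
        if config.duration_s < needed:
            raise ValueError(
                f"duration {config.duration_s} s cannot hold {n_trials} trials "
                f"at {isi_s} s spacing (needs >= {needed} s)"
            )
        onsets = isi_s * (1 + np.arange(n_trials))
        gate = np.zeros(n)
        half = int(round(isi_s / 2 * config.fs_hz))
        for o in onsets:
            i0 = int(round(o * config.fs_hz))
            gate[i0 : i0 + half] = 1.0
        events = pd.DataFrame(
            {"onset": onsets, "duration": np.full(n_trials, isi_s / 2),
             "trial_type": ["stimulus"] * n_trials}
        )
    else:
        events = pd.DataFrame(columns=["onset", "duration", "trial_type"])

    field = simulate_source_field(config, layout, task_gate=gate)
    rec = sample_electrodes(field, layout, config)
    return rec, events
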