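"""Recording containers and signal preprocessing.

The processing chain mirrors intraoperative ECoG practice and is applied
in a fixed order: bad-channel masking -> notch filtering (line noise and
its harmonics) -> common median reference -> band operations (Butterworth
band-pass for ndRMS, Morlet band power for correlation/task analyses) ->
trial segmentation.  Filtering is applied to the continuous recording
before segmentation, since 1-1.75 s trials are too short to band-pass at
1-4 Hz without severe edge effects.

All filters are Butterworth and applied zero-phase (forward-backward,
``sosfiltfilt``); the stated orders refer to the designed filter before
the backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Recording",
    "TrialSet",
    "DEFAULT_BANDS",
    "UNFILTERED",
    "default_bandset",
    "band_name",
    "detect_bad_channels",
    "notch_filter",
    "common_median_reference",
    "bandpass_filter",
    "morlet_band_power",
    "segment_trials",
    "channel_report",
]

#: the eight dyadic analysis bands (Hz); amplitude falls roughly as a
#: power law over frequency, so bandwidths form a geometric sequence
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (1, 4), (4, 8), (8, 16), (16, 32), (32, 64), (64, 128), (128, 256), (256, 499),
)

#: sentinel band id meaning "no band-pass applied"
UNFILTERED = "unfiltered"


def default_bandset() -> list:
    """The eight dyadic bands plus the unfiltered sentinel, in order."""
    return [*DEFAULT_BANDS, UNFILTERED]


def band_name(band) -> str:
    if band == UNFILTERED or band is None:
        return UNFILTERED
    lo, hi = band
    return f"{lo:g}-{hi:g}Hz"


@dataclass
class Recording:
    """Multichannel recording: channels x samples, in microvolts."""

    data: np.ndarray
    fs_hz: float
    channel_id: tuple[str, ...]
    good_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_id) != self.data.shape[0]:
            raise ValueError("channel_id length must match channel count")
        if self.good_mask is None:
            self.good_mask = np.ones(self.data.shape[0], dtype=bool)
        self.good_mask = np.asarray(self.good_mask, dtype=bool)
        if not np.all(np.isfinite(self.data[self.good_mask])):
            raise ValueError("good channels contain non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(), good_mask=self.good_mask.copy())


@dataclass
class TrialSet:
    """Epoched data: trial x channel x sample, with rest/active labels."""

    epochs: np.ndarray
    label: np.ndarray  # "rest" or "active" per trial
    onset_s: np.ndarray
    duration_s: np.ndarray
    fs_hz: float
    channel_id: tuple[str, ...]
    good_mask: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trial x channel x sample")
        self.label = np.asarray(self.label)
        if len(self.label) != self.epochs.shape[0]:
            raise ValueError("one label per trial required")
        if np.any(np.asarray(self.duration_s) <= 0):
            raise ValueError("durations must be positive")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    def select(self, label: str) -> "TrialSet":
        m = self.label == label
        return TrialSet(
            self.epochs[m], self.label[m], np.asarray(self.onset_s)[m],
            np.asarray(self.duration_s)[m], self.fs_hz, self.channel_id, self.good_mask,
        )


# ---------------------------------------------------------------------------
# bad channel detection


def _band_power(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    m = (f >= lo) & (f <= hi)
    return float(np.trapezoid(p[m], f[m])) if m.sum() > 1 else 0.0


def detect_bad_channels(
    rec: Recording,
    flat_sd_uv: float = 1e-8,
    amplitude_mads: float = 5.0,
    line_freq_hz: float = 50.0,
    line_half_width_hz: float = 1.0,
    line_power_ratio: float = 0.5,
    outlier_sds: float = 5.0,
    outlier_fraction: float = 0.01,
    total_band_hz: tuple[float, float] = (1.0, 499.0),
) -> tuple[np.ndarray, dict[str, list[str]]]:
    """Flag bad channels with reasons {flat, amplitude, line_noise, outliers}.

    Defaults: *flat* if the channel sd falls below ``flat_sd_uv``;
    *amplitude* if the robust channel amplitude (scaled MAD) deviates more
    than ``amplitude_mads`` scaled MADs from the cross-channel median;
    *line_noise* if power within ``line_freq_hz +- line_half_width_hz``
    exceeds ``line_power_ratio`` times the total power in
    ``total_band_hz``; *outliers* if more than ``outlier_fraction`` of
    samples exceed ``outlier_sds`` channel standard deviations.

    Thresholds are heuristics intended for a screening pass; the report is
    meant to be confirmed by visual inspection.
    """
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    X = rec.data
    sd = X.std(axis=1, ddof=0)
    reasons: dict[str, list[str]] = {}

    def flag(i: int, why: str) -> None:
        reasons.setdefault(rec.channel_id[i], []).append(why)

    flat = sd < flat_sd_uv
    for i in np.flatnonzero(flat):
        flag(i, "flat")

    med = np.median(X, axis=1, keepdims=True)
    amp = 1.4826 * np.median(np.abs(X - med), axis=1)  # scaled MAD per channel
    amp_med = np.median(amp)
    amp_spread = 1.4826 * np.median(np.abs(amp - amp_med))
    if amp_spread > 0:
        for i in np.flatnonzero(np.abs(amp - amp_med) > amplitude_mads * amp_spread):
            if not flat[i]:
                flag(i, "amplitude")

    nper = int(min(4096, rec.n_samples))
    f, pxx = sps.welch(X, fs=rec.fs_hz, nperseg=nper, axis=1)
    for i in range(rec.n_channels):
        if flat[i]:
            continue
        line = _band_power(f, pxx[i], line_freq_hz - line_half_width_hz,
                           line_freq_hz + line_half_width_hz)
        total = _band_power(f, pxx[i], *total_band_hz)
        if total > 0 and line > line_power_ratio * total:
            flag(i, "line_noise")

    with np.errstate(invalid="ignore"):
        dev = np.abs(X - X.mean(axis=1, keepdims=True))
        frac = np.mean(dev > outlier_sds * sd[:, None], axis=1)
    for i in np.flatnonzero((frac > outlier_fraction) & ~flat):
        flag(i, "outliers")

    good = np.array([cid not in reasons for cid in rec.channel_id])
    return good, reasons


def channel_report(rec: Recording, reasons: dict[str, list[str]]) -> pd.DataFrame:
    """Per-channel quality table (channel, flagged, reasons) for review."""
    return pd.DataFrame(
        {
            "channel": list(rec.channel_id),
            "flagged": [cid in reasons for cid in rec.channel_id],
            "reasons": [",".join(reasons.get(cid, [])) for cid in rec.channel_id],
        }
    )


# ---------------------------------------------------------------------------
# filters and referencing


def _apply_sos(rec: Recording, sos: np.ndarray) -> Recording:
    out = rec.copy()
    out.data = sps.sosfiltfilt(sos, out.data, axis=1)
    return out


def notch_filter(
    rec: Recording,
    base_freqs_hz: tuple[float, ...] = (50.0, 24.0),
    half_width_hz: float = 1.0,
    order: int = 4,
    max_freq_hz: float = 499.0,
) -> Recording:
    """Cascaded Butterworth band-stop at each base frequency and every
    integer harmonic up to ``max_freq_hz``, applied zero-phase.

    Defaults remove 50 Hz mains noise and a 24 Hz artifact (each with all
    harmonics) using 4th-order stop bands of +-1 Hz around each target.
    """
    nyq = rec.fs_hz / 2.0
    stops: list[np.ndarray] = []
    for base in base_freqs_hz:
        k = 1
        while base * k <= max_freq_hz:
            lo, hi = base * k - half_width_hz, base * k + half_width_hz
            if hi >= nyq:
                raise ValueError(f"stop band {lo}-{hi} Hz reaches Nyquist ({nyq} Hz)")
            stops.append(sps.butter(order, [lo, hi], btype="bandstop",
                                    fs=rec.fs_hz, output="sos"))
            k += 1
    if not stops:
        return rec.copy()
    return _apply_sos(rec, np.vstack(stops))


def common_median_reference(rec: Recording) -> Recording:
    """Subtract the per-sample median across good channels from every good
    channel; bad channels are left untouched.

    Removes activity common to all electrodes (line noise, the reference
    electrode's signal) more robustly than a common average.
    """
    good = rec.good_mask
    if good.sum() < 2:
        raise ValueError("need at least 2 good channels")
    out = rec.copy()
    med = np.median(out.data[good], axis=0, keepdims=True)
    out.data[good] -= med
    return out


def bandpass_filter(rec: Recording, band) -> Recording:
    """Butterworth band-pass, zero-phase.

    Order 3 for the two lowest bands (1-4 and 4-8 Hz), order 4 otherwise.
    The ``"unfiltered"`` sentinel returns the input unchanged (copy).
    """
    if band == UNFILTERED or band is None:
        return rec.copy()
    lo, hi = band
    nyq = rec.fs_hz / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} must satisfy 0 < low < high < {nyq}")
    order = 3 if hi <= 8 else 4
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs_hz, output="sos")
    return _apply_sos(rec, sos)


def morlet_band_power(
    data: Recording | np.ndarray,
    band: tuple[float, float],
    fs_hz: float | None = None,
    n_cycles: float = 7.0,
    n_freqs: int = 5,
) -> np.ndarray:
    """Morlet-wavelet band power: squared coefficient magnitude averaged
    over ``n_freqs`` log-spaced frequencies within the band.

    Accepts a Recording or a channels x samples (or trials x channels x
    samples) array plus ``fs_hz``.  Returns a power series with the same
    leading shape as the input.

    On short epochs the cycle count is capped per frequency so that the
    wavelet fits within the signal (at most 80% of its length); an epoch
    too short for even a single cycle at the band's low edge is an error.
    """
    from mne.time_frequency import tfr_array_morlet

    if isinstance(data, Recording):
        fs_hz = data.fs_hz
        X = data.data
    else:
        if fs_hz is None:
            raise ValueError("fs_hz required when passing a bare array")
        X = np.asarray(data, dtype=float)
    lo, hi = band
    if not 0 < lo < hi < fs_hz / 2:
        raise ValueError(f"band {band} invalid for fs {fs_hz}")
    freqs = np.geomspace(lo, hi, n_freqs)
    squeeze = X.ndim == 2
    if squeeze:
        X = X[None]
    n_samples = X.shape[-1]
    # a Morlet atom spans ~10 sigma = (10/2pi) * n_cycles / f seconds;
    # keep it within ~90% of the epoch
    cycles = np.minimum(n_cycles, 0.9 * (2 * np.pi / 10) * freqs * n_samples / fs_hz)
    if cycles.min() < 0.5:
        raise ValueError(
            f"epoch too short ({n_samples} samples at {fs_hz} Hz) for a "
            f"wavelet at {lo} Hz"
        )
    power = tfr_array_morlet(X, fs_hz, freqs, n_cycles=cycles,
                             output="power", verbose="error")
    out = power.mean(axis=2)  # average over the band's frequencies
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# segmentation


def segment_trials(rec: Recording, events: pd.DataFrame, scheme: str = "half_isi") -> TrialSet:
    """Cut rest/active trials around stimulus onsets.

    ``half_isi``: rest covers the half inter-stimulus interval before each
    onset, active the half interval after it.  ``fixed_1p5s``: 1.5 s
    windows on either side of the onset (task-response analysis).
    Intervals are half-open in samples; trials that would exceed the
    recording bounds are dropped.
    """
    if "onset" not in events.columns:
        raise ValueError("events table requires an 'onset' column (seconds)")
    onsets = np.sort(np.asarray(events["onset"], dtype=float))
    if len(onsets) == 0:
        raise ValueError("no events")
    if scheme == "half_isi":
        if len(onsets) < 2:
            raise ValueError("half_isi scheme needs >= 2 events to infer the ISI")
        half = float(np.median(np.diff(onsets))) / 2.0
    elif scheme == "fixed_1p5s":
        half = 1.5
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    n_win = int(round(half * rec.fs_hz))
    epochs, labels, t0s = [], [], []
    for onset in onsets:
        i0 = int(round(onset * rec.fs_hz))
        for label, start in (("rest", i0 - n_win), ("active", i0)):
            if start < 0 or start + n_win > rec.n_samples:
                continue  # out-of-bounds trial dropped
            epochs.append(rec.data[:, start : start + n_win])
            labels.append(label)
            t0s.append(start / rec.fs_hz)
    if not epochs:
        raise ValueError("no valid trials within recording bounds")
    return TrialSet(
        epochs=np.stack(epochs),
        label=np.array(labels),
        onset_s=np.array(t0s),
        duration_s=np.full(len(epochs), n_win / rec.fs_hz),
        fs_hz=rec.fs_hz,
        channel_id=rec.channel_id,
        good_mask=rec.good_mask.copy(),
    )
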