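"""File I/O: recordings (EDF, raw binary + JSON sidecar), BIDS-style
TSV tables, analysis configuration, and provenance headers.

Recordings are stored either as EDF (16-bit, physical units microvolts;
written by the minimal single-record writer here, read back through
MNE's EDF reader) or as a raw little-endian float64 binary matrix with a
JSON sidecar carrying sampling rate, channel names and units.  The raw
container round-trips bit-identically; EDF round-trips within its 16-bit
quantization step.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import Recording

__all__ = [
    "write_edf",
    "write_raw",
    "read_recording",
    "read_events_tsv",
    "write_events_tsv",
    "write_table",
    "read_table",
    "AnalysisConfig",
]


def _pad(s, n: int) -> bytes:
    b = str(s).encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(rec: Recording, path) -> None:
    """Write a Recording as a minimal EDF file (one data record).

    16-bit digitization over each channel's physical range, physical
    dimension microvolts.  Readable by standard EDF software including
    ``mne.io.read_raw_edf``.
    """
    data = rec.data
    n_ch, n_s = data.shape
    rec_dur = n_s / rec.fs_hz
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    pmax = np.where(pmax - pmin <= 0, pmax + 1.0, pmax)  # avoid a zero span
    pmin_s = [f"{v:.6g}" for v in pmin]
    pmax_s = [f"{v:.6g}" for v in pmax]
    hdr = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(256 * (1 + n_ch), 8),
            _pad("", 44),
            _pad(1, 8),
            _pad(f"{rec_dur:g}", 8),
            _pad(n_ch, 4),
        ]
        + [_pad(c, 16) for c in rec.channel_id]
        + [_pad("", 80)] * n_ch
        + [_pad("uV", 8)] * n_ch
        + [_pad(v, 8) for v in pmin_s]
        + [_pad(v, 8) for v in pmax_s]
        + [_pad(-32768, 8)] * n_ch
        + [_pad(32767, 8)] * n_ch
        + [_pad("", 80)] * n_ch
        + [_pad(n_s, 8)] * n_ch
        + [_pad("", 32)] * n_ch
    )
    pmin_f = np.array([float(v) for v in pmin_s])
    pmax_f = np.array([float(v) for v in pmax_s])
    scale = (pmax_f - pmin_f) / 65535.0
    dig = np.round((data - pmin_f[:, None]) / scale[:, None]) - 32768
    dig = np.clip(dig, -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(dig.tobytes())


def _read_edf(path) -> Recording:
    from mne.io import read_raw_edf

    raw = read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,  # MNE returns volts; store microvolts
        fs_hz=float(raw.info["sfreq"]),
        channel_id=tuple(raw.ch_names),
    )


def write_raw(rec: Recording, path) -> None:
    """Write the raw binary container: ``<path>`` (little-endian float64,
    channel-major) plus ``<path>.json`` sidecar."""
    path = Path(path)
    rec.data.astype("<f8").tofile(path)
    sidecar = {
        "fs_hz": rec.fs_hz,
        "channel_id": list(rec.channel_id),
        "units": "uV",
        "shape": list(rec.data.shape),
        "dtype": "<f8",
        "good_mask": rec.good_mask.astype(int).tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def _read_raw(path) -> Recording:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if "fs_hz" not in meta:
        raise ValueError(f"sidecar {sidecar_path} lacks the sampling rate 'fs_hz'")
    data = np.fromfile(path, dtype=meta.get("dtype", "<f8")).reshape(meta["shape"])
    return Recording(
        data=data,
        fs_hz=float(meta["fs_hz"]),
        channel_id=tuple(meta["channel_id"]),
        good_mask=np.asarray(meta.get("good_mask", np.ones(len(data))), dtype=bool),
    )


def read_recording(path, fmt: str | None = None, n_expected_channels: int | None = None) -> Recording:
    """Read a recording from EDF or the raw+JSON container.

    Format is inferred from the extension when not given.  If
    ``n_expected_channels`` is provided (e.g. from an electrodes table)
    a mismatch raises an error naming both counts.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "raw"
    if fmt == "edf":
        rec = _read_edf(path)
    elif fmt in ("raw", "raw+json"):
        rec = _read_raw(path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")
    if n_expected_channels is not None and rec.n_channels != n_expected_channels:
        raise ValueError(
            f"recording has {rec.n_channels} channels but the electrode table "
            f"lists {n_expected_channels}"
        )
    return rec


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events[["onset", "duration", "trial_type"]].to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "onset" not in df.columns:
        raise ValueError("events.tsv requires an 'onset' column")
    return df


# ---------------------------------------------------------------------------
# tables with provenance


def write_table(df: pd.DataFrame, path, config_hash: str = "", seed: int | None = None) -> None:
    """Write a tidy TSV with a provenance comment header."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# ndrms_version={__version__}\n")
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# analysis configuration


@dataclass
class AnalysisConfig:
    """Pipeline configuration; flags of the CLI mirror these names."""

    recording: str = ""
    electrodes: str = ""
    events: str = ""
    output_dir: str = "ndrms_out"
    mode: str = "awake"  # or "stream"
    scheme: str = "half_isi"  # trial segmentation scheme
    bands: list = field(default_factory=list)  # empty -> default band set
    round_to_mm: float = 0.1
    min_pairs: int = 10
    notch_base_freqs_hz: tuple[float, ...] = (50.0, 24.0)
    run_correlation: bool = False
    run_task_response: bool = False
    task_band: tuple[float, float] = (64.0, 128.0)
    alpha: float = 0.05
    seed: int = 0

    def config_hash(self) -> str:
        # output_dir does not affect the analysis, so it is not hashed
        d = {k: v for k, v in self.__dict__.items() if k != "output_dir"}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls(**d)
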