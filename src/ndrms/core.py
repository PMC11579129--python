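"""The normalized differential root-mean-square (ndRMS) statistic.

ndRMS quantifies the information NOT shared between two signals.  Each
trial signal is z-normalized (mean 0, standard deviation 1, population
denominator), the normalized signals are subtracted within an electrode
pair, and the RMS of that differential signal is taken:

    ndRMS(x, y) = RMS( z(x) - z(y) )

Bounds: 0 for identical signals, sqrt(2) for independent white noise,
2 for sinusoids in antiphase.  The population-sd normalization makes the
identity ndRMS = sqrt(2 (1 - r)) with the Pearson correlation r hold
exactly at finite length; ``ndrms_oracle`` exposes that closed form as an
independent cross-check of the direct computation.

For awake recordings the statistic is computed per rest trial and
summarised as the median over trials (robust to outlier trials); for
anesthesia recordings it is computed once over the whole stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .geometry import PairTable
from .preprocess import Recording, TrialSet

__all__ = [
    "DegenerateTrialError",
    "PairNdrms",
    "znormalize",
    "ndrms_pair",
    "ndrms_oracle",
    "ndrms_per_pair",
    "pair_ndrms_frame",
]

#: a trial is degenerate when its sd is below this fraction of its scale
_DEGENERATE_REL_SD = 1e-12


class DegenerateTrialError(ValueError):
    """Raised when a (near-)constant series cannot be z-normalized."""


def _check_series(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be 1-D with at least 2 samples")
    return x


def znormalize(series: np.ndarray) -> np.ndarray:
    """Z-normalize a trial series to mean 0 and sd 1 (population sd).

    Raises :class:`DegenerateTrialError` for constant input; callers
    exclude that pair-trial rather than assigning it a value.
    """
    x = _check_series(series)
    sd = x.std(ddof=0)
    scale = max(np.abs(x).max(), 1.0)
    if sd <= _DEGENERATE_REL_SD * scale:
        raise DegenerateTrialError("constant (zero-variance) series")
    return (x - x.mean()) / sd


def ndrms_pair(x: np.ndarray, y: np.ndarray) -> float:
    """ndRMS between two equal-length series: RMS of z(x) - z(y).

    Symmetric, bounded in [0, 2], and invariant to positive affine
    transforms of either input.
    """
    x = _check_series(x)
    y = _check_series(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    d = znormalize(x) - znormalize(y)
    return float(np.sqrt(np.mean(d * d)))


def ndrms_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form ndRMS, sqrt(2 (1 - r)), from the Pearson correlation.

    Kept separate from :func:`ndrms_pair` (which computes the difference
    RMS directly) so the two routes verify each other.
    """
    zx = znormalize(x)
    zy = znormalize(y)
    if zx.shape != zy.shape:
        raise ValueError("length mismatch")
    r = float(np.mean(zx * zy))  # population-normalized correlation
    return float(np.sqrt(max(2.0 * (1.0 - r), 0.0)))


@dataclass
class PairNdrms:
    """Per-pair ndRMS: per-trial values plus the trial summary."""

    pair_index: int  # row in the PairTable this belongs to
    values: np.ndarray  # one ndRMS per valid trial (length 1 in stream mode)
    summary: float  # median over trials (awake) or the single value (stream)
    n_trials: int  # number of valid (non-degenerate) trials


def _znorm_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-normalization with a validity mask (False = degenerate)."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    scale = np.maximum(np.abs(X).max(axis=1, keepdims=True), 1.0)
    valid = (sd > _DEGENERATE_REL_SD * scale).ravel()
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, valid


def _pair_rms(Z: np.ndarray, valid: np.ndarray, ia: np.ndarray, ib: np.ndarray,
              chunk: int = 512) -> np.ndarray:
    """RMS of z-differences for many pairs; NaN where either side degenerate."""
    out = np.full(len(ia), np.nan)
    for s in range(0, len(ia), chunk):
        a = ia[s : s + chunk]
        b = ib[s : s + chunk]
        d = Z[a] - Z[b]
        out[s : s + chunk] = np.sqrt(np.mean(d * d, axis=1))
    out[~(valid[ia] & valid[ib])] = np.nan
    return out


def ndrms_per_pair(
    data: TrialSet | Recording,
    pairs: PairTable,
    mode: str = "awake",
    max_degenerate_frac: float = 0.5,
) -> list[PairNdrms]:
    """Compute ndRMS for every included pair of a pair table.

    Parameters
    ----------
    data
        In ``"awake"`` mode a :class:`TrialSet` whose epochs are the rest
        trials of the (already band-filtered) recording; in ``"stream"``
        mode a continuous :class:`Recording` analysed as a single trial.
    pairs
        Pair table over the same channel indexing as ``data``.
    mode
        ``"awake"``: median over per-trial values. ``"stream"``: one value
        across the entire recording (anesthesia analysis).
    max_degenerate_frac
        A pair is dropped entirely when more than this fraction of its
        trials is degenerate (constant signal on either electrode).

    Returns
    -------
    list of PairNdrms, excluded pairs omitted.
    """
    ia, ib = pairs.index_a, pairs.index_b
    if mode == "stream":
        if not isinstance(data, Recording):
            raise TypeError("stream mode expects a continuous Recording")
        Z, valid = _znorm_rows(data.data)
        rms = _pair_rms(Z, valid, ia, ib)
        per_trial = rms[None, :]
    elif mode == "awake":
        if not isinstance(data, TrialSet):
            raise TypeError("awake mode expects a TrialSet of rest trials")
        rest = data.select("rest") if "active" in data.label else data
        if rest.n_trials == 0:
            raise ValueError("no rest trials available")
        per_trial = np.empty((rest.n_trials, len(ia)))
        for t in range(rest.n_trials):
            Z, valid = _znorm_rows(rest.epochs[t])
            per_trial[t] = _pair_rms(Z, valid, ia, ib)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    results: list[PairNdrms] = []
    for p in np.flatnonzero(pairs.included):
        vals = per_trial[:, p]
        good = ~np.isnan(vals)
        n_good = int(good.sum())
        if n_good == 0 or (per_trial.shape[0] - n_good) / per_trial.shape[0] > max_degenerate_frac:
            continue  # flagged by omission; callers compare against the pair table
        kept = vals[good]
        results.append(
            PairNdrms(
                pair_index=int(p),
                values=kept,
                summary=float(np.median(kept)),
                n_trials=n_good,
            )
        )
    return results


def pair_ndrms_frame(
    results: Iterable[PairNdrms], pairs: PairTable, band: str
) -> pd.DataFrame:
    """Tidy per-pair table: pair, distance_mm, band, n_trials, ndrms."""
    rows = [
        {
            "pair": f"{pairs.id_a[r.pair_index]}-{pairs.id_b[r.pair_index]}",
            "distance_mm": float(pairs.distance_mm[r.pair_index]),
            "band": band,
            "n_trials": r.n_trials,
            "ndrms": r.summary,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["pair", "distance_mm", "band", "n_trials", "ndrms"])
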