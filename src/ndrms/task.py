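"""Task-response mapping: trial-wise high-frequency band power regressed
on a binary rest/active regressor, per electrode.

The 64-128 Hz band is used as the marker of local neural activity.  Per
channel, the Pearson correlation r between trial-mean band power and the
0/1 task regressor is converted to a signed coefficient of determination
sign(r) * r^2, with a two-sided p-value from the t-distribution and
Bonferroni correction over the number of channels tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sst

from .preprocess import TrialSet, morlet_band_power

__all__ = ["trial_band_power", "signed_r2_map"]

DEFAULT_TASK_BAND = (64.0, 128.0)


def trial_band_power(
    trials: TrialSet,
    band: tuple[float, float] = DEFAULT_TASK_BAND,
    n_cycles: float = 7.0,
    n_freqs: int = 5,
) -> np.ndarray:
    """Mean Morlet band power per trial and channel.

    Returns an (n_trials, n_channels) array of the power time series
    averaged over each trial's samples.
    """
    if trials.n_trials == 0:
        raise ValueError("empty trial set")
    power = morlet_band_power(trials.epochs, band, fs_hz=trials.fs_hz,
                              n_cycles=n_cycles, n_freqs=n_freqs)
    return power.mean(axis=-1)


def signed_r2_map(
    powers: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    n_channels: int | None = None,
    channel_id: tuple[str, ...] | None = None,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-channel signed R^2 between trial power and a binary regressor.

    Parameters
    ----------
    powers : (n_trials, n_channels)
        Trial-mean band power.
    labels : (n_trials,)
        Binary regressor: 0 for rest, 1 for active (or "rest"/"active").
    alpha
        Family-wise significance level before Bonferroni division.
    n_channels
        Bonferroni denominator; defaults to the number of channels in
        ``powers``.  Channels with zero power variance are reported with
        NaN statistics and are not tested, but still count in the
        denominator (conservative).
    log_transform
        Correlate log-power instead of raw power.

    Returns
    -------
    DataFrame with columns channel, r, signed_r2, p, significant, and
    metadata in ``.attrs`` (alpha, n_trials, n_channels_tested).
    """
    P = np.asarray(powers, dtype=float)
    if P.ndim != 2:
        raise ValueError("powers must be (n_trials, n_channels)")
    y = np.asarray(labels)
    if y.dtype.kind in "US":
        y = (y == "active").astype(float)
    y = y.astype(float)
    n = len(y)
    if n != P.shape[0]:
        raise ValueError("one label per trial required")
    if n < 3:
        raise ValueError("need at least 3 trials")
    if len(np.unique(y)) < 2:
        raise ValueError("both rest and active labels must be present")
    if log_transform:
        P = np.log(np.maximum(P, np.finfo(float).tiny))

    n_den = n_channels if n_channels is not None else P.shape[1]
    yz = y - y.mean()
    r = np.full(P.shape[1], np.nan)
    sd = P.std(axis=0, ddof=0)
    ok = sd > 0
    Pc = P[:, ok] - P[:, ok].mean(axis=0)
    r[ok] = (yz @ Pc) / (n * yz.std(ddof=0) * sd[ok])

    p = np.full(P.shape[1], np.nan)
    r_ok = np.clip(r[ok], -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r_ok * np.sqrt((n - 2) / (1.0 - r_ok**2))
    p_ok = 2.0 * sst.t.sf(np.abs(tstat), df=n - 2)
    p_ok[np.abs(r_ok) >= 1.0] = 0.0  # perfect separation: t -> inf
    p[ok] = p_ok

    thresh = alpha / n_den
    sig = np.zeros(P.shape[1], dtype=bool)
    sig[ok] = p[ok] < thresh
    ids = channel_id if channel_id is not None else tuple(
        f"ch{i:02d}" for i in range(P.shape[1])
    )
    out = pd.DataFrame(
        {"channel": list(ids), "r": r, "signed_r2": np.sign(r) * r**2,
         "p": p, "significant": sig}
    )
    out.attrs.update(
        {"alpha": alpha, "n_trials": n, "n_channels_tested": int(n_den),
         "band": "64-128Hz"}
    )
    return out
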