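"""IED-resolved aggregation, distance-averaged correlation, and the
HD-vs-UHD grid comparison.

Aggregation proceeds over three levels: per recording (mean over the
equidistant pairs of each IED bin), per participant (mean over task
repetitions), and group (mean over participants, keeping only IED bins
present in at least two participants).  The grid comparison tests, at
each IED shared by the two grids, the per-band values (eight dyadic bands
plus the unfiltered signal, nine values per grid) with a two-sided
Wilcoxon rank-sum test, Bonferroni-corrected over the matched IEDs.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sst

from .core import PairNdrms
from .geometry import IedBins, PairTable
from .preprocess import TrialSet, morlet_band_power

__all__ = [
    "ndrms_by_ied",
    "average_levels",
    "correlation_by_ied",
    "compare_grids",
    "rank_sum_test",
    "median_over_bands",
]

_COLUMNS = ["level", "participant", "repetition", "ied_mm", "band", "statistic", "value", "n_pairs"]


def _rows_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=_COLUMNS)


def ndrms_by_ied(
    pair_values: Iterable[PairNdrms],
    bins: IedBins,
    band: str,
    participant: str = "p01",
    repetition: int = 1,
) -> pd.DataFrame:
    """Mean ndRMS over the equidistant pairs of each IED bin.

    Pairs excluded upstream (degenerate trials) simply do not contribute;
    a bin left empty after exclusions is dropped with a warning.
    """
    summary = {r.pair_index: r.summary for r in pair_values}
    rows = []
    for dist, members in zip(bins.bin_distance_mm, bins.members):
        vals = [summary[i] for i in members if i in summary]
        if not vals:
            warnings.warn(f"IED bin {dist} mm empty after pair exclusions; dropped")
            continue
        rows.append(
            {"level": "recording", "participant": participant, "repetition": repetition,
             "ied_mm": float(dist), "band": band, "statistic": "ndrms",
             "value": float(np.mean(vals)), "n_pairs": len(vals)}
        )
    return _rows_frame(rows)


def average_levels(rows: pd.DataFrame, level: str, min_participants: int = 2) -> pd.DataFrame:
    """Average one aggregation level up.

    ``level="participant"``: mean over repetitions per (participant, IED,
    band).  ``level="group"``: mean over participants per (IED, band),
    keeping only bins present in at least ``min_participants``
    participants.
    """
    if rows.empty:
        return _rows_frame([])
    stat = rows["statistic"].iloc[0]
    if level == "participant":
        expect = "recording"
        keys = ["participant", "ied_mm", "band"]
    elif level == "group":
        expect = "participant"
        keys = ["ied_mm", "band"]
    else:
        raise ValueError(f"unknown target level {level!r}")
    if not (rows["level"] == expect).all():
        raise ValueError(f"input rows must all be at level {expect!r}")
    g = rows.groupby(keys, as_index=False).agg(
        value=("value", "mean"), n_pairs=("n_pairs", "sum"), n_src=("value", "size")
    )
    if level == "group":
        g = g[g["n_src"] >= min_participants]
        g["participant"] = "all"
    g = g.assign(level=level, statistic=stat, repetition=0)
    return g[_COLUMNS].reset_index(drop=True)


def correlation_by_ied(
    trials: TrialSet,
    pairs: PairTable,
    bins: IedBins,
    band,
    participant: str = "p01",
    repetition: int = 1,
    use_power: bool = True,
    n_cycles: float = 7.0,
    n_freqs: int = 5,
) -> pd.DataFrame:
    """Distance-averaged Pearson correlation per IED bin.

    For every rest trial, the per-channel band signal (Morlet band power
    by default; band-passed voltage with ``use_power=False``) is
    correlated within each electrode pair; coefficients are averaged over
    trials and then over the pairs of each IED bin.
    """
    from .preprocess import UNFILTERED, band_name

    rest = trials.select("rest") if "active" in trials.label else trials
    if rest.n_trials == 0:
        raise ValueError("no rest trials")
    n_pairs_total = len(pairs)
    r_sum = np.zeros(n_pairs_total)
    r_cnt = np.zeros(n_pairs_total, dtype=int)
    for t in range(rest.n_trials):
        X = rest.epochs[t]
        if use_power and band not in (UNFILTERED, None):
            X = morlet_band_power(X, band, fs_hz=rest.fs_hz,
                                  n_cycles=n_cycles, n_freqs=n_freqs)
        sd = X.std(axis=1, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X)
        r = C[pairs.index_a, pairs.index_b]
        ok = (sd[pairs.index_a] > 0) & (sd[pairs.index_b] > 0) & np.isfinite(r)
        r_sum[ok] += r[ok]
        r_cnt[ok] += 1
    rows = []
    for dist, members in zip(bins.bin_distance_mm, bins.members):
        m = members[r_cnt[members] > 0]
        if len(m) == 0:
            continue
        mean_r = float(np.mean(r_sum[m] / r_cnt[m]))
        rows.append(
            {"level": "recording", "participant": participant, "repetition": repetition,
             "ied_mm": float(dist), "band": band_name(band), "statistic": "correlation",
             "value": mean_r, "n_pairs": int(len(m))}
        )
    return _rows_frame(rows)


def rank_sum_test(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the sum of ranks of the lower-ranked
    sample (midranks for ties); under complete separation of two 9-value
    samples W = 45 and the exact two-sided p is 2/48620.  Exact p for
    sample sizes up to 12, normal approximation beyond.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per sample")
    ranks = sst.rankdata(np.concatenate([a, b]))
    ra, rb = ranks[: len(a)].sum(), ranks[len(a) :].sum()
    w = float(min(ra, rb))
    method = "exact" if max(len(a), len(b)) <= 12 else "asymptotic"
    p = float(sst.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    return w, p


def compare_grids(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    matched: list[tuple[int, int, float, float]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare two grids' per-band ndRMS at matched IEDs.

    ``table_a``/``table_b`` hold per-band values (one row per band) at
    each IED; ``matched`` comes from :func:`geometry.matched_ied_bins`.
    Per matched IED a two-sided rank-sum test is run between the two
    per-band samples; p-values are Bonferroni-corrected by the number of
    matched IEDs.
    """
    if not matched:
        return pd.DataFrame(
            columns=["ied_a_mm", "ied_b_mm", "n_a", "n_b", "rank_sum_statistic",
                     "p_two_sided", "p_bonferroni", "significant"]
        )
    n_tests = len(matched)
    out = []
    for _, _, da, db in matched:
        va = table_a.loc[np.isclose(table_a["ied_mm"], da), "value"].to_numpy()
        vb = table_b.loc[np.isclose(table_b["ied_mm"], db), "value"].to_numpy()
        w, p = rank_sum_test(va, vb)
        p_bonf = min(1.0, p * n_tests)
        out.append(
            {"ied_a_mm": da, "ied_b_mm": db, "n_a": len(va), "n_b": len(vb),
             "rank_sum_statistic": w, "p_two_sided": p, "p_bonferroni": p_bonf,
             "significant": bool(p_bonf < alpha)}
        )
    return pd.DataFrame(out)


def median_over_bands(rows: pd.DataFrame) -> pd.DataFrame:
    """Median of the per-band values at each IED (one row per IED), the
    per-IED summary used when comparing grids visually."""
    g = rows.groupby("ied_mm", as_index=False)["value"].median()
    return g.rename(columns={"value": "median_over_bands"})
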