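"""IED aggregation, level averaging, correlation curves and the
HD-vs-UHD rank-sum comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ndrms import (
    Recording,
    TrialSet,
    average_levels,
    bin_equidistant,
    compare_grids,
    correlation_by_ied,
    make_square_layout,
    matched_ied_bins,
    median_over_bands,
    ndrms_by_ied,
    ndrms_per_pair,
    pair_distance_table,
    rank_sum_test,
)
from ndrms.core import PairNdrms


def _pair_values(pairs, values):
    return [
        PairNdrms(pair_index=i, values=np.array([v]), summary=float(v), n_trials=1)
        for i, v in enumerate(values)
    ]


class TestNdrmsByIed:
    def test_bin_means(self):
        lay = make_square_layout(2, 2, 1.0, 0.2)
        pairs = pair_distance_table(lay)
        bins = bin_equidistant(pairs, min_pairs=1)
        # 4 side pairs at 1.0 mm, 2 diagonals at 1.4 mm
        side_vals = {0.9, 1.1, 1.0, 1.2}
        vals = np.empty(6)
        for i, d in enumerate(pairs.distance_mm):
            vals[i] = 1.05 if np.isclose(d, 1.0) else 2.0
        rows = ndrms_by_ied(_pair_values(pairs, vals), bins, "unfiltered")
        assert rows.loc[rows.ied_mm == 1.0, "value"].iloc[0] == pytest.approx(1.05)
        assert rows.loc[rows.ied_mm == 1.4, "value"].iloc[0] == pytest.approx(2.0)
        assert rows["n_pairs"].tolist() == [4, 2]

    def test_missing_pairs_shrink_bin(self):
        lay = make_square_layout(2, 2, 1.0, 0.2)
        pairs = pair_distance_table(lay)
        bins = bin_equidistant(pairs, min_pairs=1)
        rows = ndrms_by_ied(_pair_values(pairs, np.ones(6))[:3], bins, "unfiltered")
        assert rows["n_pairs"].sum() == 3


class TestAverageLevels:
    def _recording_rows(self, participant, repetition, values):
        return pd.DataFrame(
            {
                "level": "recording", "participant": participant,
                "repetition": repetition, "ied_mm": list(values),
                "band": "unfiltered", "statistic": "ndrms",
                "value": list(values.values()), "n_pairs": 12,
            }
        )

    def test_repetition_mean(self):
        rows = pd.concat([
            self._recording_rows("p01", 1, {3.0: 1.2}),
            self._recording_rows("p01", 2, {3.0: 1.4}),
        ])
        out = average_levels(rows, "participant")
        assert out["value"].iloc[0] == pytest.approx(1.3)
        assert (out["level"] == "participant").all()

    def test_group_requires_two_participants(self):
        rows = pd.concat([
            self._recording_rows("p01", 1, {3.0: 1.2, 6.0: 1.5}),
            self._recording_rows("p02", 1, {3.0: 1.4}),
        ])
        part = average_levels(rows, "participant")
        group = average_levels(part, "group")
        # 6.0 mm bin present in one participant only -> excluded
        assert group["ied_mm"].tolist() == [3.0]
        assert group["value"].iloc[0] == pytest.approx(1.3)

    def test_single_participant_group_empty(self):
        part = average_levels(self._recording_rows("p01", 1, {3.0: 1.2}), "participant")
        assert average_levels(part, "group").empty

    def test_group_mean_convexity(self, rng):
        frames = []
        for p in range(4):
            vals = {d: float(rng.uniform(1, 2)) for d in (3.0, 4.2, 6.0)}
            frames.append(self._recording_rows(f"p{p}", 1, vals))
        part = average_levels(pd.concat(frames), "participant")
        group = average_levels(part, "group")
        for _, row in group.iterrows():
            contrib = part.loc[part.ied_mm == row.ied_mm, "value"]
            assert contrib.min() - 1e-12 <= row.value <= contrib.max() + 1e-12


class TestCorrelationByIed:
    def _trials(self, epochs, fs=2000.0):
        n, c, _ = epochs.shape
        return TrialSet(
            epochs=epochs, label=np.array(["rest"] * n), onset_s=np.zeros(n),
            duration_s=np.ones(n), fs_hz=fs,
            channel_id=tuple(f"c{i}" for i in range(c)), good_mask=np.ones(c, bool),
        )

    def test_identical_channels_r_one(self, rng):
        lay = make_square_layout(2, 2, 1.0, 0.2)
        pairs = pair_distance_table(lay)
        bins = bin_equidistant(pairs, min_pairs=1)
        x = rng.standard_normal(3000)
        epochs = np.tile(x, (2, 4, 1))
        rows = correlation_by_ied(self._trials(epochs), pairs, bins, (64, 128))
        assert np.allclose(rows["value"], 1.0, atol=1e-9)

    def test_independent_noise_near_zero(self, rng):
        lay = make_square_layout(2, 2, 1.0, 0.2)
        pairs = pair_distance_table(lay)
        bins = bin_equidistant(pairs, min_pairs=1)
        epochs = rng.standard_normal((60, 4, 1000))
        rows = correlation_by_ied(
            self._trials(epochs), pairs, bins, (64, 128), n_freqs=3
        )
        assert np.all(np.abs(rows["value"]) < 0.07)

    def test_voltage_mode_shared_signal(self, rng):
        lay = make_square_layout(2, 2, 1.0, 0.2)
        pairs = pair_distance_table(lay)
        bins = bin_equidistant(pairs, min_pairs=1)
        shared = rng.standard_normal((5, 1, 800))
        epochs = np.broadcast_to(shared, (5, 4, 800)).copy()
        epochs += 0.3 * rng.standard_normal(epochs.shape)
        rows = correlation_by_ied(
            self._trials(epochs), pairs, bins, (64, 128), use_power=False
        )
        assert np.all(rows["value"] > 0.8)


class TestRankSum:
    def test_complete_separation_anchor(self):
        # two 9-value samples, no overlap: W = 45, exact p = 2/48620
        lo = np.linspace(1.0, 1.2, 9)
        hi = np.linspace(1.5, 1.9, 9)
        w, p = rank_sum_test(hi, lo)
        assert w == 45.0
        assert p == pytest.approx(2 / 48620, rel=1e-9)
        assert p < 1e-4

    def test_identical_samples_not_significant(self):
        x = np.arange(9.0)
        _, p = rank_sum_test(x, x)
        assert p > 0.6

    def test_exact_p_matches_permutation_enumeration(self, rng):
        # independent oracle: enumerate all C(n+m, n) label assignments
        for n in (4, 5):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n) + 0.8
            w_obs, p_exact = rank_sum_test(x, y)
            pooled = np.concatenate([x, y])
            ranks = np.argsort(np.argsort(pooled)) + 1.0
            total = 0
            extreme = 0
            for idx in itertools.combinations(range(2 * n), n):
                w1 = ranks[list(idx)].sum()
                w2 = ranks.sum() - w1
                total += 1
                if min(w1, w2) <= w_obs + 1e-9:
                    extreme += 1
            assert p_exact == pytest.approx(extreme / total, abs=1e-12)

    def test_sample_too_small_errors(self):
        with pytest.raises(ValueError):
            rank_sum_test([1.0], [2.0, 3.0])


class TestCompareGrids:
    def _table(self, values_by_ied):
        rows = []
        for ied, vals in values_by_ied.items():
            for b, v in enumerate(vals):
                rows.append({"ied_mm": ied, "band": f"b{b}", "value": v})
        return pd.DataFrame(rows)

    def test_separated_grids_significant(self):
        a = self._table({3.0: np.linspace(1.0, 1.2, 9), 4.2: np.linspace(1.0, 1.2, 9)})
        b = self._table({3.1: np.linspace(1.5, 1.7, 9), 4.1: np.linspace(1.5, 1.7, 9)})
        matched = [(0, 0, 3.0, 3.1), (1, 1, 4.2, 4.1)]
        out = compare_grids(a, b, matched)
        assert (out["rank_sum_statistic"] == 45.0).all()
        assert out["p_bonferroni"].to_numpy() == pytest.approx(2 * 2 / 48620)
        assert out["significant"].all()

    def test_bonferroni_doubles_p(self):
        rng = np.random.default_rng(4)
        a = self._table({3.0: rng.normal(1.3, 0.1, 9), 4.2: rng.normal(1.3, 0.1, 9)})
        b = self._table({3.1: rng.normal(1.35, 0.1, 9), 4.1: rng.normal(1.35, 0.1, 9)})
        matched = [(0, 0, 3.0, 3.1), (1, 1, 4.2, 4.1)]
        out = compare_grids(a, b, matched)
        np.testing.assert_allclose(
            out["p_bonferroni"], np.minimum(1.0, 2 * out["p_two_sided"])
        )

    def test_no_matches_empty_frame(self):
        out = compare_grids(self._table({}), self._table({}), [])
        assert out.empty


def test_median_over_bands():
    df = pd.DataFrame({"ied_mm": [3.0] * 3 + [4.2] * 3, "value": [1, 2, 6, 4, 5, 9]})
    out = median_over_bands(df)
    assert out.loc[out.ied_mm == 3.0, "median_over_bands"].iloc[0] == 2
    assert out.loc[out.ied_mm == 4.2, "median_over_bands"].iloc[0] == 5
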