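"""End-to-end analysis pipeline.

Stage order is fixed: bad-channel masking -> notch filtering -> common
median reference -> per-band operations (Butterworth band-pass for
ndRMS, Morlet power for correlation / task mapping) -> trial
segmentation -> per-pair statistics -> IED aggregation.  Every stage
logs the counts it kept (channels, trials, bins); outputs are tidy TSVs
with a provenance header plus a JSON summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, geometry, preprocess, stats, task
from .io import (
    AnalysisConfig,
    read_events_tsv,
    read_recording,
    write_table,
)

__all__ = ["run_pipeline"]

log = logging.getLogger("ndrms")


def _parse_bands(bands: list) -> list:
    if not bands:
        return preprocess.default_bandset()
    out = []
    for b in bands:
        out.append(preprocess.UNFILTERED if b in ("unfiltered", None) else tuple(b))
    return out


def run_pipeline(config: AnalysisConfig) -> dict[str, Path]:
    """Run the configured analysis; returns the paths written.

    In ``awake`` mode, ndRMS is the median over rest trials; ``stream``
    mode (anesthesia) computes a single value over the whole recording
    and needs no events file.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    outputs: dict[str, Path] = {}

    layout = geometry.read_electrodes_tsv(config.electrodes)
    rec = read_recording(config.recording, n_expected_channels=layout.n_electrodes)
    log.info("loaded recording: %d channels, %.1f s at %g Hz",
             rec.n_channels, rec.duration_s, rec.fs_hz)

    good, reasons = preprocess.detect_bad_channels(rec)
    rec.good_mask = good
    report = preprocess.channel_report(rec, reasons)
    outputs["channel_report"] = out_dir / "channel_report.tsv"
    write_table(report, outputs["channel_report"], chash, config.seed)
    log.info("bad-channel screening: kept %d/%d channels", good.sum(), rec.n_channels)

    rec = preprocess.notch_filter(rec, base_freqs_hz=tuple(config.notch_base_freqs_hz))
    rec = preprocess.common_median_reference(rec)

    pairs = geometry.pair_distance_table(layout, rec.good_mask)
    bins = geometry.bin_equidistant(pairs, config.round_to_mm, config.min_pairs)
    log.info("pairs: %d over %d good electrodes; %d IED bins with >= %d pairs",
             len(pairs), int(rec.good_mask.sum()), len(bins), config.min_pairs)

    events = None
    if config.mode == "awake":
        events = read_events_tsv(config.events)

    bands = _parse_bands(config.bands)
    ied_rows, pair_rows, corr_rows = [], [], []
    for band in bands:
        name = preprocess.band_name(band)
        filtered = preprocess.bandpass_filter(rec, band)
        if config.mode == "awake":
            trials = preprocess.segment_trials(filtered, events, config.scheme)
            rest = trials.select("rest")
            log.info("band %s: %d rest trials of %.2f s", name, rest.n_trials,
                     float(rest.duration_s[0]))
            values = core.ndrms_per_pair(rest, pairs, mode="awake")
        else:
            values = core.ndrms_per_pair(filtered, pairs, mode="stream")
        pair_rows.append(core.pair_ndrms_frame(values, pairs, name))
        ied_rows.append(stats.ndrms_by_ied(values, bins, name))
        if config.run_correlation and band is not preprocess.UNFILTERED:
            trials = preprocess.segment_trials(rec, events, config.scheme) \
                if config.mode == "awake" else None
            if trials is not None:
                corr_rows.append(stats.correlation_by_ied(trials, pairs, bins, band))

    outputs["pair_ndrms"] = out_dir / "pair_ndrms.tsv"
    write_table(pd.concat(pair_rows, ignore_index=True), outputs["pair_ndrms"], chash, config.seed)
    ied_table = pd.concat(ied_rows, ignore_index=True)
    outputs["ndrms_by_ied"] = out_dir / "ndrms_by_ied.tsv"
    write_table(ied_table, outputs["ndrms_by_ied"], chash, config.seed)
    log.info("ndRMS table: %d (bin, band) rows", len(ied_table))

    if corr_rows:
        outputs["correlation_by_ied"] = out_dir / "correlation_by_ied.tsv"
        write_table(pd.concat(corr_rows, ignore_index=True),
                    outputs["correlation_by_ied"], chash, config.seed)

    if config.run_task_response:
        if config.mode != "awake":
            raise ValueError("task-response mapping requires awake mode with events")
        trials = preprocess.segment_trials(rec, events, "fixed_1p5s")
        powers = task.trial_band_power(trials, tuple(config.task_band))
        labels = trials.label
        good_idx = np.flatnonzero(rec.good_mask)
        tmap = task.signed_r2_map(
            powers[:, good_idx], labels, alpha=config.alpha,
            channel_id=tuple(rec.channel_id[i] for i in good_idx),
        )
        outputs["task_response"] = out_dir / "task_response.tsv"
        write_table(tmap, outputs["task_response"], chash, config.seed)
        log.info("task map: %d/%d significant channels",
                 int(tmap["significant"].sum()), len(tmap))

    summary = {
        "config_hash": chash,
        "n_channels": rec.n_channels,
        "n_good_channels": int(rec.good_mask.sum()),
        "n_pairs": len(pairs),
        "n_bins": len(bins),
        "bands": [preprocess.band_name(b) for b in bands],
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1))
    outputs["summary"] = summary_path
    return outputs
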