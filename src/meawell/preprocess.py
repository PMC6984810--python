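"""Spike-event QC, array firing-rate metrics, and threshold spike detection.

Three pre-analysis steps common to multi-well MEA work:

* removal of events from "high-noise" electrodes, identified by a
  crossing threshold more than 3 SD above the mean crossing threshold
  of the recording;
* the array-level mean firing rate MFR = n / s (spikes over seconds),
  log-transformed as log10((n + 1) / s) so silent arrays stay finite;
* exclusion of inactive arrays falling more than 2 SD below the median
  log10 Hz of the plate before treatment groups are formed.

A simple amplitude-threshold spike detector (5.5 x moving-window RMS)
is included for synthetic raw voltage traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .interchange import SpikeEvent, SpikeTable, crossing_index, waveform_samples


@dataclass(frozen=True)
class ArrayActivity:
    """Firing activity of one well (array) in one recording."""

    well: str
    recording_id: str
    n_spikes: int
    mfr: float  # Hz
    log_mfr: float  # log10 Hz, computed from (n+1)/s


def filter_high_noise_spikes(
    table: SpikeTable, pool_recordings: bool = False
) -> tuple[SpikeTable, int]:
    """Drop events whose crossing threshold exceeds mean + 3 SD.

    The mean and SD of the crossing threshold are computed over all
    events of each recording separately (the noise regime is
    recording-specific); set ``pool_recordings`` to pool the statistics
    across the whole table instead.  Returns the filtered table and the
    number of excluded events.
    """
    if table.n_events < 2:
        return table.subset(list(table.events)), 0
    thr = np.array([e.crossing_threshold for e in table.events])
    rids = np.array([e.recording_id for e in table.events])
    keep = np.ones(len(thr), dtype=bool)
    groups = [None] if pool_recordings else list(dict.fromkeys(rids))
    for rid in groups:
        m = np.ones(len(thr), dtype=bool) if rid is None else rids == rid
        if m.sum() < 2:
            continue
        limit = thr[m].mean() + 3.0 * thr[m].std(ddof=1)
        keep &= ~m | (thr <= limit)
    kept = [e for e, k in zip(table.events, keep) if k]
    return table.subset(kept), int((~keep).sum())


def compute_mfr(events: list[SpikeEvent], well: str, recording_id: str, duration: float) -> ArrayActivity:
    """Mean firing rate of one array: all electrodes of the well pooled."""
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    n = sum(1 for e in events if e.well == well and e.recording_id == recording_id)
    return ArrayActivity(
        well=well,
        recording_id=recording_id,
        n_spikes=n,
        mfr=n / duration,
        log_mfr=float(np.log10((n + 1) / duration)),
    )


def array_activities(table: SpikeTable, recording_id: str | None = None) -> list[ArrayActivity]:
    """Per-well activities for one recording (or all recordings)."""
    rids = [recording_id] if recording_id else table.recording_ids
    counts: dict[tuple[str, str], int] = {}
    for e in table.events:
        counts[(e.well, e.recording_id)] = counts.get((e.well, e.recording_id), 0) + 1
    out = []
    for rid in rids:
        dur = table.recording(rid).duration
        for well in table.layout.well_labels:
            n = counts.get((well, rid), 0)
            out.append(
                ArrayActivity(
                    well=well,
                    recording_id=rid,
                    n_spikes=n,
                    mfr=n / dur,
                    log_mfr=float(np.log10((n + 1) / dur)),
                )
            )
    return out


def select_active_arrays(activities: list[ArrayActivity]) -> tuple[set[str], set[str]]:
    """Partition wells into (active, excluded) by the 2-SD-below-median rule.

    An array is active when its log10 MFR is no more than 2 SD below
    the median of the whole sample set.  With zero spread every array
    is active.
    """
    if len(activities) < 2:
        raise ValueError("need at least 2 arrays to select active ones")
    vals = np.array([a.log_mfr for a in activities])
    threshold = np.median(vals) - 2.0 * vals.std(ddof=1)
    active = {a.well for a, v in zip(activities, vals) if v >= threshold}
    excluded = {a.well for a in activities} - active
    return active, excluded


# ---------------------------------------------------------------------------
# threshold detection on raw traces (synthetic-trace support)

_CHI2_1_MEDIAN = 0.45493642311957174  # median of chi-square(1)


def moving_rms(trace: np.ndarray, rate: float, window_ms: float = 10.0) -> np.ndarray:
    """Background RMS over a centered moving window, robust to spikes.

    The mean square over a raw window is badly inflated by any spike
    inside it, so the background power is estimated as the windowed
    *median* of the squared samples, rescaled to be unbiased for
    Gaussian noise (median of sigma^2 * chi-square(1) is ~0.455 sigma^2).
    Reflective padding at the edges.
    """
    n_win = max(int(round(window_ms * rate / 1000.0)), 1)
    ms = median_filter(trace.astype(float) ** 2, size=n_win, mode="reflect")
    return np.sqrt(ms / _CHI2_1_MEDIAN)


def detect_spikes(
    trace: np.ndarray,
    rate: float,
    k_sd: float = 5.5,
    rms_window_ms: float = 10.0,
    pre_ms: float = 1.0,
    post_ms: float = 2.0,
    refractory_ms: float = 1.0,
    well: str = "A1",
    electrode: int = 1,
    recording_id: str = "rec",
) -> list[SpikeEvent]:
    """Detect spikes where |v| exceeds ``k_sd`` x moving-window RMS.

    The per-event crossing threshold records k_sd x RMS at the crossing
    sample; detections within ``refractory_ms`` of a previous one are
    suppressed.  Waveforms follow the interchange window convention
    (crossing at index floor(pre_ms * rate / 1000)).
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    if rate <= 0:
        raise ValueError("rate must be positive")
    rms = moving_rms(trace, rate, rms_window_ms)
    limit = k_sd * rms
    above = np.abs(trace) > limit
    # rising edges of the |v| > limit indicator
    crossings = np.flatnonzero(above & ~np.roll(above, 1))
    if above[0]:
        crossings = np.union1d(crossings, [0])
    n_pre = crossing_index(pre_ms, rate)
    n_total = waveform_samples(pre_ms, post_ms, rate)
    refractory = int(round(refractory_ms * rate / 1000.0))
    events: list[SpikeEvent] = []
    last = -np.inf
    for c in crossings:
        if c - last < refractory:
            continue
        last = c
        lo = c - n_pre
        hi = lo + n_total
        wave = np.zeros(n_total)
        src_lo, src_hi = max(lo, 0), min(hi, len(trace))
        wave[src_lo - lo : src_hi - lo] = trace[src_lo:src_hi]
        events.append(
            SpikeEvent(
                well=well,
                electrode=electrode,
                recording_id=recording_id,
                timestamp=c / rate,
                crossing_threshold=float(limit[c]),
                waveform=wave,
            )
        )
    return events
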