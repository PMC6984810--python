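import numpy as np
import pytest

from meawell.interchange import (
    PlateLayout,
    RecordingMeta,
    SpikeEvent,
    SpikeTable,
    waveform_samples,
)
from meawell.simulate import SimConfig, simulate_plate


def make_event(
    well="A1",
    electrode=1,
    recording_id="r1",
    timestamp=1.0,
    threshold=10.0,
    waveform=None,
    n_samples=38,
    truth_neuron=None,
):
    if waveform is None:
        waveform = np.zeros(n_samples)
    return SpikeEvent(
        well=well,
        electrode=electrode,
        recording_id=recording_id,
        timestamp=timestamp,
        crossing_threshold=threshold,
        waveform=np.asarray(waveform, dtype=float),
        truth_neuron=truth_neuron,
    )


def make_table(events, duration=600.0, n_recordings=1, layout=None):
    layout = layout or PlateLayout()
    recs = [RecordingMeta(recording_id=f"r{k+1}", duration=duration) for k in range(n_recordings)]
    return SpikeTable(layout=layout, recordings=recs, events=events)


@pytest.fixture(scope="session")
def small_layout():
    return PlateLayout(n_rows=2, n_cols=4)  # 8 wells x 8 electrodes


@pytest.fixture(scope="session")
def small_plate(small_layout):
    """An 8-well simulated plate with two 10-min recordings."""
    cfg = SimConfig(
        layout=small_layout,
        recording_durations=(600.0, 600.0),
        recording_phases=("pre", "post"),
        seed=11,
    )
    return simulate_plate(cfg)


#: trough-width (samples), rebound offset (samples), rebound ratio — three
#: visibly different extracellular waveform shapes
WAVE_SHAPES = [(1, 3, 0.15), (2, 6, 0.45), (4, 10, 0.8)]


def biphasic_wave(amp_uv, shape=0, n_samples=38, crossing=12, rng=None, noise_sd=0.0):
    """Test waveform: trough at the crossing with a shape-dependent rebound."""
    width, reb_off, reb_ratio = WAVE_SHAPES[shape % len(WAVE_SHAPES)]
    t = np.arange(n_samples, dtype=float)
    w = -amp_uv * np.exp(-0.5 * ((t - crossing) / width) ** 2)
    w += reb_ratio * amp_uv * np.exp(-0.5 * ((t - crossing - reb_off) / (1.5 * width)) ** 2)
    if rng is not None and noise_sd > 0:
        w = w + rng.normal(0, noise_sd, n_samples)
    return w


def separable_electrode_events(
    amps=(12.0, 60.0, 300.0),
    n_per=60,
    noise_sd=1.0,
    seed=0,
    recording_ids=("r1",),
    duration=600.0,
):
    """Events from neurons with distinct templates on one electrode.

    Neurons differ both in amplitude (ratios >= 3) and in waveform
    shape (trough width, rebound), as distinct cells near one electrode
    do.
    """
    rng = np.random.default_rng(seed)
    events = []
    for j, amp in enumerate(amps):
        for k in range(n_per):
            rid = recording_ids[k % len(recording_ids)]
            events.append(
                make_event(
                    timestamp=float(rng.random() * duration),
                    waveform=biphasic_wave(amp, shape=j, rng=rng, noise_sd=noise_sd),
                    recording_id=rid,
                    truth_neuron=f"n{j}",
                )
            )
    return events
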