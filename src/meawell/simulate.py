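"""Synthetic multi-well MEA generator with full ground truth.

Emulates the statistical structure of spontaneous activity on a
96-well, 8-electrode plate sampled at 12.5 kHz:

* array (well-level) firing rates are log-normal — latent log10 rates
  drawn from a configurable normal (default mean -0.8, SD 0.55
  log10 Hz, a calibration choice giving a plausible spread of quiet to
  busy wells);
* each electrode carries one or more neurons with distinct biphasic
  waveform templates whose amplitudes come from extracellular volume-
  conductor geometry (linear source approximation), so amplitude and
  firing rate are independent;
* spike trains are Poisson, with a configurable fraction of
  within-well neuron pairs sharing a jittered parent process
  (detectable as STTC coupling);
* day-to-day latent rates carry over with correlation rho (default
  0.8), so repeated recordings of the same plate correlate;
* per-group treatment effects scale firing rates and/or template
  amplitudes in post-treatment phases;
* optional raw voltage traces (template sums plus Gaussian noise,
  optionally band-passed) exercise threshold spike detection.

Every emitted spike is labelled with its true neuron so that sorting,
network inference and the statistical models can be validated against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .design import correlated_followup
from .interchange import (
    PlateLayout,
    RecordingMeta,
    SpikeEvent,
    SpikeTable,
    crossing_index,
    waveform_samples,
)

# ---------------------------------------------------------------------------
# extracellular amplitude model


def lsa_amplitude(i: float, sigma: float, delta_s: float, r: float, h: float) -> float:
    """Extracellular potential of a line current source (volts).

    V_e = I / (4 pi sigma delta_s) * ln| (sqrt(h^2+r^2) - h) / (sqrt(l^2+r^2) - l) |

    with l = h + delta_s: ``i`` the source current (A), ``sigma`` the
    extracellular conductivity (S/m), ``delta_s`` the cylinder length
    (m), ``r`` the radial and ``h`` the longitudinal distance from the
    cylinder end (m).  For r much larger than delta_s this converges to
    the Coulomb point-source potential I / (4 pi r sigma).
    """
    if sigma <= 0 or delta_s <= 0 or r <= 0:
        raise ValueError("sigma, delta_s and r must be positive (r = 0 is singular)")
    l = h + delta_s
    num = np.sqrt(h**2 + r**2) - h
    den = np.sqrt(l**2 + r**2) - l
    return float(i / (4.0 * np.pi * sigma * delta_s) * np.log(abs(num / den)))


def point_source_amplitude(i: float, sigma: float, d: float) -> float:
    """Coulomb point-source extracellular potential I / (4 pi d sigma)."""
    if sigma <= 0 or d <= 0:
        raise ValueError("sigma and d must be positive")
    return float(i / (4.0 * np.pi * d * sigma))


# ---------------------------------------------------------------------------
# configuration and ground truth


@dataclass
class CouplingSpec:
    """Within-well spike-train coupling via shared parent processes."""

    fraction: float = 0.15  # fraction of neuron pairs coupled
    parent_share: float = 0.7  # probability a parent event enters each child
    jitter_sd_ms: float = 5.0


@dataclass
class TemplateSpec:
    """Waveform template parameter ranges (amplitudes from LSA geometry)."""

    current_na: tuple[float, float] = (5.0, 30.0)
    radial_um: tuple[float, float] = (20.0, 100.0)
    longitudinal_um: tuple[float, float] = (0.0, 50.0)
    segment_um: float = 50.0
    conductivity_s_m: float = 0.3
    trough_width_ms: tuple[float, float] = (0.15, 0.35)
    rebound_width_ms: tuple[float, float] = (0.4, 0.8)
    rebound_ratio: tuple[float, float] = (0.2, 0.5)


@dataclass
class SimConfig:
    """Full specification of a simulated experiment."""

    layout: PlateLayout = field(default_factory=PlateLayout)
    recording_durations: tuple[float, ...] = (1800.0, 1800.0)
    recording_phases: tuple[str, ...] = ("pre", "post")
    neurons_per_electrode: dict[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.40, 3: 0.25}
    )
    array_log_rate: tuple[float, float] = (-0.8, 0.55)  # mean, SD of log10 Hz
    within_array_rate_shape: float = 1.0  # Gamma shape for neuron rate shares
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    day_correlation: float = 0.8
    templates: TemplateSpec = field(default_factory=TemplateSpec)
    noise_sd: float = 3.0  # uV
    detect_k_sd: float = 5.5
    high_noise_electrode_frac: float = 0.0
    high_noise_multiplier: float = 10.0
    groups: dict[str, str] = field(default_factory=dict)  # well -> group label
    treatment_effects: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    # group -> phase -> (rate multiplier, amplitude multiplier)
    seed: int = 0

    def __post_init__(self):
        if self.layout.n_wells <= 0:
            raise ValueError("layout must have at least one well")
        if len(self.recording_durations) != len(self.recording_phases):
            raise ValueError("recording_durations and recording_phases must align")
        if not np.isclose(sum(self.neurons_per_electrode.values()), 1.0):
            raise ValueError("neurons_per_electrode probabilities must sum to 1")
        if not 0.0 <= self.coupling.fraction <= 1.0:
            raise ValueError("coupling fraction must be in [0, 1]")


@dataclass
class NeuronTruth:
    neuron_id: str
    well: str
    electrode: int
    base_rate: float  # Hz, pre-treatment
    template: np.ndarray  # uV
    amplitude_uv: float
    geometry: dict


@dataclass
class GroundTruth:
    """Registry of simulated neurons and their per-recording parameters."""

    neurons: dict[str, NeuronTruth]
    rate_table: pd.DataFrame  # index neuron_id, columns recording_id -> Hz
    amp_scale: pd.DataFrame  # index neuron_id, columns recording_id -> multiplier
    coupled_pairs: list[tuple[str, str]]
    groups: dict[str, str]
    latent_log_rates: pd.DataFrame  # index well, columns recording_id


def apply_treatment(
    truth: GroundTruth,
    group_effects: dict[str, dict[str, tuple[float, float]]],
    phases: dict[str, str],
) -> GroundTruth:
    """Scale post-phase rates and amplitudes per treatment group.

    ``group_effects`` maps group -> phase -> (rate multiplier,
    amplitude multiplier); ``phases`` maps recording_id -> phase label.
    Recordings whose phase has no entry for a group are untouched, so a
    washout phase with multiplier 1 restores baseline.
    """
    rate = truth.rate_table.copy()
    amp = truth.amp_scale.copy()
    for nid, neuron in truth.neurons.items():
        group = truth.groups.get(neuron.well)
        if group is None or group not in group_effects:
            continue
        for rid in rate.columns:
            eff = group_effects[group].get(phases[rid])
            if eff is None:
                continue
            rate_mult, amp_mult = eff
            if rate_mult < 0 or amp_mult < 0:
                raise ValueError("multipliers must be non-negative")
            rate.loc[nid, rid] *= rate_mult
            amp.loc[nid, rid] *= amp_mult
    return GroundTruth(
        neurons=truth.neurons,
        rate_table=rate,
        amp_scale=amp,
        coupled_pairs=truth.coupled_pairs,
        groups=truth.groups,
        latent_log_rates=truth.latent_log_rates,
    )


# ---------------------------------------------------------------------------
# waveform templates


def make_template(
    n_samples: int,
    crossing_idx: int,
    rate: float,
    amplitude_uv: float,
    trough_width_ms: float,
    rebound_width_ms: float,
    rebound_ratio: float,
) -> np.ndarray:
    """Biphasic template: negative trough at the crossing, later rebound."""
    t = (np.arange(n_samples) - crossing_idx) / rate * 1000.0  # ms
    trough = -np.exp(-0.5 * (t / trough_width_ms) ** 2)
    reb_center = trough_width_ms + rebound_width_ms
    rebound = rebound_ratio * np.exp(-0.5 * ((t - reb_center) / rebound_width_ms) ** 2)
    shape = trough + rebound
    span = shape.max() - shape.min()
    return shape * (amplitude_uv / span)


# ---------------------------------------------------------------------------
# spike trains


def simulate_trains(
    rates: dict[str, float],
    duration: float,
    coupling: CouplingSpec | None = None,
    seed: int = 0,
    fixed_pairs: list[tuple[str, str]] | None = None,
) -> tuple[dict[str, np.ndarray], list[tuple[str, str]]]:
    """Poisson spike trains with optional shared-parent coupling.

    Uncoupled neurons fire as independent homogeneous Poisson processes
    at their target rate.  A coupled pair shares a parent Poisson
    process at the smaller of the two rates: each parent event is
    copied into each child with probability ``parent_share`` and
    Gaussian timing jitter; independent residual spikes top each child
    up to its target rate.  Returns (trains, coupled_pairs).
    """
    rng = np.random.default_rng(seed)
    coupling = coupling or CouplingSpec(fraction=0.0)
    ids = list(rates)
    for nid, r in rates.items():
        if r < 0:
            raise ValueError(f"negative rate for {nid}")

    def poisson_train(rate: float) -> np.ndarray:
        n = rng.poisson(rate * duration)
        return np.sort(rng.random(n) * duration)

    if fixed_pairs is not None:
        pairs = [p for p in fixed_pairs if rates[p[0]] > 0 and rates[p[1]] > 0]
    else:
        # choose disjoint coupled pairs among neurons with positive rates
        firing = [i for i in ids if rates[i] > 0]
        rng.shuffle(firing)
        n_pairs = int(np.floor(coupling.fraction * len(firing) / 2.0))
        pairs = [(firing[2 * k], firing[2 * k + 1]) for k in range(n_pairs)]
    paired = {x for p in pairs for x in p}

    trains: dict[str, np.ndarray] = {}
    for a, b in pairs:
        parent_rate = min(rates[a], rates[b])
        parent = poisson_train(parent_rate)
        for child in (a, b):
            keep = parent[rng.random(parent.size) < coupling.parent_share]
            jitter = rng.normal(0.0, coupling.jitter_sd_ms / 1000.0, keep.size)
            shared = np.clip(keep + jitter, 0.0, duration)
            residual_rate = max(rates[child] - parent_rate * coupling.parent_share, 0.0)
            t = np.sort(np.concatenate([shared, poisson_train(residual_rate)]))
            trains[child] = t
    for nid in ids:
        if nid not in paired:
            trains[nid] = poisson_train(rates[nid])
    return trains, pairs


# ---------------------------------------------------------------------------
# the plate


def _latent_log_rates(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-well latent log10 rates, correlated across recordings.

    The first recording's latents are drawn from the configured normal;
    each later recording re-uses the correlated-follow-up construction
    on centred values (so the marginal mean is preserved) with
    rho = day_correlation.
    """
    wells = list(config.layout.well_labels)
    mean, sd = config.array_log_rate
    a = mean + sd * rng.standard_normal(len(wells))
    cols = {}
    rids = [f"r{k + 1}" for k in range(len(config.recording_durations))]
    cols[rids[0]] = a
    for k, rid in enumerate(rids[1:], start=2):
        if sd == 0 or len(wells) < 3 or config.day_correlation >= 1.0:
            cols[rid] = a.copy()
        else:
            centered = a - a.mean()
            b = correlated_followup(centered, config.day_correlation, seed=int(rng.integers(2**31)))
            cols[rid] = a.mean() + b
    return pd.DataFrame(cols, index=wells)


def build_ground_truth(config: SimConfig) -> tuple[GroundTruth, list[RecordingMeta]]:
    """Draw the neuron registry and per-recording rates (no spikes yet)."""
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    layout = config.layout
    rids = [f"r{k + 1}" for k in range(len(config.recording_durations))]
    recordings = [
        RecordingMeta(recording_id=rid, duration=d, phase=ph)
        for rid, d, ph in zip(rids, config.recording_durations, config.recording_phases)
    ]
    latents = _latent_log_rates(config, rng)

    counts = np.array(sorted(config.neurons_per_electrode))
    probs = np.array([config.neurons_per_electrode[c] for c in counts])
    n_samp = waveform_samples(1.0, 2.0, layout.sampling_rate)
    c_idx = crossing_index(1.0, layout.sampling_rate)
    ts = config.templates

    neurons: dict[str, NeuronTruth] = {}
    rate_rows = {}
    for well in layout.well_labels:
        well_neurons: list[str] = []
        shares: list[float] = []
        for elec in range(1, layout.electrodes_per_well + 1):
            k = int(rng.choice(counts, p=probs))
            for j in range(k):
                nid = f"{well}_{elec}_n{j + 1}"
                current = rng.uniform(*ts.current_na) * 1e-9
                r = rng.uniform(*ts.radial_um) * 1e-6
                h = rng.uniform(*ts.longitudinal_um) * 1e-6
                amp_uv = abs(
                    lsa_amplitude(current, ts.conductivity_s_m, ts.segment_um * 1e-6, r, h)
                ) * 1e6
                template = make_template(
                    n_samp,
                    c_idx,
                    layout.sampling_rate,
                    amp_uv,
                    rng.uniform(*ts.trough_width_ms),
                    rng.uniform(*ts.rebound_width_ms),
                    rng.uniform(*ts.rebound_ratio),
                )
                neurons[nid] = NeuronTruth(
                    neuron_id=nid,
                    well=well,
                    electrode=elec,
                    base_rate=0.0,  # filled below
                    template=template,
                    amplitude_uv=amp_uv,
                    geometry={"i_a": current, "r_m": r, "h_m": h, "delta_s_m": ts.segment_um * 1e-6},
                )
                well_neurons.append(nid)
                shares.append(rng.gamma(config.within_array_rate_shape))
        share = np.array(shares)
        share = share / share.sum()
        for nid, s in zip(well_neurons, share):
            rates = {rid: float(s * 10.0 ** latents.loc[well, rid]) for rid in rids}
            neurons[nid].base_rate = rates[rids[0]]
            rate_rows[nid] = rates

    rate_table = pd.DataFrame.from_dict(rate_rows, orient="index")[rids]
    amp_scale = pd.DataFrame(1.0, index=rate_table.index, columns=rids)
    truth = GroundTruth(
        neurons=neurons,
        rate_table=rate_table,
        amp_scale=amp_scale,
        coupled_pairs=[],
        groups=dict(config.groups),
        latent_log_rates=latents,
    )
    if config.treatment_effects:
        phases = {r.recording_id: (r.phase or "") for r in recordings}
        truth = apply_treatment(truth, config.treatment_effects, phases)
    return truth, recordings


def simulate_plate(config: SimConfig) -> tuple[SpikeTable, GroundTruth]:
    """Generate a labelled spike table for the configured experiment."""
    truth, recordings = build_ground_truth(config)
    layout = config.layout
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[1])

    # per-electrode noise level (a configurable fraction are "high-noise")
    noise_sd = {}
    for well in layout.well_labels:
        for elec in range(1, layout.electrodes_per_well + 1):
            mult = (
                config.high_noise_multiplier
                if rng.random() < config.high_noise_electrode_frac
                else 1.0
            )
            noise_sd[(well, elec)] = config.noise_sd * mult

    by_well: dict[str, list[str]] = {}
    for nid, nr in truth.neurons.items():
        by_well.setdefault(nr.well, []).append(nid)

    # coupled pairs are a property of the culture: fixed per well, shared
    # by every recording
    well_pairs: dict[str, list[tuple[str, str]]] = {}
    for w_idx, well in enumerate(layout.well_labels):
        nids = by_well.get(well, [])
        if not nids:
            continue
        pair_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=(500 + w_idx,))
        )
        firing = [n for n in nids if truth.rate_table.loc[n, recordings[0].recording_id] > 0]
        pair_rng.shuffle(firing)
        n_pairs = int(np.floor(config.coupling.fraction * len(firing) / 2.0))
        well_pairs[well] = [(firing[2 * k], firing[2 * k + 1]) for k in range(n_pairs)]

    events: list[SpikeEvent] = []
    coupled: list[tuple[str, str]] = sorted(p for ps in well_pairs.values() for p in ps)
    for rec in recordings:
        rid = rec.recording_id
        for w_idx, well in enumerate(layout.well_labels):
            nids = by_well.get(well, [])
            if not nids:
                continue
            rates = {nid: float(truth.rate_table.loc[nid, rid]) for nid in nids}
            sub_seed = int(
                np.random.SeedSequence(
                    entropy=ss.entropy, spawn_key=(1000 + w_idx, recordings.index(rec))
                ).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            trains, _ = simulate_trains(
                rates,
                rec.duration,
                config.coupling,
                seed=sub_seed,
                fixed_pairs=well_pairs[well],
            )
            ev_rng = np.random.default_rng(sub_seed + 1)
            for nid in nids:
                neuron = truth.neurons[nid]
                amp_mult = float(truth.amp_scale.loc[nid, rid])
                sd = noise_sd[(neuron.well, neuron.electrode)]
                thr = config.detect_k_sd * sd
                for t in trains[nid]:
                    wave = neuron.template * amp_mult + ev_rng.normal(0.0, sd, neuron.template.size)
                    events.append(
                        SpikeEvent(
                            well=neuron.well,
                            electrode=neuron.electrode,
                            recording_id=rid,
                            timestamp=float(min(t, rec.duration)),
                            crossing_threshold=float(thr),
                            waveform=wave,
                            truth_neuron=nid,
                        )
                    )
    truth.coupled_pairs = coupled
    table = SpikeTable(
        layout=layout,
        recordings=recordings,
        events=events,
        pre_ms=1.0,
        post_ms=2.0,
    )
    return table, truth


# ---------------------------------------------------------------------------
# raw traces


def synth_raw_trace(
    neurons: list[tuple[np.ndarray, np.ndarray]],
    duration: float,
    noise_sd: float,
    rate: float,
    bandpass: tuple[float, float] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Raw voltage trace: template sums at true times plus white noise.

    ``neurons`` is a list of (template, spike_times) pairs; templates
    are inserted with their crossing sample at each spike time.  An
    optional second-order zero-phase Butterworth band-pass mirrors
    acquisition filtering.  Intended for short test traces (<= 60 s).
    Returns (trace, true spike times per neuron).
    """
    if duration > 60.0:
        raise ValueError("raw-trace mode is limited to 60 s")
    n = int(round(duration * rate))
    rng = np.random.default_rng(seed)
    trace = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    c_idx = crossing_index(1.0, rate)
    truth_times = []
    for template, times in neurons:
        times = np.asarray(times, dtype=float)
        truth_times.append(times)
        for t in times:
            start = int(round(t * rate)) - c_idx
            lo, hi = max(start, 0), min(start + template.size, n)
            trace[lo:hi] += template[lo - start : hi - start]
    if bandpass is not None:
        low, high = bandpass
        b, a = butter(2, [low, high], btype="bandpass", fs=rate)
        trace = filtfilt(b, a, trace)
    return trace, truth_times
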