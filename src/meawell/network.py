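"""Functional-connectivity inference from sorted spike trains.

Pairwise firing correlation between putative neurons on an array is
quantified by the spike time tiling coefficient (STTC),

    STTC = 1/2 * [ (P_A - T_B)/(1 - P_A*T_B) + (P_B - T_A)/(1 - P_B*T_A) ],

where T_X is the fraction of the recording tiled by +-dt windows
around train X's spikes (overlaps merged, clipped to the recording)
and P_X is the fraction of X's spikes falling within +-dt of any spike
of the other train.  The default window dt is 100 ms.  Unlike raw
cross-correlation counts, the statistic is insensitive to the firing
rates of the two trains.

An observed pair is called a functional edge when its STTC falls
outside the central 99% of a null distribution built from random spike
trains with the same event counts (1000 permutations, quantiles
0.5% / 99.5%).  Per array and recording the validated edges form an
undirected graph summarized by the average local clustering
coefficient, isolates counted as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .interchange import SpikeTable
from .sorting import SpikeCluster


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one cluster in one recording."""

    cluster_id: str
    recording_id: str
    times: np.ndarray  # strictly increasing, seconds
    duration: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size and (t.min() < 0 or t.max() > self.duration):
            raise ValueError("spike times outside [0, duration]")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.times)


@dataclass
class STTCPair:
    cluster_a: str
    cluster_b: str
    sttc: float
    null_lo: float
    null_hi: float
    is_edge: bool
    n_permutations: int


@dataclass
class FunctionalNetwork:
    """STTC-validated graph of one array in one recording."""

    array_key: tuple[str, str]  # (well, recording_id)
    nodes: list[str]
    edges: list[STTCPair]
    cbar: float

    @property
    def edge_pairs(self) -> set[frozenset]:
        return {frozenset((e.cluster_a, e.cluster_b)) for e in edges_of(self)}


def edges_of(net: FunctionalNetwork) -> list[STTCPair]:
    return [e for e in net.edges if e.is_edge]


def _tiled_fraction(times: np.ndarray, dt: float, duration: float) -> float:
    """Fraction of [0, duration] covered by the union of +-dt windows."""
    if times.size == 0:
        return 0.0
    starts = np.clip(times - dt, 0.0, duration)
    ends = np.clip(times + dt, 0.0, duration)
    # times sorted => starts sorted; merge overlapping windows in one pass
    gaps = np.maximum(starts[1:] - ends[:-1], 0.0)
    total = (ends[-1] - starts[0]) - gaps.sum()
    return float(total / duration)


def _prop_within(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Fraction of spikes in a lying within +-dt of any spike in b."""
    if a.size == 0:
        return 0.0
    j = np.searchsorted(b, a)
    near = np.zeros(a.size, dtype=bool)
    left_ok = j > 0
    near[left_ok] = a[left_ok] - b[j[left_ok] - 1] <= dt
    right_ok = j < b.size
    near[right_ok] |= b[j[right_ok]] - a[right_ok] <= dt
    return float(near.mean())


def sttc(a: SpikeTrain, b: SpikeTrain, dt: float = 0.1) -> float:
    """Spike time tiling coefficient of two trains (window +-dt seconds).

    A term whose denominator 1 - P*T vanishes contributes 0 (this
    occurs when one train's windows tile the entire recording).
    Raises on empty trains; callers skip those pairs.
    """
    if a.n == 0 or b.n == 0:
        raise ValueError("STTC undefined for empty trains")
    if a.duration != b.duration:
        raise ValueError("trains must share a recording duration")
    ta = _tiled_fraction(np.asarray(a.times, float), dt, a.duration)
    tb = _tiled_fraction(np.asarray(b.times, float), dt, b.duration)
    pa = _prop_within(np.asarray(a.times, float), np.asarray(b.times, float), dt)
    pb = _prop_within(np.asarray(b.times, float), np.asarray(a.times, float), dt)
    total = 0.0
    if 1.0 - pa * tb != 0.0:
        total += (pa - tb) / (1.0 - pa * tb)
    if 1.0 - pb * ta != 0.0:
        total += (pb - ta) / (1.0 - pb * ta)
    return 0.5 * total


def sttc_null(
    n_a: int,
    n_b: int,
    duration: float,
    dt: float = 0.1,
    n_perm: int = 1000,
    quantiles: tuple[float, float] = (0.005, 0.995),
    seed: int = 0,
    shuffle_from: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Null STTC distribution for a pair with the observed spike counts.

    Each permutation draws n_a and n_b uniform-random spike times on
    [0, duration] (homogeneous-Poisson-like surrogates with matched
    counts) and records their STTC.  Passing ``shuffle_from`` switches
    to an inter-spike-interval shuffle of the two observed trains,
    which preserves each train's interval distribution.  Returns the
    requested empirical quantiles and the full null vector.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("spike counts must be >= 1")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_perm)
    for k in range(n_perm):
        if shuffle_from is None:
            ta = np.sort(rng.random(n_a) * duration)
            tb = np.sort(rng.random(n_b) * duration)
        else:
            ta = _isi_shuffle(shuffle_from[0], duration, rng)
            tb = _isi_shuffle(shuffle_from[1], duration, rng)
        vals[k] = sttc(
            SpikeTrain("a", "r", ta, duration),
            SpikeTrain("b", "r", tb, duration),
            dt,
        )
    lo, hi = np.quantile(vals, quantiles)
    return float(lo), float(hi), vals


def _isi_shuffle(times: np.ndarray, duration: float, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of inter-spike intervals with a random offset."""
    t = np.sort(np.asarray(times, float))
    isi = np.diff(np.concatenate([[0.0], t]))
    new = np.cumsum(rng.permutation(isi))
    slack = duration - new[-1]
    return np.sort((new + rng.random() * max(slack, 0.0)) % duration)


def call_edges(
    pairs: dict[tuple[str, str], float],
    nulls: dict[tuple[str, str], tuple[float, float]],
    n_permutations: int = 1000,
) -> list[STTCPair]:
    """Flag pairs whose observed STTC lies outside the null interval."""
    if set(pairs) != set(nulls):
        raise ValueError("pair keys of observed and null values do not match")
    out = []
    for key in sorted(pairs):
        obs = pairs[key]
        lo, hi = nulls[key]
        out.append(
            STTCPair(
                cluster_a=key[0],
                cluster_b=key[1],
                sttc=obs,
                null_lo=lo,
                null_hi=hi,
                is_edge=bool(obs < lo or obs > hi),
                n_permutations=n_permutations,
            )
        )
    return out


def clustering_coefficient(nodes: list[str], edges: list[tuple[str, str]]) -> float:
    """Average local clustering coefficient, isolates counted as zero."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if g.number_of_nodes() == 0:
        return 0.0
    return float(np.mean(list(nx.clustering(g).values())))


def trains_by_cluster(
    table: SpikeTable, clusters: list[SpikeCluster], recording_id: str
) -> dict[str, SpikeTrain]:
    """One SpikeTrain per cluster for a recording (silent clusters omitted)."""
    duration = table.recording(recording_id).duration
    out = {}
    for c in clusters:
        t = np.array(
            sorted(
                table.events[i].timestamp
                for i in c.member_events
                if table.events[i].recording_id == recording_id
            )
        )
        t = np.unique(t)
        if t.size:
            out[c.cluster_id] = SpikeTrain(c.cluster_id, recording_id, t, duration)
    return out


def build_networks(
    table: SpikeTable,
    clusters: list[SpikeCluster],
    dt: float = 0.1,
    n_perm: int = 1000,
    quantiles: tuple[float, float] = (0.005, 0.995),
    seed: int = 0,
) -> list[FunctionalNetwork]:
    """Per (well, recording) functional network over that array's clusters."""
    nets = []
    by_well: dict[str, list[SpikeCluster]] = {}
    for c in clusters:
        by_well.setdefault(c.electrode_key[0], []).append(c)
    ss = np.random.SeedSequence(seed)
    pair_counter = 0  # iteration order is deterministic, so a running index seeds each null
    for well in sorted(by_well):
        for rid in table.recording_ids:
            trains = trains_by_cluster(table, by_well[well], rid)
            node_ids = sorted(trains)
            obs: dict[tuple[str, str], float] = {}
            nulls: dict[tuple[str, str], tuple[float, float]] = {}
            for i, a in enumerate(node_ids):
                for b in node_ids[i + 1 :]:
                    obs[(a, b)] = sttc(trains[a], trains[b], dt)
                    child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(pair_counter,))
                    pair_counter += 1
                    lo, hi, _ = sttc_null(
                        trains[a].n,
                        trains[b].n,
                        trains[a].duration,
                        dt=dt,
                        n_perm=n_perm,
                        quantiles=quantiles,
                        seed=child.generate_state(1)[0] & 0x7FFFFFFF,
                    )
                    nulls[(a, b)] = (lo, hi)
            pairs = call_edges(obs, nulls, n_permutations=n_perm)
            cbar = clustering_coefficient(
                node_ids, [(e.cluster_a, e.cluster_b) for e in pairs if e.is_edge]
            )
            nets.append(
                FunctionalNetwork(array_key=(well, rid), nodes=node_ids, edges=pairs, cbar=cbar)
            )
    return nets
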