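"""Unsupervised, recording-independent spike sorting.

Each electrode's spike events are pooled across *all* recordings of an
experiment before clustering, so that a putative neuron keeps one
identity over time instead of being re-derived per session.  Six shape
descriptors are computed per waveform (peak, valley, amplitude,
peak-valley interval, area under the curve, non-linear energy), log
transformed, projected onto the first two principal components, and
clustered by Gaussian-kernel mean-shift (default bandwidth h = 1.5).
Each cluster is represented by the member waveform nearest its
PC-space mode.

Longitudinal activity of a cluster across chronological recordings is
classified into one of four paradigms: persistent, lost, recovering,
or emergent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.decomposition import PCA

from .interchange import RecordingMeta, SpikeTable

LOG_EPS = 1e-6  # offset inside log10(|x| + eps): valley, AUC and NLE can be <= 0


class FiringPattern(str, Enum):
    PERSISTENT = "persistent"
    LOST = "lost"
    RECOVERING = "recovering"
    EMERGENT = "emergent"


@dataclass(frozen=True)
class WaveformFeatures:
    """Shape descriptors of one spike waveform."""

    peak: float  # uV
    valley: float  # uV
    amplitude: float  # uV, peak - valley
    peak_valley_interval: float  # ms
    auc: float  # uV*ms, signed trapezoidal integral
    nle: float  # uV^2, max of psi(x_n) = x_n^2 - x_{n-1} x_{n+1}

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.peak, self.valley, self.amplitude, self.peak_valley_interval, self.auc, self.nle]
        )


@dataclass
class SpikeCluster:
    """A putative single neuron: one electrode's events grouped by shape."""

    electrode_key: tuple[str, int]  # (well, electrode)
    cluster_id: str
    member_events: list[int]  # indices into the table's event list
    centroid_pc: np.ndarray  # 2-vector, PC space
    representative_event: int
    representative_amplitude: float  # uV


def extract_features(waveform: np.ndarray, rate: float) -> WaveformFeatures:
    """Compute the six shape descriptors of a waveform sampled at ``rate``."""
    v = np.asarray(waveform, dtype=float)
    if v.size < 3:
        raise ValueError("waveform must have at least 3 samples")
    i_peak = int(np.argmax(v))
    i_valley = int(np.argmin(v))
    dt_ms = 1000.0 / rate
    t = np.arange(v.size) * dt_ms
    psi = v[1:-1] ** 2 - v[:-2] * v[2:]
    return WaveformFeatures(
        peak=float(v[i_peak]),
        valley=float(v[i_valley]),
        amplitude=float(v[i_peak] - v[i_valley]),
        peak_valley_interval=float(abs(i_peak - i_valley) * dt_ms),
        auc=float(np.trapezoid(v, t)),
        nle=float(psi.max()),
    )


def nle_profile(waveform: np.ndarray) -> np.ndarray:
    """Per-sample non-linear energy psi over interior samples."""
    v = np.asarray(waveform, dtype=float)
    return v[1:-1] ** 2 - v[:-2] * v[2:]


def embed_features(
    features: list[WaveformFeatures], scale: bool = False
) -> np.ndarray:
    """Project log-transformed features onto the first two PCs.

    Feature magnitudes are mapped x -> ln(|x| + 1e-6): the natural log
    (the convention of the statistical environment this procedure comes
    from), with magnitudes because valley, AUC and NLE may be
    non-positive.  Columns are mean-centered (optionally unit-variance
    scaled) and scores on the first two principal components returned,
    PC1 variance >= PC2 variance.  The scale matters: the downstream
    mean-shift bandwidth (default 1.5) is calibrated to natural-log
    PC scores.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 events to embed")
    x = np.stack([f.as_array() for f in features])
    x = np.log(np.abs(x) + LOG_EPS)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    if np.allclose(x, 0):
        return np.zeros((len(features), 2))
    pca = PCA(n_components=2, svd_solver="full")
    k = min(2, min(x.shape))
    scores = pca.fit_transform(x)[:, :k]
    if k < 2:
        scores = np.column_stack([scores, np.zeros(len(features))])
    return scores


def mean_shift(
    points: np.ndarray,
    bandwidth: float = 1.5,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel mean-shift mode seeking.

    Every point is iteratively moved to the Gaussian-weighted mean of
    the *original* sample (kernel exp(-||d||^2 / (2 h^2))) until the
    largest displacement falls below ``tol``.  Converged positions
    within h/10 of one another are merged into a single mode; modes are
    numbered in discovery order.  Returns (labels, modes).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite points")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x = pts.copy()
    inv2h2 = 1.0 / (2.0 * bandwidth**2)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-d2 * inv2h2)
        new = (w @ pts) / w.sum(axis=1, keepdims=True)
        shift = np.linalg.norm(new - x, axis=1).max()
        x = new
        if shift < tol:
            break
    merge_radius = bandwidth / 10.0
    modes: list[np.ndarray] = []
    labels = np.empty(len(x), dtype=int)
    for i, p in enumerate(x):
        for k, m in enumerate(modes):
            if np.linalg.norm(p - m) <= merge_radius:
                labels[i] = k
                break
        else:
            modes.append(p)
            labels[i] = len(modes) - 1
    return labels, np.array(modes)


def map_centroid(mode: np.ndarray, member_points: np.ndarray) -> int:
    """Index of the member point nearest the mode (ties -> lowest index)."""
    pts = np.atleast_2d(np.asarray(member_points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("no member points")
    d = np.linalg.norm(pts - np.asarray(mode, dtype=float), axis=1)
    return int(np.argmin(d))


def sort_spikes(
    table: SpikeTable, bandwidth: float = 1.5
) -> tuple[SpikeTable, list[SpikeCluster]]:
    """Cluster every electrode's pooled events into putative neurons.

    Events are pooled across all recordings per (well, electrode) so
    the clustering — and hence cluster identity — does not depend on
    how spikes were split across recording sessions.  Cluster ids are
    ``{well}_{electrode}_{k}``.  Electrodes with fewer than 3 events
    form a single flagged cluster.
    """
    rate = table.layout.sampling_rate
    by_electrode: dict[tuple[str, int], list[int]] = {}
    for i, e in enumerate(table.events):
        by_electrode.setdefault((e.well, e.electrode), []).append(i)

    clusters: list[SpikeCluster] = []
    out = table.subset([e for e in table.events])
    for (well, elec), idxs in sorted(by_electrode.items()):
        # stable within-electrode order regardless of recording split
        idxs = sorted(idxs, key=lambda i: (out.events[i].timestamp, i))
        waves = [out.events[i].waveform for i in idxs]
        if len(idxs) < 3:
            warnings.warn(
                f"electrode {well}/{elec}: {len(idxs)} events, too few to sort; single cluster",
                stacklevel=2,
            )
            labels = np.zeros(len(idxs), dtype=int)
            modes = np.zeros((1, 2))
            pcs = np.zeros((len(idxs), 2))
        else:
            feats = [extract_features(w, rate) for w in waves]
            pcs = embed_features(feats)
            labels, modes = mean_shift(pcs, bandwidth=bandwidth)
        for k in range(labels.max() + 1):
            members = [idxs[j] for j in np.flatnonzero(labels == k)]
            member_pcs = pcs[labels == k]
            rep_local = map_centroid(modes[k], member_pcs)
            rep = members[rep_local]
            w = out.events[rep].waveform
            cid = f"{well}_{elec}_{k + 1}"
            for i in members:
                out.events[i].cluster_id = cid
            clusters.append(
                SpikeCluster(
                    electrode_key=(well, elec),
                    cluster_id=cid,
                    member_events=members,
                    centroid_pc=np.asarray(modes[k], dtype=float),
                    representative_event=rep,
                    representative_amplitude=float(w.max() - w.min()),
                )
            )
    return out, clusters


def classify_pattern(active: list[bool] | np.ndarray) -> FiringPattern:
    """Classify a cluster's chronological activity vector.

    persistent: active in every recording; lost: active first, silent
    through the end; recovering: active first, silent for an interior
    run, active again; emergent: silent first, active later (any
    subsequent silence does not re-classify).
    """
    a = np.asarray(active, dtype=bool)
    if a.size < 2:
        raise ValueError("need at least 2 recordings")
    if not a.any():
        raise ValueError("all-false activity vector: no such cluster")
    if a.all():
        return FiringPattern.PERSISTENT
    if not a[0]:
        return FiringPattern.EMERGENT
    first_false = int(np.flatnonzero(~a)[0])
    if not a[first_false:].any():
        return FiringPattern.LOST
    return FiringPattern.RECOVERING


def cluster_frequency(
    cluster: SpikeCluster, table: SpikeTable, recording: RecordingMeta
) -> float:
    """Firing rate (Hz) of a cluster within one recording; 0 if silent."""
    n = sum(
        1
        for i in cluster.member_events
        if table.events[i].recording_id == recording.recording_id
    )
    return n / recording.duration


def cluster_activity_matrix(
    clusters: list[SpikeCluster], table: SpikeTable
) -> dict[str, np.ndarray]:
    """Per-cluster boolean activity over the table's chronological recordings."""
    order = {rid: i for i, rid in enumerate(table.recording_ids)}
    out = {}
    for c in clusters:
        act = np.zeros(len(order), dtype=bool)
        for i in c.member_events:
            act[order[table.events[i].recording_id]] = True
        out[c.cluster_id] = act
    return out
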