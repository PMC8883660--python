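"""Per-channel spike sorting and noise-cluster rejection.

The original study sorted spikes with superparamagnetic clustering followed
by supervised visual curation. Neither the clustering algorithm nor the
manual curation is this pipeline's contribution, so the stage is a
deterministic, pluggable stand-in: waveform cutouts are projected onto
principal components and partitioned by k-means, with the cluster count
chosen by the silhouette criterion, and units are auto-labelled
``neural``/``noise`` by two quantitative rules (refractory-violation
fraction and amplitude consistency). Externally sorted trains can be
imported via the CSV interface, bypassing this module entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .core import UnitSpikeTrain
from .detection import SpikeEvents


@dataclass(frozen=True)
class SortConfig:
    """Sorting and noise-rule parameters.

    ``silhouette_floor`` is the score a split must beat for more than one
    cluster to be accepted (a single homogeneous cloud never reaches it);
    ties in the silhouette criterion break toward fewer clusters.
    """

    n_features: int = 3
    max_clusters_per_channel: int = 5
    min_cluster_size: int = 20
    silhouette_floor: float = 0.5
    refractory_violation_max: float = 0.02  # max fraction of ISIs < 1 ms
    refractory_isi: float = 0.001
    #: amplitude-consistency rule, x noise SD. Set slightly above the
    #: detector's peak-to-peak threshold factor (8) so clusters hugging the
    #: detection threshold — noise crossings, not units — are rejected.
    amplitude_floor_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.max_clusters_per_channel < 1:
            raise ValueError("max_clusters_per_channel must be >= 1")


@dataclass
class SortedUnit:
    """One putative unit on one channel, with sorting provenance."""

    unit_id: str
    region: str
    channel: int
    timestamps: np.ndarray
    mean_peak_to_peak: float
    event_indices: np.ndarray
    label: str = "neural"

    def to_spike_train(self) -> UnitSpikeTrain:
        return UnitSpikeTrain(
            unit_id=self.unit_id,
            region=self.region,
            timestamps=self.timestamps,
            channel=self.channel,
            label=self.label,
            provenance="detected",
        )


def cluster_channel(
    events: SpikeEvents,
    config: SortConfig | None = None,
    seed: int = 0,
    *,
    region: str = "RFA",
) -> list[SortedUnit]:
    """Partition one channel's detected events into putative units.

    Cutouts are reduced to ``n_features`` principal components and clustered
    with k-means for k = 1..max_clusters_per_channel; the silhouette-best k
    wins (k = 1 unless some split clears ``silhouette_floor``). Fewer than
    ``min_cluster_size`` events form a single unit without clustering.
    Deterministic given the seed. Every input event is assigned to exactly
    one unit.
    """
    config = config or SortConfig()
    if events.cutouts is None:
        raise ValueError("events must carry cutouts; run extract_cutouts first")
    n = events.n_events
    if n == 0:
        return []
    if n < config.min_cluster_size:
        assignment = np.zeros(n, dtype=int)
        n_clusters = 1
    else:
        aligned = _realign_cutouts(events.cutouts)
        feats = PCA(
            n_components=min(config.n_features, n, aligned.shape[1]),
            random_state=seed,
        ).fit_transform(aligned)
        best_k, best_score, best_labels = 1, config.silhouette_floor, np.zeros(n, dtype=int)
        k_max = min(config.max_clusters_per_channel, n - 1)
        for k in range(2, k_max + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(feats)
            if len(np.unique(km.labels_)) < 2:
                continue
            # a split that carves off fewer events than a credible unit
            # (min_cluster_size) is overfitting waveform overlaps, not units
            if np.bincount(km.labels_).min() < config.min_cluster_size:
                continue
            score = silhouette_score(feats, km.labels_)
            if score > best_score:  # strict: ties break toward fewer clusters
                best_k, best_score, best_labels = k, score, km.labels_
        assignment, n_clusters = best_labels, best_k
    units = []
    order = np.argsort([-np.sum(assignment == c) for c in range(n_clusters)])
    for rank, c in enumerate(order):
        idx = np.flatnonzero(assignment == c)
        ts = events.times[idx]
        srt = np.argsort(ts)
        idx, ts = idx[srt], ts[srt]
        ts, keep = _dedupe(ts)
        idx = idx[keep]
        units.append(
            SortedUnit(
                unit_id=f"ch{events.channel}u{rank}",
                region=region,
                channel=events.channel,
                timestamps=ts,
                mean_peak_to_peak=float(np.mean(events.peak_to_peak[idx])),
                event_indices=idx,
            )
        )
    return units


def _realign_cutouts(
    cutouts: np.ndarray, max_shift: int = 2, n_iter: int = 2
) -> np.ndarray:
    """Shift each cutout by up to ``max_shift`` samples onto the mean waveform.

    Threshold detection aligns events to the nearest sample, so a spike whose
    true extremum falls between grid points lands on either neighbour; the
    resulting one-sample jitter would otherwise split one unit into several
    shape clusters. Realignment is used for feature extraction only; stored
    cutouts and event times are untouched.
    """
    x = cutouts.copy()
    shifts = range(-max_shift, max_shift + 1)
    for _ in range(n_iter):
        template = x.mean(axis=0)
        stacks = np.stack([np.roll(x, s, axis=1) for s in shifts])
        sse = ((stacks - template) ** 2).sum(axis=2)  # (n_shifts, n_events)
        best = np.argmin(sse, axis=0)
        x = stacks[best, np.arange(x.shape[0])]
    return x


def _dedupe(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strictly-increasing view of sorted times (drops exact duplicates)."""
    if ts.size <= 1:
        return ts, np.arange(ts.size)
    keep = np.concatenate([[True], np.diff(ts) > 0])
    return ts[keep], np.flatnonzero(keep)


def apply_noise_rules(
    units: list[SortedUnit],
    config: SortConfig | None = None,
    noise_sd: float | None = None,
) -> list[SortedUnit]:
    """Label each unit ``neural`` or ``noise``.

    A unit is a noise cluster if (a) more than ``refractory_violation_max``
    of its ISIs are shorter than 1 ms — a physiologically impossible rate of
    refractory violations for a single neuron — or (b) its mean cutout
    peak-to-peak amplitude falls below ``amplitude_floor_factor`` times the
    channel noise SD. All downstream analyses consume only neural units.
    """
    config = config or SortConfig()
    out = []
    for u in units:
        label = "neural"
        isis = np.diff(u.timestamps)
        if isis.size:
            frac_violation = float(np.mean(isis < config.refractory_isi))
            if frac_violation > config.refractory_violation_max:
                label = "noise"
        if (
            noise_sd is not None
            and u.mean_peak_to_peak < config.amplitude_floor_factor * noise_sd
        ):
            label = "noise"
        u.label = label
        out.append(u)
    return out


def neural_trains(units: list[SortedUnit]) -> list[UnitSpikeTrain]:
    """Spike trains of the units labelled neural, ready for analysis."""
    return [u.to_spike_train() for u in units if u.label == "neural"]
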