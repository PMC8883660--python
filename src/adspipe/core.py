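"""Shared data containers for the analysis pipeline.

The pipeline operates on two in-memory objects throughout: a
:class:`ContinuousRecording` (channels x samples voltage matrix with channel
metadata) and a :class:`UnitSpikeTrain` (sorted spike timestamps of one
putative single unit). Timestamps are seconds from recording start, sample
indices are 0-based, and all time intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REGIONS = ("RFA", "S1")

DEFAULT_SAMPLE_RATE = 30_000.0


@dataclass
class UnitSpikeTrain:
    """Spike timestamps of one putative single unit.

    Parameters
    ----------
    unit_id : str
        Unique unit identifier.
    region : str
        Cortical region the unit was recorded from, ``"RFA"`` or ``"S1"``.
    timestamps : ndarray
        Spike times in seconds, strictly increasing.
    channel : int, optional
        Recording channel the unit was isolated on.
    label : str
        ``"neural"`` or ``"noise"``; only neural units enter the analyses.
    provenance : str
        ``"ground_truth"`` for simulated trains, ``"detected"`` for trains
        recovered by detection + sorting.
    """

    unit_id: str
    region: str
    timestamps: np.ndarray
    channel: int | None = None
    label: str = "neural"
    provenance: str = "ground_truth"

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.ndim != 1:
            raise ValueError("timestamps must be a 1-d array")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError(f"unit {self.unit_id}: timestamps must be strictly increasing")
        self.timestamps = ts

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)

    def with_timestamps(self, timestamps: np.ndarray) -> "UnitSpikeTrain":
        """Copy of this unit with new spike times (metadata preserved)."""
        return replace(self, timestamps=np.asarray(timestamps, dtype=float))

    def count_in(self, start: float, end: float) -> int:
        """Number of spikes in the half-open interval [start, end)."""
        lo, hi = np.searchsorted(self.timestamps, [start, end], side="left")
        return int(hi - lo)

    def slice(self, start: float, end: float) -> np.ndarray:
        """Spike times falling in [start, end)."""
        lo, hi = np.searchsorted(self.timestamps, [start, end], side="left")
        return self.timestamps[lo:hi]


def make_channel_table(
    n_per_region: int = 16, n_shanks: int = 4, regions: tuple[str, ...] = REGIONS
) -> pd.DataFrame:
    """Build the channel -> (region, shank, site) map for two implanted arrays.

    Mirrors the four-shank, sixteen-site layout of the implants: channels
    ``0..n-1`` belong to the first region, ``n..2n-1`` to the second.
    """
    rows = []
    ch = 0
    sites_per_shank = max(1, n_per_region // n_shanks)
    for region in regions:
        for k in range(n_per_region):
            rows.append(
                {
                    "channel": ch,
                    "region": region,
                    "shank": k // sites_per_shank,
                    "site": k % sites_per_shank,
                }
            )
            ch += 1
    return pd.DataFrame(rows)


@dataclass
class ContinuousRecording:
    """Multi-channel sampled extracellular voltage trace.

    ``samples`` is a (channels, time) matrix in microvolts. Each channel maps
    to exactly one region via ``channel_table`` (columns ``channel``,
    ``region``, ``shank``, ``site``).
    """

    samples: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    channel_table: pd.DataFrame = field(default_factory=make_channel_table)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if len(self.channel_table) != self.n_channels:
            raise ValueError(
                f"channel_table has {len(self.channel_table)} rows for "
                f"{self.n_channels} channels"
            )
        regions = set(self.channel_table["region"])
        if not regions.issubset(REGIONS):
            raise ValueError(f"unknown regions in channel_table: {regions - set(REGIONS)}")

    @property
    def n_channels(self) -> int:
        return int(self.samples.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[1])

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / sample_rate)."""
        return self.n_samples / self.sample_rate

    def channels_of(self, region: str) -> np.ndarray:
        """Channel indices belonging to one region."""
        tab = self.channel_table
        return tab.loc[tab["region"] == region, "channel"].to_numpy()

    def region_of(self, channel: int) -> str:
        tab = self.channel_table
        return str(tab.loc[tab["channel"] == channel, "region"].iloc[0])


def spawn_seeds(seed: int, n: int, *, salt: int = 0) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one master seed.

    Deterministic: the same (seed, salt) always yields the same children.
    """
    ss = np.random.SeedSequence([int(seed), int(salt)])
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n, dtype=np.uint64)]
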