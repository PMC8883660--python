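"""Experimental phase schedule and per-unit, per-phase mean firing rates.

The experiment has two arms. Control (CTR) animals are recorded through a
20-min pre-lesion baseline (PreL), a 60-min post-lesion hour analysed as
three consecutive 20-min thirds (PoL1-3), then a 20-min pre-stimulation
period (PreS), a 60-min sham-stimulation period (Stim, 0 uA), and a 20-min
post-stimulation period (PoS). Stimulated (ADS) animals are implanted after
the lesion, so their timeline is PreS / Stim / PoS only.

Firing is quantified as the mean firing rate (MFR, spikes/s) of each unit
within each phase, with a minimum-rate inclusion filter of 0.01 spikes/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import UnitSpikeTrain

#: canonical phase durations in seconds (20-min phases; Stim is an hour)
PHASE_DURATIONS = {
    "PreL": 1200.0,
    "PoL1": 1200.0,
    "PoL2": 1200.0,
    "PoL3": 1200.0,
    "PreS": 1200.0,
    "Stim": 3600.0,
    "PoS": 1200.0,
}

CTR_PHASES = ("PreL", "PoL1", "PoL2", "PoL3", "PreS", "Stim", "PoS")
ADS_PHASES = ("PreS", "Stim", "PoS")

#: default minimum MFR for a unit to be considered at all
MIN_RATE = 0.01


class ScheduleError(ValueError):
    """Inconsistent phase anchors or overlapping phases."""


@dataclass
class PhaseSchedule:
    """Named, ordered, non-overlapping recording epochs of one experiment.

    ``phases`` maps phase name to a half-open ``[start, end)`` interval in
    seconds. Insertion order is the temporal order and is validated.
    """

    group: str
    phases: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("CTR", "ADS"):
            raise ScheduleError(f"unknown group {self.group!r}")
        prev_end = -np.inf
        for name, (start, end) in self.phases.items():
            if end <= start:
                raise ScheduleError(f"phase {name}: empty or inverted interval")
            if start < prev_end:
                raise ScheduleError(f"phase {name} overlaps the preceding phase")
            prev_end = end

    @property
    def names(self) -> list[str]:
        return list(self.phases)

    def interval(self, name: str) -> tuple[float, float]:
        return self.phases[name]

    def duration(self, name: str) -> float:
        start, end = self.phases[name]
        return end - start

    @property
    def span(self) -> tuple[float, float]:
        starts = [s for s, _ in self.phases.values()]
        ends = [e for _, e in self.phases.values()]
        return min(starts), max(ends)


def build_schedule(
    group: str,
    *,
    start: float = 0.0,
    postlesion_start: float | None = None,
    time_scale: float = 1.0,
) -> PhaseSchedule:
    """Construct the phase timeline of one experimental group.

    For CTR the pre-lesion baseline starts at ``start``; ``postlesion_start``
    anchors the beginning of the post-lesion hour (lesion induction itself is
    not recorded), defaulting to the end of PreL. ADS schedules contain only
    PreS/Stim/PoS starting at ``start``.

    ``time_scale`` uniformly shrinks all phase durations; it exists so the
    full pipeline (including waveform rendering at 30 kHz) can be exercised
    at desk scale. The canonical experiment uses ``time_scale=1``.
    """
    if time_scale <= 0:
        raise ScheduleError("time_scale must be positive")
    dur = {k: v * time_scale for k, v in PHASE_DURATIONS.items()}

    phases: dict[str, tuple[float, float]] = {}
    if group == "CTR":
        t = start
        phases["PreL"] = (t, t + dur["PreL"])
        t += dur["PreL"]
        if postlesion_start is not None:
            if postlesion_start < t:
                raise ScheduleError(
                    f"postlesion_start {postlesion_start} precedes the end of PreL ({t})"
                )
            t = postlesion_start
        for name in ("PoL1", "PoL2", "PoL3", "PreS", "Stim", "PoS"):
            phases[name] = (t, t + dur[name])
            t += dur[name]
    elif group == "ADS":
        t = start
        for name in ADS_PHASES:
            phases[name] = (t, t + dur[name])
            t += dur[name]
    else:
        raise ScheduleError(f"unknown group {group!r}")
    return PhaseSchedule(group=group, phases=phases)


def mean_firing_rate(train: UnitSpikeTrain, interval: tuple[float, float]) -> float:
    """MFR of one unit in a half-open interval: spike count / duration."""
    start, end = interval
    if end <= start:
        raise ValueError("phase interval must have positive duration")
    return train.count_in(start, end) / (end - start)


def rate_table(
    trains: list[UnitSpikeTrain],
    schedule: PhaseSchedule,
    phases: list[str] | None = None,
) -> pd.DataFrame:
    """Per-unit, per-phase MFR table (columns unit_id, region, phase, mfr)."""
    names = list(phases) if phases is not None else schedule.names
    rows = []
    for train in trains:
        for name in names:
            rows.append(
                {
                    "unit_id": train.unit_id,
                    "region": train.region,
                    "phase": name,
                    "mfr": mean_firing_rate(train, schedule.interval(name)),
                }
            )
    return pd.DataFrame(rows, columns=["unit_id", "region", "phase", "mfr"])


def filter_units(rates: pd.DataFrame, min_rate: float = MIN_RATE) -> pd.DataFrame:
    """Apply the minimum-firing-rate inclusion filter (0.01 spikes/s).

    A unit is included if its MFR reaches ``min_rate`` in at least one of the
    analysed phases; a unit below threshold in every phase is dropped from all
    downstream analyses. Applying the filter globally (rather than per phase)
    keeps the unit set constant across compared phases, which the per-unit
    pre/post comparisons require. Returns a copy with an ``included`` column.
    """
    out = rates.copy()
    keep = out.groupby("unit_id")["mfr"].transform("max") >= min_rate
    out["included"] = keep.to_numpy()
    return out


def included_units(rates: pd.DataFrame) -> list[str]:
    """Unit ids passing the inclusion filter (requires ``included`` column)."""
    return sorted(rates.loc[rates["included"], "unit_id"].unique())
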