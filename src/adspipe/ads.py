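"""Event-level simulator of closed-loop activity-dependent stimulation (ADS).

In the closed-loop paradigm a spike detected on a selected premotor (RFA)
trigger channel elicits one intracortical microstimulation pulse in
somatosensory cortex (S1). A blanking period (28 ms by default) follows
each stimulus, during which new triggers are ignored — this prevents
stimulus-evoked spikes and artifacts from re-triggering and caps the
stimulation rate at 1/0.028 ~ 35.7 Hz. Control animals run the identical
loop with the pulse current set to 0 uA.

The simulator works on spike-event streams, not voltages: the recorded
spike train of the chosen trigger channel stands in for the hardware's
voltage-threshold crossings. Pulse shape (charge-balanced biphasic,
cathodal-leading, 200 us per phase) is carried as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .synthetic import DEFAULT_REFRACTORY, GroundTruthTrains, _enforce_refractory


@dataclass(frozen=True)
class ADSConfig:
    """Closed-loop stimulation parameters.

    ``pulse_amplitude`` is 0 uA for the control (CTR) condition and 60 uA for
    stimulated (ADS) animals. ``evoked_probability`` / latency parameters
    govern the simulated per-pulse evoked response in target units (the study
    premise is that each pulse can evoke activity; per-pulse response
    statistics are a generator choice, not a measured quantity).
    """

    blanking_period: float = 0.028
    pulse_amplitude: float = 60.0
    pulse_phase_width: float = 200e-6  # metadata only; cathodal-leading biphasic
    evoked_probability: float = 0.3
    evoked_latency_mean: float = 0.005
    evoked_latency_sd: float = 0.002
    stim_channel: int | None = None

    def __post_init__(self) -> None:
        if self.blanking_period <= 0:
            raise ValueError("blanking_period must be positive")
        if not 0.0 <= self.evoked_probability <= 1.0:
            raise ValueError("evoked_probability must be in [0, 1]")
        if self.pulse_amplitude < 0:
            raise ValueError("pulse_amplitude must be non-negative")


@dataclass
class StimEventLog:
    """Emitted stimulation pulses: times, amplitude, and triggering spikes."""

    times: np.ndarray
    amplitude: float
    trigger_times: np.ndarray
    blanking_period: float = 0.028

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.trigger_times = np.asarray(self.trigger_times, dtype=float)
        if self.times.size != self.trigger_times.size:
            raise ValueError("times and trigger_times must align")
        if self.times.size > 1:
            gaps = np.diff(self.times)
            if np.any(gaps < self.blanking_period - 1e-12):
                raise ValueError("stimulation times violate the blanking period")

    @property
    def n_stimuli(self) -> int:
        return int(self.times.size)

    def rate(self, window: tuple[float, float]) -> float:
        """Mean stimulation rate (Hz) over a time window."""
        start, end = window
        n = np.searchsorted(self.times, end) - np.searchsorted(self.times, start)
        return float(n) / (end - start)


def run_ads(
    trigger_times: np.ndarray,
    config: ADSConfig,
    stim_window: tuple[float, float],
) -> StimEventLog:
    """Run the greedy blanking-gated trigger-to-stimulus rule.

    Scanning triggers in time order, a trigger inside ``stim_window`` emits a
    stimulus at the trigger time unless it falls within ``blanking_period``
    after the previously emitted stimulus (stimulus-anchored blanking; the
    window is half-open ``[start, end)``). The rule is greedy
    and deterministic, so re-running on the same input reproduces the log
    exactly, and no two stimuli are closer than the blanking period.
    """
    triggers = np.asarray(trigger_times, dtype=float)
    if triggers.size > 1 and np.any(np.diff(triggers) < 0):
        raise ValueError("trigger timestamps must be sorted")
    start, end = stim_window
    emitted: list[float] = []
    i = int(np.searchsorted(triggers, start, side="left"))
    n = triggers.size
    while i < n and triggers[i] < end:
        t = triggers[i]
        emitted.append(t)
        # jump straight to the first trigger clear of the blanking window
        i = int(np.searchsorted(triggers, t + config.blanking_period, side="left"))
    times = np.asarray(emitted)
    return StimEventLog(
        times=times,
        amplitude=config.pulse_amplitude,
        trigger_times=times.copy(),
        blanking_period=config.blanking_period,
    )


def apply_stim_effect(
    target_trains: GroundTruthTrains,
    log: StimEventLog,
    config: ADSConfig,
    seed: int | np.random.Generator = 0,
) -> GroundTruthTrains:
    """Add stimulus-evoked spikes to target units.

    With zero pulse amplitude (the CTR condition) the input is returned
    unchanged. Otherwise each stimulus independently evokes, per target unit,
    one spike with probability ``evoked_probability`` at a latency drawn from
    a normal distribution truncated at zero. Evoked spikes falling within the
    unit's refractory floor of an existing (or already-accepted evoked) spike
    are dropped; trains are returned re-sorted.
    """
    if config.pulse_amplitude == 0 or log.n_stimuli == 0:
        return target_trains
    rng = np.random.default_rng(seed)
    out = []
    for tr in target_trains.trains:
        model = target_trains.models.get(tr.unit_id)
        floor = model.refractory_floor if model is not None else DEFAULT_REFRACTORY
        respond = rng.random(log.n_stimuli) < config.evoked_probability
        n_resp = int(respond.sum())
        if n_resp == 0:
            out.append(tr)
            continue
        lat = rng.normal(config.evoked_latency_mean, config.evoked_latency_sd, n_resp)
        while np.any(lat < 0):  # truncate the latency distribution at zero
            bad = lat < 0
            lat[bad] = rng.normal(
                config.evoked_latency_mean, config.evoked_latency_sd, int(bad.sum())
            )
        evoked = np.sort(log.times[respond] + lat)
        merged = _merge_with_refractory(tr.timestamps, evoked, floor)
        out.append(tr.with_timestamps(merged))
    return replace(target_trains, trains=out)


def _merge_with_refractory(
    existing: np.ndarray, added: np.ndarray, floor: float
) -> np.ndarray:
    """Merge added spikes into an existing train, dropping collisions.

    Existing spikes are always kept; an added spike is accepted only if it is
    at least ``floor`` away from the previously kept spike and from the next
    existing spike.
    """
    if added.size == 0:
        return existing
    if existing.size == 0:
        return _enforce_refractory(added, floor)
    merged: list[float] = []
    is_orig = np.concatenate(
        [np.ones(existing.size, dtype=bool), np.zeros(added.size, dtype=bool)]
    )
    all_ts = np.concatenate([existing, added])
    order = np.argsort(all_ts, kind="stable")
    all_ts, is_orig = all_ts[order], is_orig[order]
    last = -np.inf
    # position of the next original spike after each index
    next_orig = np.full(all_ts.size, np.inf)
    nxt = np.inf
    for i in range(all_ts.size - 1, -1, -1):
        next_orig[i] = nxt
        if is_orig[i]:
            nxt = all_ts[i]
    for i in range(all_ts.size):
        t = all_ts[i]
        if is_orig[i]:
            merged.append(t)
            last = t
        elif t - last >= floor and next_orig[i] - t >= floor:
            merged.append(t)
            last = t
    return np.asarray(merged)
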