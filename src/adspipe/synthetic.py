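"""Synthetic ground-truth spike trains and rendered extracellular traces.

Every downstream stage of the pipeline (detection, sorting, rate metrics,
change classification, irregularity) is validated against data produced
here, because the in vivo recordings have no public accession. The
generator works at two levels:

* **event level** — renewal / doubly-stochastic interspike-interval (ISI)
  models produce ground-truth spike trains whose irregularity spans the
  Regular / Random / Bursty range, and per-phase rate multipliers emulate
  the lesion (premotor RFA up, somatosensory S1 down) and stimulation
  (both up, burstier) effects;
* **signal level** — spike trains are rendered into 30 kHz multi-channel
  voltage traces as waveform templates plus Gaussian noise, giving the
  detector a scored benchmark.

ISI-based generation was chosen over biophysical simulation deliberately:
all analysis stages consume spike times only, so a renewal model with a
refractory floor is the minimal sufficient ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ContinuousRecording, UnitSpikeTrain, make_channel_table
from .unit_metrics import PhaseSchedule

#: minimum ISI enforced by default: the ~1 ms absolute refractory period of
#: cortical neurons. Note this is a property of the simulated neurons, not
#: of the detector — the detector separately enforces its own 2 ms dead
#: time ("at most one spike per peak lifetime period"). A 2 ms ground-truth
#: floor would over-regularise burst firing: at a 50 spikes/s intra-burst
#: rate it pushes LvR below the Bursty band the generator must reach.
DEFAULT_REFRACTORY = 0.001

#: gamma ISI shapes placing mean LvR (R = 5 ms) at the center of each
#: firing-pattern band; Lv of a gamma renewal process is 3/(2*kappa + 1),
#: so kappa = 0.5 targets the Bursty center 1.5 (the refractoriness
#: correction then inflates it slightly).
BAND_SHAPES = {"Regular": 4.0, "Random": 1.0, "Bursty": 0.5}


@dataclass(frozen=True)
class ISIModel:
    """Parametric interspike-interval model of one unit.

    ``family`` is one of

    - ``"gamma"`` — renewal process with gamma ISIs of shape ``shape`` (kappa)
      and mean ``1/rate``. kappa > 1 is more regular than Poisson, kappa < 1
      burstier; kappa = 1 is exponential.
    - ``"poisson"`` — gamma with shape fixed at 1.
    - ``"bursty_doubly_stochastic"`` — two-state telegraph rate switching
      between ``burst_rate_high`` and ``burst_rate_low`` with symmetric
      switching rate ``burst_switch_rate``; produces high-irregularity
      (LvR > 1.25) trains like the slow cyclic bursting seen after
      closed-loop stimulation.

    ``refractory_floor`` is added to every drawn ISI and the ISI mean is
    renormalised back to ``1/rate``, so the target rate is preserved.
    """

    family: str = "poisson"
    rate: float = 1.0
    shape: float = 1.0
    burst_rate_high: float = 50.0
    burst_rate_low: float = 0.5
    burst_switch_rate: float = 0.5
    refractory_floor: float = DEFAULT_REFRACTORY

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "poisson", "bursty_doubly_stochastic"):
            raise ValueError(f"unknown ISI family {self.family!r}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        if self.refractory_floor < 0:
            raise ValueError("refractory_floor must be non-negative")
        if self.family == "poisson" and self.shape != 1.0:
            object.__setattr__(self, "shape", 1.0)


def generate_isi_train(
    model: ISIModel, duration: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Simulate one spike train on ``[0, duration)``.

    Returns strictly increasing spike times. Gamma/Poisson trains are renewal
    processes: ISIs are ``refractory_floor + Gamma(shape, scale)`` with the
    scale chosen so the mean ISI equals ``1/rate`` (requires
    ``1/rate > refractory_floor``). The bursty family simulates a symmetric
    two-state telegraph rate and draws Poisson spikes within each state
    dwell, then enforces the refractory floor.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    if model.family in ("gamma", "poisson"):
        mean_isi = 1.0 / model.rate
        free = mean_isi - model.refractory_floor
        if free <= 0:
            raise ValueError(
                f"rate {model.rate}/s is incompatible with a "
                f"{model.refractory_floor * 1e3:.1f} ms refractory floor"
            )
        scale = free / model.shape
        # draw in blocks until the cumulative time exceeds the duration
        times: list[np.ndarray] = []
        t = 0.0
        block = max(64, int(duration * model.rate * 1.25) + 16)
        while t < duration:
            isis = model.refractory_floor + rng.gamma(model.shape, scale, size=block)
            cum = t + np.cumsum(isis)
            times.append(cum)
            t = cum[-1]
        ts = np.concatenate(times)
        return ts[ts < duration]
    # bursty: telegraph process between high and low rate states
    t = 0.0
    state_high = bool(rng.integers(0, 2))
    spikes: list[np.ndarray] = []
    while t < duration:
        dwell = rng.exponential(1.0 / model.burst_switch_rate)
        end = min(t + dwell, duration)
        rate = model.burst_rate_high if state_high else model.burst_rate_low
        n = rng.poisson(rate * (end - t))
        if n:
            spikes.append(np.sort(rng.uniform(t, end, size=n)))
        t = end
        state_high = not state_high
    if not spikes:
        return np.empty(0)
    ts = np.concatenate(spikes)
    return _enforce_refractory(ts, model.refractory_floor)


def _enforce_refractory(ts: np.ndarray, floor: float) -> np.ndarray:
    """Greedy left-to-right pruning so that consecutive ISIs are >= floor."""
    if ts.size <= 1 or floor <= 0:
        return ts
    keep = np.ones(ts.size, dtype=bool)
    last = ts[0]
    for i in range(1, ts.size):
        if ts[i] - last < floor:
            keep[i] = False
        else:
            last = ts[i]
    return ts[keep]


@dataclass
class GroundTruthTrains:
    """A cohort of ground-truth units with their generative models.

    ``multipliers`` maps ``unit_id -> {phase_name: multiplier}``; a
    multiplier m scales the unit's expected rate within that phase (m < 1 by
    thinning, m > 1 by superposing extra Poisson spikes).
    """

    trains: list[UnitSpikeTrain]
    models: dict[str, ISIModel] = field(default_factory=dict)
    multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def unit(self, unit_id: str) -> UnitSpikeTrain:
        for tr in self.trains:
            if tr.unit_id == unit_id:
                return tr
        raise KeyError(unit_id)


def apply_phase_modulation(
    trains: GroundTruthTrains, schedule: PhaseSchedule
) -> GroundTruthTrains:
    """Scale each unit's rate within each phase by its multiplier.

    Within a phase with multiplier m, spikes are independently kept with
    probability m (m <= 1), or kept and superposed with extra homogeneous
    Poisson spikes at rate ``(m - 1) * base_rate`` (m > 1), so the expected
    phase rate is ``m * base_rate``. Spikes outside every phase are left
    unchanged. The result is re-sorted and the unit's refractory floor is
    re-imposed (superposition can otherwise create implausibly short ISIs);
    the ISI family is therefore only approximately preserved under
    modulation. Deterministic given ``trains.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([trains.seed, 0x5EED]))
    out_trains = []
    for tr in trains.trains:
        mults = trains.multipliers.get(tr.unit_id, {})
        model = trains.models.get(tr.unit_id)
        base_rate = model.rate if model is not None else None
        floor = model.refractory_floor if model is not None else DEFAULT_REFRACTORY
        ts = tr.timestamps
        keep = np.ones(ts.size, dtype=bool)
        extra: list[np.ndarray] = []
        changed = False
        for name in schedule.names:
            m = mults.get(name, 1.0)
            if m == 1.0:
                continue
            changed = True
            start, end = schedule.interval(name)
            lo, hi = np.searchsorted(ts, [start, end], side="left")
            if m < 1.0:
                keep[lo:hi] &= rng.random(hi - lo) < m
            else:
                if base_rate is None:
                    raise ValueError(
                        f"unit {tr.unit_id}: boosting requires a known base rate"
                    )
                n = rng.poisson((m - 1.0) * base_rate * (end - start))
                if n:
                    extra.append(rng.uniform(start, end, size=n))
        if not changed:
            out_trains.append(tr)
            continue
        parts = [ts[keep]] + extra
        merged = np.sort(np.concatenate(parts))
        merged = _enforce_refractory(merged, floor)
        out_trains.append(tr.with_timestamps(merged))
    return replace(trains, trains=out_trains)


@dataclass
class WaveformTemplate:
    """Stereotyped action-potential waveform spanning the cutout window.

    ``samples`` covers -0.4 ms to +0.8 ms around the aligned peak at the
    recording sample rate; the alignment point (largest |amplitude|) sits at
    index ``round(0.0004 * sample_rate)``. ``channel_footprint`` maps channel
    index -> gain weight.
    """

    samples: np.ndarray
    sample_rate: float
    channel_footprint: dict[int, float]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        n_expected = round(0.0012 * self.sample_rate) + 1
        if self.samples.size != n_expected:
            raise ValueError(
                f"template length {self.samples.size} != cutout window "
                f"{n_expected} samples"
            )
        align = round(0.0004 * self.sample_rate)
        if int(np.argmax(np.abs(self.samples))) != align:
            raise ValueError("template peak must sit at the alignment point")

    @property
    def align_index(self) -> int:
        return round(0.0004 * self.sample_rate)

    @property
    def peak_to_peak_amplitude(self) -> float:
        return float(self.samples.max() - self.samples.min())


def make_biphasic_template(
    peak_to_peak: float,
    sample_rate: float = 30_000.0,
    channel_footprint: dict[int, float] | None = None,
    *,
    trough_width: float = 2.5e-4,
    rebound_frac: float = 0.45,
) -> WaveformTemplate:
    """Canonical negative-first extracellular spike template.

    A narrow negative (trough) lobe at the alignment point followed by a
    broader positive rebound, built from Gaussian lobes and normalised to the
    requested peak-to-peak amplitude in microvolts. The ~0.25 ms lobe width
    keeps the energy inside the 300-3000 Hz spike band.
    """
    n = round(0.0012 * sample_rate) + 1
    align = round(0.0004 * sample_rate)
    t = (np.arange(n) - align) / sample_rate
    trough = -np.exp(-0.5 * (t / trough_width) ** 2)
    rebound = rebound_frac * np.exp(-0.5 * ((t - 2.8 * trough_width) / (1.8 * trough_width)) ** 2)
    w = trough + rebound
    # recentre: overlapping lobes can shift the extremum off the grid point
    w = np.roll(w, align - int(np.argmax(np.abs(w))))
    w *= peak_to_peak / (w.max() - w.min())
    if channel_footprint is None:
        channel_footprint = {0: 1.0}
    return WaveformTemplate(
        samples=w, sample_rate=sample_rate, channel_footprint=channel_footprint
    )


def render_extracellular(
    trains: GroundTruthTrains | list[UnitSpikeTrain],
    templates: dict[str, WaveformTemplate],
    noise_sd: float,
    *,
    duration: float,
    sample_rate: float = 30_000.0,
    channel_table=None,
    seed: int | np.random.Generator = 0,
) -> tuple[ContinuousRecording, list[str]]:
    """Render spike trains into a continuous multi-channel voltage trace.

    Each spike adds its unit's template (peak sample aligned to the spike
    timestamp with nearest-sample rounding, scaled by the channel footprint)
    on top of zero-mean Gaussian noise of the given SD. Rendering is additive
    over units. Returns the recording and the ids of events whose template
    had to be truncated at a recording edge (``"unit_id@time"``).
    """
    unit_list = trains.trains if isinstance(trains, GroundTruthTrains) else trains
    if channel_table is None:
        n_ch = 1 + max(
            (ch for tpl in templates.values() for ch in tpl.channel_footprint), default=0
        )
        channel_table = make_channel_table(n_per_region=n_ch, regions=("RFA",))
    n_channels = len(channel_table)
    n_samples = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        data = rng.normal(0.0, noise_sd, size=(n_channels, n_samples))
    else:
        data = np.zeros((n_channels, n_samples))
    truncated: list[str] = []
    for tr in unit_list:
        tpl = templates[tr.unit_id]
        w = tpl.samples
        align = tpl.align_index
        centers = np.round(tr.timestamps * sample_rate).astype(np.int64)
        starts = centers - align
        for ch, gain in tpl.channel_footprint.items():
            wav = gain * w
            for t_s, s0 in zip(tr.timestamps, starts):
                s1 = s0 + w.size
                if s0 < 0 or s1 > n_samples:
                    truncated.append(f"{tr.unit_id}@{t_s:.6f}")
                    lo = max(s0, 0)
                    hi = min(s1, n_samples)
                    if hi > lo:
                        data[ch, lo:hi] += wav[lo - s0 : hi - s0]
                else:
                    data[ch, s0:s1] += wav
    rec = ContinuousRecording(
        samples=data, sample_rate=sample_rate, channel_table=channel_table
    )
    return rec, truncated


# ---------------------------------------------------------------------------
# cohort construction for pipeline-level runs

#: per-phase rate multipliers emulating the lesion and stimulation effects:
#: relative to its own baseline, premotor cortex (RFA) speeds up after the
#: lesion while somatosensory cortex (S1) slows down, and closed-loop
#: stimulation raises firing in both regions. Values are the ratios of the
#: reported per-phase group medians to baseline.
DEFAULT_MULTIPLIERS = {
    "CTR": {
        "RFA": {"PreL": 1.0, "PoL1": 1.40, "PoL2": 0.97, "PoL3": 0.73,
                "PreS": 1.17, "Stim": 1.17, "PoS": 1.36},
        "S1": {"PreL": 1.0, "PoL1": 0.68, "PoL2": 0.56, "PoL3": 0.44,
               "PreS": 0.69, "Stim": 0.69, "PoS": 0.99},
    },
    "ADS": {
        "RFA": {"PreS": 1.0, "Stim": 1.25, "PoS": 1.54},
        "S1": {"PreS": 1.0, "Stim": 1.25, "PoS": 1.19},
    },
}

#: baseline median MFR (spikes/s) per region in each group's first phase
DEFAULT_BASE_RATES = {
    "CTR": {"RFA": 1.54, "S1": 4.49},
    "ADS": {"RFA": 0.96, "S1": 0.54},
}


def generate_cohort(
    group: str,
    schedule: PhaseSchedule,
    *,
    units_per_region: dict[str, int] | int = 12,
    base_rates: dict[str, float] | None = None,
    multipliers: dict[str, dict[str, float]] | None = None,
    isi_shape: float = 1.0,
    rate_dispersion: float = 0.5,
    min_rate: float = 0.05,
    refractory_floor: float = DEFAULT_REFRACTORY,
    pos_bursty: bool = False,
    bursty_model: ISIModel | None = None,
    seed: int = 0,
) -> GroundTruthTrains:
    """Simulate one animal's ground-truth units for a full phase schedule.

    Per region, unit base rates are drawn log-normally around the region's
    baseline median (``rate_dispersion`` is the log-sd, emulating the wide
    rate spread across units), ISIs follow a gamma model of shape
    ``isi_shape`` (1 = Poisson-like, the Random baseline regime), and the
    group's per-phase multipliers are applied by thinning/superposition.

    With ``pos_bursty=True`` the post-stimulation phase is re-generated from
    a bursty doubly-stochastic model, emulating the burstiness shift induced
    by closed-loop stimulation.
    """
    if base_rates is None:
        base_rates = DEFAULT_BASE_RATES[group]
    if multipliers is None:
        multipliers = DEFAULT_MULTIPLIERS[group]
    if isinstance(units_per_region, int):
        units_per_region = {r: units_per_region for r in base_rates}
    rng = np.random.default_rng(seed)
    t0, t1 = schedule.span
    trains: list[UnitSpikeTrain] = []
    models: dict[str, ISIModel] = {}
    mults: dict[str, dict[str, float]] = {}
    ch = 0
    for region, n_units in units_per_region.items():
        for k in range(n_units):
            uid = f"{region.lower()}{k:02d}"
            rate = float(
                np.clip(
                    base_rates[region] * rng.lognormal(0.0, rate_dispersion),
                    min_rate,
                    1.0 / (4 * refractory_floor),
                )
            )
            model = ISIModel(
                family="gamma", rate=rate, shape=isi_shape,
                refractory_floor=refractory_floor,
            )
            ts = generate_isi_train(model, t1 - t0, rng) + t0
            trains.append(
                UnitSpikeTrain(unit_id=uid, region=region, timestamps=ts, channel=ch)
            )
            models[uid] = model
            mults[uid] = dict(multipliers[region])
            ch += 1
    gt = GroundTruthTrains(trains=trains, models=models, multipliers=mults, seed=seed)
    gt = apply_phase_modulation(gt, schedule)
    if pos_bursty and "PoS" in schedule.names:
        start, end = schedule.interval("PoS")
        new_trains = []
        for tr in gt.trains:
            base = models[tr.unit_id]
            bm = bursty_model or ISIModel(
                family="bursty_doubly_stochastic",
                rate=base.rate,
                burst_rate_high=max(10.0, 8.0 * base.rate),
                burst_rate_low=0.1 * base.rate,
                burst_switch_rate=0.5,
                refractory_floor=base.refractory_floor,
            )
            seg = generate_isi_train(bm, end - start, rng) + start
            ts = tr.timestamps
            outside = ts[(ts < start) | (ts >= end)]
            merged = np.sort(np.concatenate([outside, seg]))
            new_trains.append(tr.with_timestamps(merged))
        gt = replace(gt, trains=new_trains)
    return gt
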