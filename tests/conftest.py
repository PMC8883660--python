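"""Shared fixtures: small synthetic benchmarks generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adspipe import (
    FilterSpec,
    ISIModel,
    UnitSpikeTrain,
    bandpass,
    generate_isi_train,
    make_biphasic_template,
    render_extracellular,
)


@pytest.fixture(scope="session")
def detection_benchmark():
    """20 Poisson units (5 spikes/s) on 4 channels, 60 s at 30 kHz, noise SD
    10 uV, amplitudes 120-250 uV (>= 8x the filtered noise SD), band-limited.

    Returns (filtered recording, ground-truth trains).
    """
    rng = np.random.default_rng(7)
    chan = pd.DataFrame(
        [{"channel": c, "region": "RFA", "shank": 0, "site": c} for c in range(4)]
    )
    trains, templates = [], {}
    for u in range(20):
        ch = u % 4
        ts = generate_isi_train(ISIModel(family="poisson", rate=5.0), 60.0, seed=100 + u)
        uid = f"u{u:02d}"
        trains.append(UnitSpikeTrain(unit_id=uid, region="RFA", timestamps=ts, channel=ch))
        templates[uid] = make_biphasic_template(
            rng.uniform(120, 250), channel_footprint={ch: 1.0}
        )
    rec, _ = render_extracellular(
        trains, templates, noise_sd=10.0, duration=60.0, channel_table=chan, seed=11
    )
    return bandpass(rec, FilterSpec()), trains


@pytest.fixture(scope="session")
def single_channel_trace(detection_benchmark):
    """One filtered channel and the ground-truth spike times on it."""
    rec, trains = detection_benchmark
    gt = np.sort(np.concatenate([t.timestamps for t in trains if t.channel == 0]))
    return rec.samples[0], rec.sample_rate, gt
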