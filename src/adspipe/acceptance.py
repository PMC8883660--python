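"""Self-contained calibration measurements of the pipeline's core claims.

Each function recomputes, from scratch, one of the quantities the analysis
chain is built around: the blanking-capped stimulation rate of the
closed-loop controller, the LvR calibration of stationary Poisson firing,
and the null coverage of the shuffle-based change classifier. They are used
by both the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .ads import ADSConfig, run_ads
from .change_analysis import BootstrapConfig, bin_rates, bootstrap_change
from .core import spawn_seeds
from .irregularity import LvRConfig, compute_lvr
from .synthetic import ISIModel, generate_isi_train


def saturated_stimulation_rate(
    duration: float = 60.0,
    sample_rate: float = 30_000.0,
    blanking_period: float = 0.028,
) -> tuple[float, int]:
    """Stimulation rate (Hz) when the trigger fires at every sample.

    A trigger event at every sample over ``duration`` seconds is fed through
    the blanking-gated loop; returns (emitted stimuli / duration, number of
    trigger events). With 28 ms blanking the cap is 1/0.028 ~ 35.7 Hz.
    """
    triggers = np.arange(0.0, duration, 1.0 / sample_rate)
    cfg = ADSConfig(blanking_period=blanking_period)
    log = run_ads(triggers, cfg, (0.0, duration))
    return log.n_stimuli / duration, triggers.size


def poisson_lvr_calibration(
    n_trains: int = 200,
    rate: float = 5.0,
    duration: float = 1200.0,
    seed: int = 1,
) -> tuple[float, np.ndarray]:
    """Mean LvR (R = 5 ms) over independently seeded stationary Poisson trains.

    Expected to land inside the Random firing-pattern band 1 +- 0.25.
    Returns (mean, all values).
    """
    cfg = LvRConfig()
    model = ISIModel(family="poisson", rate=rate)
    vals = np.array(
        [
            compute_lvr(generate_isi_train(model, duration, seed=s), cfg).lvr
            for s in spawn_seeds(seed, n_trains, salt=2)
        ]
    )
    return float(vals.mean()), vals


def null_coverage(
    n_units: int = 2000,
    n_shuffles: int = 2000,
    rate: float = 2.0,
    phase_duration: float = 1200.0,
    bin_width: float = 60.0,
    seed: int = 3,
) -> float:
    """Percent of units labelled no_change when nothing changed.

    For each simulated unit, two independent segments of one homogeneous
    Poisson process are binned into 1-min rates and classified against the
    two-sided 95% shuffle-null interval; under the null ~95% of units should
    be labelled no_change.
    """
    cfg = BootstrapConfig(n_shuffles=n_shuffles, seed=seed)
    model = ISIModel(family="poisson", rate=rate)
    interval = (0.0, phase_duration)
    n_nc = 0
    for child in np.random.SeedSequence([seed, 0xC07]).spawn(n_units):
        rng = np.random.default_rng(child)
        a = bin_rates(generate_isi_train(model, phase_duration, rng), interval, bin_width)
        b = bin_rates(generate_isi_train(model, phase_duration, rng), interval, bin_width)
        if bootstrap_change(a, b, cfg, rng=rng).label == "no_change":
            n_nc += 1
    return 100.0 * n_nc / n_units
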