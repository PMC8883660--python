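"""Shuffle-null classification of per-unit firing-rate changes.

To decide whether a unit's firing changed between two recording phases, the
two phases are divided into 1-min rate bins, and the observed difference of
mean binned rates is compared against a null distribution built by
repeatedly re-partitioning the pooled bins at random into two groups of the
original sizes (10,000 shuffles by default). A difference falling outside
the two-sided 95% empirical confidence interval of this zero-centred null
is classified ``increased`` or ``decreased``; otherwise ``no_change``.
Per-animal fractions of each label are summarised as mean +/- SEM across
animals. No multiple-testing correction is applied across units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import UnitSpikeTrain


@dataclass(frozen=True)
class BootstrapConfig:
    """Shuffle-null parameters.

    The default shuffle re-partitions the pooled bins *without* replacement
    into groups of the original sizes (a permutation null — the most direct
    reading of shuffling bins into two groups); ``with_replacement=True``
    switches to a bootstrap resample of each group from the pool.
    """

    bin_width: float = 60.0
    n_shuffles: int = 10_000
    ci_level: float = 0.95
    seed: int = 0
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.n_shuffles < 1000:
            raise ValueError("n_shuffles must be >= 1000")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class ChangeLabel:
    """Bootstrap classification of one unit between two phases."""

    unit_id: str
    phase_pair: tuple[str, str]
    observed_diff: float  # mean binned rate B - mean binned rate A, spikes/s
    ci_low: float
    ci_high: float
    label: str  # increased / decreased / no_change


def bin_rates(
    train: UnitSpikeTrain | np.ndarray,
    interval: tuple[float, float],
    bin_width: float = 60.0,
) -> np.ndarray:
    """Per-bin firing rates (spikes/s) over consecutive bins of a phase.

    The number of bins is ``floor(duration / bin_width)``; a trailing partial
    bin is dropped (none occurs with 20-min phases and 1-min bins).
    """
    start, end = interval
    ts = train.timestamps if isinstance(train, UnitSpikeTrain) else np.asarray(train)
    n_bins = int(np.floor((end - start) / bin_width))
    if n_bins < 1:
        raise ValueError("phase shorter than one bin")
    edges = start + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(ts, bins=edges)
    return counts / bin_width


def shuffle_null(
    bins_a: np.ndarray,
    bins_b: np.ndarray,
    config: BootstrapConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Zero-centred null distribution of the difference of group means.

    Pooled bins are re-partitioned ``n_shuffles`` times into groups of sizes
    (len(a), len(b)); each re-partition contributes the difference
    mean(group2) - mean(group1) and its negation, so the null is exactly
    symmetric (the swap of the two groups is itself a valid shuffle). The
    pool is sorted first, making the null invariant to the order the two
    phases are supplied in.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    a = np.asarray(bins_a, dtype=float)
    b = np.asarray(bins_b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a + n_b < 2 or n_a == 0 or n_b == 0:
        raise ValueError("need at least one bin in each phase and two in total")
    pooled = np.sort(np.concatenate([a, b]))
    n = pooled.size
    if config.with_replacement:
        g1 = pooled[rng.integers(0, n, size=(config.n_shuffles, n_a))]
        g2 = pooled[rng.integers(0, n, size=(config.n_shuffles, n_b))]
        diffs = g2.mean(axis=1) - g1.mean(axis=1)
    else:
        # vectorised random re-partitions: argsort of uniforms = random perm
        perm = np.argsort(rng.random((config.n_shuffles, n)), axis=1)
        shuffled = pooled[perm]
        diffs = shuffled[:, n_a:].mean(axis=1) - shuffled[:, :n_a].mean(axis=1)
    return np.concatenate([diffs, -diffs])


def bootstrap_change(
    bins_a: np.ndarray,
    bins_b: np.ndarray,
    config: BootstrapConfig | None = None,
    *,
    unit_id: str = "",
    phase_pair: tuple[str, str] = ("A", "B"),
    rng: np.random.Generator | None = None,
) -> ChangeLabel:
    """Classify the rate change of one unit between two binned phases.

    The observed difference is mean(bins_b) - mean(bins_a); the label is
    ``increased`` when it exceeds the upper equal-tail empirical quantile of
    the shuffle null, ``decreased`` below the lower one, else ``no_change``
    (values exactly on a quantile boundary stay ``no_change``, the
    conservative resolution). Deterministic given the config seed. Swapping
    the two phases negates the observed difference and swaps the
    increased/decreased labels exactly.
    """
    config = config or BootstrapConfig()
    a = np.asarray(bins_a, dtype=float)
    b = np.asarray(bins_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("need at least one bin in each phase and two in total")
    observed = float(b.mean() - a.mean())
    null = shuffle_null(a, b, config, rng=rng)
    alpha = 1.0 - config.ci_level
    ci_low, ci_high = np.quantile(null, [alpha / 2, 1 - alpha / 2])
    if observed > ci_high:
        label = "increased"
    elif observed < ci_low:
        label = "decreased"
    else:
        label = "no_change"
    return ChangeLabel(
        unit_id=unit_id,
        phase_pair=phase_pair,
        observed_diff=observed,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        label=label,
    )


def classify_units(
    trains: list[UnitSpikeTrain],
    interval_a: tuple[float, float],
    interval_b: tuple[float, float],
    config: BootstrapConfig | None = None,
    phase_pair: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Run the change classifier for every unit between two phase intervals.

    Returns a DataFrame (unit_id, region, phase_a, phase_b, rate_a, rate_b,
    observed_diff, ci_low, ci_high, label) with one independent shuffle
    stream per unit derived from the config seed.
    """
    config = config or BootstrapConfig()
    ss = np.random.SeedSequence([config.seed, 0xB00])
    rows = []
    for child, tr in zip(ss.spawn(len(trains)), trains):
        rng = np.random.default_rng(child)
        ba = bin_rates(tr, interval_a, config.bin_width)
        bb = bin_rates(tr, interval_b, config.bin_width)
        res = bootstrap_change(
            ba, bb, config, unit_id=tr.unit_id, phase_pair=phase_pair, rng=rng
        )
        rows.append(
            {
                "unit_id": tr.unit_id,
                "region": tr.region,
                "phase_a": phase_pair[0],
                "phase_b": phase_pair[1],
                "rate_a": float(ba.mean()),
                "rate_b": float(bb.mean()),
                "observed_diff": res.observed_diff,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "label": res.label,
            }
        )
    return pd.DataFrame(rows)


LABELS = ("increased", "decreased", "no_change")


def change_fractions(labels: pd.DataFrame, by: tuple[str, ...] = ("region",)) -> pd.DataFrame:
    """Fractions of increased/decreased/no_change units, mean +/- SEM.

    ``labels`` must contain columns ``animal``, ``label`` and the grouping
    columns in ``by``. Per animal the three fractions sum to one; the
    summary averages fractions across animals within each group and reports
    the standard error of the mean (0 for a single animal).
    """
    if "animal" not in labels.columns:
        labels = labels.assign(animal=0)
    rows = []
    for key, grp in labels.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        per_animal = []
        for _, sub in grp.groupby("animal"):
            counts = sub["label"].value_counts()
            total = len(sub)
            per_animal.append([counts.get(lab, 0) / total for lab in LABELS])
        fracs = np.asarray(per_animal)
        mean = fracs.mean(axis=0)
        sem = (
            fracs.std(axis=0, ddof=1) / np.sqrt(fracs.shape[0])
            if fracs.shape[0] > 1
            else np.zeros(3)
        )
        for lab, m, s in zip(LABELS, mean, sem):
            rows.append(dict(zip(by, key)) | {"label": lab, "mean_fraction": m, "sem": s})
    return pd.DataFrame(rows)
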