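"""End-to-end orchestration: simulate -> detect -> sort -> analyse.

``run_pipeline`` executes the full offline analysis chain on synthetic
animals under one seeded configuration and persists every intermediate as
CSV (plus a JSON manifest), mirroring the study's processing order: raw
data is band-limited, spikes are detected and sorted, and the resulting
neural units feed the mean-firing-rate, change-classification and
irregularity analyses. Group-level statistics are thin delegations to
standard routines (Friedman omnibus with a Tukey-type post-hoc on ranks,
Wilcoxon signed-rank within group, Wilcoxon rank-sum between groups): they
are routine statistics, and the pipeline's substance is the stages
upstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from . import io as adsio
from .ads import ADSConfig, StimEventLog, apply_stim_effect, run_ads
from .change_analysis import BootstrapConfig, change_fractions, classify_units
from .core import UnitSpikeTrain, spawn_seeds
from .detection import PTSDParams, detect_spikes_ptsd, estimate_noise_sd, extract_cutouts
from .irregularity import LvRConfig, lvr_summary, lvr_table
from .preprocessing import FilterSpec, bandpass
from .sorting import SortConfig, apply_noise_rules, cluster_channel, neural_trains
from .synthetic import (
    GroundTruthTrains,
    generate_cohort,
    make_biphasic_template,
    render_extracellular,
)
from .unit_metrics import build_schedule, filter_units, rate_table

logger = logging.getLogger("adspipe")


@dataclass
class PipelineConfig:
    """One experiment's configuration; every stage block can be defaulted."""

    group: str = "CTR"
    n_animals: int = 3
    seed: int = 0
    time_scale: float = 1.0
    render: bool = False
    units_per_region: int = 12
    noise_sd: float = 10.0
    amplitude_range: tuple[float, float] = (120.0, 250.0)
    isi_shape: float = 1.0
    rate_dispersion: float = 0.5
    pos_bursty: bool | None = None  # default: True for ADS, False for CTR
    ads: ADSConfig = field(default_factory=ADSConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    ptsd: PTSDParams = field(default_factory=PTSDParams)
    sort: SortConfig = field(default_factory=SortConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    lvr: LvRConfig = field(default_factory=LvRConfig)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.group not in ("CTR", "ADS"):
            raise ValueError("group must be 'CTR' or 'ADS'")
        if self.pos_bursty is None:
            self.pos_bursty = self.group == "ADS"
        if self.group == "CTR":
            # control animals run the identical loop at zero current
            self.ads = ADSConfig(
                **{**asdict_config(self.ads), "pulse_amplitude": 0.0}
            )
        # keep the shuffle bins commensurate with scaled phases (20 bins/phase)
        if self.time_scale != 1.0 and self.bootstrap.bin_width == 60.0:
            self.bootstrap = BootstrapConfig(
                **{
                    **asdict_config(self.bootstrap),
                    "bin_width": 60.0 * self.time_scale,
                }
            )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        blocks = {
            "ads": ADSConfig,
            "filter": FilterSpec,
            "ptsd": PTSDParams,
            "sort": SortConfig,
            "bootstrap": BootstrapConfig,
            "lvr": LvRConfig,
        }
        for name, cls_ in blocks.items():
            if name in raw and isinstance(raw[name], dict):
                raw[name] = cls_(**raw[name])
        if "amplitude_range" in raw:
            raw["amplitude_range"] = tuple(raw["amplitude_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = asdict_config(v) if hasattr(v, "__dataclass_fields__") else v
        out["amplitude_range"] = list(self.amplitude_range)
        return out


def asdict_config(obj) -> dict:
    d = dict(obj.__dict__)
    return {k: (dict(v) if isinstance(v, dict) else v) for k, v in d.items()}


#: phase pairs classified per group (baseline vs later phases)
CHANGE_PAIRS = {
    "CTR": [("PreL", "PoL1"), ("PreL", "PoL2"), ("PreL", "PoL3"),
            ("PreL", "PreS"), ("PreS", "PoS")],
    "ADS": [("PreS", "PoS")],
}
#: phases entering the omnibus rate comparison (spontaneous-activity phases)
OMNIBUS_PHASES = {
    "CTR": ["PreL", "PoL1", "PoL2", "PoL3", "PreS", "PoS"],
    "ADS": ["PreS", "PoS"],
}


def simulate_animal(
    config: PipelineConfig, animal_seed: int
) -> tuple[GroundTruthTrains, StimEventLog | None, object]:
    """Generate one animal's ground truth and (if ADS) its stimulation log."""
    schedule = build_schedule(config.group, time_scale=config.time_scale)
    gt = generate_cohort(
        config.group,
        schedule,
        units_per_region=config.units_per_region,
        isi_shape=config.isi_shape,
        rate_dispersion=config.rate_dispersion,
        pos_bursty=bool(config.pos_bursty),
        seed=animal_seed,
    )
    log = None
    if "Stim" in schedule.names:
        rfa = [tr for tr in gt.trains if tr.region == "RFA"]
        if rfa:
            # trigger channel: the highest-rate RFA unit, as a stand-in for
            # the experimenter's choice of a high-SNR channel
            trigger = max(rfa, key=lambda tr: tr.n_spikes)
            log = run_ads(trigger.timestamps, config.ads, schedule.interval("Stim"))
            if config.ads.pulse_amplitude > 0 and log.n_stimuli:
                from dataclasses import replace

                s1 = [tr for tr in gt.trains if tr.region == "S1"]
                s1_gt = replace(gt, trains=s1)
                s1_gt = apply_stim_effect(s1_gt, log, config.ads, seed=animal_seed + 1)
                merged = [tr for tr in gt.trains if tr.region == "RFA"] + s1_gt.trains
                gt = replace(gt, trains=merged)
    return gt, log, schedule


def detect_and_sort(
    gt: GroundTruthTrains, config: PipelineConfig, animal_seed: int, duration: float
) -> list[UnitSpikeTrain]:
    """Render ground truth to voltages, then recover units by PTSD + sorting.

    Each unit is rendered on its own channel (well-isolated single units);
    the detected events on every channel are clustered and noise-labelled,
    and only neural units are returned.
    """
    rng = np.random.default_rng(animal_seed + 7)
    templates = {}
    chan_rows = []
    for tr in gt.trains:
        amp = rng.uniform(*config.amplitude_range)
        templates[tr.unit_id] = make_biphasic_template(
            amp, channel_footprint={tr.channel: 1.0}
        )
        chan_rows.append(
            {"channel": tr.channel, "region": tr.region, "shank": 0, "site": tr.channel}
        )
    chan_table = pd.DataFrame(chan_rows).sort_values("channel").reset_index(drop=True)
    rec, _ = render_extracellular(
        gt,
        templates,
        config.noise_sd,
        duration=duration,
        channel_table=chan_table,
        seed=animal_seed + 8,
    )
    rec = bandpass(rec, config.filter)
    out: list[UnitSpikeTrain] = []
    for ch in chan_table["channel"]:
        sig = rec.samples[ch]
        noise_sd = estimate_noise_sd(sig, config.ptsd.noise_sd_method)
        events = detect_spikes_ptsd(
            sig, config.ptsd, rec.sample_rate, channel=ch, noise_sd=noise_sd
        )
        events = extract_cutouts(sig, events)
        units = cluster_channel(
            events, config.sort, seed=animal_seed, region=rec.region_of(ch)
        )
        units = apply_noise_rules(units, config.sort, noise_sd=noise_sd)
        out.extend(neural_trains(units))
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages for every simulated animal and collect results.

    Returns a bundle with the rate table, change labels and fractions, LvR
    tables and ratios, stimulation logs, group statistics and the manifest.
    Bit-reproducible given ``config.seed``; when ``out_dir`` is given every
    table is persisted as CSV alongside a ``manifest.json``.
    """
    t_start = time.time()
    seeds = spawn_seeds(config.seed, config.n_animals, salt=17)
    schedule = build_schedule(config.group, time_scale=config.time_scale)
    all_rates, all_labels, all_lvr, logs = [], [], [], {}
    for a, animal_seed in enumerate(seeds):
        t0 = time.time()
        gt, log, schedule = simulate_animal(config, animal_seed)
        if log is not None:
            logs[a] = log
        if config.render:
            _, end = schedule.span
            trains = detect_and_sort(gt, config, animal_seed, duration=end)
        else:
            trains = gt.trains
        assert all(tr.label == "neural" for tr in trains)
        # namespace unit ids per animal so cohort tables stay unambiguous
        from dataclasses import replace as dc_replace

        trains = [dc_replace(tr, unit_id=f"a{a}:{tr.unit_id}") for tr in trains]
        rates = rate_table(trains, schedule)
        rates = filter_units(rates)
        rates.insert(0, "animal", a)
        all_rates.append(rates)
        keep = set(rates.loc[rates["included"], "unit_id"])
        analysed = [tr for tr in trains if tr.unit_id in keep]
        for pair in CHANGE_PAIRS[config.group]:
            labels = classify_units(
                analysed,
                schedule.interval(pair[0]),
                schedule.interval(pair[1]),
                config.bootstrap,
                phase_pair=pair,
            )
            labels.insert(0, "animal", a)
            all_labels.append(labels)
        lvr = lvr_table(analysed, schedule, OMNIBUS_PHASES[config.group], config.lvr)
        lvr.insert(0, "animal", a)
        all_lvr.append(lvr)
        logger.info(
            "animal %d: %d units, %.1fs", a, len(trains), time.time() - t0
        )
    rates = pd.concat(all_rates, ignore_index=True)
    labels = pd.concat(all_labels, ignore_index=True)
    lvr = pd.concat(all_lvr, ignore_index=True)
    fractions = (
        labels.groupby(["phase_a", "phase_b"])
        .apply(lambda g: change_fractions(g), include_groups=False)
        .reset_index(level=[0, 1])
        .reset_index(drop=True)
    )
    ratios, hists = lvr_summary(lvr, "PreS", "PoS", config=config.lvr)
    stats_report = group_comparisons(
        rates[rates["included"]],
        OMNIBUS_PHASES[config.group],
        pre_post=("PreS", "PoS"),
        alpha=config.alpha,
    )
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "animal_seeds": seeds,
        "n_units": int(rates["unit_id"].nunique()),
        "elapsed_s": round(time.time() - t_start, 3),
        "versions": _versions(),
    }
    bundle = {
        "schedule": schedule,
        "rates": rates,
        "labels": labels,
        "fractions": fractions,
        "lvr": lvr,
        "lvr_ratios": ratios,
        "lvr_histograms": hists,
        "stim_logs": logs,
        "group_stats": stats_report,
        "manifest": manifest,
    }
    if out_dir is not None:
        _persist(bundle, Path(out_dir))
    return bundle


def _versions() -> dict:
    import scipy
    import sklearn

    from . import __version__

    return {
        "adspipe": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
    }


def _persist(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["rates"].to_csv(out_dir / "rate_table.csv", index=False)
    bundle["labels"].to_csv(out_dir / "change_labels.csv", index=False)
    bundle["fractions"].to_csv(out_dir / "change_fractions.csv", index=False)
    bundle["lvr"].to_csv(out_dir / "lvr_results.csv", index=False)
    bundle["lvr_ratios"].to_csv(out_dir / "lvr_ratios.csv", index=False)
    for name, hist in bundle["lvr_histograms"].items():
        hist.to_csv(out_dir / f"lvr_hist_{name}.csv", index=False)
    for a, log in bundle["stim_logs"].items():
        adsio.stim_log_to_csv(out_dir / f"stim_log_animal{a}.csv", log)
    with open(out_dir / "group_stats.json", "w") as f:
        json.dump(bundle["group_stats"], f, indent=2)
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(bundle["manifest"], f, indent=2)


# ---------------------------------------------------------------------------
# group-level statistics (delegated to standard routines)


def group_comparisons(
    rates: pd.DataFrame,
    phases: list[str],
    *,
    pre_post: tuple[str, str] = ("PreS", "PoS"),
    other_group: pd.DataFrame | None = None,
    value: str = "mfr",
    alpha: float = 0.05,
) -> dict:
    """Nonparametric group statistics on a per-unit, per-phase value table.

    Runs, in order: a normality screen (Lilliefors-corrected KS per phase);
    a Friedman omnibus test across phases over units (3+ phases); a
    Tukey-type post-hoc on the Friedman mean ranks, only when the omnibus is
    significant at ``alpha``; a Wilcoxon signed-rank on the pre/post pair;
    and, if ``other_group`` is given, a Wilcoxon rank-sum between the two
    groups' pre/post differences. Returns a JSON-serialisable report naming
    every test, statistic, p-value and the correction applied.
    """
    wide = (
        rates.pivot_table(index="unit_id", columns="phase", values=value)
        .reindex(columns=phases)
        .dropna()
    )
    report: dict = {"alpha": alpha, "n_units": int(len(wide)), "phases": phases}
    report["normality"] = {}
    for p in phases:
        x = wide[p].to_numpy()
        if x.size >= 4 and np.ptp(x) > 0:
            _, pval = lilliefors(x, dist="norm")
            report["normality"][p] = {"test": "lilliefors_ks", "p": float(pval)}
    report["nonparametric"] = all(
        v["p"] < alpha for v in report["normality"].values()
    ) if report["normality"] else True
    if len(phases) >= 3 and len(wide) >= 3:
        stat, pval = stats.friedmanchisquare(*[wide[p] for p in phases])
        report["omnibus"] = {
            "test": "friedman",
            "statistic": float(stat),
            "p": float(pval),
            "significant": bool(pval < alpha),
        }
        if pval < alpha:
            report["posthoc"] = _friedman_posthoc(wide, alpha)
            report["posthoc"]["correction"] = "tukey_kramer_on_ranks"
    if pre_post[0] in wide.columns and pre_post[1] in wide.columns:
        pre, post = wide[pre_post[0]], wide[pre_post[1]]
        if np.any(pre != post):
            stat, pval = stats.wilcoxon(pre, post)
            report["paired_pre_post"] = {
                "test": "wilcoxon_signed_rank",
                "pair": list(pre_post),
                "statistic": float(stat),
                "p": float(pval),
                "significant": bool(pval < alpha),
            }
        else:
            report["paired_pre_post"] = {
                "test": "wilcoxon_signed_rank",
                "pair": list(pre_post),
                "statistic": 0.0,
                "p": 1.0,
                "significant": False,
            }
    if other_group is not None:
        other_wide = (
            other_group.pivot_table(index="unit_id", columns="phase", values=value)
            .reindex(columns=list(pre_post))
            .dropna()
        )
        d1 = (wide[pre_post[1]] - wide[pre_post[0]]).to_numpy()
        d2 = (other_wide[pre_post[1]] - other_wide[pre_post[0]]).to_numpy()
        stat, pval = stats.ranksums(d1, d2)
        report["between_groups"] = {
            "test": "wilcoxon_rank_sum",
            "statistic": float(stat),
            "p": float(pval),
            "significant": bool(pval < alpha),
        }
    return report


def _friedman_posthoc(wide: pd.DataFrame, alpha: float) -> dict:
    """Tukey-type pairwise comparison of Friedman mean ranks.

    Pairwise mean-rank differences are compared against the critical
    difference ``q_{alpha; k, inf} * sqrt(k(k+1) / (12 n))`` from the
    studentized-range distribution, the standard post-hoc after a
    significant Friedman test.
    """
    ranks = wide.rank(axis=1)
    k = wide.shape[1]
    n = wide.shape[0]
    mean_ranks = ranks.mean(axis=0)
    q_crit = float(stats.studentized_range.ppf(1 - alpha, k, np.inf))
    cd = q_crit * np.sqrt(k * (k + 1) / (12.0 * n))
    pairs = {}
    cols = list(wide.columns)
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(mean_ranks.iloc[j] - mean_ranks.iloc[i])
            pairs[f"{cols[i]} vs {cols[j]}"] = {
                "mean_rank_diff": diff,
                "significant": bool(abs(diff) > cd),
            }
    return {
        "critical_difference": float(cd),
        "mean_ranks": {c: float(mean_ranks[c]) for c in cols},
        "pairs": pairs,
    }
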