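"""Generator correctness: ISI statistics, phase modulation, rendering."""

import numpy as np
import pandas as pd
import pytest

from adspipe import (
    GroundTruthTrains,
    ISIModel,
    UnitSpikeTrain,
    apply_phase_modulation,
    generate_isi_train,
    make_biphasic_template,
    render_extracellular,
)
from adspipe.unit_metrics import PhaseSchedule

CHAN1 = pd.DataFrame([{"channel": 0, "region": "RFA", "shank": 0, "site": 0}])


class TestGenerateISITrain:
    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            generate_isi_train(ISIModel(family="poisson", rate=5.0), -1.0, seed=0)
        with pytest.raises(ValueError):
            ISIModel(family="poisson", rate=0.0)
        with pytest.raises(ValueError):
            ISIModel(family="gamma", rate=5.0, shape=-1.0)

    def test_poisson_forces_unit_shape(self):
        assert ISIModel(family="poisson", rate=2.0, shape=3.0).shape == 1.0

    def test_near_deterministic_gamma_is_regular(self):
        """Huge gamma shape -> clock-like train: ~rate*duration spikes, CV ~ 0."""
        ts = generate_isi_train(ISIModel(family="gamma", rate=10.0, shape=1e6), 10.0, seed=2)
        isis = np.diff(ts)
        assert abs(ts.size - 100) <= 2
        assert isis.std() / isis.mean() < 0.01

    def test_poisson_count_law(self):
        """Spike count of a 1200 s, 5 spikes/s train is within 3*sqrt(6000)."""
        m = ISIModel(family="poisson", rate=5.0)
        n = generate_isi_train(m, 1200.0, seed=42).size
        assert abs(n - 6000) < 3 * np.sqrt(6000)

    @pytest.mark.parametrize(
        "model",
        [
            ISIModel(family="poisson", rate=5.0),
            ISIModel(family="gamma", rate=3.0, shape=4.0),
            ISIModel(family="gamma", rate=8.0, shape=0.5),
            ISIModel(
                family="bursty_doubly_stochastic",
                rate=25.0,
                burst_rate_high=50.0,
                burst_rate_low=0.5,
                burst_switch_rate=0.5,
            ),
        ],
        ids=["poisson", "regular", "bursty-gamma", "telegraph"],
    )
    def test_train_invariants(self, model):
        """Strictly increasing times in [0, duration), ISIs >= floor."""
        ts = generate_isi_train(model, 120.0, seed=5)
        assert ts.size > 0
        assert np.all(ts >= 0) and np.all(ts < 120.0)
        assert np.all(np.diff(ts) >= model.refractory_floor - 1e-12)

    @pytest.mark.parametrize("kappa", [4.0, 1.0, 0.5])
    def test_rate_recovery(self, kappa):
        """Empirical rate matches the target within 3 standard errors at 1200 s."""
        m = ISIModel(family="gamma", rate=5.0, shape=kappa)
        n = generate_isi_train(m, 1200.0, seed=9).size
        se = np.sqrt(6000.0 / kappa)  # gamma renewal count variance ~ N/kappa
        assert abs(n - 6000) < 3 * se + 3

    def test_seed_determinism(self):
        m = ISIModel(family="bursty_doubly_stochastic", rate=25.0)
        a = generate_isi_train(m, 60.0, seed=123)
        b = generate_isi_train(m, 60.0, seed=123)
        np.testing.assert_array_equal(a, b)


class TestPhaseModulation:
    def _gt(self, rate=2.0, duration=1200.0, mult=None, seed=0):
        m = ISIModel(family="poisson", rate=rate)
        ts = generate_isi_train(m, duration, seed=seed)
        return GroundTruthTrains(
            trains=[UnitSpikeTrain("u0", "RFA", ts)],
            models={"u0": m},
            multipliers={"u0": mult or {}},
            seed=seed,
        )

    def test_identity_multiplier(self):
        sched = PhaseSchedule("ADS", {"PreS": (0.0, 1200.0)})
        gt = self._gt(mult={"PreS": 1.0})
        out = apply_phase_modulation(gt, sched)
        np.testing.assert_array_equal(out.trains[0].timestamps, gt.trains[0].timestamps)

    def test_zero_multiplier_annihilates_phase(self):
        sched = PhaseSchedule("ADS", {"PreS": (0.0, 600.0), "Stim": (600.0, 1200.0)})
        gt = self._gt(mult={"PreS": 1.0, "Stim": 0.0})
        out = apply_phase_modulation(gt, sched)
        ts = out.trains[0].timestamps
        assert np.all(ts < 600.0)

    def test_boost_expectation(self):
        """x1.5 on a 2 spikes/s unit over 1200 s -> mean count ~ 3600 (2%)."""
        sched = PhaseSchedule("ADS", {"PreS": (0.0, 1200.0)})
        counts = [
            apply_phase_modulation(
                self._gt(mult={"PreS": 1.5}, seed=s), sched
            ).trains[0].n_spikes
            for s in range(120)
        ]
        assert abs(np.mean(counts) / 3600.0 - 1.0) < 0.02

    def test_spikes_outside_phases_unchanged(self):
        sched = PhaseSchedule("ADS", {"PreS": (100.0, 200.0)})
        gt = self._gt(duration=300.0, mult={"PreS": 0.0})
        out = apply_phase_modulation(gt, sched)
        ts0, ts1 = gt.trains[0].timestamps, out.trains[0].timestamps
        outside = ts0[(ts0 < 100.0) | (ts0 >= 200.0)]
        np.testing.assert_array_equal(ts1, outside)


class TestRendering:
    def test_pure_noise_sd(self):
        rec, _ = render_extracellular(
            [], {}, 10.0, duration=2.0, channel_table=CHAN1, seed=1
        )
        assert abs(rec.samples.std() / 10.0 - 1.0) < 0.02

    def test_noiseless_spike_recovered_exactly(self):
        """With no noise, the template trough sits at the spike sample."""
        ts = np.array([0.05, 0.10, 0.35])
        tr = UnitSpikeTrain("u0", "RFA", ts, channel=0)
        tpl = make_biphasic_template(100.0, channel_footprint={0: 1.0})
        rec, trunc = render_extracellular(
            [tr], {"u0": tpl}, 0.0, duration=0.5, channel_table=CHAN1, seed=0
        )
        assert trunc == []
        sig = rec.samples[0]
        troughs = np.sort(np.argsort(sig)[:3]) / rec.sample_rate
        np.testing.assert_allclose(troughs, ts, atol=1.0 / rec.sample_rate)

    def test_superposition_over_units(self):
        """Rendering is additive over units (noise excluded)."""
        t1 = UnitSpikeTrain("a", "RFA", np.array([0.0501, 0.0504]), channel=0)
        t2 = UnitSpikeTrain("b", "RFA", np.array([0.0502, 0.2]), channel=0)
        tpls = {
            "a": make_biphasic_template(100.0, channel_footprint={0: 1.0}),
            "b": make_biphasic_template(150.0, channel_footprint={0: 1.0}),
        }
        both, _ = render_extracellular(
            [t1, t2], tpls, 0.0, duration=0.5, channel_table=CHAN1
        )
        only1, _ = render_extracellular([t1], tpls, 0.0, duration=0.5, channel_table=CHAN1)
        only2, _ = render_extracellular([t2], tpls, 0.0, duration=0.5, channel_table=CHAN1)
        np.testing.assert_array_equal(both.samples, only1.samples + only2.samples)

    def test_edge_spike_flagged_and_truncated(self):
        tr = UnitSpikeTrain("u0", "RFA", np.array([0.0001]), channel=0)
        tpl = make_biphasic_template(100.0, channel_footprint={0: 1.0})
        rec, trunc = render_extracellular(
            [tr], {"u0": tpl}, 0.0, duration=0.1, channel_table=CHAN1
        )
        assert len(trunc) == 1 and trunc[0].startswith("u0@")

    def test_render_determinism(self):
        tr = UnitSpikeTrain("u0", "RFA", np.array([0.05]), channel=0)
        tpl = {"u0": make_biphasic_template(120.0, channel_footprint={0: 1.0})}
        a, _ = render_extracellular([tr], tpl, 5.0, duration=0.2, channel_table=CHAN1, seed=3)
        b, _ = render_extracellular([tr], tpl, 5.0, duration=0.2, channel_table=CHAN1, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_template_window_invariants(self):
        tpl = make_biphasic_template(100.0, sample_rate=30_000.0)
        assert tpl.samples.size == 37
        assert tpl.align_index == 12
        assert abs(tpl.peak_to_peak_amplitude - 100.0) < 1e-9
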