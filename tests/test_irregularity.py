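"""LvR irregularity statistic and firing-pattern classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adspipe import (
    BAND_SHAPES,
    ISIModel,
    LvRConfig,
    classify_pattern,
    compute_lvr,
    generate_isi_train,
)
from adspipe.irregularity import lvr_histogram, lvr_summary, lvr_table
from adspipe.unit_metrics import PhaseSchedule
from adspipe.core import UnitSpikeTrain


def lvr_naive(isis, R):
    """Independent oracle: literal loop over the defining sum."""
    n = len(isis)
    total = 0.0
    for i in range(n - 1):
        a, b = isis[i], isis[i + 1]
        total += (1 - 4 * a * b / (a + b) ** 2) * (1 + 4 * R / (a + b))
    return 3.0 / (n - 1) * total


isi_vectors = st.lists(
    st.floats(min_value=1e-4, max_value=10.0, allow_nan=False), min_size=3, max_size=60
)


class TestComputeLvR:
    def test_constant_train_gives_zero(self):
        """Equal ISIs: every variability factor vanishes, LvR = 0 exactly."""
        res = compute_lvr(np.arange(0.0, 10.0, 0.25))
        assert res.lvr == 0.0

    def test_worked_example(self):
        """ISIs 10/20/10/20 ms with R = 5 ms -> 5/9 = 0.5556."""
        ts = np.cumsum([0.0, 0.010, 0.020, 0.010, 0.020])
        res = compute_lvr(ts)
        assert res.n_isis == 4
        assert res.lvr == pytest.approx(5.0 / 9.0, abs=1e-12)
        assert round(res.lvr, 4) == 0.5556

    def test_poisson_train_lands_in_random_band(self):
        """Stationary Poisson trains have mean LvR within 1 +- 0.25."""
        vals = [
            compute_lvr(
                generate_isi_train(ISIModel(family="poisson", rate=5.0), 1200.0, seed=s)
            ).lvr
            for s in range(25)
        ]
        assert 0.75 <= np.mean(vals) <= 1.25

    def test_short_train_undefined(self):
        res = compute_lvr(np.array([0.0, 0.1, 0.2, 0.35]))
        assert res.pattern == "undefined"
        assert np.isfinite(res.lvr)

    def test_invalid_timestamps_rejected(self):
        with pytest.raises(ValueError):
            compute_lvr(np.array([0.0, 0.2, 0.1]))
        with pytest.raises(ValueError):
            compute_lvr(np.array([0.0, 0.1, 0.1, 0.2]))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(isi_vectors)
    def test_nonnegative_and_matches_naive_oracle(self, isis):
        """On arbitrary ISI vectors LvR >= 0 and the vectorised value equals
        the literal loop evaluation to 1e-12."""
        ts = np.concatenate([[0.0], np.cumsum(isis)])
        res = compute_lvr(ts, LvRConfig(min_isis=2))
        assert res.lvr >= 0.0
        assert res.lvr == pytest.approx(lvr_naive(np.diff(ts), 0.005), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(isi_vectors, st.floats(min_value=0.1, max_value=10.0))
    def test_scale_invariance_at_zero_R(self, isis, c):
        """With R = 0 LvR is invariant to rescaling all ISIs; with R > 0 the
        correction term shrinks as ISIs grow."""
        cfg0 = LvRConfig(refractoriness_R=0.0, min_isis=2)
        ts = np.concatenate([[0.0], np.cumsum(isis)])
        ts_scaled = np.concatenate([[0.0], np.cumsum(np.asarray(isis) * c)])
        assert compute_lvr(ts_scaled, cfg0).lvr == pytest.approx(
            compute_lvr(ts, cfg0).lvr, rel=1e-9, abs=1e-12
        )
        cfg = LvRConfig(min_isis=2)
        big = np.concatenate([[0.0], np.cumsum(np.asarray(isis) * 100.0)])
        assert compute_lvr(big, cfg).lvr <= compute_lvr(ts, cfg).lvr + 1e-9


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "lvr,expected",
        [
            (1.0, "Random"),
            (0.5, "Regular"),
            (1.5, "Bursty"),
            (0.0, "unclassified"),
            (1.9, "unclassified"),
            (0.75, "Regular"),  # shared boundary goes to the lower band
            (1.25, "Random"),
        ],
    )
    def test_band_assignment(self, lvr, expected):
        assert classify_pattern(lvr) == expected

    @pytest.mark.parametrize("band", ["Regular", "Random", "Bursty"])
    def test_band_shape_recovery(self, band):
        """Gamma generators at the band shapes land in their band in >= 90%
        of seeded 1200 s runs."""
        m = ISIModel(family="gamma", rate=5.0, shape=BAND_SHAPES[band])
        hits = 0
        n_runs = 30
        for s in range(n_runs):
            res = compute_lvr(generate_isi_train(m, 1200.0, seed=500 + s))
            hits += res.pattern == band
        assert hits / n_runs >= 0.9


class TestSummary:
    def _table(self):
        sched = PhaseSchedule("ADS", {"PreS": (0.0, 600.0), "Stim": (600.0, 4200.0),
                                      "PoS": (4200.0, 4800.0)})
        trains = []
        for k in range(6):
            pre = generate_isi_train(ISIModel(family="poisson", rate=5.0), 600.0, seed=k)
            post = generate_isi_train(
                ISIModel(family="gamma", rate=5.0, shape=0.5), 600.0, seed=100 + k
            )
            ts = np.concatenate([pre, post + 4200.0])
            trains.append(UnitSpikeTrain(f"u{k}", "RFA", ts))
        return lvr_table(trains, sched, ["PreS", "PoS"])

    def test_burstier_post_phase_raises_ratio(self):
        """Random -> bursty switch: every post/pre LvR ratio exceeds 1."""
        ratios, hists = lvr_summary(self._table(), "PreS", "PoS")
        assert len(ratios) == 6
        assert (ratios["ratio"] > 1.0).all()
        assert np.median(ratios["ratio"]) > 1.0

    def test_identical_phases_unit_ratio(self):
        tab = self._table()
        tab.loc[tab["phase"] == "PoS", "lvr"] = tab.loc[
            tab["phase"] == "PreS", "lvr"
        ].to_numpy()
        ratios, _ = lvr_summary(tab, "PreS", "PoS")
        np.testing.assert_allclose(ratios["ratio"], 1.0)

    def test_direction_flag(self):
        tab = self._table()
        fwd, _ = lvr_summary(tab, "PreS", "PoS", direction="post_over_pre")
        rev, _ = lvr_summary(tab, "PreS", "PoS", direction="pre_over_post")
        np.testing.assert_allclose(fwd["ratio"].to_numpy() * rev["ratio"].to_numpy(), 1.0)

    def test_histogram_bin_width(self):
        hist = lvr_histogram(np.array([0.3, 0.31, 1.0, 1.52]), 0.05)
        widths = hist["bin_right"] - hist["bin_left"]
        np.testing.assert_allclose(widths, 0.05)
        assert hist["count"].sum() == 4
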