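"""Manual-switch extraction, exclusion rules, rate correlation, and
peri-event histograms."""

import numpy as np
import pytest

from oknpupil.synth import SimConfig, simulate_percept_sequence, simulate_reports, simulate_stimulus_events
from oknpupil.types import EventSeries
from oknpupil.validation import (
    ObserverSummary,
    alternation_fraction,
    extract_manual_switches,
    group_histogram,
    peri_event_histogram,
    qc_exclude_observers,
    switch_rate_correlation,
    switch_rate_per_min,
)


def presses(times, dirs):
    return EventSeries(
        np.asarray(times, float),
        np.full(len(times), "key_press", dtype=object),
        np.asarray(dirs, dtype=object),
    )


class TestManualSwitches:
    def test_direction_changes_are_switches(self):
        out = extract_manual_switches(presses([1, 2, 3, 4], ["left", "right", "right", "left"]))
        np.testing.assert_allclose(out.times, [2.0, 4.0])
        assert list(out.directions) == ["right", "left"]

    def test_all_same_direction_no_switches(self):
        assert len(extract_manual_switches(presses([1, 2, 3], ["left"] * 3))) == 0

    def test_output_alternates(self):
        rng = np.random.default_rng(0)
        dirs = rng.choice(["left", "right"], 50)
        out = extract_manual_switches(presses(np.arange(50.0), dirs))
        d = list(out.directions)
        assert all(a != b for a, b in zip(d[:-1], d[1:]))

    def test_non_directional_key_rejected(self):
        with pytest.raises(ValueError, match="non-directional"):
            extract_manual_switches(presses([1.0], ["space"]))

    def test_alternation_fraction_full_alternation(self):
        assert alternation_fraction(
            presses([1, 2, 3, 4], ["right", "left", "right", "left"])
        ) == pytest.approx(1.0)

    def test_alternation_fraction_partial(self):
        # L,R,R,L: 2 changes over 3 transitions
        assert alternation_fraction(
            presses([1, 2, 3, 4], ["left", "right", "right", "left"])
        ) == pytest.approx(2 / 3)


class TestExclusionRules:
    def _summary(self, **kw):
        base = dict(observer="o1", condition="switch_relevant")
        base.update(kw)
        return ObserverSummary(**base)

    def test_low_alternation_excluded(self):
        df = qc_exclude_observers([self._summary(alternation_fraction=0.34)])
        assert bool(df["exclude"][0])

    def test_typical_alternation_retained(self):
        df = qc_exclude_observers([self._summary(alternation_fraction=0.82)])
        assert not bool(df["exclude"][0])

    def test_key_spamming_excluded(self):
        s = self._summary(
            condition="inversion_relevant", n_presses=51, n_inversions=10
        )
        df = qc_exclude_observers([s])
        assert bool(df["exclude"][0])
        assert "ratio" in df["reason"][0]

    def test_exclusion_in_one_condition_marks_observer(self):
        s1 = self._summary(alternation_fraction=0.3)
        s2 = self._summary(condition="inversion_relevant", n_presses=5, n_inversions=10)
        df = qc_exclude_observers([s1, s2])
        assert df["observer_excluded"].all()


class TestRateCorrelation:
    def test_identical_vectors_r_one(self):
        assert switch_rate_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_reversed_order_r_minus_one(self):
        assert switch_rate_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 4.0])
        b = np.array([2.0, 2.0, 5.0])
        expected = np.sum((a - a.mean()) * (b - b.mean())) / (
            np.sqrt(np.sum((a - a.mean()) ** 2)) * np.sqrt(np.sum((b - b.mean()) ** 2))
        )
        assert switch_rate_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            switch_rate_correlation([1, 1, 1], [1, 2, 3])

    def test_rate_per_min(self):
        ev = EventSeries(np.arange(10.0), np.full(10, "okn_switch", object), None)
        assert switch_rate_per_min(ev, 120.0) == pytest.approx(5.0)


def switches_at(times, dirs):
    return EventSeries(
        np.asarray(times, float),
        np.full(len(times), "okn_switch", dtype=object),
        np.asarray(dirs, dtype=object),
    )


class TestPeriEventHistogram:
    def test_no_switches_all_zero(self):
        anchors = presses([10.0], ["left"])
        h = peri_event_histogram(switches_at([], []), anchors)
        assert h["count_total"].sum() == 0

    def test_fixed_one_second_lead_lands_in_expected_bin(self):
        anchors = presses([10.0, 20.0, 30.0], ["left", "right", "left"])
        sw = switches_at([9.0, 19.0, 29.0], ["left", "right", "left"])
        h = peri_event_histogram(sw, anchors)
        peak = h.loc[h["count_total"].idxmax()]
        assert peak["bin_left_s"] == pytest.approx(-1.0)
        assert peak["count_matching"] == 3
        assert h["count_nonmatching"].sum() == 0

    def test_direction_mismatch_counted_separately(self):
        anchors = presses([10.0], ["left"])
        sw = switches_at([9.0], ["right"])
        h = peri_event_histogram(sw, anchors)
        assert h["count_nonmatching"].sum() == 1
        assert h["count_matching"].sum() == 0

    def test_total_equals_pairs_within_window(self, rng):
        anchors = presses(np.sort(rng.uniform(5, 95, 20)), rng.choice(["left", "right"], 20))
        sw = switches_at(np.sort(rng.uniform(0, 100, 50)), rng.choice(["left", "right"], 50))
        h = peri_event_histogram(sw, anchors, window_s=(-3.0, 1.5))
        pairs = sum(
            1
            for at in anchors.times
            for stt in sw.times
            if -3.0 <= stt - at < 1.5
        )
        assert h["count_total"].sum() == pairs

    def test_simulated_reports_peak_in_paper_range(self):
        # switches reported with ~1-s delay: the histogram peak must fall
        # 0.75-1.5 s before the press
        cfg = SimConfig(seed=4)
        rng = np.random.default_rng(4)
        _, sw = simulate_percept_sequence(cfg, rng, duration_s=3000.0)
        reports = simulate_reports(sw, cfg, rng, duration_s=3000.0)
        manual = extract_manual_switches(reports)
        h = peri_event_histogram(sw, manual)
        peak = h.loc[h["count_total"].idxmax()]
        assert -1.5 <= peak["bin_left_s"] and peak["bin_right_s"] <= -0.75

    def test_group_histogram_mean_and_sem(self):
        h1 = peri_event_histogram(
            switches_at([9.0], ["left"]), presses([10.0], ["left"])
        )
        h2 = peri_event_histogram(
            switches_at([8.0], ["left"]), presses([10.0], ["left"])
        )
        g = group_histogram(
            [h[["bin_left_s", "bin_right_s", "mean_per_anchor"]] for h in (h1, h2)]
        )
        assert g["n_observers"].iloc[0] == 2
        assert g["mean_per_anchor"].sum() == pytest.approx(1.0)


class TestInversionAnchoredControl:
    def test_independent_switches_show_no_alignment_with_inversions(self):
        # Supplement-style negative control: OKN switches are statistically
        # independent of triangle inversions, so no lag bin should deviate
        # from the chance level by more than 3 standard errors
        per_obs = []
        for seed in range(10):
            cfg = SimConfig(seed=seed)
            rng = np.random.default_rng(1000 + seed)
            _, sw = simulate_percept_sequence(cfg, rng, duration_s=1200.0)
            inv, _ = simulate_stimulus_events(cfg, rng, duration_s=1200.0)
            h = peri_event_histogram(sw, inv, split_matching=False)
            per_obs.append(h[["bin_left_s", "bin_right_s", "mean_per_anchor"]])
        g = group_histogram(per_obs)
        chance = g["mean_per_anchor"].mean()
        dev = (g["mean_per_anchor"] - chance).abs()
        assert (dev <= 3.0 * g["sem"] + 1e-12).all()
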