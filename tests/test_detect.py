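"""Click-train detection: reflection exclusion, chaining, buzz, rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from porpclick.detect import (
    ClickTrain,
    ClickTrainDetector,
    classify_buzz,
    exclude_reflections,
    find_trains,
    summarize_rates,
)
from porpclick.simulate import SceneConfig, SurfaceGhost, render_scene


def brute_force_trains(times, min_clicks=6, lo=1e-3, hi=0.2):
    """Oracle: enumerate chains by walking pairwise gaps."""
    chains, cur = [], [times[0]] if len(times) else []
    for a, b in zip(times, times[1:]):
        if lo <= b - a <= hi:
            cur.append(b)
        else:
            chains.append(cur)
            cur = [b]
    chains.append(cur)
    return [c for c in chains if len(c) >= min_clicks]


def brute_force_buzz(icis, thr=0.010, need=4):
    """Oracle: exhaustive window scan for a run of `need` fast ICIs."""
    for i in range(len(icis) - need + 1):
        if all(x < thr for x in icis[i : i + need]):
            return True
    return False


class TestExcludeReflections:
    def test_ghost_at_0p8ms_removed(self, event_frame):
        out = exclude_reflections(event_frame([0.0, 0.0008, 0.050]))
        assert list(out["time"]) == [0.0, 0.050]

    def test_boundary_1p1ms_retained(self, event_frame):
        out = exclude_reflections(event_frame([0.0, 0.0011, 0.050]))
        assert len(out) == 3

    def test_idempotent(self, event_frame):
        ev = event_frame([0.0, 0.0004, 0.0008, 0.030, 0.0304])
        once = exclude_reflections(ev)
        twice = exclude_reflections(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_unsorted_raises(self, event_frame):
        with pytest.raises(ValueError, match="sorted"):
            exclude_reflections(event_frame([0.1, 0.0]))

    def test_random_ghost_injection_recovers_truth(self, event_frame):
        """Ghosts at U(0.1, 0.9) ms lags vanish; truth stream survives."""
        rng = np.random.default_rng(17)
        true_times = np.cumsum(rng.uniform(0.02, 0.1, 40))
        ghosts = true_times + rng.uniform(1e-4, 9e-4, 40)
        mixed = np.sort(np.concatenate([true_times, ghosts]))
        out = exclude_reflections(event_frame(mixed))
        assert np.allclose(out["time"].to_numpy(), true_times)


class TestFindTrains:
    def test_six_at_50ms_is_one_train(self, event_frame):
        trains = find_trains(event_frame(np.arange(6) * 0.05))
        assert len(trains) == 1
        assert trains[0].n_clicks == 6
        assert np.allclose(trains[0].ici_series, 0.05)

    def test_five_clicks_is_no_train(self, event_frame):
        assert find_trains(event_frame(np.arange(5) * 0.05)) == []

    def test_gap_splits_two_trains(self, event_frame):
        t = np.concatenate([np.arange(6) * 0.05, 0.55 + np.arange(6) * 0.02])
        trains = find_trains(event_frame(t))
        assert [tr.n_clicks for tr in trains] == [6, 6]

    @settings(deadline=None, max_examples=50)
    @given(gaps=st.lists(st.floats(0.0005, 0.4), min_size=1, max_size=60))
    def test_matches_brute_force_oracle(self, event_frame, gaps):
        times = np.cumsum(np.asarray(gaps))
        trains = find_trains(event_frame(times), min_ici_s=1e-3)
        oracle = brute_force_trains(list(times))
        assert [t.n_clicks for t in trains] == [len(c) for c in oracle]
        for tr, c in zip(trains, oracle):
            assert np.allclose(tr.times, c)

    def test_no_event_in_two_trains_and_short_chains_dropped(self, event_frame):
        rng = np.random.default_rng(3)
        times = np.cumsum(rng.uniform(0.002, 0.35, 200))
        trains = find_trains(event_frame(times))
        seen = np.concatenate([t.times for t in trains]) if trains else []
        assert len(seen) == len(set(seen))  # disjoint
        leftover = sorted(set(times) - set(seen))
        for chain in brute_force_trains(leftover, min_clicks=1):
            assert len(chain) <= 5


class TestClassifyBuzz:
    def _train(self, icis, event_frame):
        return ClickTrain(event_frame(np.concatenate([[0], np.cumsum(icis)])))

    def test_five_clicks_all_fast_is_buzz(self, event_frame):
        assert classify_buzz(self._train([0.008] * 4, event_frame))

    def test_broken_run_is_not_buzz(self, event_frame):
        icis = [0.008, 0.008, 0.012, 0.008, 0.008]
        assert not classify_buzz(self._train(icis, event_frame))

    def test_time_translation_invariant(self, event_frame):
        icis = [0.008] * 4 + [0.05]
        t1 = self._train(icis, event_frame)
        ev = event_frame(np.concatenate([[0], np.cumsum(icis)]) + 1234.5)
        assert classify_buzz(t1) == classify_buzz(ClickTrain(ev))

    def test_1000_random_sequences_match_window_oracle(self, event_frame):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = rng.integers(5, 15)
            icis = rng.uniform(0.004, 0.02, n)
            got = classify_buzz(self._train(icis, event_frame))
            assert got == brute_force_buzz(list(icis))


class TestSummarizeRates:
    def test_published_denominator_convention(self, event_frame):
        """110 buzzes over 1,257 non-buzz trains gives 8.8 %."""
        buzz = ClickTrain(event_frame(np.cumsum([0.0] + [0.008] * 5)))
        slow = ClickTrain(event_frame(np.arange(6) * 0.05))
        trains = [buzz] * 110 + [slow] * 1257
        out = summarize_rates(trains, ["day"] * len(trains))
        assert out["overall"]["n_buzz"] == 110
        assert out["overall"]["n_click_trains"] == 1257
        assert out["overall"]["buzz_ratio_pct"] == pytest.approx(8.8, abs=0.06)

    def test_zero_buzzes(self, event_frame):
        slow = ClickTrain(event_frame(np.arange(6) * 0.05))
        out = summarize_rates([slow] * 10, ["day"] * 10)
        assert out["overall"]["buzz_ratio_pct"] == 0.0

    def test_no_trains_ratio_missing(self):
        out = summarize_rates([], [])
        assert out["overall"]["buzz_ratio_pct"] is None

    def test_strata_conserve_totals(self, event_frame):
        buzz = ClickTrain(event_frame(np.cumsum([0.0] + [0.008] * 5)))
        slow = ClickTrain(event_frame(np.arange(6) * 0.05))
        trains = [buzz, slow, slow, buzz, slow]
        labels = ["day", "day", "night", "night", "night"]
        out = summarize_rates(trains, labels)
        assert (
            out["day"]["n_buzz"] + out["night"]["n_buzz"]
            == out["overall"]["n_buzz"]
        )
        assert (
            out["day"]["n_click_trains"] + out["night"]["n_click_trains"]
            == out["overall"]["n_click_trains"]
        )


class TestDetectorOnSimulatorTruth:
    def test_perfect_recall_precision_with_ghosts(self):
        """Detector output equals the simulator truth, ghosts included."""
        cfg = SceneConfig(
            seed=21,
            n_trains=8,
            range_span=(5.0, 20.0),
            surface_ghost=SurfaceGhost(enabled=True, delay_s=4e-4,
                                       attenuation_db=3.0),
        )
        scene = render_scene(cfg)
        trains = ClickTrainDetector().transform(scene.events)
        truth_counts = (
            scene.events.query("sensor_id=='atag_4m' and ~is_ghost")
            .groupby("train_id").size()
        )
        expected = truth_counts[truth_counts >= 6]
        assert len(trains) == len(expected)
        for tr in trains:
            tid = tr.events["train_id"].iloc[0]
            assert (tr.events["train_id"] == tid).all()
            assert not tr.events["is_ghost"].any()
            assert tr.n_clicks == expected[tid]
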