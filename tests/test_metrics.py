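"""Click/click-train parameter extraction and the sonar equation."""

import numpy as np
import pandas as pd
import pytest

from porpclick.detect import ClickTrain, ClickTrainDetector
from porpclick.localize import TrainLocalizer
from porpclick.metrics import (
    BandError,
    ClickMetrics,
    ClickParameterExtractor,
    DegenerateClickError,
    asl,
    click_duration,
    spectral_params,
    train_ici,
)
from porpclick.screen import OnAxisScreener
from porpclick.simulate import SceneConfig, render_scene, synth_click

from conftest import run_state

FS = 576_000.0


class TestSpectralParams:
    def test_gaussian_pip_peak_equals_center(self):
        w = synth_click(130.0, 15e-6, 5.0, FS)
        peak, center, bw = spectral_params(w, FS)
        bin_khz = FS / 4096 / 1e3
        assert peak == pytest.approx(130.0, abs=bin_khz)
        assert center == pytest.approx(130.0, abs=bin_khz)

    def test_bw_matches_gaussian_closed_form(self):
        sigma = 15e-6
        w = synth_click(130.0, sigma, 5.0, FS)
        _, _, bw = spectral_params(w, FS)
        want = np.sqrt(np.log(2)) / (np.pi * sigma) / 1e3
        assert bw == pytest.approx(want, rel=0.05)

    def test_two_tone_band_does_not_jump_to_minor_lobe(self):
        """130 kHz + a -10 dB 90 kHz component: band stays on the main lobe."""
        w = synth_click(130.0, 15e-6, 5.0, FS)
        w2 = synth_click(90.0, 15e-6, 5.0 * 10 ** (-10 / 20), FS)
        x = w + w2
        peak, center, bw = spectral_params(x, FS)
        assert peak == pytest.approx(130.0, abs=0.2)
        f_lo = center - bw / 2
        assert f_lo > 100.0  # -3 dB edge never reaches the 90 kHz lobe

    def test_center_inside_band_property(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            f = rng.uniform(115, 145)
            s = rng.uniform(15e-6, 30e-6)
            peak, center, bw = spectral_params(synth_click(f, s, 2.0, FS), FS)
            assert bw > 0
            assert center - bw / 2 <= center <= center + bw / 2
            assert abs(center - peak) <= bw

    def test_band_error_when_no_crossing(self):
        # white noise floor: the -3 dB crossing can vanish at band edges
        with pytest.raises(BandError):
            spectral_params(np.ones(64), FS, nfft=64)


class TestClickDuration:
    def test_gaussian_threshold_at_peak_over_e2_gives_4_sigma(self):
        sigma = 20e-6
        w = synth_click(130.0, sigma, 5.0, FS)
        env_peak = 5.0  # zero-to-peak of the calibrated pip
        dur = click_duration(w, FS, env_peak * np.exp(-2))
        assert dur == pytest.approx(4 * sigma * 1e6, rel=0.05)

    def test_threshold_above_peak_degenerates(self):
        w = synth_click(130.0, 15e-6, 1.0, FS)
        with pytest.raises(DegenerateClickError):
            click_duration(w, FS, 10.0)

    def test_duration_monotone_in_sigma(self):
        durs = [
            click_duration(synth_click(130.0, s, 5.0, FS), FS, 0.5)
            for s in (15e-6, 20e-6, 30e-6, 40e-6)
        ]
        assert np.all(np.diff(durs) > 0)


class TestAsl:
    def test_closed_form(self):
        tl, a = asl(150.0, 10.0, 0.048)
        assert tl == pytest.approx(20.48, abs=1e-6)
        assert a == pytest.approx(170.48, abs=1e-6)

    def test_identity_at_one_metre(self):
        _, a = asl(140.0, 1.0, 0.0)
        assert a == 140.0

    def test_monotone_in_range(self):
        vals = [asl(150.0, r, 0.048)[1] for r in (2, 5, 10, 30, 59)]
        assert np.all(np.diff(vals) > 0)

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError):
            asl(150.0, 0.0, 0.048)


class TestTrainIci:
    def _train(self, times, pp):
        return ClickTrain(
            pd.DataFrame(
                {"time": times, "pp_ch1": pp, "pp_ch2": np.asarray(pp) * 0.7,
                 "tdoa": 0.0, "sensor_id": "atag_4m"}
            )
        )

    def test_flanking_average(self):
        t = [0.0, 0.040, 0.084]  # ICIs 40 and 44 ms around the peak
        tr = self._train(t, [1.0, 5.0, 1.0])
        assert train_ici(tr) == pytest.approx(42.0)

    def test_constant_train(self):
        t = np.arange(6) * 0.05
        pp = [1, 2, 9, 3, 2, 1]
        assert train_ici(self._train(t, pp)) == pytest.approx(50.0)

    def test_edge_peak_raises(self):
        tr = self._train(np.arange(6) * 0.05, [9, 2, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="edge"):
            train_ici(tr)

    def test_1000_random_trains_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(6, 20))
            icis = rng.uniform(0.005, 0.15, n - 1)
            t = np.concatenate([[0], np.cumsum(icis)])
            pp = rng.uniform(1, 10, n)
            pp[0] = pp[-1] = 0.1  # keep the peak interior
            tr = self._train(t, pp)
            i = int(np.argmax(pp))
            want = (icis[i - 1] + icis[i]) / 2 * 1e3
            assert train_ici(tr) == pytest.approx(want)


class TestParameterRecovery:
    def test_recovery_on_simulated_accepted_clicks(self):
        """ASL/peak-f/BW/duration recovered from rendered scenes.

        Spans SL 160-190 dB, f 125-140 kHz, r 5-30 m (close enough for
        the 6.3 Pa logger threshold to trigger across the SL span).
        """
        rng = np.random.default_rng(7)
        rows = []
        trials = 0
        while len(rows) < 40 and trials < 120:
            trials += 1
            sl = rng.uniform(165, 190)
            f = rng.uniform(125, 140)
            r = rng.uniform(5, 30)
            cfg = SceneConfig(
                seed=int(rng.integers(2**31)), n_trains=1, source_level=sl,
                center_frequency=f, source_positions=((r, 3.6, 0.0),),
            )
            scene = render_scene(cfg)
            state = run_state(scene)
            state["trains"] = ClickTrainDetector().transform(scene.events)
            if not state["trains"]:
                continue
            state = TrainLocalizer().fit().transform(state)
            state = OnAxisScreener().fit().transform(state)
            state["true_ranges"] = {
                0: float(scene.truth["range_true"].iloc[0])
            }
            state = ClickParameterExtractor(use_true_range=True).fit().transform(state)
            m = state["metrics"]
            if not len(m):
                continue
            rows.append(
                {
                    "asl_err": m["asl"].iloc[0] - sl,
                    "peak_err_khz": m["peak_frequency"].iloc[0] - f,
                    "bw": m["bw3"].iloc[0],
                }
            )
        assert len(rows) >= 40
        df = pd.DataFrame(rows)
        assert df["asl_err"].abs().median() <= 1.0
        bin_khz = FS / 4096 / 1e3
        assert (df["peak_err_khz"].abs() <= bin_khz).mean() > 0.9
        want_bw = np.sqrt(np.log(2)) / (np.pi * 15e-6) / 1e3
        assert np.median(np.abs(df["bw"] - want_bw) / want_bw) <= 0.10


class TestClickMetricsInvariants:
    def test_asl_identity_enforced(self):
        with pytest.raises(ValueError, match="RL"):
            ClickMetrics(
                asl=170.0, rl=150.0, tl=19.0, peak_frequency=130.0,
                center_frequency=130.0, bw3=20.0, duration=60.0, ici=40.0,
                n_clicks=10, range_m=10.0,
            )

    def test_positive_bandwidth_enforced(self):
        with pytest.raises(ValueError):
            ClickMetrics(
                asl=170.0, rl=150.0, tl=20.0, peak_frequency=130.0,
                center_frequency=130.0, bw3=-1.0, duration=60.0, ici=40.0,
                n_clicks=10, range_m=10.0,
            )
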