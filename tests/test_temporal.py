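import numpy as np
import pytest

import fpvs
from conftest import simulate_unit
from fpvs.exceptions import (
    DegenerateBaselineError,
    EmptyResultError,
    InvalidParameterError,
)
from fpvs.temporal import average_epochs, epoch_faces, notch_filter, smooth_epochs

FS = 1000.0


def power(x):
    return float(np.sum(np.asarray(x, float) ** 2))


class TestNotchFilter:
    def test_base_frequency_removed(self):
        t = np.arange(70000) / FS
        x = np.cos(2 * np.pi * 6.0 * t)
        y = notch_filter(x, FS)
        assert power(y) < 1e-3 * power(x)

    def test_oddball_frequency_untouched(self):
        t = np.arange(70000) / FS
        x = np.cos(2 * np.pi * 1.2 * t)
        y = notch_filter(x, FS)
        np.testing.assert_allclose(y, x, atol=1e-9)

    def test_white_noise_loses_exactly_the_notched_bins(self, rng):
        x = rng.normal(0, 1, 70000)
        y = notch_filter(x, FS)
        coef = np.fft.rfft(x)
        fr = np.fft.rfftfreq(x.size, 1 / FS)
        mask = np.zeros(fr.size, bool)
        for f in (6.0, 12.0, 18.0):
            mask |= np.abs(fr - f) <= 0.025 + 1e-12
        assert int(mask.sum()) == 9  # three bins per notch at df = 1/70 Hz
        removed = (np.sum(np.abs(coef[mask]) ** 2) * 2) / x.size
        assert power(x) - power(y) == pytest.approx(removed, rel=1e-9)

    def test_invalid_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            notch_filter(np.zeros(100), FS, width_hz=0.0)


class TestEpoching:
    def test_interior_onsets_all_retained(self):
        x = np.zeros(70000)
        onsets = 5.0 + np.arange(60) / 1.2
        epochs, time, n_dropped = epoch_faces(x, FS, onsets)
        assert epochs.shape == (60, 1000)
        assert n_dropped == 0
        assert time[0] == pytest.approx(-0.166)
        assert time[-1] == pytest.approx(0.834 - 1 / FS)

    def test_boundary_onsets_dropped(self, spike_schedule):
        """First onset (window starts before 0) and an onset at 69.9 s are dropped."""
        x = np.zeros(70000)
        epochs, _, n_dropped = epoch_faces(x, FS, [0.0, 35.0, 69.9])
        assert epochs.shape[0] == 1
        assert n_dropped == 2

    def test_full_schedule_epoch_count(self, spike_schedule):
        x = np.zeros(70000)
        epochs, _, n_dropped = epoch_faces(x, FS, spike_schedule.face_onsets_s)
        assert epochs.shape[0] + n_dropped == 84

    def test_no_epochs_raises(self):
        with pytest.raises(EmptyResultError):
            epoch_faces(np.zeros(1000), FS, [50.0])

    def test_shift_is_fifth_of_base_cycle(self):
        assert 0.033 == pytest.approx((1 / 6) / 5, abs=0.0004)


class TestAveraging:
    def test_constant_epochs_give_zero_net(self):
        time = -0.166 + np.arange(1000) / FS
        groups = [np.full((10, 1000), 7.0), np.full((8, 1000), 3.0)]
        curve, sd = average_epochs(groups, time)
        np.testing.assert_allclose(curve, 0.0, atol=1e-12)
        assert sd == 0.0

    def test_burst_at_150ms_peaks_there(self, rng):
        time = -0.166 + np.arange(1000) / FS
        epochs = rng.normal(0, 0.1, (84, 1000))
        i150 = int(round((0.150 + 0.166) * FS))
        epochs[:, i150 : i150 + 30] += 100.0
        sm = smooth_epochs(epochs, FS)
        curve, _ = average_epochs([sm], time)
        assert abs(time[np.argmax(curve)] - 0.150) < 0.04
        assert curve.max() > 0

    def test_per_sequence_baseline_subtraction(self):
        """Sequences with different offsets each end up centred on zero baseline."""
        time = -0.166 + np.arange(1000) / FS
        g1 = np.full((5, 1000), 10.0)
        g2 = np.full((5, 1000), 2.0)
        g2[:, 500:] = 4.0  # late deviation in sequence 2 only
        curve, _ = average_epochs([g1, g2], time)
        bmask = (time >= -0.166) & (time < 0)
        assert abs(curve[bmask].mean()) < 1e-12
        assert curve[900] == pytest.approx(1.0)  # (0 + 2)/2


class TestLatency:
    def _step_curve(self, at_s=0.120, value=10.0, until_s=None):
        time = -0.166 + np.arange(1000) / FS
        net = np.zeros(1000)
        hi = time < until_s if until_s is not None else np.ones(1000, bool)
        net[(time >= at_s) & hi] = value
        return time, net

    def test_step_latency_and_sign(self):
        time, net = self._step_curve(0.120, 10.0)
        lat, sign = fpvs.response_latency(time, net, baseline_sd_hz=1.0)
        assert lat == pytest.approx(120.0, abs=1.0)
        assert sign == "increase"

    def test_brief_crossing_is_missing(self):
        time, net = self._step_curve(0.120, 10.0, until_s=0.140)  # 20 ms only
        lat, sign = fpvs.response_latency(time, net, baseline_sd_hz=1.0)
        assert lat is None and sign == "undetermined"

    def test_mirror_curve_same_latency_opposite_sign(self):
        time, net = self._step_curve(0.120, 10.0)
        lat_p, sign_p = fpvs.response_latency(time, net, 1.0)
        lat_n, sign_n = fpvs.response_latency(time, -net, 1.0)
        assert lat_p == lat_n
        assert (sign_p, sign_n) == ("increase", "decrease")

    def test_zero_baseline_sd_raises(self):
        time, net = self._step_curve()
        with pytest.raises(DegenerateBaselineError):
            fpvs.response_latency(time, net, 0.0)


class TestPeriFaceResponse:
    def test_suppressive_unit_negative_net(self, spike_schedule, rng):
        trains = simulate_unit(
            spike_schedule, rng, baseline_rate_hz=20.0, face_gain=-1.0,
            face_response_duration_s=0.4,
        )
        peri = fpvs.peri_face_response(trains, spike_schedule)
        assert peri.amplitude_hz < 0
        assert peri.sign == "decrease"

    def test_sign_antisymmetry_on_rate_series(self, spike_schedule, rng):
        """Negating the rate series negates amplitude and flips the sign."""
        trains = simulate_unit(spike_schedule, rng, baseline_rate_hz=15.0, face_gain=1.0)
        peri = fpvs.peri_face_response(trains, spike_schedule)
        lat, sign = fpvs.response_latency(peri.time_s, -peri.net_rate_hz, peri.baseline_sd_hz)
        assert lat == peri.latency_ms
        assert {sign, peri.sign} == {"increase", "decrease"}

    def test_bootstrap_baseline_agrees_on_strong_response(self, spike_schedule, rng):
        trains = simulate_unit(spike_schedule, rng, face_gain=1.5)
        p_samples = fpvs.peri_face_response(trains, spike_schedule)
        p_boot = fpvs.peri_face_response(
            trains, spike_schedule, baseline_method="bootstrap", n_boot=200,
            rng=np.random.default_rng(0),
        )
        assert p_boot.sign == p_samples.sign == "increase"
        assert abs(p_boot.latency_ms - p_samples.latency_ms) < 30
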