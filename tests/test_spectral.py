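import numpy as np
import pytest

import fpvs
from conftest import simulate_unit
from fpvs.containers import AmplitudeSpectrum
from fpvs.exceptions import (
    DegenerateSpectrumError,
    InvalidParameterError,
    MisalignedFrequencyError,
)


def make_spectrum(amplitudes, df=1.0):
    amps = np.asarray(amplitudes, dtype=float)
    return AmplitudeSpectrum(
        freqs_hz=np.arange(amps.size) * df,
        amplitudes=amps,
        phases=np.zeros(amps.size),
        df_hz=df,
    )


class TestBinning:
    def test_direct_binning(self):
        train = fpvs.SpikeTrain([0.0005, 0.0015], 0.01)
        binned = fpvs.bin_spikes(train, 1000.0)
        assert list(binned.counts[:3]) == [1, 1, 0]
        assert binned.counts.sum() == 2

    def test_empty_train(self):
        binned = fpvs.bin_spikes(fpvs.SpikeTrain([], 1.0), 1000.0)
        assert binned.counts.sum() == 0
        assert binned.n_bins == 1000

    def test_out_of_range_time_named_in_error(self):
        with pytest.raises(InvalidParameterError, match="70.5"):
            fpvs.bin_spikes(fpvs.SpikeTrain([1.0, 70.500000], 70.0), 1000.0)

    def test_face_locked_comb_peaks_at_oddball_bin(self, spike_schedule):
        """A Dirac comb at the 84 face onsets concentrates at k x 1.2 Hz."""
        train = fpvs.SpikeTrain(spike_schedule.face_onsets_s, 70.0)
        spec = fpvs.amplitude_spectrum(fpvs.bin_spikes(train, 1000.0))
        i = spec.bin_index(1.2)
        neighborhood = spec.amplitudes[i - 10 : i + 11]
        assert np.argmax(neighborhood) == 10
        assert spec.amplitudes[i] > 50 * np.median(neighborhood)
        # harmonics carry the same comb amplitude
        assert spec.amplitudes[spec.bin_index(2.4)] == pytest.approx(spec.amplitudes[i], rel=1e-3)


class TestAmplitudeSpectrum:
    def test_constant_series_has_no_non_dc_power(self):
        spec = fpvs.amplitude_spectrum(np.full(700, 3.0), 10.0)
        assert np.all(spec.amplitudes[1:] < 1e-12)
        assert spec.amplitudes[0] == pytest.approx(3.0)

    def test_pure_cosine_single_bin(self):
        fs, dur = 1000.0, 70.0
        t = np.arange(int(fs * dur)) / fs
        spec = fpvs.amplitude_spectrum(np.cos(2 * np.pi * 1.2 * t), fs)
        i = int(round(1.2 * dur))
        assert i == 84
        assert spec.amplitudes[i] == pytest.approx(1.0, rel=1e-9)
        others = np.delete(spec.amplitudes[1:], i - 1)
        assert np.all(others < 1e-9)

    def test_matches_naive_dft(self, rng):
        """Brute-force O(N^2) DFT oracle on a random 256-sample train."""
        x = rng.poisson(2.0, 256).astype(float)
        spec = fpvs.amplitude_spectrum(x, 256.0)
        n = x.size
        k = np.arange(n // 2 + 1)
        coef = np.array([np.sum(x * np.exp(-2j * np.pi * kk * np.arange(n) / n)) for kk in k])
        amp = np.abs(coef) * 2 / n
        amp[0] /= 2
        amp[-1] /= 2
        np.testing.assert_allclose(spec.amplitudes, amp, rtol=1e-9, atol=1e-12)

    def test_parseval_energy_identity(self, rng):
        """Total spectral energy equals time-domain energy for any train."""
        x = rng.poisson(1.5, 500).astype(float)
        spec = fpvs.amplitude_spectrum(x, 500.0)
        n = x.size
        a = spec.amplitudes.copy()
        energy = n * (a[0] ** 2 + a[-1] ** 2 + np.sum(a[1:-1] ** 2) / 2)
        assert energy == pytest.approx(np.sum(x**2), rel=1e-6)


class TestHarmonicZ:
    def test_hand_computed_z(self):
        """Target 30 over neighbours 10 +/- 2 (population s.d.) gives Z = 10."""
        amps = np.zeros(80)
        amps[30] = 30.0
        amps[20:30] = [8, 12] * 5
        amps[31:41] = [12, 8] * 5
        stats = fpvs.harmonic_z(make_spectrum(amps), [30.0], n_side=10)
        assert stats.z_score == pytest.approx(10.0)
        assert stats.summed_amplitude == 30.0
        assert stats.snr == pytest.approx(3.0)

    def test_zero_z_iff_target_equals_neighbour_mean(self):
        amps = np.zeros(80)
        amps[20:30] = [8, 12] * 5
        amps[31:41] = [12, 8] * 5
        amps[30] = 10.0  # exactly the neighbour mean
        assert fpvs.harmonic_z(make_spectrum(amps), [30.0]).z_score == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        amps = rng.uniform(1, 5, 200)
        z1 = fpvs.harmonic_z(make_spectrum(amps), [100.0]).z_score
        z2 = fpvs.harmonic_z(make_spectrum(amps * 37.5), [100.0]).z_score
        assert z1 == pytest.approx(z2, rel=1e-12)

    def test_degenerate_spectrum_raises(self):
        amps = np.ones(80)
        with pytest.raises(DegenerateSpectrumError):
            fpvs.harmonic_z(make_spectrum(amps), [30.0])

    def test_misaligned_target_raises_with_nearest_bin(self):
        with pytest.raises(MisalignedFrequencyError, match="30"):
            fpvs.harmonic_z(make_spectrum(np.ones(80)), [30.4])

    def test_matches_naive_reimplementation(self, rng):
        """Loop-based sum-then-Z oracle on random 300-bin spectra, 4 harmonics."""
        amps = rng.uniform(0.5, 2.0, 300)
        spec = make_spectrum(amps, df=0.1)
        targets = [3.0, 6.0, 9.0, 12.0]
        stats = fpvs.harmonic_z(spec, targets, n_side=10)
        bins = [int(round(f / 0.1)) for f in targets]
        tsum = sum(amps[b] for b in bins)
        neigh = []
        for pos in range(1, 11):
            neigh.append(sum(amps[b - pos] for b in bins))
            neigh.append(sum(amps[b + pos] for b in bins))
        neigh = np.array(neigh)
        z = (tsum - neigh.mean()) / neigh.std(ddof=0)
        assert stats.z_score == pytest.approx(z, rel=1e-12)
        assert stats.summed_amplitude == pytest.approx(tsum, rel=1e-12)

    def test_blocked_bins_replaced_by_next_outward(self):
        """A neighbour on a harmonic of the other frequency is skipped."""
        amps = np.full(100, 1.0)
        amps[45] = 100.0  # contaminating harmonic inside the neighbourhood
        amps[50] = 5.0
        amps[39] = 3.0  # the next bin outward that replaces it
        spec = make_spectrum(amps)
        with_excl = fpvs.harmonic_z(spec, [50.0], exclude_freqs_hz=[45.0])
        without = fpvs.harmonic_z(spec, [50.0])
        assert with_excl.z_score != pytest.approx(without.z_score)
        # with the contaminant excluded the neighbourhood is 1s and one 3
        neigh = np.array([1.0] * 19 + [3.0])
        assert with_excl.z_score == pytest.approx((5 - neigh.mean()) / neigh.std(ddof=0))


class TestSnrSpectrum:
    def test_flat_spectrum_snr_one(self):
        snr = fpvs.snr_spectrum(make_spectrum(np.full(100, 2.5)))
        inner = snr[13:-12]
        np.testing.assert_allclose(inner, 1.0)
        assert np.isnan(snr[:13]).all() and np.isnan(snr[-12:]).all()

    def test_isolated_peak_snr_is_ratio(self):
        amps = np.full(100, 1.0)
        amps[50] = 10.0
        snr = fpvs.snr_spectrum(make_spectrum(amps))
        assert snr[50] == pytest.approx(10.0)

    def test_matches_loop_oracle_exactly(self, rng):
        amps = rng.uniform(0.1, 3.0, 500)
        snr = fpvs.snr_spectrum(make_spectrum(amps))
        for k in [13, 100, 250, 487]:
            neigh = [amps[k + o] for o in range(2, 13)] + [amps[k - o] for o in range(2, 13)]
            assert snr[k] == pytest.approx(amps[k] / np.mean(neigh), rel=1e-12)


class TestClassifyUnit:
    def test_strong_positive_gain_is_face_selective(self, spike_schedule, rng):
        trains = simulate_unit(spike_schedule, rng, face_gain=0.8)
        c = fpvs.classify_unit(trains, spike_schedule)
        assert c.face_selective_p01 and c.face_selective_p05
        assert c.visually_responsive

    def test_suppressive_unit_is_face_exclusive(self, spike_schedule, rng):
        # duty cycle 2/5 of the face period: the suppression square wave has
        # no 5th/10th harmonic, so nothing leaks into the 6 and 12 Hz bins
        trains = simulate_unit(
            spike_schedule, rng, base_mod_depth=0.0, face_gain=-1.0,
            face_response_duration_s=(1 / 1.2) * (2 / 5),
        )
        c = fpvs.classify_unit(trains, spike_schedule)
        assert c.face_selective_p05
        assert not c.visually_responsive
        assert c.face_exclusive

    def test_p01_implies_p05(self, spike_schedule, rng):
        for gain in (0.0, 0.4, 1.0):
            trains = simulate_unit(spike_schedule, rng, face_gain=gain)
            c = fpvs.classify_unit(trains, spike_schedule)
            assert (not c.face_selective_p01) or c.face_selective_p05

    def test_base_mode_6_only(self, spike_schedule, rng):
        trains = simulate_unit(spike_schedule, rng, face_gain=0.0)
        c6 = fpvs.classify_unit(trains, spike_schedule, base_mode="6")
        c612 = fpvs.classify_unit(trains, spike_schedule, base_mode="6+12")
        assert c6.base_stats.target_freqs_hz == (6.0,)
        assert c612.base_stats.target_freqs_hz == (6.0, 12.0)

    def test_gain_monotonically_raises_face_z(self, spike_schedule):
        """Common-random-number replicates: higher face gain, higher mean face Z."""
        z_lo, z_hi = [], []
        for seed in range(40):
            for gain, store in ((0.3, z_lo), (0.6, z_hi)):
                rng = np.random.default_rng(1000 + seed)
                trains = [
                    fpvs.simulate_spike_train(
                        spike_schedule, fpvs.UnitSimParams(face_gain=gain), rng, sequence_id=k
                    )
                    for k in range(2)
                ]
                store.append(fpvs.classify_unit(trains, spike_schedule).face_z)
        assert np.mean(z_hi) > np.mean(z_lo)
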