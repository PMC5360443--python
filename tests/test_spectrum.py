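import numpy as np
import pandas as pd
import pytest

from hft.recording import EEGRecording
from hft.sim import SimParams, simulate_trial
from hft.spectrum import (
    AmplitudeSpectrum,
    FrequencySet,
    amplitude_spectrum,
    enumerate_im,
    group_significance,
    preprocess,
    snr_at,
    snr_spectrum,
)


def _sine_recording(freq=10.0, fs=500.0, duration=50.0, amp=1.0, n_channels=2):
    t = np.arange(int(fs * duration)) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return EEGRecording(data=data, fs=fs, labels=[f"ch{i}" for i in range(n_channels)])


class TestPreprocess:
    def test_resample_1000_to_500(self):
        rng = np.random.default_rng(0)
        rec = EEGRecording(
            data=rng.standard_normal((3, 10000)),
            fs=1000.0,
            labels=["a", "b", "c"],
            cycle_onsets=np.array([0, 2000, 4000]),
        )
        out = preprocess(rec)
        assert out.fs == 500.0
        assert out.n_samples == 5000
        assert np.array_equal(out.cycle_onsets, [0, 1000, 2000])

    def test_average_reference(self):
        rng = np.random.default_rng(1)
        rec = EEGRecording(
            data=rng.standard_normal((4, 5000)) + 5.0, fs=500.0, labels=list("abcd")
        )
        out = preprocess(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_10hz_attenuation_below_1pct(self):
        # two antiphase channels so the average reference is a no-op and
        # only the high-pass filter acts on the sinusoid
        t = np.arange(25000) / 500.0
        data = np.vstack([np.sin(2 * np.pi * 10.0 * t), -np.sin(2 * np.pi * 10.0 * t)])
        rec = EEGRecording(data=data, fs=500.0, labels=["a", "b"])
        out = preprocess(rec)
        mid = slice(5000, 20000)  # avoid filtfilt edge transients
        amp_ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert abs(1 - amp_ratio) < 0.01

    def test_unsupported_fs(self):
        rec = _sine_recording(fs=256.0, duration=10.0)
        with pytest.raises(ValueError):
            preprocess(rec)


class TestAmplitudeSpectrum:
    def test_resolution_002(self):
        spec = amplitude_spectrum(_sine_recording())
        assert np.isclose(spec.resolution, 0.02)

    def test_unit_sine_calibration(self):
        spec = amplitude_spectrum(_sine_recording(amp=1.0))
        assert np.isclose(spec.amplitude[0, spec.bin_of(10.0)], 1.0, atol=1e-9)

    def test_parseval(self):
        rng = np.random.default_rng(2)
        rec = EEGRecording(data=rng.standard_normal((1, 5000)), fs=500.0, labels=["x"])
        spec = amplitude_spectrum(rec)
        n = rec.n_samples
        amp = spec.amplitude[0]
        # one-sided: power = dc^2 + sum(a_k^2)/2 + nyq^2
        power = amp[0] ** 2 + 0.5 * np.sum(amp[1:-1] ** 2) + amp[-1] ** 2
        assert np.isclose(power, np.mean(rec.data[0] ** 2), rtol=1e-6)


class TestSnrAt:
    def _flat_spectrum(self, value=2.0):
        freqs = np.arange(0, 2501) * 0.02
        amp = np.full((1, freqs.size), value)
        return AmplitudeSpectrum(freqs=freqs, amplitude=amp, labels=["x"])

    def test_flat_spectrum_snr_1(self):
        assert np.isclose(snr_at(self._flat_spectrum(), 10.0)[0], 1.0)

    def test_single_bin_peak(self):
        spec = self._flat_spectrum(1.0)
        spec.amplitude[0, spec.bin_of(10.0)] = 10.0
        assert np.isclose(snr_at(spec, 10.0)[0], 10.0)

    def test_exactly_20_neighbours(self):
        spec = self._flat_spectrum(1.0)
        idx = spec.bin_of(10.0)
        # poison everything outside the +-10-bin window; SNR must not change
        spec.amplitude[0, : idx - 10] = 999.0
        spec.amplitude[0, idx + 11 :] = 999.0
        assert np.isclose(snr_at(spec, 10.0)[0], 1.0)
        # ...and every bin inside the window counts
        spec.amplitude[0, idx - 10] = 21.0  # raises mean of 20 neighbours by 1
        assert np.isclose(snr_at(spec, 10.0)[0], 0.5)

    def test_off_grid_rejected(self):
        with pytest.raises(ValueError):
            snr_at(self._flat_spectrum(), 10.003)

    def test_edge_rejected(self):
        with pytest.raises(ValueError):
            snr_at(self._flat_spectrum(), 0.1)

    def test_scale_invariance(self):
        spec = self._flat_spectrum(1.0)
        spec.amplitude[0, spec.bin_of(7.4)] = 5.0
        v1 = snr_at(spec, 7.4)[0]
        spec.amplitude *= 17.3
        assert np.isclose(snr_at(spec, 7.4)[0], v1)

    def test_noise_snr_near_one(self):
        rng = np.random.default_rng(3)
        params = SimParams(a1=0, a2_base=0, a2_slope=0, g_base=0, g_slope=0, n_channels=2)
        rec = simulate_trial(params, 0.7, rng)
        spec = amplitude_spectrum(rec)
        snr = snr_spectrum(spec)
        bins = rng.integers(100, spec.freqs.size - 50, size=1000)
        vals = snr.amplitude[:, bins]  # both channels, 2000 values
        assert 0.95 < np.nanmean(vals) < 1.05


class TestEnumerateIm:
    def test_four_lowest_order(self):
        comps, coll = enumerate_im(10.0, 1.3, [(1, -2), (1, -1), (1, 1), (1, 2)])
        assert [c.freq for c in comps] == [7.4, 8.7, 11.3, 12.6]
        assert coll == []

    def test_higher_orders(self):
        comps, _ = enumerate_im(10.0, 1.3, [(2, -1), (2, 2)])
        assert [c.freq for c in comps] == [18.7, 22.6]

    def test_collision_with_harmonic(self):
        comps, coll = enumerate_im(10.0, 2.5, [(1, 2)])
        assert comps == []
        assert len(coll) == 1 and coll[0].freq == 15.0  # 6 x 2.5

    def test_zero_order_rejected(self):
        with pytest.raises(ValueError):
            enumerate_im(10.0, 1.3, [(0, 1)])

    def test_grid_exactness(self):
        foi = FrequencySet()
        res = 0.02
        for f in list(foi.roles()):
            assert abs(f / res - round(f / res)) * res < 1e-9


class TestGroupSignificance:
    def test_all_snr_one_not_significant(self):
        df = pd.DataFrame(
            {"participant": range(6), "frequency": 10.0, "snr": [1.0] * 6}
        )
        res = group_significance(df)
        assert np.isnan(res["t"][0]) or res["t"][0] == 0.0
        assert not res["significant"][0]

    def test_fdr_hand_computation(self):
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests([0.001, 0.02, 0.04], method="fdr_bh")
        assert np.allclose(p_adj, [0.003, 0.03, 0.04])

    def test_range_restriction(self):
        df = pd.DataFrame(
            {
                "participant": list(range(4)) * 2,
                "frequency": [0.5] * 4 + [10.0] * 4,
                "snr": [5.0, 6.0, 5.5, 6.5] * 2,
            }
        )
        res = group_significance(df)
        assert set(res["frequency"]) == {10.0}

    def test_insufficient_participants(self):
        df = pd.DataFrame({"participant": [0], "frequency": [10.0], "snr": [2.0]})
        with pytest.raises(ValueError):
            group_significance(df)

    def test_im_significant_iff_gain(self):
        foi = FrequencySet()
        im_freqs = [c.freq for c in foi.im]

        def session_snr(g_base, seed):
            rng = np.random.default_rng(seed)
            rows = []
            params = SimParams(n_channels=4, fs=100.0, g_base=g_base, g_slope=0.0)
            for pid in range(5):
                rec = simulate_trial(params, 0.75, rng)
                spec = amplitude_spectrum(rec)
                for f in im_freqs:
                    rows.append((pid, f, snr_at(spec, f).mean()))
            return pd.DataFrame(rows, columns=["participant", "frequency", "snr"])

        res_on = group_significance(session_snr(0.6, 1))
        assert res_on["significant"].all()
        res_off = group_significance(session_snr(0.0, 2))
        assert not res_off["significant"].any()
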