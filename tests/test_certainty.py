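import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from hft.certainty import (
    certainty_bin,
    fdr_adjust,
    fit_certainty_effect,
    interaction_contrast,
    topo_correlation_compare,
)
from hft.montage import CHANNELS_64
from hft.sim import Topography


class TestCertaintyBin:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.52, 1), (1.00, 10), (0.55, 2), (0.50, 1), (0.999, 10), (0.60, 3), (0.949, 9), (0.95, 10)],
    )
    def test_examples(self, p, expected):
        assert certainty_bin(p).index == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            certainty_bin(0.49)
        with pytest.raises(ValueError):
            certainty_bin(1.01)

    def test_total_function_dense_sweep(self):
        # every p in [0.5, 1] maps to exactly one of 10 bins, no gaps,
        # boundaries left-closed
        ps = np.round(np.arange(0.5, 1.0001, 0.001), 6)
        bins = np.array([certainty_bin(p).index for p in ps])
        assert set(bins) == set(range(1, 11))
        assert (np.diff(bins) >= 0).all()
        for b in range(1, 11):
            lo = 0.5 + 0.05 * (b - 1)
            assert certainty_bin(round(lo, 6)).index == b


def make_table(
    slopes: dict[str, float],
    n_part: int = 4,
    n_chan: int = 6,
    n_trials: int = 10,
    noise: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic tidy SNR table with known log2-SNR certainty slopes.

    Independent oracle for the mixed-model code: the generating model is
    written out directly rather than going through the simulator.
    """
    freq_of = {"ssvep": [10.0], "swift": [1.3], "im": [8.7, 11.3]}
    rng = np.random.default_rng(seed)
    channels = [f"ch{i}" for i in range(n_chan)]
    certainties = np.linspace(0.5, 1.0, n_trials)
    rows = []
    for pid in range(n_part):
        intercept_p = rng.normal(0, 0.2)
        slope_jit = rng.normal(0, 0.01)
        for trial, c in enumerate(certainties):
            bin_idx = certainty_bin(c).index
            for role, freqs in slopes.items():
                for f in freq_of[role]:
                    beta = slopes[role] + slope_jit
                    for ch in channels:
                        log2snr = 1.5 + intercept_p + beta * bin_idx + rng.normal(0, noise)
                        rows.append((pid, trial, c, ch, f, role, 2.0**log2snr))
    df = pd.DataFrame(
        rows,
        columns=["participant", "trial", "certainty", "channel", "frequency", "role", "snr"],
    )
    return df


ROI_SYNTH = tuple(f"ch{i}" for i in range(6))


class TestFitCertaintyEffect:
    def test_recovers_negative_slope(self):
        df = make_table({"swift": -0.08, "ssvep": 0.0}, seed=1)
        res = fit_certainty_effect(
            df, level="frequency", frequency=1.3, random_structure="fast", roi=ROI_SYNTH
        )
        assert res.direction == "-"
        assert res.p_raw < 0.01
        assert res.estimate == pytest.approx(-0.08, abs=0.03)

    def test_flat_slope_not_significant(self):
        df = make_table({"ssvep": 0.0}, seed=2)
        res = fit_certainty_effect(
            df, level="frequency", frequency=10.0, random_structure="fast", roi=ROI_SYNTH
        )
        assert res.p_raw > 0.05

    def test_category_level_pools_frequencies(self):
        df = make_table({"im": 0.06}, seed=3)
        res = fit_certainty_effect(
            df, level="category", category="im", random_structure="fast", roi=ROI_SYNTH
        )
        assert res.direction == "+"
        assert res.p_raw < 0.01

    def test_affine_rescaling_invariance(self):
        df = make_table({"swift": -0.06}, seed=4)
        r1 = fit_certainty_effect(
            df, level="frequency", frequency=1.3, predictor="proportion",
            random_structure="fast", roi=ROI_SYNTH,
        )
        df2 = df.copy()
        df2["certainty"] = 0.5 + 0.5 * (df2["certainty"] - 0.5)  # affine squeeze
        r2 = fit_certainty_effect(
            df2, level="frequency", frequency=1.3, predictor="proportion",
            random_structure="fast", roi=ROI_SYNTH,
        )
        assert r1.chi2 == pytest.approx(r2.chi2, abs=0.05)

    def test_nonpositive_snr_rejected(self):
        df = make_table({"swift": 0.0}, n_part=2, n_trials=4, seed=5)
        df.loc[0, "snr"] = 0.0
        with pytest.raises(ValueError):
            fit_certainty_effect(
                df, level="frequency", frequency=1.3, random_structure="fast", roi=ROI_SYNTH
            )

    def test_permutation_null_chi2_distribution(self):
        # with no certainty effect in the data, permuting the certainty
        # column leaves a null draw; the LRT statistic should then track
        # its asymptotic chi2(1) law
        rng = np.random.default_rng(6)
        stats = []
        for rep in range(40):
            df = make_table({"swift": 0.0}, n_part=3, n_chan=4, n_trials=8, seed=100 + rep)
            uniq = df["certainty"].unique()
            remap = dict(zip(uniq, rng.permutation(uniq)))
            df["certainty"] = df["certainty"].map(remap)
            res = fit_certainty_effect(
                df, level="frequency", frequency=1.3, random_structure="fast", roi=("ch0", "ch1", "ch2", "ch3")
            )
            stats.append(res.chi2)
        ks = spstats.kstest(stats, spstats.chi2(1).cdf)
        assert ks.pvalue > 0.01

    def test_type_i_calibration(self):
        rejections = 0
        n_rep = 60
        for rep in range(n_rep):
            df = make_table({"swift": 0.0}, n_part=4, n_chan=4, n_trials=8, seed=500 + rep)
            res = fit_certainty_effect(
                df, level="frequency", frequency=1.3, random_structure="fast",
                roi=("ch0", "ch1", "ch2", "ch3"),
            )
            rejections += res.p_raw < 0.05
        assert rejections / n_rep <= 0.15


class TestInteractionContrast:
    def test_positive_contrast_recovered(self):
        df = make_table({"ssvep": 0.0, "im": 0.07}, seed=7)
        res = interaction_contrast(df, "im", "ssvep", random_structure="fast", roi=ROI_SYNTH)
        assert res.direction == "+"
        assert res.p_raw < 0.01

    def test_sign_flip_antisymmetry(self):
        df = make_table({"ssvep": 0.0, "im": -0.07}, seed=7)
        res = interaction_contrast(df, "im", "ssvep", random_structure="fast", roi=ROI_SYNTH)
        assert res.direction == "-"

    def test_equal_slopes_calibrated(self):
        # identical injected slopes: rejections should stay near nominal
        rejections = 0
        n_rep = 15
        for rep in range(n_rep):
            df = make_table(
                {"ssvep": 0.03, "im": 0.03}, n_part=3, n_chan=4, n_trials=8, seed=800 + rep
            )
            res = interaction_contrast(
                df, "im", "ssvep", random_structure="fast", roi=("ch0", "ch1", "ch2", "ch3")
            )
            rejections += res.p_raw < 0.05
        assert rejections / n_rep <= 0.25


class TestFdrAdjust:
    def test_step_up(self):
        from hft.certainty import LMEResult

        results = [
            LMEResult("frequency", f"{f}", "certainty", 0.0, "0", 1.0, 1, p)
            for f, p in zip((1, 2, 3), (0.001, 0.02, 0.04))
        ]
        adj = fdr_adjust(results)
        assert [round(r.p_fdr, 10) for r in adj] == [0.003, 0.03, 0.04]


class TestTopoComparison:
    def test_identical_maps(self):
        m = np.arange(10.0)
        res = topo_correlation_compare(m, m, m)
        assert res.r_im_ssvep == pytest.approx(1.0)
        assert res.z == 0.0

    def test_closed_form(self):
        # construct maps with known correlations r1 = 0.8, r2 = 0.3
        rng = np.random.default_rng(9)
        n = 64
        base = rng.standard_normal(n)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        im_map = base
        ssvep_map = 0.8 * base + np.sqrt(1 - 0.64) * a
        swift_map = 0.3 * base + np.sqrt(1 - 0.09) * b
        res = topo_correlation_compare(im_map, ssvep_map, swift_map)
        expected = (np.arctanh(res.r_im_ssvep) - np.arctanh(res.r_im_swift)) / np.sqrt(
            2.0 / (n - 3)
        )
        assert res.z == pytest.approx(expected)
        assert res.n_channels == 64

    def test_simulator_topographies_favor_ssvep(self):
        topo = Topography.standard(list(CHANNELS_64))
        res = topo_correlation_compare(topo.interaction, topo.bottom_up, topo.top_down)
        assert res.z > 0
        assert res.r_im_ssvep > res.r_im_swift

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            topo_correlation_compare(np.ones(10), np.arange(10.0), np.arange(10.0))

    def test_too_few_channels(self):
        with pytest.raises(ValueError):
            topo_correlation_compare(np.arange(3.0), np.arange(3.0), np.arange(3.0))
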