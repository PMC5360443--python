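"""Spectral analysis: preprocessing, amplitude spectra, neighbour-bin SNR,
intermodulation enumeration, and group-level significance tests.

SNR at a tagged frequency is the amplitude at that bin divided by the
mean amplitude of the 10 bins on either side (20 neighbours total,
+-0.02 to +-0.2 Hz at the canonical 0.02 Hz resolution), so SNR = 1
means no tagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .recording import EEGRecording

__all__ = [
    "AmplitudeSpectrum",
    "FrequencySet",
    "IMComponent",
    "amplitude_spectrum",
    "enumerate_im",
    "group_significance",
    "preprocess",
    "snr_at",
    "snr_spectrum",
    "snr_table",
]

N_NEIGHBORS_PER_SIDE = 10
GRID_TOL = 1e-6


def preprocess(
    rec: EEGRecording, target_fs: float = 500.0, highpass_hz: float = 0.6
) -> EEGRecording:
    """Resample to 500 Hz, high-pass at 0.6 Hz, convert to average reference.

    The high-pass is a zero-phase 4th-order Butterworth (applied
    forward-backward).  Inputs at 1000 Hz are decimated by polyphase
    anti-aliased resampling; 500 Hz inputs pass through.
    """
    if rec.fs not in (500.0, 1000.0) and not np.isclose(rec.fs, target_fs):
        raise ValueError(f"unsupported sampling rate {rec.fs}")
    data = rec.data
    onsets = rec.cycle_onsets
    fs = rec.fs
    if fs != target_fs:
        down = int(round(fs / target_fs))
        data = sps.resample_poly(data, up=1, down=down, axis=1)
        onsets = onsets // down
        fs = target_fs
    sos = sps.butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
    data = sps.sosfiltfilt(sos, data, axis=1)
    data = data - data.mean(axis=0, keepdims=True)
    return EEGRecording(data=data, fs=fs, labels=list(rec.labels), cycle_onsets=onsets)


@dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum per channel.

    Normalised so a unit-amplitude sinusoid on the bin grid yields
    amplitude 1.0 at its bin (2/N scaling; DC and Nyquist 1/N).
    """

    freqs: np.ndarray  # strictly increasing, spacing = 1/duration
    amplitude: np.ndarray  # (n_channels, n_bins)
    labels: list[str] = field(default_factory=list)

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def bin_of(self, f: float) -> int:
        """Index of the bin at frequency ``f``; error if off-grid."""
        idx = int(round(f / self.resolution))
        if idx < 0 or idx >= self.freqs.size or abs(self.freqs[idx] - f) > GRID_TOL:
            raise ValueError(f"{f} Hz is not on the {self.resolution} Hz bin grid")
        return idx


def amplitude_spectrum(rec: EEGRecording) -> AmplitudeSpectrum:
    """Trial-level FFT amplitude spectrum (bin spacing = 1/duration)."""
    n = rec.n_samples
    spec = np.abs(np.fft.rfft(rec.data, axis=1))
    amp = spec * (2.0 / n)
    amp[:, 0] = spec[:, 0] / n
    if n % 2 == 0:
        amp[:, -1] = spec[:, -1] / n
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.fs)
    return AmplitudeSpectrum(freqs=freqs, amplitude=amp, labels=list(rec.labels))


def snr_at(
    spec: AmplitudeSpectrum, f: float, n_neighbors: int = N_NEIGHBORS_PER_SIDE
) -> np.ndarray:
    """Per-channel SNR at an on-grid frequency.

    Amplitude at ``f`` divided by the mean over ``n_neighbors`` bins on
    each side of ``f`` (the bin itself excluded): 20 neighbours spanning
    +-0.02 to +-0.2 Hz at the 0.02 Hz canonical resolution.
    """
    idx = spec.bin_of(f)
    if idx - n_neighbors < 0 or idx + n_neighbors >= spec.freqs.size:
        raise ValueError(f"{f} Hz is within {n_neighbors} bins of the spectrum edge")
    sl = np.r_[idx - n_neighbors : idx, idx + 1 : idx + n_neighbors + 1]
    denom = spec.amplitude[:, sl].mean(axis=1)
    return spec.amplitude[:, idx] / denom


def snr_spectrum(
    spec: AmplitudeSpectrum, n_neighbors: int = N_NEIGHBORS_PER_SIDE
) -> AmplitudeSpectrum:
    """SNR at every bin (NaN within ``n_neighbors`` bins of the edges)."""
    amp = spec.amplitude
    win = 2 * n_neighbors + 1
    kernel = np.ones(win) / (2 * n_neighbors)
    kernel[n_neighbors] = 0.0
    neigh = np.apply_along_axis(lambda a: np.convolve(a, kernel, mode="same"), 1, amp)
    snr = amp / neigh
    snr[:, :n_neighbors] = np.nan
    snr[:, -n_neighbors:] = np.nan
    return AmplitudeSpectrum(freqs=spec.freqs, amplitude=snr, labels=list(spec.labels))


@dataclass(frozen=True)
class IMComponent:
    """Intermodulation frequency ``n1*f1 + n2*f2`` (both orders nonzero)."""

    n1: int
    n2: int
    freq: float

    @property
    def order(self) -> int:
        return abs(self.n1) + abs(self.n2)

    @property
    def name(self) -> str:
        s1 = "f1" if self.n1 == 1 else f"{self.n1}f1"
        s2 = {1: "+f2", -1: "-f2"}.get(self.n2, f"{self.n2:+d}f2")
        return s1 + s2


def _is_harmonic(freq: float, base: float, tol: float = 1e-9) -> bool:
    k = round(freq / base)
    return k >= 1 and abs(freq - k * base) < tol


def enumerate_im(
    f1: float, f2: float, orders: list[tuple[int, int]]
) -> tuple[list[IMComponent], list[IMComponent]]:
    """Intermodulation components for the given (n1, n2) order pairs.

    Returns ``(components, collisions)``: unique positive-frequency
    components sorted by frequency, and the rejected components whose
    frequency coincides with a pure harmonic of f1 or f2.
    """
    if f1 <= 0 or f2 <= 0:
        raise ValueError("tagging frequencies must be positive")
    comps: dict[float, IMComponent] = {}
    collisions: list[IMComponent] = []
    for n1, n2 in orders:
        if n1 == 0 or n2 == 0:
            raise ValueError(f"({n1}, {n2}): zero order is a harmonic, not an IM")
        freq = round(n1 * f1 + n2 * f2, 9)
        if freq <= 0:
            continue
        comp = IMComponent(n1=n1, n2=n2, freq=freq)
        if _is_harmonic(freq, f1) or _is_harmonic(freq, f2):
            collisions.append(comp)
            continue
        comps.setdefault(freq, comp)
    return [comps[f] for f in sorted(comps)], collisions


#: the four lowest-order intermodulation order pairs analysed by default
DEFAULT_IM_ORDERS: tuple[tuple[int, int], ...] = ((1, -2), (1, -1), (1, 1), (1, 2))


@dataclass
class FrequencySet:
    """Tagged-frequency bookkeeping for one (f1, f2) design."""

    f1: float = 10.0
    f2: float = 1.3
    n1_harmonics: tuple[int, ...] = (1, 2)
    n2_harmonics: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    im_orders: tuple[tuple[int, int], ...] = DEFAULT_IM_ORDERS

    @property
    def ssvep_harmonics(self) -> list[float]:
        return [round(n * self.f1, 9) for n in self.n1_harmonics]

    @property
    def swift_harmonics(self) -> list[float]:
        return [round(n * self.f2, 9) for n in self.n2_harmonics]

    @property
    def im(self) -> list[IMComponent]:
        return enumerate_im(self.f1, self.f2, list(self.im_orders))[0]

    def roles(self) -> dict[float, str]:
        """Frequency -> role map over every tagged frequency."""
        out: dict[float, str] = {}
        for f in self.ssvep_harmonics:
            out[f] = "ssvep" if f == self.f1 else "harmonic"
        for f in self.swift_harmonics:
            out[f] = "swift" if f == self.f2 else "harmonic"
        for c in self.im:
            out[c.freq] = "im"
        return out

    def analysis_frequencies(self) -> dict[float, str]:
        """The frequencies entering the certainty models.

        f1 and f2, their first harmonics, and the four lowest-order IM
        components; values are category labels ssvep/swift/im.
        """
        out = {self.f1: "ssvep", round(2 * self.f1, 9): "ssvep",
               self.f2: "swift", round(2 * self.f2, 9): "swift"}
        for c in self.im:
            out[c.freq] = "im"
        return out


def snr_table(
    trials,
    foi: FrequencySet | None = None,
    *,
    channels: list[str] | None = None,
    do_preprocess: bool = True,
) -> pd.DataFrame:
    """Tidy per-trial, per-channel SNR table at all tagged frequencies.

    ``trials`` is an iterable of :class:`~hft.sim.SessionTrial` (or of
    ``(participant, trial, certainty, EEGRecording)`` tuples).  Columns:
    participant, trial, certainty, channel, frequency, role, snr,
    log2snr.
    """
    foi = foi or FrequencySet()
    rows = []
    for item in trials:
        if hasattr(item, "recording"):
            pid, tid, cert, rec = item.participant, item.trial, item.certainty, item.recording
        else:
            pid, tid, cert, rec = item
        if do_preprocess:
            rec = preprocess(rec, target_fs=rec.fs if rec.fs != 1000.0 else 500.0)
        spec = amplitude_spectrum(rec)
        if channels is not None:
            keep = [i for i, lab in enumerate(rec.labels) if lab in channels]
            labels = [rec.labels[i] for i in keep]
            spec = AmplitudeSpectrum(
                freqs=spec.freqs, amplitude=spec.amplitude[keep], labels=labels
            )
        else:
            labels = list(rec.labels)
        for freq, role in foi.roles().items():
            snr = snr_at(spec, freq)
            for ch, val in zip(labels, snr):
                rows.append((pid, tid, cert, ch, freq, role, val))
    df = pd.DataFrame(
        rows,
        columns=["participant", "trial", "certainty", "channel", "frequency", "role", "snr"],
    )
    if (df["snr"] <= 0).any():
        raise ValueError("non-positive SNR encountered; cannot take log2")
    df["log2snr"] = np.log2(df["snr"])
    return df


def group_significance(
    snr_by_participant: pd.DataFrame,
    alpha: float = 0.01,
    *,
    f_range: tuple[float, float] = (1.0, 40.0),
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-sample t-tests of participant-mean SNR against 1, FDR-adjusted.

    ``snr_by_participant`` needs columns participant, frequency, snr
    (one row per participant x frequency; average over trials/channels
    first).  Frequencies outside ``f_range`` are dropped.  FDR is
    Benjamini-Hochberg across all tested frequencies.
    """
    df = snr_by_participant
    required = {"participant", "frequency", "snr"}
    if not required.issubset(df.columns):
        raise ValueError(f"need columns {sorted(required)}")
    out = []
    for freq, grp in df.groupby("frequency"):
        if not (f_range[0] <= freq <= f_range[1]):
            continue
        vals = grp.groupby("participant")["snr"].mean().to_numpy()
        if vals.size < 2:
            raise ValueError("need at least 2 participants per frequency")
        t, p = spstats.ttest_1samp(vals, 1.0, alternative=alternative)
        out.append((freq, vals.size, t, p))
    res = pd.DataFrame(out, columns=["frequency", "n", "t", "p_raw"])
    if len(res):
        rej, p_fdr, _, _ = multipletests(res["p_raw"], alpha=alpha, method="fdr_bh")
        res["p_fdr"] = p_fdr
        res["significant"] = rej
    return res.sort_values("frequency").reset_index(drop=True)
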