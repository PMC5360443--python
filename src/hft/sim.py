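"""Synthetic multichannel EEG forward model.

Generates recordings containing a contrast-driven response at f1 (plus
one harmonic), a scrambling-driven response at f2 (harmonic series), and
an interaction term formed by multiplying the two source waveforms — the
minimal nonlinearity that produces intermodulation components at
``n1*f1 + n2*f2``.  Source amplitudes depend linearly on the trial's
certainty level, with a negative slope for the f2 source and a positive
slope for the interaction gain, mirroring the qualitative effect
directions the analysis pipeline is meant to recover.  Background noise
is 1/f-shaped Gaussian, independent per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .montage import (
    CENTRO_PARIETAL,
    OCCIPITAL,
    TEMPORO_PARIETAL,
    default_labels,
)
from .recording import EEGRecording

__all__ = [
    "SimParams",
    "SessionTrial",
    "Topography",
    "inject_artifacts",
    "iter_session",
    "simulate_session",
    "simulate_trial",
]


@dataclass
class SimParams:
    """Forward-model parameters (amplitudes in microvolts)."""

    f1: float = 10.0
    f2: float = 1.3
    a1: float = 2.0  # contrast-response source amplitude
    a2_base: float = 1.5  # scrambling-response amplitude at certainty 0.5
    a2_slope: float = -1.6  # per unit certainty (negative: decreases)
    g_base: float = 0.3  # interaction gain at certainty 0.5
    g_slope: float = 1.0  # per unit certainty (positive: increases)
    n_harmonics_swift: int = 8
    noise_exponent: float = 1.0  # power ~ 1/f^exponent
    noise_scale: float = 1.0  # noise standard deviation, microvolts
    n_channels: int = 64
    fs: float = 500.0
    duration_s: float = 50.0
    nonlinearity: str = "product"  # or "quadratic": (b + s)^2 static nonlinearity

    def __post_init__(self) -> None:
        if min(self.a1, self.a2_base, self.noise_scale) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.nonlinearity not in ("product", "quadratic"):
            raise ValueError("nonlinearity must be 'product' or 'quadratic'")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass
class Topography:
    """Per-channel source weights.

    Bottom-up (and interaction) weights peak over occipital channels;
    top-down weights peak over temporo-parietal channels.
    """

    labels: list[str]
    bottom_up: np.ndarray
    top_down: np.ndarray
    interaction: np.ndarray

    @classmethod
    def standard(cls, labels: list[str]) -> "Topography":
        bu, td, im = [], [], []
        for lab in labels:
            if lab in OCCIPITAL:
                w = (1.0, 0.40, 1.0)
            elif lab in TEMPORO_PARIETAL:
                w = (0.30, 1.0, 0.30)
            elif lab in CENTRO_PARIETAL:
                w = (0.50, 0.80, 0.45)
            else:
                w = (0.10, 0.20, 0.10)
            bu.append(w[0])
            td.append(w[1])
            im.append(w[2])
        return cls(
            labels=list(labels),
            bottom_up=np.array(bu),
            top_down=np.array(td),
            interaction=np.array(im),
        )


def _pink_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, exponent: float, scale: float
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^exponent, unit-free RMS ``scale``."""
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * shaping
    noise = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = noise.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return scale * noise / rms


def _source_waveforms(params: SimParams, certainty: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.arange(params.n_samples) / params.fs
    b = params.a1 * (
        np.sin(2 * np.pi * params.f1 * t) + 0.3 * np.sin(4 * np.pi * params.f1 * t)
    )
    s_unit = sum(
        (1.0 / k) * np.sin(2 * np.pi * k * params.f2 * t)
        for k in range(1, params.n_harmonics_swift + 1)
    )
    a2 = max(params.a2_base + params.a2_slope * (certainty - 0.5), 0.0)
    s = a2 * s_unit
    g = max(params.g_base + params.g_slope * (certainty - 0.5), 0.0)
    # The interaction multiplies the *unit-amplitude* waveforms, so the
    # IM certainty trend is set by g alone; multiplying the full
    # amplitude-modulated s would couple the falling a2 into the IM
    # amplitudes and cancel the rising gain at the default effect sizes.
    if params.nonlinearity == "product":
        i = g * (b / max(params.a1, 1e-12)) * s_unit
    else:
        i = g * (b / max(params.a1, 1e-12) + s_unit) ** 2
    return b, s, i


def simulate_trial(
    params: SimParams,
    certainty: float,
    rng: np.random.Generator,
    topography: Topography | None = None,
) -> EEGRecording:
    """One trial's recording at the given certainty level (in [0.5, 1])."""
    if not (0.5 <= certainty <= 1.0):
        raise ValueError("certainty must lie in [0.5, 1]")
    labels = default_labels(params.n_channels)
    topo = topography if topography is not None else Topography.standard(labels)
    b, s, i = _source_waveforms(params, certainty)
    data = (
        topo.bottom_up[:, None] * b
        + topo.top_down[:, None] * s
        + topo.interaction[:, None] * i
    )
    if params.noise_scale > 0:
        data = data + _pink_noise(
            rng, params.n_channels, params.n_samples, params.noise_exponent, params.noise_scale
        )
    else:
        data = data + 0.0  # materialise a copy
    n_cycles = int(np.floor(params.duration_s * params.f2 + 1e-9))
    onsets = np.floor(np.arange(n_cycles) * params.fs / params.f2).astype(int)
    return EEGRecording(data=data, fs=params.fs, labels=labels, cycle_onsets=onsets)


@dataclass
class SessionTrial:
    """One simulated trial plus its behavioural record."""

    participant: int
    trial: int
    certainty: float
    recording: EEGRecording
    instructed: str
    true_count: int
    response_count: int


def _behaviour(
    certainty: float, rng: np.random.Generator, n_cycles: int, error_rate: float
) -> tuple[str, int, int]:
    instructed = "face" if rng.random() < 0.5 else "house"
    dominant_count = int(np.floor(certainty * n_cycles + 0.5))
    true_count = dominant_count if instructed == "face" else n_cycles - dominant_count
    response = true_count
    if error_rate > 0 and rng.random() < error_rate:
        response = max(0, true_count + int(rng.integers(-3, 4)))
    return instructed, true_count, response


def iter_session(
    params: SimParams,
    n_participants: int,
    trials_per_participant: int = 56,
    certainty_grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    *,
    behavioral_error_rate: float = 0.0,
    between_participant_sd: float = 0.1,
):
    """Yield :class:`SessionTrial` objects one at a time (memory-friendly).

    Each participant gets lognormal multiplicative random effects on the
    source amplitudes and interaction gain, plus a mild jitter of the
    topography weights, before the trial-level noise draw.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    if rng is None:
        rng = np.random.default_rng()
    if certainty_grid is None:
        certainty_grid = np.linspace(0.5, 1.0, trials_per_participant)
    certainty_grid = np.asarray(certainty_grid, dtype=float)
    labels = default_labels(params.n_channels)
    base_topo = Topography.standard(labels)
    n_cycles = int(np.floor(params.duration_s * params.f2 + 1e-9))

    for p in range(n_participants):
        fac = np.exp(rng.normal(0.0, between_participant_sd, size=3))
        slope_fac = np.exp(rng.normal(0.0, between_participant_sd, size=2))
        pp = replace(
            params,
            a1=params.a1 * fac[0],
            a2_base=params.a2_base * fac[1],
            g_base=params.g_base * fac[2],
            a2_slope=params.a2_slope * slope_fac[0],
            g_slope=params.g_slope * slope_fac[1],
        )
        jitter = 1.0 + rng.normal(0.0, between_participant_sd / 2.0, size=(3, len(labels)))
        topo = Topography(
            labels=labels,
            bottom_up=base_topo.bottom_up * jitter[0],
            top_down=base_topo.top_down * jitter[1],
            interaction=base_topo.interaction * jitter[2],
        )
        order = rng.permutation(certainty_grid.size)
        n_trials = min(trials_per_participant, certainty_grid.size)
        for t in range(n_trials):
            certainty = float(certainty_grid[order[t]])
            rec = simulate_trial(pp, certainty, rng, topography=topo)
            instructed, true_count, response = _behaviour(
                certainty, rng, n_cycles, behavioral_error_rate
            )
            yield SessionTrial(
                participant=p,
                trial=t,
                certainty=certainty,
                recording=rec,
                instructed=instructed,
                true_count=true_count,
                response_count=response,
            )


def simulate_session(*args, **kwargs) -> list[SessionTrial]:
    """Materialised list version of :func:`iter_session`.

    Note: a full-size session (56 trials x 64 channels x 25,000 samples)
    holds ~0.7 GB; prefer :func:`iter_session` for streaming analysis.
    """
    return list(iter_session(*args, **kwargs))


def inject_artifacts(
    rec: EEGRecording,
    cycle_fraction: float,
    rng: np.random.Generator,
    *,
    amplitude: float = 160.0,
    sample_fraction: float = 0.05,
) -> tuple[EEGRecording, np.ndarray]:
    """Corrupt a fraction of cycles with large spikes and step artifacts.

    Selected cycles get ``sample_fraction`` of their sample points (on
    every channel) replaced by alternating +/-``amplitude`` microvolt
    values, exceeding both the absolute-amplitude and the
    sample-to-sample-step noise thresholds.  Returns the corrupted copy
    and the boolean ground-truth mask of injected cycles.
    """
    if not (0.0 <= cycle_fraction <= 1.0):
        raise ValueError("cycle_fraction must lie in [0, 1]")
    out = rec.copy()
    slices = out.cycle_slices()
    n_cycles = len(slices)
    n_bad = int(round(cycle_fraction * n_cycles))
    truth = np.zeros(n_cycles, dtype=bool)
    if n_bad == 0:
        return out, truth
    bad = rng.choice(n_cycles, size=n_bad, replace=False)
    truth[bad] = True
    for c in bad:
        sl = slices[c]
        length = sl.stop - sl.start
        k = max(1, int(np.ceil(sample_fraction * length)))
        pos = sl.start + rng.choice(length, size=k, replace=False)
        signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
        out.data[:, pos] = amplitude * signs
    return out, truth
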