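"""Behavioural and EEG quality control: noisy-sample flagging, noisy-cycle
replacement, and participant/trial exclusion rules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import EEGRecording

__all__ = [
    "BehavioralRecord",
    "NoiseMask",
    "exclude_participants",
    "exclude_trials",
    "exclusion_summary",
    "flag_noisy_cycles",
    "flag_noisy_samples",
    "replace_noisy_cycles",
]

ABS_THRESHOLD_UV = 80.0
STEP_THRESHOLD_UV = 40.0
SD_THRESHOLD = 6.0
CYCLE_NOISY_FRACTION = 0.02  # "over 2%" is a strict inequality
PARTICIPANT_NOISY_FRACTION = 0.10
COUNTING_R_THRESHOLD = 0.9
TRIAL_SD_CUTOFF = 2.5


@dataclass
class NoiseMask:
    """Boolean noise flags per (channel, sample) and per cycle."""

    flags: np.ndarray  # (n_channels, n_samples)
    cycle_flags: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def fraction_noisy_cycles(self) -> float:
        if self.cycle_flags.size == 0:
            return 0.0
        return float(self.cycle_flags.mean())


def flag_noisy_samples(
    rec: EEGRecording,
    abs_threshold: float = ABS_THRESHOLD_UV,
    step_threshold: float = STEP_THRESHOLD_UV,
    sd_threshold: float = SD_THRESHOLD,
) -> NoiseMask:
    """Flag sample points that violate any of three per-channel rules.

    A sample is noisy if (1) its absolute value exceeds +-80 uV, (2) it
    jumps more than 40 uV from the previous sample, or (3) it lies more
    than 6 trial standard deviations from the channel's trial mean.
    """
    x = rec.data
    rule1 = np.abs(x) > abs_threshold
    rule2 = np.zeros_like(rule1)
    rule2[:, 1:] = np.abs(np.diff(x, axis=1)) > step_threshold
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf
    rule3 = np.abs(x - mu) > sd_threshold * sd
    return NoiseMask(flags=rule1 | rule2 | rule3)


def flag_noisy_cycles(
    mask: NoiseMask,
    rec: EEGRecording,
    threshold: float = CYCLE_NOISY_FRACTION,
    *,
    per_channel: bool = False,
) -> NoiseMask:
    """Flag cycles in which the noisy-sample fraction strictly exceeds 2%.

    By default the fraction pools flagged sample points over all
    channels; ``per_channel=True`` flags a cycle if any single channel
    exceeds the threshold.
    """
    slices = rec.cycle_slices()
    cycle_flags = np.zeros(len(slices), dtype=bool)
    for i, sl in enumerate(slices):
        block = mask.flags[:, sl]
        if per_channel:
            cycle_flags[i] = bool((block.mean(axis=1) > threshold).any())
        else:
            cycle_flags[i] = bool(block.mean() > threshold)
    return NoiseMask(flags=mask.flags, cycle_flags=cycle_flags)


def replace_noisy_cycles(rec: EEGRecording, mask: NoiseMask) -> EEGRecording:
    """Replace every sample of flagged cycles by the channel's trial mean.

    Unflagged samples are untouched (bitwise identical).
    """
    out = rec.copy()
    if mask.cycle_flags.size == 0 or not mask.cycle_flags.any():
        return out
    means = rec.data.mean(axis=1)
    for sl, bad in zip(rec.cycle_slices(), mask.cycle_flags):
        if bad:
            out.data[:, sl] = means[:, None]
    return out


@dataclass
class BehavioralRecord:
    """One trial's counting task outcome."""

    trial: int
    instructed: str
    response_count: int
    true_count: int

    def __post_init__(self) -> None:
        if self.response_count < 0 or self.true_count < 0:
            raise ValueError("counts must be non-negative")


def _counting_r(records: list[BehavioralRecord]) -> float:
    resp = np.array([r.response_count for r in records], dtype=float)
    true = np.array([r.true_count for r in records], dtype=float)
    if np.std(resp) == 0 or np.std(true) == 0:
        return np.nan
    return float(np.corrcoef(resp, true)[0, 1])


def exclude_participants(
    behavior: dict[int, list[BehavioralRecord]],
    noisy_fraction: dict[int, float],
    r_threshold: float = COUNTING_R_THRESHOLD,
    noise_threshold: float = PARTICIPANT_NOISY_FRACTION,
) -> pd.DataFrame:
    """Participant-level exclusion report.

    A participant is excluded when counting accuracy r < 0.9 (strict) or
    when over 10% of their cycles were noisy.  Undefined r (zero
    variance in the counts) is flagged for manual review rather than
    auto-excluded.
    """
    rows = []
    for pid, records in behavior.items():
        if not records:
            raise ValueError(f"participant {pid} has no trials")
        r = _counting_r(records)
        frac = float(noisy_fraction.get(pid, 0.0))
        reasons = []
        manual = False
        if np.isnan(r):
            manual = True
            reasons.append("undefined_counting_r")
        elif r < r_threshold:
            reasons.append("low_counting_accuracy")
        if frac > noise_threshold:
            reasons.append("noisy_eeg")
        excluded = any(reason != "undefined_counting_r" for reason in reasons)
        rows.append(
            {
                "participant": pid,
                "counting_r": r,
                "fraction_noisy_cycles": frac,
                "excluded": excluded,
                "manual_review": manual,
                "reason": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def exclude_trials(
    records: list[BehavioralRecord],
    cutoff_sd: float = TRIAL_SD_CUTOFF,
    *,
    absolute: bool = False,
) -> np.ndarray:
    """Keep-mask over trials from the 2.5 SD response-accuracy rule.

    ``d = response - true`` per trial; a trial is kept iff
    ``|d - mean(d)| <= 2.5 * sd(d)``.  With ``absolute=True`` the rule
    is applied to ``|d|`` instead (the distance variant).  Zero spread
    keeps everything.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 trials")
    d = np.array([r.response_count - r.true_count for r in records], dtype=float)
    if absolute:
        d = np.abs(d)
    sd = d.std(ddof=1)
    if sd == 0:
        return np.ones(len(records), dtype=bool)
    return np.abs(d - d.mean()) <= cutoff_sd * sd


def exclusion_summary(
    n_participants_included: int,
    trials_per_participant: int,
    n_trials_excluded: int,
) -> dict:
    """Totals for the within-participant exclusion step.

    Returns the pooled trial count and the excluded percentage rounded
    to one decimal.
    """
    total = n_participants_included * trials_per_participant
    pct = round(100.0 * n_trials_excluded / total, 1)
    return {
        "n_participants": n_participants_included,
        "trials_per_participant": trials_per_participant,
        "total_trials": total,
        "n_trials_excluded": n_trials_excluded,
        "pct_trials_excluded": pct,
    }
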