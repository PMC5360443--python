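"""64-channel 10-10 montage and the posterior region of interest."""

from __future__ import annotations

__all__ = ["CHANNELS_64", "POSTERIOR_ROI", "posterior_roi", "default_labels"]

# Posterior ROI: all centro-parietal, temporo-parietal, parietal,
# parieto-occipital and occipital electrodes (30 in total).
POSTERIOR_ROI: tuple[str, ...] = (
    "CPz", "CP1", "CP2", "CP3", "CP4", "CP5", "CP6",
    "TP7", "TP8", "TP9", "TP10",
    "Pz", "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8",
    "POz", "PO3", "PO4", "PO7", "PO8", "PO9", "PO10",
    "Oz", "O1", "O2",
)

_ANTERIOR: tuple[str, ...] = (
    "Fp1", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
)

CHANNELS_64: tuple[str, ...] = _ANTERIOR + POSTERIOR_ROI

assert len(CHANNELS_64) == 64 and len(set(CHANNELS_64)) == 64
assert len(POSTERIOR_ROI) == 30

# channel groups used by the forward model's topographies
OCCIPITAL = ("Oz", "O1", "O2", "POz", "PO3", "PO4", "PO7", "PO8", "PO9", "PO10")
TEMPORO_PARIETAL = (
    "TP7", "TP8", "TP9", "TP10",
    "P5", "P6", "P7", "P8", "CP5", "CP6",
)
CENTRO_PARIETAL = ("CPz", "CP1", "CP2", "CP3", "CP4", "Pz", "P1", "P2", "P3", "P4")


def default_labels(n_channels: int = 64) -> list[str]:
    """First ``n_channels`` labels, posterior electrodes first.

    Reduced montages (used to scale simulations down) keep occipital and
    temporo-parietal coverage so topography invariants stay testable.
    """
    if n_channels == 64:
        return list(CHANNELS_64)
    if n_channels > 64:
        raise ValueError("montage supports at most 64 channels")
    posterior_first = POSTERIOR_ROI + _ANTERIOR
    return list(posterior_first[:n_channels])


def posterior_roi(labels: list[str] | None = None) -> list[str]:
    """ROI labels present in ``labels`` (all 30 when ``labels`` is None)."""
    if labels is None:
        return list(POSTERIOR_ROI)
    return [lab for lab in labels if lab in POSTERIOR_ROI]
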