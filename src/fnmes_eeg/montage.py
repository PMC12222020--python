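"""64-channel 10–20/10–10 montage: names, template coordinates, neighbours, ROIs.

The cap layout is the standard extended 10–20 set used by 64-channel
waveguard-style systems.  Electrode coordinates come from the idealised
template head shipped with MNE-Python; they are needed only to define
neighbour relations for channel interpolation, never for source modelling.
"""

from __future__ import annotations

import functools

import numpy as np

#: The 64 scalp channels, frontal to occipital rows.
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2", "Iz",
)

#: Occipito-temporal electrodes over which trial-level N170 amplitude is
#: averaged (the face-sensitive posterior set).
N170_CHANNELS: tuple[str, ...] = (
    "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

#: Central (somatomotor) region of interest.
ROI_CENTRAL: tuple[str, ...] = ("Cz", "C1", "C2", "C3", "C4")
#: Occipital regions of interest paired with the central set for coherence.
ROI_OCCIPITAL_LEFT: tuple[str, ...] = ("P1", "P3", "P5", "P7", "PO3", "PO5", "PO7")
ROI_OCCIPITAL_MIDDLE: tuple[str, ...] = ("Pz", "POz", "Oz")
ROI_OCCIPITAL_RIGHT: tuple[str, ...] = ("P2", "P4", "P6", "P8", "PO4", "PO6", "PO8")

OCCIPITAL_ROIS: dict[str, tuple[str, ...]] = {
    "left": ROI_OCCIPITAL_LEFT,
    "middle": ROI_OCCIPITAL_MIDDLE,
    "right": ROI_OCCIPITAL_RIGHT,
}


def channel_index(names: list[str] | tuple[str, ...], subset) -> np.ndarray:
    """Indices of ``subset`` channels within ``names`` (raises on a miss)."""
    lut = {c: i for i, c in enumerate(names)}
    missing = [c for c in subset if c not in lut]
    if missing:
        raise KeyError(f"channels not in montage: {missing}")
    return np.array([lut[c] for c in subset], dtype=int)


@functools.lru_cache(maxsize=1)
def template_positions() -> dict[str, np.ndarray]:
    """3-D template coordinates (metres) for the 64 montage channels."""
    import mne

    with np.errstate(all="ignore"):
        try:
            mon = mne.channels.make_standard_montage("colin27_1005")
        except ValueError:  # older MNE naming
            mon = mne.channels.make_standard_montage("standard_1005")
    pos = mon.get_positions()["ch_pos"]
    return {ch: np.asarray(pos[ch], dtype=float) for ch in CHANNELS_64}


def neighbours(channel: str, radius: float = 0.045) -> list[str]:
    """Montage channels within ``radius`` metres of ``channel`` (excl. itself)."""
    pos = template_positions()
    p0 = pos[channel]
    out = [c for c in CHANNELS_64
           if c != channel and np.linalg.norm(pos[c] - p0) <= radius]
    return out


def posterior_gain_profile(frontal: float = 1.0, occipital: float = 0.1) -> np.ndarray:
    """Per-channel gain decreasing from the face (frontal/temporal) towards
    the occiput — the spatial footprint of a stimulation artifact whose
    source sits on the cheeks.

    Gains interpolate linearly in the anterior–posterior (y) coordinate from
    ``frontal`` at the front of the cap to ``occipital`` at the back.
    """
    pos = template_positions()
    y = np.array([pos[c][1] for c in CHANNELS_64])
    frac = (y - y.min()) / (y.max() - y.min())  # 0 = back, 1 = front
    return occipital + (frontal - occipital) * frac
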