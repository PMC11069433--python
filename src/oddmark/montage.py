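"""Sensor montages: 64-channel extended 10-20 layout with mastoids.

Positions are unit-sphere coordinates (dimensionless); physical scaling to a
head radius happens in the forward model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SensorMontage", "default_montage", "DEFAULT_CHANNELS"]

# 64-channel extended 10-20 set (Quik-Cap style) including linked-mastoid
# electrodes M1/M2; all names resolve in MNE's 10-05 standard montage.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "M1", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "M2",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)


@dataclass
class SensorMontage:
    """Electrode names and 3D positions projected onto the unit sphere."""

    channel_names: list[str]
    positions: np.ndarray  # (n_channels, 3), unit norm rows
    reference_label: str = "Cz"

    def __post_init__(self) -> None:
        self.channel_names = list(self.channel_names)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.positions.shape != (len(self.channel_names), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.channel_names)} channels"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("montage positions must be finite")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(norms <= 0):
            raise ValueError("montage positions must be nonzero")
        self.positions = self.positions / norms[:, None]

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def angles_from(self, name: str) -> np.ndarray:
        """Great-circle angle (radians) of every channel from ``name``."""
        ref = self.positions[self.index(name)]
        cosang = np.clip(self.positions @ ref, -1.0, 1.0)
        return np.arccos(cosang)


def default_montage() -> SensorMontage:
    """The 64-channel extended 10-20 montage (incl. M1/M2 mastoids).

    Positions come from MNE's standard 10-05 electrode set and are projected
    onto the unit sphere around the head center.
    """
    import mne

    with np.errstate(all="ignore"):
        try:
            std = mne.channels.make_standard_montage("colin27_1005")
        except ValueError:  # older montage name
            std = mne.channels.make_standard_montage("standard_1005")
    pos_map = std.get_positions()["ch_pos"]
    positions = np.array([pos_map[name] for name in DEFAULT_CHANNELS])
    return SensorMontage(list(DEFAULT_CHANNELS), positions, reference_label="Cz")
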