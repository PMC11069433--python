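"""Epoched multichannel EEG container used throughout the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import SensorMontage

__all__ = ["TrialEpochs"]

STANDARD = "standard"
DEVIANT = "deviant"


@dataclass
class TrialEpochs:
    """Trials x channels x timepoints of epoched EEG in microvolts.

    ``time_ms`` is the uniform per-sample time axis with 0 ms at stimulus
    onset; ``category`` labels each trial ``standard`` or ``deviant``.
    """

    data: np.ndarray
    time_ms: np.ndarray
    sampling_rate_hz: float
    condition: str
    category: np.ndarray
    subject_id: str
    montage: SensorMontage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.category = np.asarray(self.category, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x timepoints")
        n_trials, n_ch, n_t = self.data.shape
        if n_ch != self.montage.n_channels:
            raise ValueError(
                f"data has {n_ch} channels but montage has "
                f"{self.montage.n_channels}"
            )
        if self.time_ms.shape != (n_t,):
            raise ValueError("time axis length does not match data")
        dt = np.diff(self.time_ms)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("time axis must be strictly increasing and uniform")
        if self.category.shape != (n_trials,):
            raise ValueError("category must label every trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "TrialEpochs":
        return replace(
            self,
            data=self.data.copy(),
            time_ms=self.time_ms.copy(),
            category=self.category.copy(),
        )

    def select(self, idx: np.ndarray) -> "TrialEpochs":
        """Subset of trials (indices or boolean mask), data copied."""
        idx = np.asarray(idx)
        return replace(
            self, data=self.data[idx].copy(), category=self.category[idx].copy()
        )

    def split_categories(self) -> tuple["TrialEpochs", "TrialEpochs"]:
        """(standard epochs, deviant epochs)."""
        return (
            self.select(self.category == STANDARD),
            self.select(self.category == DEVIANT),
        )

    def average(self, category: str | None = None) -> np.ndarray:
        """Ensemble-average ERP (channels x timepoints)."""
        if category is None:
            return self.data.mean(axis=0)
        mask = self.category == category
        if not mask.any():
            raise ValueError(f"no {category!r} trials to average")
        return self.data[mask].mean(axis=0)

    def difference_wave(self) -> np.ndarray:
        """Deviant-average minus standard-average ERP (channels x time)."""
        return self.average(DEVIANT) - self.average(STANDARD)

    def time_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        return (self.time_ms >= start_ms) & (self.time_ms <= end_ms)
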