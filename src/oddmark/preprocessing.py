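"""Preprocessing chain: band-limiting, baseline correction, rereferencing,
amplitude-based trial rejection, count equalization, channel interpolation.

Order of the full chain mirrors common ERP practice: filter -> baseline ->
rereference -> reject -> equalize.  Filters are zero-phase 4th-order
Butterworth (forward-backward), which preserves ERP latencies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .epochs import DEVIANT, STANDARD, TrialEpochs

__all__ = [
    "PreprocConfig",
    "bandlimit",
    "baseline_correct",
    "rereference",
    "reject_amplitude",
    "equalize_counts",
    "equalize_epochs",
    "interpolate_channel",
    "regress_out",
    "preprocess",
]

logger = logging.getLogger(__name__)

MASTOIDS = ("M1", "M2")


@dataclass
class PreprocConfig:
    highpass_hz: float = 0.1
    lowpass_hz: float = 45.0
    filter_order: int = 4
    epoch_window_ms: tuple[float, float] = (-500.0, 550.0)
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    reference: str = "linked_mastoids"  # or "average"
    reject_abs_uV: float = 100.0
    equalize_seed: int = 0

    def __post_init__(self) -> None:
        if self.highpass_hz >= self.lowpass_hz:
            raise ValueError("highpass must be below lowpass")
        b0, b1 = self.baseline_window_ms
        if b0 >= b1 or b1 > 0.0 or b0 < self.epoch_window_ms[0]:
            raise ValueError("baseline window must lie in the prestimulus epoch part")
        if self.reject_abs_uV <= 0:
            raise ValueError("reject_abs_uV must be positive")
        if self.reference not in ("linked_mastoids", "average"):
            raise ValueError(f"unknown reference {self.reference!r}")


def _sos(config: PreprocConfig, fs: float):
    nyq = fs / 2.0
    if config.lowpass_hz >= nyq:
        raise ValueError(
            f"lowpass {config.lowpass_hz} Hz must be below Nyquist {nyq} Hz"
        )
    hp = sps.butter(config.filter_order, config.highpass_hz, "highpass",
                    fs=fs, output="sos")
    lp = sps.butter(config.filter_order, config.lowpass_hz, "lowpass",
                    fs=fs, output="sos")
    return hp, lp


def bandlimit(epochs: TrialEpochs, config: PreprocConfig) -> TrialEpochs:
    """Zero-phase band limiting (high- and low-pass) along the time axis."""
    return replace(epochs, data=bandlimit_array(epochs.data,
                                                epochs.sampling_rate_hz,
                                                config))


def bandlimit_array(data: np.ndarray, fs: float, config: PreprocConfig) -> np.ndarray:
    """Filters applied to a bare array (time on the last axis).

    The high- and low-pass sections are cascaded into a single
    forward-backward pass, which is equivalent to applying them in sequence.
    """
    hp, lp = _sos(config, fs)
    # pad by the slowest filter time constant (bounded by signal length) so
    # the high-pass edge transient stays out of the analyzed span
    n = data.shape[-1]
    padlen = int(min(n - 1, 3.0 * fs / config.highpass_hz))
    out = sps.sosfiltfilt(np.vstack([hp, lp]), data, axis=-1, padlen=padlen)
    return out.astype(data.dtype, copy=False)


def baseline_correct(epochs: TrialEpochs,
                     baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
                     ) -> TrialEpochs:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    mask = epochs.time_mask(*baseline_window_ms)
    if not mask.any():
        raise ValueError(
            f"baseline window {baseline_window_ms} contains no samples"
        )
    mean = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return replace(epochs, data=epochs.data - mean)


def rereference(epochs: TrialEpochs, mode: str = "linked_mastoids") -> TrialEpochs:
    """Re-express all channels against a new reference.

    ``linked_mastoids`` subtracts the instantaneous mean of M1/M2; ``average``
    subtracts the instantaneous mean across all channels.
    """
    if mode == "average":
        ref = epochs.data.mean(axis=1, keepdims=True)
    elif mode == "linked_mastoids":
        idx = []
        for name in MASTOIDS:
            try:
                idx.append(epochs.montage.index(name))
            except KeyError:
                raise ValueError(
                    f"linked-mastoid reference requires channel {name!r}, "
                    "which is missing from the montage"
                ) from None
        ref = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown reference mode {mode!r}")
    return replace(epochs, data=epochs.data - ref)


def reject_amplitude(epochs: TrialEpochs, reject_abs_uV: float = 100.0
                     ) -> tuple[TrialEpochs, dict]:
    """Drop trials with any sample strictly beyond +/-threshold.

    Returns the kept epochs and a report with dropped indices and the
    channels that exceeded the threshold (strict inequality: a sample at
    exactly the threshold is kept).
    """
    if reject_abs_uV <= 0:
        raise ValueError("rejection threshold must be positive")
    bad = np.abs(epochs.data) > reject_abs_uV
    bad_trials = bad.any(axis=(1, 2))
    report = {
        "threshold_uV": reject_abs_uV,
        "n_total": int(epochs.n_trials),
        "n_dropped": int(bad_trials.sum()),
        "dropped_trials": np.flatnonzero(bad_trials).tolist(),
        "offending_channels": {
            int(t): [epochs.montage.channel_names[c]
                     for c in np.flatnonzero(bad[t].any(axis=-1))]
            for t in np.flatnonzero(bad_trials)
        },
    }
    if bad_trials.all():
        raise ValueError(
            f"all {epochs.n_trials} trials exceed +/-{reject_abs_uV} uV; "
            "nothing left after rejection"
        )
    return epochs.select(~bad_trials), report


def equalize_counts(standard: TrialEpochs, deviant: TrialEpochs, seed: int = 0
                    ) -> tuple[TrialEpochs, TrialEpochs]:
    """Randomly subsample standards to match the deviant count."""
    n_std, n_dev = standard.n_trials, deviant.n_trials
    if n_dev > n_std:
        raise ValueError(
            f"more deviants ({n_dev}) than standards ({n_std}); the oddball "
            "design guarantees the opposite"
        )
    if n_std == n_dev:
        return standard, deviant
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n_std, size=n_dev, replace=False))
    return standard.select(keep), deviant


def equalize_epochs(epochs: TrialEpochs, seed: int = 0) -> tuple[TrialEpochs, dict]:
    """Equalize standard/deviant counts within one mixed-category container."""
    std, dev = epochs.split_categories()
    std_eq, dev_eq = equalize_counts(std, dev, seed)
    data = np.concatenate([std_eq.data, dev_eq.data], axis=0)
    category = np.concatenate([std_eq.category, dev_eq.category])
    report = {"n_standard_before": std.n_trials, "n_deviant": dev.n_trials,
              "n_standard_after": std_eq.n_trials, "seed": seed}
    return replace(epochs, data=data, category=category), report


def interpolate_channel(epochs: TrialEpochs, bad_channel: str,
                        radius_deg: float = 40.0) -> TrialEpochs:
    """Replace one channel by the inverse-distance weighted mean of its
    neighbors within ``radius_deg`` great-circle degrees."""
    bad = epochs.montage.index(bad_channel)
    ang = np.degrees(epochs.montage.angles_from(bad_channel))
    neighbors = np.flatnonzero((ang > 0) & (ang <= radius_deg))
    if len(neighbors) < 2:
        raise ValueError(
            f"channel {bad_channel!r} has {len(neighbors)} neighbors within "
            f"{radius_deg} degrees; need at least 2 to interpolate"
        )
    w = 1.0 / ang[neighbors]
    w = w / w.sum()
    data = epochs.data.copy()
    data[:, bad, :] = np.einsum("j,ijt->it", w, epochs.data[:, neighbors, :])
    return replace(epochs, data=data)


def regress_out(epochs: TrialEpochs, reference: np.ndarray) -> TrialEpochs:
    """Least-squares regression cleaner: remove a nuisance time course
    (e.g., an EOG channel) from every EEG channel, per trial.

    ``reference`` is (n_trials, n_times) or (n_times,).
    """
    ref = np.asarray(reference, dtype=float)
    if ref.ndim == 1:
        ref = np.broadcast_to(ref, (epochs.n_trials, len(ref)))
    ref = ref - ref.mean(axis=-1, keepdims=True)
    denom = np.einsum("it,it->i", ref, ref)
    denom[denom == 0] = np.inf
    beta = np.einsum("ict,it->ic", epochs.data, ref) / denom[:, None]
    data = epochs.data - beta[:, :, None] * ref[:, None, :]
    return replace(epochs, data=data)


def preprocess(epochs: TrialEpochs, config: PreprocConfig
               ) -> tuple[TrialEpochs, dict]:
    """Full chain: filter -> baseline -> rereference -> reject -> equalize."""
    out = bandlimit(epochs, config)
    out = baseline_correct(out, config.baseline_window_ms)
    out = rereference(out, config.reference)
    out, reject_report = reject_amplitude(out, config.reject_abs_uV)
    out, equalize_report = equalize_epochs(out, config.equalize_seed)
    report = {"rejection": reject_report, "equalization": equalize_report}
    return out, report
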