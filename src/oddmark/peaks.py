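"""Temporal characterization: significance windows, peak extraction, SNR.

Deviant-vs-standard differences on the dimensionality-reduced data are
tested timepoint-wise across subjects (paired t); maximal runs of p < alpha
lasting at least 10 ms form significant segments.  Per component (MMN within
100-250 ms, P300 within 250-500 ms) a 100 ms window is centered on the
group-level extremum inside the significant segments, and each subject's
peak amplitude and latency are read off their own difference time course
inside that fixed window.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .epochs import TrialEpochs

__all__ = [
    "SignificanceProfile",
    "PeakWindow",
    "PeakMeasure",
    "timepoint_ttests",
    "select_peak_window",
    "extract_peaks",
    "compute_snr",
    "MMN_SEARCH_MS",
    "P300_SEARCH_MS",
]

logger = logging.getLogger(__name__)

MMN_SEARCH_MS = (100.0, 250.0)
P300_SEARCH_MS = (250.0, 500.0)


@dataclass
class SignificanceProfile:
    """Timepoint-wise paired-t profile with maximal significant segments."""

    time_ms: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    alpha: float
    min_run_ms: float
    segments: list[tuple[float, float]] = field(default_factory=list)

    def segment_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.time_ms), dtype=bool)
        for start, end in self.segments:
            mask |= (self.time_ms >= start) & (self.time_ms <= end)
        return mask


@dataclass
class PeakWindow:
    """A fixed-width peak window centered on the group-level extremum."""

    component: str  # MMN or P300
    condition: str
    start_ms: float
    end_ms: float
    center_ms: float


@dataclass
class PeakMeasure:
    """One subject/condition/component peak amplitude and latency."""

    subject_id: str
    condition: str
    component: str
    latency_ms: float
    amplitude_uV: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    out = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    for s, e in zip(starts, ends):
        out.append((int(idx[s]), int(idx[e])))
    return out


def timepoint_ttests(standard: np.ndarray, deviant: np.ndarray,
                     time_ms: np.ndarray, alpha: float = 0.001,
                     min_run_ms: float = 10.0) -> SignificanceProfile:
    """Paired t test (deviant - standard) across subjects at each timepoint.

    ``standard`` and ``deviant`` are (n_subjects x n_times) subject-average
    projected time courses on a shared grid.  Runs of p < alpha shorter than
    ``min_run_ms`` are discarded.
    """
    standard = np.asarray(standard, float)
    deviant = np.asarray(deviant, float)
    time_ms = np.asarray(time_ms, float)
    if standard.shape != deviant.shape or standard.shape[1] != len(time_ms):
        raise ValueError("standard/deviant must share a subjects x times grid")
    n = standard.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    diff = deviant - standard
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * sstats.t.sf(np.abs(t), df=n - 1)
    if zero_var.any():
        logger.info("zero-variance at %d timepoints; p forced to 0/1",
                    int(zero_var.sum()))
        p[zero_var] = np.where(mean[zero_var] != 0.0, 0.0, 1.0)
        t[zero_var] = np.where(mean[zero_var] != 0.0, np.inf, 0.0)

    dt = float(np.median(np.diff(time_ms))) if len(time_ms) > 1 else 1.0
    segments = []
    for first, last in _runs(p < alpha):
        run_ms = (last - first + 1) * dt
        if run_ms >= min_run_ms - 1e-9:
            segments.append((float(time_ms[first]), float(time_ms[last])))
    return SignificanceProfile(time_ms=time_ms, t_values=t, p_values=p,
                               alpha=alpha, min_run_ms=min_run_ms,
                               segments=segments)


def select_peak_window(group_difference: np.ndarray, profile: SignificanceProfile,
                       component: str, condition: str = "",
                       search_range_ms: tuple[float, float] | None = None,
                       width_ms: float = 100.0,
                       inclusive: bool = True) -> PeakWindow | None:
    """Fix the 100 ms window on the group-level extremum.

    The center is the latency of the minimum (MMN) or maximum (P300) of the
    group-average difference inside the intersection of the significant
    segments and the component's search range; the window is center +/-
    width/2, shifted (width preserved) if it would cross an epoch edge.
    Returns None when no significant segment overlaps the search range
    (component not detected).
    """
    if component not in ("MMN", "P300"):
        raise ValueError("component must be MMN or P300")
    if search_range_ms is None:
        search_range_ms = MMN_SEARCH_MS if component == "MMN" else P300_SEARCH_MS
    time_ms = profile.time_ms
    group_difference = np.asarray(group_difference, float)
    if group_difference.shape != time_ms.shape:
        raise ValueError("group difference must match the profile's time grid")
    mask = profile.segment_mask() & (time_ms >= search_range_ms[0]) \
        & (time_ms <= search_range_ms[1])
    if not mask.any():
        logger.warning("%s not detected in %s: no significant segment in "
                       "%s ms", component, condition or "data", search_range_ms)
        return None
    vals = np.where(mask, group_difference, np.nan)
    idx = int(np.nanargmin(vals) if component == "MMN" else np.nanargmax(vals))
    center = float(time_ms[idx])
    dt = float(np.median(np.diff(time_ms)))
    # inclusive bounds span width_ms (101 samples at 1 kHz); the alternative
    # convention spans width_ms - dt (a 100-sample window)
    half = width_ms / 2.0 if inclusive else (width_ms - dt) / 2.0
    start, end = center - half, center + half
    if start < time_ms[0]:
        start, end = time_ms[0], time_ms[0] + 2 * half
    if end > time_ms[-1]:
        start, end = time_ms[-1] - 2 * half, time_ms[-1]
    return PeakWindow(component=component, condition=condition,
                      start_ms=float(start), end_ms=float(end), center_ms=center)


def extract_peaks(difference: np.ndarray, time_ms: np.ndarray,
                  window: PeakWindow, subject_id: str = "") -> PeakMeasure:
    """Subject-level extremum inside the fixed window.

    MMN: (argmin, min); P300: (argmax, max); ties resolve to the earliest
    timepoint.
    """
    difference = np.asarray(difference, float)
    time_ms = np.asarray(time_ms, float)
    if difference.shape != time_ms.shape:
        raise ValueError("difference and time axis must align")
    if window.start_ms < time_ms[0] - 1e-9 or window.end_ms > time_ms[-1] + 1e-9:
        raise ValueError(
            f"window [{window.start_ms}, {window.end_ms}] ms exceeds the "
            f"epoch [{time_ms[0]}, {time_ms[-1]}] ms"
        )
    mask = (time_ms >= window.start_ms - 1e-9) & (time_ms <= window.end_ms + 1e-9)
    seg = difference[mask]
    seg_t = time_ms[mask]
    i = int(np.argmin(seg) if window.component == "MMN" else np.argmax(seg))
    return PeakMeasure(subject_id=subject_id, condition=window.condition,
                       component=window.component,
                       latency_ms=float(seg_t[i]), amplitude_uV=float(seg[i]))


def compute_snr(epochs: TrialEpochs,
                baseline_window_ms: tuple[float, float] = (-200.0, 0.0),
                dispersion: str = "avg_baseline") -> tuple[np.ndarray, float]:
    """Sensor-space SNR, 100*(p2p - sd)/p2p per channel, then averaged.

    ``p2p`` is the peak-to-peak amplitude of the ensemble-average ERP over
    the whole epoch.  The dispersion term ``sd`` is, per channel, either the
    std over time of the averaged prestimulus baseline (``avg_baseline``,
    the default: goes to zero in the noiseless limit) or the std over time
    of the averaged ERP across the whole epoch (``avg_epoch``, a shape-
    driven variant).  Channels with zero p2p are excluded with a warning.

    Returns (per-channel SNR with NaN for excluded channels, channel mean).
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials for an ensemble average")
    erp = epochs.data.mean(axis=0)
    p2p = erp.max(axis=-1) - erp.min(axis=-1)
    if dispersion == "avg_baseline":
        mask = epochs.time_mask(*baseline_window_ms)
        if not mask.any():
            raise ValueError("baseline window contains no samples")
        sd = erp[:, mask].std(axis=-1)
    elif dispersion == "avg_epoch":
        sd = erp.std(axis=-1)
    else:
        raise ValueError(f"unknown dispersion {dispersion!r}")
    snr = np.full(epochs.n_channels, np.nan)
    ok = p2p > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} channels have zero peak-to-peak amplitude; "
            "SNR undefined there", RuntimeWarning,
        )
    snr[ok] = 100.0 * (p2p[ok] - sd[ok]) / p2p[ok]
    return snr, float(np.nanmean(snr))
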