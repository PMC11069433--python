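"""PCA common spatial filter over pooled oddball-standard difference waves.

The filter is built per subject from the five condition-average difference
waveforms (deviant mean minus standard mean), time-concatenated into one
(5*T) x channels matrix.  Its leading principal components form a channel
weighting onto which single trials are projected; the K projected time
courses are averaged into one reduced time course per trial.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .epochs import TrialEpochs

__all__ = [
    "CommonSpatialFilter",
    "SpatialFilter",
    "ProjectedSeries",
    "compute_common_filter",
    "condition_specific_filter",
    "project",
    "project_waveform",
]

MMN_RANGE_MS = (100.0, 250.0)
P300_RANGE_MS = (250.0, 500.0)


class CommonSpatialFilter(TransformerMixin, BaseEstimator):
    """PCA-based spatial filter estimator.

    Parameters
    ----------
    n_components : int
        Number of retained components when ``variance_threshold`` is None
        (the default follows the four-component retention rule).
    variance_threshold : float or None
        If set, K is the smallest count whose cumulative explained-variance
        fraction reaches the threshold.
    time_ms : array or None
        Per-segment time axis.  When given, the fitted X is interpreted as
        ``n_segments`` stacked (T x channels) difference waveforms and each
        component's sign is fixed so MMN-dominant components deflect negative
        in the 100-250 ms range and P300-dominant components positive in
        250-500 ms.  Without it, signs make the largest-|loading| channel
        positive.
    """

    def __init__(self, n_components: int = 4, variance_threshold: float | None = None,
                 time_ms: np.ndarray | None = None):
        self.n_components = n_components
        self.variance_threshold = variance_threshold
        self.time_ms = time_ms

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D (time samples x channels)")
        n_samples, n_channels = X.shape
        if n_samples < n_channels:
            warnings.warn(
                f"fewer time samples ({n_samples}) than channels ({n_channels}); "
                "the covariance is rank-deficient", RuntimeWarning,
            )
        # channel means are removed per condition segment (when the
        # segmentation is known): mean structure shared across conditions
        # would otherwise couple unrelated component topographies in the
        # pooled covariance and rotate the principal axes
        self.mean_ = X.mean(axis=0)
        if self.time_ms is not None and n_samples % len(self.time_ms) == 0:
            T = len(self.time_ms)
            seg = X.reshape(-1, T, n_channels)
            Xc = (seg - seg.mean(axis=1, keepdims=True)).reshape(n_samples,
                                                                 n_channels)
        else:
            Xc = X - self.mean_
        total_var = float((Xc ** 2).sum())
        if total_var <= 1e-30:
            raise ValueError("zero-variance input: cannot build a spatial filter")
        # full SVD; eigvals of the channel covariance are s^2/(n-1)
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        ratios = (s ** 2) / (s ** 2).sum()
        self.lambda_spectrum_ = ratios
        rank = int((s ** 2 > (s[0] ** 2) * 1e-12).sum())
        if self.variance_threshold is not None:
            k = int(np.searchsorted(np.cumsum(ratios), self.variance_threshold) + 1)
            k = min(k, rank)
        else:
            k = min(self.n_components, rank)
        loadings = Vt[:k].T  # (channels, k), orthonormal columns
        loadings = self._fix_signs(loadings, Xc)
        self.loadings_ = loadings
        self.lambda_ = ratios[:k].copy()
        self.n_components_ = k
        self.n_features_in_ = n_channels
        return self

    def _fix_signs(self, loadings: np.ndarray, Xc: np.ndarray) -> np.ndarray:
        out = loadings.copy()
        time_ms = None if self.time_ms is None else np.asarray(self.time_ms, float)
        if time_ms is not None and Xc.shape[0] % len(time_ms) == 0:
            T = len(time_ms)
            n_seg = Xc.shape[0] // T
            grand = Xc.reshape(n_seg, T, -1).mean(axis=0)  # (T, channels)
            mmn = (time_ms >= MMN_RANGE_MS[0]) & (time_ms <= MMN_RANGE_MS[1])
            p3 = (time_ms >= P300_RANGE_MS[0]) & (time_ms <= P300_RANGE_MS[1])
        else:
            time_ms = None
        for j in range(out.shape[1]):
            flip = 0.0
            if time_ms is not None and mmn.any():
                p = grand @ out[:, j]
                mmn_mag = np.abs(p[mmn]).max()
                p3_mag = np.abs(p[p3]).max() if p3.any() else 0.0
                if mmn_mag >= p3_mag:
                    # MMN-dominant: negative extremum must dominate 100-250 ms
                    flip = np.abs(p[mmn].min()) - np.abs(p[mmn].max())
                else:
                    # P300-dominant: positive extremum must dominate 250-500 ms
                    flip = np.abs(p[p3].max()) - np.abs(p[p3].min())
            if flip < 0:
                out[:, j] = -out[:, j]
            elif flip == 0.0:
                # tie (or no time info): largest-|loading| channel positive
                c = int(np.abs(out[:, j]).argmax())
                if out[c, j] < 0:
                    out[:, j] = -out[:, j]
        return out

    def transform(self, X):
        """Project (n_samples x channels) onto the K components (no centering)."""
        check_is_fitted(self, "loadings_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.loadings_.shape[0]:
            raise ValueError(
                f"X has {X.shape[-1]} channels, filter expects "
                f"{self.loadings_.shape[0]}"
            )
        return X @ self.loadings_


@dataclass
class SpatialFilter:
    """Fitted channel x K loading matrix with explained-variance fractions."""

    loadings: np.ndarray  # (channels, K), orthonormal columns
    lambda_: np.ndarray  # K explained-variance fractions, non-increasing
    lambda_spectrum: np.ndarray  # full spectrum, sums to 1
    variance_threshold: float | None = None
    provenance: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_channels(self) -> int:
        return self.loadings.shape[0]

    def cumulative_lambda(self, k: int | None = None) -> float:
        k = self.K if k is None else k
        return float(np.sum(self.lambda_spectrum[:k]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "loadings": self.loadings.tolist(),
                    "lambda": self.lambda_.tolist(),
                    "lambda_spectrum": self.lambda_spectrum.tolist(),
                    "variance_threshold": self.variance_threshold,
                    "provenance": self.provenance,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "SpatialFilter":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            loadings=np.array(d["loadings"]),
            lambda_=np.array(d["lambda"]),
            lambda_spectrum=np.array(d["lambda_spectrum"]),
            variance_threshold=d.get("variance_threshold"),
            provenance=list(d.get("provenance", [])),
        )


@dataclass
class ProjectedSeries:
    """Filter-projected, component-averaged time courses (timepoints x trials)."""

    values: np.ndarray
    time_ms: np.ndarray
    condition: str
    category: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("projected values must be finite")
        if self.values.shape[0] != len(self.time_ms):
            raise ValueError("values must be timepoints x trials")

    def mean(self, category: str | None = None) -> np.ndarray:
        if category is None:
            return self.values.mean(axis=1)
        mask = np.asarray(self.category) == category
        if not mask.any():
            raise ValueError(f"no {category!r} trials")
        return self.values[:, mask].mean(axis=1)

    def difference(self) -> np.ndarray:
        return self.mean("deviant") - self.mean("standard")


def compute_common_filter(difference_waves: Mapping[str, np.ndarray],
                          time_ms: np.ndarray,
                          n_components: int = 4,
                          variance_threshold: float | None = None
                          ) -> SpatialFilter:
    """Build the common spatial filter from per-condition difference waves.

    ``difference_waves`` maps condition code -> (channels x T) average
    deviant-minus-standard waveform; waves are time-concatenated across
    conditions before the channel-covariance eigendecomposition.
    """
    if not difference_waves:
        raise ValueError("need at least one condition")
    conds = list(difference_waves)
    X = np.concatenate([np.asarray(difference_waves[c], float).T for c in conds],
                       axis=0)
    est = CommonSpatialFilter(n_components=n_components,
                              variance_threshold=variance_threshold,
                              time_ms=np.asarray(time_ms, float))
    est.fit(X)
    return SpatialFilter(
        loadings=est.loadings_,
        lambda_=est.lambda_,
        lambda_spectrum=est.lambda_spectrum_,
        variance_threshold=variance_threshold,
        provenance=conds,
    )


def condition_specific_filter(difference_wave: np.ndarray, time_ms: np.ndarray,
                              condition: str = "", n_components: int = 4,
                              variance_threshold: float | None = None
                              ) -> SpatialFilter:
    """Filter pooled from a single condition (robustness comparison)."""
    return compute_common_filter({condition or "single": difference_wave},
                                 time_ms, n_components, variance_threshold)


def _component_weights(filt: SpatialFilter, weighting: str) -> np.ndarray:
    if weighting == "equal":
        return np.full(filt.K, 1.0 / filt.K)
    if weighting == "lambda":
        return filt.lambda_ / filt.lambda_.sum()
    raise ValueError(f"unknown weighting {weighting!r}")


def project(epochs: TrialEpochs, filt: SpatialFilter,
            weighting: str = "equal") -> ProjectedSeries:
    """Project every trial onto the filter and average the K components."""
    if epochs.n_channels != filt.n_channels:
        raise ValueError(
            f"epochs have {epochs.n_channels} channels but the filter has "
            f"{filt.n_channels} rows"
        )
    w = _component_weights(filt, weighting)
    values = np.einsum("ict,ck,k->ti", epochs.data, filt.loadings, w)
    return ProjectedSeries(values=values, time_ms=epochs.time_ms,
                           condition=epochs.condition, category=epochs.category,
                           subject_id=epochs.subject_id)


def project_waveform(wave: np.ndarray, filt: SpatialFilter,
                     weighting: str = "equal") -> np.ndarray:
    """Project a (channels x T) average waveform to a single time course."""
    wave = np.asarray(wave, dtype=float)
    if wave.shape[0] != filt.n_channels:
        raise ValueError(
            f"waveform has {wave.shape[0]} channels but the filter has "
            f"{filt.n_channels} rows"
        )
    w = _component_weights(filt, weighting)
    return np.einsum("ct,ck,k->t", wave, filt.loadings, w)
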