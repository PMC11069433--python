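"""Synthetic oddball-EEG generator with known ground truth.

Emulates a five-condition (auditory A, visual V, audiovisual AV, cross-audio
CrA, cross-visual CrV) oddball experiment: 64-channel, 1 kHz epochs of
[-500, 550] ms around stimulus onset, 400 trials per condition of which 14%
are deviants.  Deviant responses equal the standard response plus an MMN
(negative, fronto-central or posterior depending on the deviant modality)
and a P300 (positive, centro-parietal) component; additive noise is a sum of
pink (1/f) and white processes.  Every injected latency and amplitude is
returned as a ground-truth record so downstream stages can be validated.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .epochs import DEVIANT, STANDARD, TrialEpochs
from .montage import SensorMontage, default_montage

__all__ = [
    "CONDITIONS",
    "ParadigmConfig",
    "ErpComponentSpec",
    "NoiseModel",
    "SubjectSimConfig",
    "make_trial_sequence",
    "make_topography",
    "default_components",
    "simulate_condition",
    "simulate_subject",
    "simulate_epochs",
    "pink_noise",
]

CONDITIONS: tuple[str, ...] = ("A", "V", "AV", "CrA", "CrV")

# Group-mean latencies (ms) and amplitudes (uV) used as generator defaults.
# Amplitudes are on the measured scale of the downstream pipeline: the
# equal-weight average over K=4 projected components attenuates a single
# component's time course by 1/K, so the generator injects
# PROJECTION_GAIN * amplitude into channel space for the measurement to
# land on the stated value.
MMN_LATENCY_MS = {"A": 180.81, "V": 187.76, "AV": 154.28, "CrA": 142.90, "CrV": 171.81}
MMN_AMPLITUDE_UV = {"A": -10.91, "V": -8.74, "AV": -11.18, "CrA": -11.37, "CrV": -10.11}
P300_LATENCY_MS = {"A": 337.34, "V": 390.62, "AV": 330.38, "CrA": 328.81, "CrV": 312.24}
P300_AMPLITUDE_UV = {"A": 12.13, "V": 10.87, "AV": 13.29, "CrA": 12.59, "CrV": 9.23}
PROJECTION_GAIN = 4.0

# Deviant modality decides the MMN topography; cross-modal conditions reuse
# the topography of the modality of their deviant stimulus.
DEVIANT_MODALITY = {"A": "audio", "V": "visual", "AV": "audio", "CrA": "audio", "CrV": "visual"}
STANDARD_MODALITY = {"A": "audio", "V": "visual", "AV": "both", "CrA": "visual", "CrV": "audio"}

MMN_SEARCH_MS = (100.0, 250.0)
P300_SEARCH_MS = (250.0, 500.0)


@dataclass
class ParadigmConfig:
    """Trial-sequence parameters of the oddball paradigm."""

    n_trials_per_condition: int = 400
    oddball_fraction: float = 0.14
    block_size: int = 100
    n_blocks_per_condition: int = 4
    isi_range_ms: tuple[float, float] = (800.0, 1200.0)
    stimulus_duration_ms: float = 350.0
    conditions: tuple[str, ...] = CONDITIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.oddball_fraction <= 1.0:
            raise ValueError("oddball_fraction must lie in [0, 1]")
        if self.n_trials_per_condition != self.block_size * self.n_blocks_per_condition:
            raise ValueError(
                "n_trials_per_condition must equal block_size * n_blocks_per_condition"
            )

    @property
    def n_deviants(self) -> int:
        return int(round(self.oddball_fraction * self.n_trials_per_condition))


def make_trial_sequence(config: ParadigmConfig, condition: str) -> np.ndarray:
    """Per-trial standard/deviant labels, randomized within blocks.

    The total deviant count is ``round(fraction * n_trials)``; deviants are
    partitioned multinomially across blocks (so per-block counts vary) and
    each block's order is shuffled independently.
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    import zlib

    cond_key = zlib.crc32(condition.encode()) % (2**31)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(cond_key, 1))
    )
    n_dev = config.n_deviants
    counts = rng.multinomial(n_dev, np.full(config.n_blocks_per_condition,
                                            1.0 / config.n_blocks_per_condition))
    # a block cannot hold more deviants than trials; redistribute any excess
    while np.any(counts > config.block_size):
        i = int(np.argmax(counts))
        j = int(np.argmin(counts))
        counts[i] -= 1
        counts[j] += 1
    labels = []
    for c in counts:
        block = np.array([DEVIANT] * int(c) + [STANDARD] * (config.block_size - int(c)),
                         dtype=object)
        rng.shuffle(block)
        labels.append(block)
    return np.concatenate(labels)


@dataclass
class ErpComponentSpec:
    """One Gaussian ERP component: peak latency, signed amplitude, FWHM, topography."""

    name: str  # N100, MMN or P300
    latency_ms: float
    amplitude_uV: float
    width_ms: float  # full width at half maximum
    topography: np.ndarray  # unit-norm channel weights

    def __post_init__(self) -> None:
        self.topography = np.asarray(self.topography, dtype=float)
        norm = np.linalg.norm(self.topography)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("topography must be finite and nonzero")
        self.topography = self.topography / norm
        if self.name == "MMN" and self.amplitude_uV >= 0:
            raise ValueError("MMN amplitude must be negative")
        if self.name == "P300" and self.amplitude_uV <= 0:
            raise ValueError("P300 amplitude must be positive")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")

    def waveform(self, time_ms: np.ndarray) -> np.ndarray:
        """Unit-peak Gaussian bump scaled by the signed amplitude."""
        sigma = self.width_ms / 2.3548200450309493  # FWHM -> SD
        return self.amplitude_uV * np.exp(
            -0.5 * ((time_ms - self.latency_ms) / sigma) ** 2
        )


def make_topography(montage: SensorMontage, center_channel: str,
                    spread_deg: float = 30.0) -> np.ndarray:
    """Unit-norm Gaussian-on-the-sphere channel weighting around a channel."""
    ang = np.degrees(montage.angles_from(center_channel))
    w = np.exp(-((ang / spread_deg) ** 2))
    return w / np.linalg.norm(w)


def bilateral_topography(montage: SensorMontage, left: str, right: str,
                         spread_deg: float = 30.0) -> np.ndarray:
    """Unit-norm sum of two lateralized Gaussian blobs."""
    w = (make_topography(montage, left, spread_deg)
         + make_topography(montage, right, spread_deg))
    return w / np.linalg.norm(w)


@dataclass
class NoiseModel:
    """Additive sensor noise: 1/f^exponent pink plus white.

    The pink component models volume-conducted background EEG and is
    spatially mixed across channels with a Gaussian angular kernel of scale
    ``spatial_smoothing_deg`` (unit-variance preserving), which gives the
    channel covariance the low spatial rank of real recordings; the white
    component is independent sensor noise.
    """

    pink_exponent: float = 1.0
    pink_scale_uV: float = 2.2
    white_scale_uV: float = 0.8
    spatial_smoothing_deg: float = 20.0
    band_limit_hz: float = 125.0  # acquisition antialiasing bandwidth


def _orthogonalize(w: np.ndarray, against: Sequence[np.ndarray]) -> np.ndarray:
    for v in against:
        w = w - (w @ v) * v
    return w / np.linalg.norm(w)


def default_components(montage: SensorMontage) -> dict:
    """Per-condition standard components and deviant-only MMN/P300 components.

    Standard responses carry a modality-appropriate N100; deviant responses
    add the condition's MMN and P300 on top of the standard response.
    Topographies follow the classic scalp distributions: fronto-central
    auditory MMN, bilateral occipito-temporal visual MMN, centro-parietal
    P300.
    """
    # The four deviant-component topographies carry zero weight at the
    # mastoids (so the linked-mastoid reference leaves them intact) and are
    # mutually orthogonalized (Gram-Schmidt): residual side-lobes mimic the
    # return fields of the underlying dipoles and make the components
    # spatially separable, the regime in which a common spatial filter
    # cleanly factors the data.
    def _blob(center):
        w = make_topography(montage, center)
        for m in ("M1", "M2"):
            try:
                w[montage.index(m)] = 0.0
            except KeyError:
                pass
        return w / np.linalg.norm(w)

    topo_p3 = _blob("Pz")
    topo_aud_mmn = _orthogonalize(_blob("FCz"), [topo_p3])
    topo_vis_mmn = _orthogonalize(_blob("P8"), [topo_p3, topo_aud_mmn])
    topo_n1_mod = _orthogonalize(_blob("Cz"),
                                 [topo_p3, topo_aud_mmn, topo_vis_mmn])
    topo_aud_n1 = make_topography(montage, "Cz")
    topo_vis_n1 = make_topography(montage, "Oz")
    comps: dict[str, dict[str, list[ErpComponentSpec]]] = {}
    for cond in CONDITIONS:
        standard: list[ErpComponentSpec] = []
        if STANDARD_MODALITY[cond] in ("audio", "both"):
            standard.append(ErpComponentSpec("N100", 100.0, -4.0, 60.0,
                                             topo_aud_n1))
        if STANDARD_MODALITY[cond] in ("visual", "both"):
            standard.append(ErpComponentSpec("N100", 140.0, -3.0, 70.0,
                                             topo_vis_n1))
        mmn_topo = topo_aud_mmn if DEVIANT_MODALITY[cond] == "audio" \
            else topo_vis_mmn
        mmn_width = 70.0 if DEVIANT_MODALITY[cond] == "audio" else 100.0
        deviant_extra = [
            ErpComponentSpec("MMN", MMN_LATENCY_MS[cond],
                             PROJECTION_GAIN * MMN_AMPLITUDE_UV[cond],
                             mmn_width, mmn_topo),
            ErpComponentSpec("P300", P300_LATENCY_MS[cond],
                             PROJECTION_GAIN * P300_AMPLITUDE_UV[cond],
                             120.0, topo_p3),
            # deviants release the N100 from stimulus-repetition adaptation:
            # a genuine fourth difference component that completes the
            # rank-4 signal basis the four-component filter retains
            ErpComponentSpec("N100", 75.0, PROJECTION_GAIN * -3.0, 50.0,
                             topo_n1_mod),
        ]
        comps[cond] = {"standard": standard, "deviant_extra": deviant_extra}
    return comps


@dataclass
class SubjectSimConfig:
    """Cohort-level simulation parameters."""

    n_subjects: int = 21
    sampling_rate_hz: float = 1000.0
    epoch_window_ms: tuple[float, float] = (-500.0, 550.0)
    latency_jitter_sd_ms: float = 20.0
    amplitude_jitter_sd_uV: float = 2.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    montage: SensorMontage = field(default_factory=default_montage)
    components: Mapping | None = None  # default_components(montage) if None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        lo, hi = self.epoch_window_ms
        if not lo <= 0.0 <= hi:
            raise ValueError("epoch window must contain stimulus onset (0 ms)")
        if self.components is None:
            self.components = default_components(self.montage)

    def time_axis(self) -> np.ndarray:
        lo, hi = self.epoch_window_ms
        dt = 1000.0 / self.sampling_rate_hz
        n = int(round((hi - lo) / dt)) + 1
        return lo + dt * np.arange(n)


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
               exponent: float, fs: float) -> np.ndarray:
    """1/f^exponent noise along the last axis, unit SD per series."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = rng.normal(size=shape[:-1] + (len(freqs),)) + 1j * rng.normal(
        size=shape[:-1] + (len(freqs),)
    )
    x = np.fft.irfft(spec * amp, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


_KERNEL_CACHE: dict = {}


def _spatial_kernel(montage: SensorMontage, smoothing_deg: float) -> np.ndarray:
    """Row-normalized Gaussian angular mixing matrix (variance preserving)."""
    key = (id(montage), smoothing_deg)
    if key not in _KERNEL_CACHE:
        cosang = np.clip(montage.positions @ montage.positions.T, -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
        A = np.exp(-((ang / smoothing_deg) ** 2))
        _KERNEL_CACHE[key] = A / np.linalg.norm(A, axis=1, keepdims=True)
    return _KERNEL_CACHE[key]


def _subject_rng(sim: SubjectSimConfig, subject: int, condition: str,
                 stream: int) -> np.random.Generator:
    """Counter-style RNG keyed by (seed, subject, condition, stream)."""
    key = (subject, CONDITIONS.index(condition) if condition in CONDITIONS else 99,
           stream)
    return np.random.default_rng(np.random.SeedSequence(sim.seed, spawn_key=key))


def _jittered_components(sim: SubjectSimConfig, subject: int,
                         condition: str) -> tuple[list, list, dict]:
    """Subject-specific component parameters and the ground-truth record."""
    spec = sim.components[condition]
    rng = _subject_rng(sim, subject, condition, stream=0)
    deviant_extra = []
    truth: dict = {}
    for comp in spec["deviant_extra"]:
        lat = comp.latency_ms + rng.normal(0.0, sim.latency_jitter_sd_ms)
        # amplitude jitter acts on the measured (projected) scale
        amp = comp.amplitude_uV + PROJECTION_GAIN * rng.normal(
            0.0, sim.amplitude_jitter_sd_uV)
        if comp.name == "N100":
            # deviance-related N100 modulation stays below the MMN search
            # range so it cannot capture MMN peak windows
            lat = float(np.clip(lat, 40.0, 95.0))
            amp = min(amp, -0.5 * PROJECTION_GAIN)
        elif comp.name == "MMN":
            lat = float(np.clip(lat, MMN_SEARCH_MS[0] + 10, MMN_SEARCH_MS[1] - 10))
            amp = min(amp, -2.0 * PROJECTION_GAIN)
        elif comp.name == "P300":
            lat = float(np.clip(lat, P300_SEARCH_MS[0] + 10, P300_SEARCH_MS[1] - 10))
            amp = max(amp, 2.0 * PROJECTION_GAIN)
        lo, hi = sim.epoch_window_ms
        if not lo < lat < hi:
            raise ValueError(
                f"{comp.name} latency {lat:.1f} ms outside epoch window {sim.epoch_window_ms}"
            )
        jit = ErpComponentSpec(comp.name, lat, amp, comp.width_ms, comp.topography)
        deviant_extra.append(jit)
        best = comp.topography.argmax()
        truth[comp.name] = {
            "latency_ms": lat,
            "amplitude_uV": amp,
            "width_ms": comp.width_ms,
            "best_channel": sim.montage.channel_names[int(best)],
        }
    for comp in spec["standard"]:
        lo, hi = sim.epoch_window_ms
        if not lo < comp.latency_ms < hi:
            raise ValueError(
                f"{comp.name} latency {comp.latency_ms:.1f} ms outside epoch window"
            )
    return list(spec["standard"]), deviant_extra, truth


def simulate_condition(sim: SubjectSimConfig, paradigm: ParadigmConfig,
                       subject: int, condition: str) -> tuple[TrialEpochs, dict]:
    """Simulate one subject x condition block of epochs plus ground truth."""
    time_ms = sim.time_axis()
    n_t = len(time_ms)
    labels = make_trial_sequence(
        ParadigmConfig(**{**paradigm.__dict__,
                          "seed": paradigm.seed + 7919 * subject}), condition
    )
    n_trials = len(labels)
    standard_comps, deviant_extra, truth = _jittered_components(sim, subject, condition)

    standard_wave = np.zeros((sim.montage.n_channels, n_t))
    for comp in standard_comps:
        standard_wave += np.outer(comp.topography, comp.waveform(time_ms))
    extra_wave = np.zeros_like(standard_wave)
    for comp in deviant_extra:
        extra_wave += np.outer(comp.topography, comp.waveform(time_ms))

    nm = sim.noise
    noisy = nm.pink_scale_uV > 0 or nm.white_scale_uV > 0
    # single precision for bulk noisy epochs; full precision in the
    # zero-noise limit so exact ground-truth recovery holds to 1e-12
    dtype = np.float32 if noisy else np.float64
    data = np.tile(standard_wave.astype(dtype), (n_trials, 1, 1))
    data[labels == DEVIANT] += extra_wave.astype(dtype)

    if noisy:
        noise_rng = _subject_rng(sim, subject, condition, stream=1)
        data += _synth_noise(noise_rng, sim, n_trials, n_t)

    epochs = TrialEpochs(
        data=data, time_ms=time_ms, sampling_rate_hz=sim.sampling_rate_hz,
        condition=condition, category=labels, subject_id=f"S{subject:02d}",
        montage=sim.montage,
    )
    return epochs, truth


def _synth_noise(rng: np.random.Generator, sim: SubjectSimConfig,
                 n_trials: int, n_t: int) -> np.ndarray:
    """Pink + white noise synthesized in the frequency domain.

    The pink (1/f^exponent) component is spatially mixed across channels;
    the white component is independent per channel.  Both are band-limited
    to ``band_limit_hz`` and normalized so each component's time-domain SD
    equals its scale (in the ensemble sense).
    """
    import scipy.fft

    nm = sim.noise
    n_ch = sim.montage.n_channels
    freqs = np.fft.rfftfreq(n_t, d=1.0 / sim.sampling_rate_hz)
    n_bins = len(freqs)
    nb = int(np.searchsorted(freqs, nm.band_limit_hz, side="right"))
    nb = max(nb, 2)

    def normalized(amp):
        # SD of irfft(z * amp) with z ~ CN(0, 2) per bin is 2*||amp||/n
        return amp / (2.0 * np.sqrt((amp ** 2).sum()) / n_t)

    spec = np.zeros((n_trials, n_ch, n_bins), dtype=np.complex64)
    shape = (n_trials, n_ch, nb)
    if nm.pink_scale_uV > 0:
        a_pink = np.zeros(nb, dtype=np.float64)
        a_pink[1:] = freqs[1:nb] ** (-nm.pink_exponent / 2.0)
        a_pink = normalized(a_pink).astype(np.float32)
        zp = rng.standard_normal(shape, dtype=np.float32) \
            + 1j * rng.standard_normal(shape, dtype=np.float32)
        zp *= nm.pink_scale_uV * a_pink
        if nm.spatial_smoothing_deg > 0:
            kern = _spatial_kernel(sim.montage, nm.spatial_smoothing_deg)
            zp = np.einsum("dc,icf->idf", kern.astype(np.float32), zp,
                           optimize=True)
        spec[..., :nb] += zp
        del zp
    if nm.white_scale_uV > 0:
        a_white = np.zeros(nb, dtype=np.float64)
        a_white[1:] = 1.0
        a_white = normalized(a_white).astype(np.float32)
        zw = rng.standard_normal(shape, dtype=np.float32) \
            + 1j * rng.standard_normal(shape, dtype=np.float32)
        zw *= nm.white_scale_uV * a_white
        spec[..., :nb] += zw
        del zw
    return scipy.fft.irfft(spec, n=n_t, axis=-1)


def simulate_subject(sim: SubjectSimConfig, paradigm: ParadigmConfig,
                     subject: int) -> tuple[dict[str, TrialEpochs], dict]:
    """All five conditions for one subject.  Roughly 1 GB at full defaults."""
    epochs = {}
    truth = {}
    for cond in paradigm.conditions:
        epochs[cond], truth[cond] = simulate_condition(sim, paradigm, subject, cond)
    return epochs, truth


def simulate_epochs(sim: SubjectSimConfig, paradigm: ParadigmConfig
                    ) -> Iterator[tuple[str, dict[str, TrialEpochs], dict]]:
    """Stream (subject_id, condition->epochs, ground truth) per subject.

    Yields one subject at a time; at full defaults a whole cohort does not
    fit in memory at once.
    """
    for subject in range(sim.n_subjects):
        epochs, truth = simulate_subject(sim, paradigm, subject)
        yield f"S{subject:02d}", epochs, truth
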