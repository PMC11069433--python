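"""End-to-end pipeline: simulate/ingest -> preprocess -> spatial filter ->
peak characterization -> group statistics -> optional source localization.

Every stage is driven by one JSON-serializable :class:`PipelineConfig`; a
:class:`RunManifest` records configuration hash, per-stage counts and output
digests so that identical seeds reproduce identical runs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .epochs import DEVIANT, STANDARD, TrialEpochs
from .inverse import ELoretaConfig, eloreta_inverse, localize_condition, threshold_map
from .leadfield import spherical_leadfield
from .montage import default_montage
from .paradigm import (CONDITIONS, NoiseModel, ParadigmConfig,
                       SubjectSimConfig, simulate_subject)
from .peaks import (MMN_SEARCH_MS, P300_SEARCH_MS, compute_snr, extract_peaks,
                    select_peak_window, timepoint_ttests)
from .preprocessing import PreprocConfig, preprocess
from .spatial import compute_common_filter, project_waveform
from .stats import bonferroni_posthoc, rm_anova

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "collect_projections"]

logger = logging.getLogger(__name__)


@dataclass
class SimSettings:
    """Serializable subset of the generator configuration."""

    n_subjects: int = 21
    sampling_rate_hz: float = 1000.0
    epoch_window_ms: tuple[float, float] = (-500.0, 550.0)
    latency_jitter_sd_ms: float = 20.0
    amplitude_jitter_sd_uV: float = 2.0
    pink_exponent: float = 1.0
    pink_scale_uV: float = 2.2
    white_scale_uV: float = 0.8
    spatial_smoothing_deg: float = 20.0

    def to_subject_config(self, seed: int) -> SubjectSimConfig:
        return SubjectSimConfig(
            n_subjects=self.n_subjects,
            sampling_rate_hz=self.sampling_rate_hz,
            epoch_window_ms=tuple(self.epoch_window_ms),
            latency_jitter_sd_ms=self.latency_jitter_sd_ms,
            amplitude_jitter_sd_uV=self.amplitude_jitter_sd_uV,
            noise=NoiseModel(self.pink_exponent, self.pink_scale_uV,
                             self.white_scale_uV, self.spatial_smoothing_deg),
            seed=seed,
        )


@dataclass
class FilterSettings:
    n_components: int = 4
    variance_threshold: float | None = None
    weighting: str = "equal"


@dataclass
class PeakSettings:
    alpha: float = 0.001
    min_run_ms: float = 10.0
    width_ms: float = 100.0


@dataclass
class LocalizationSettings:
    enabled: bool = False
    lambda_reg: float = 0.1
    grid_spacing_mm: float = 20.0
    threshold_percentile: float = 99.0
    head_radius_mm: float = 85.0


@dataclass
class PipelineConfig:
    seed: int = 0
    conditions: tuple[str, ...] = CONDITIONS
    sim: SimSettings = field(default_factory=SimSettings)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    filter: FilterSettings = field(default_factory=FilterSettings)
    peaks: PeakSettings = field(default_factory=PeakSettings)
    localization: LocalizationSettings = field(default_factory=LocalizationSettings)
    n_trials_per_condition: int = 400
    block_size: int = 100
    oddball_fraction: float = 0.14
    log_level: str = "INFO"

    def paradigm(self) -> ParadigmConfig:
        return ParadigmConfig(
            n_trials_per_condition=self.n_trials_per_condition,
            block_size=self.block_size,
            n_blocks_per_condition=self.n_trials_per_condition // self.block_size,
            oddball_fraction=self.oddball_fraction,
            conditions=tuple(self.conditions),
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["conditions"] = tuple(d.get("conditions", CONDITIONS))
        for key, sub in (("sim", SimSettings), ("preproc", PreprocConfig),
                         ("filter", FilterSettings), ("peaks", PeakSettings),
                         ("localization", LocalizationSettings)):
            if key in d and isinstance(d[key], dict):
                kwargs = dict(d[key])
                for tup_field in ("epoch_window_ms", "baseline_window_ms"):
                    if tup_field in kwargs and kwargs[tup_field] is not None:
                        kwargs[tup_field] = tuple(kwargs[tup_field])
                d[key] = sub(**kwargs)
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    stages: list[str]
    trial_counts: dict
    segments_found: dict
    windows: dict
    snr_by_subject: dict
    output_digests: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class CohortReduction:
    """Subject-average projections and per-subject summaries of a cohort.

    ``projections[cond][category]`` is an (n_subjects x n_times) matrix of
    filter-projected subject averages; ``grand_erps`` holds cleaned
    grand-average standard/deviant ERPs (channels x time) per condition for
    source localization; ``lambda4_by_subject`` is the cumulative explained-
    variance fraction of each subject's first four principal components.
    """

    projections: dict
    trial_counts: dict
    snr_by_subject: dict
    lambda4_by_subject: dict
    grand_erps: dict
    truths: dict
    time_ms: np.ndarray


def collect_projections(config: PipelineConfig) -> CohortReduction:
    """Simulate and reduce the cohort to subject-average projections."""
    sim = config.sim.to_subject_config(config.seed)
    paradigm = config.paradigm()
    conds = list(config.conditions)
    time_ms = sim.time_axis()
    n_t = len(time_ms)
    proj = {c: {STANDARD: [], DEVIANT: []} for c in conds}
    grand = {c: {STANDARD: np.zeros((sim.montage.n_channels, n_t)),
                 DEVIANT: np.zeros((sim.montage.n_channels, n_t))}
             for c in conds}
    counts: dict = {}
    snrs: dict = {}
    truths: dict = {}
    lambda4: dict = {}
    for s in range(sim.n_subjects):
        subject_id = f"S{s:02d}"
        epochs_by_cond, truth = simulate_subject(sim, paradigm, s)
        truths[subject_id] = truth
        diffs = {}
        avgs = {}
        snr_vals = []
        counts[subject_id] = {}
        for c in conds:
            cfg = dataclasses.replace(config.preproc,
                                      equalize_seed=config.seed + 1009 * s)
            clean, report = preprocess(epochs_by_cond[c], cfg)
            _, snr_mean = compute_snr(epochs_by_cond[c],
                                      cfg.baseline_window_ms)
            snr_vals.append(snr_mean)
            counts[subject_id][c] = {
                "kept": clean.n_trials,
                "dropped": report["rejection"]["n_dropped"],
            }
            std_avg = clean.average(STANDARD)
            dev_avg = clean.average(DEVIANT)
            diffs[c] = dev_avg - std_avg
            avgs[c] = (std_avg, dev_avg)
            grand[c][STANDARD] += std_avg / sim.n_subjects
            grand[c][DEVIANT] += dev_avg / sim.n_subjects
            del epochs_by_cond[c], clean
        snrs[subject_id] = float(np.mean(snr_vals))
        filt = compute_common_filter(
            diffs, time_ms, n_components=config.filter.n_components,
            variance_threshold=config.filter.variance_threshold,
        )
        lambda4[subject_id] = filt.cumulative_lambda(4)
        for c in conds:
            std_avg, dev_avg = avgs[c]
            proj[c][STANDARD].append(
                project_waveform(std_avg, filt, config.filter.weighting))
            proj[c][DEVIANT].append(
                project_waveform(dev_avg, filt, config.filter.weighting))
    for c in conds:
        proj[c][STANDARD] = np.array(proj[c][STANDARD])
        proj[c][DEVIANT] = np.array(proj[c][DEVIANT])
    return CohortReduction(projections=proj, trial_counts=counts,
                           snr_by_subject=snrs, lambda4_by_subject=lambda4,
                           grand_erps=grand, truths=truths, time_ms=time_ms)


def run_pipeline(config: PipelineConfig, output_dir) -> RunManifest:
    """Execute all stages and write tables, reports and the manifest."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    stage = "simulate+preprocess+filter"
    try:
        red = collect_projections(config)
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err
    proj, counts, snrs = red.projections, red.trial_counts, red.snr_by_subject
    grand, time_ms = red.grand_erps, red.time_ms

    conds = list(config.conditions)
    stage = "characterize"
    windows: dict = {}
    segments: dict = {}
    records = []
    try:
        for c in conds:
            profile = timepoint_ttests(
                proj[c][STANDARD], proj[c][DEVIANT], time_ms,
                alpha=config.peaks.alpha, min_run_ms=config.peaks.min_run_ms,
            )
            segments[c] = profile.segments
            diffs = proj[c][DEVIANT] - proj[c][STANDARD]
            group_diff = diffs.mean(axis=0)
            windows[c] = {}
            for comp, rng in (("MMN", MMN_SEARCH_MS), ("P300", P300_SEARCH_MS)):
                win = select_peak_window(group_diff, profile, comp, condition=c,
                                         search_range_ms=rng,
                                         width_ms=config.peaks.width_ms)
                windows[c][comp] = win
                if win is None:
                    continue
                for s in range(diffs.shape[0]):
                    pm = extract_peaks(diffs[s], time_ms, win,
                                       subject_id=f"S{s:02d}")
                    records.append(dataclasses.asdict(pm))
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    measures = pd.DataFrame.from_records(
        records, columns=["subject_id", "condition", "component",
                          "latency_ms", "amplitude_uV"])
    measures.to_csv(out / "peak_measures.csv", index=False)

    stage = "group_stats"
    stats_report: dict = {}
    summary_rows = []
    try:
        for comp in ("MMN", "P300"):
            sub = measures[measures.component == comp]
            detected = [c for c in conds if windows[c].get(comp) is not None]
            for c in detected:
                grp = sub[sub.condition == c]
                summary_rows.append({
                    "condition": c, "component": comp,
                    "latency_mean_ms": grp.latency_ms.mean(),
                    "latency_sd_ms": grp.latency_ms.std(ddof=1),
                    "amplitude_mean_uV": grp.amplitude_uV.mean(),
                    "amplitude_sd_uV": grp.amplitude_uV.std(ddof=1),
                })
            if len(detected) < 2:
                continue
            for measure in ("latency_ms", "amplitude_uV"):
                mat = np.column_stack([
                    sub[sub.condition == c].sort_values("subject_id")[measure]
                    for c in detected
                ])
                res = rm_anova(mat)
                post = bonferroni_posthoc(mat, detected)
                stats_report[f"{comp}_{measure}"] = {
                    "conditions": detected,
                    "anova": dataclasses.asdict(res),
                    "posthoc": [dataclasses.asdict(p) for p in post],
                }
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    summary = pd.DataFrame(
        summary_rows, columns=["condition", "component", "latency_mean_ms",
                               "latency_sd_ms", "amplitude_mean_uV",
                               "amplitude_sd_uV"])
    summary.to_csv(out / "summary_table.csv", index=False)
    with open(out / "group_stats.json", "w") as fh:
        json.dump(stats_report, fh, indent=2, default=float)
    with open(out / "snr.json", "w") as fh:
        json.dump(snrs, fh, indent=2)

    stages = ["simulate", "preprocess", "filter", "characterize", "stats"]
    if config.localization.enabled:
        stage = "localize"
        try:
            montage = default_montage()
            lf = spherical_leadfield(
                montage, grid_spacing_mm=config.localization.grid_spacing_mm,
                head_radius_mm=config.localization.head_radius_mm,
            )
            op = eloreta_inverse(lf, ELoretaConfig(
                lambda_reg=config.localization.lambda_reg))
            maps = []
            for c in conds:
                for comp in ("MMN", "P300"):
                    win = windows[c].get(comp)
                    if win is None:
                        continue
                    std_ep = _erp_as_epochs(grand[c][STANDARD], time_ms,
                                            config, c, STANDARD, montage)
                    dev_ep = _erp_as_epochs(grand[c][DEVIANT], time_ms,
                                            config, c, DEVIANT, montage)
                    smap = localize_condition(std_ep, dev_ep, win, lf,
                                              operator=op)
                    smap = threshold_map(
                        smap, config.localization.threshold_percentile)
                    kept = smap.intensity != 0
                    for v in np.flatnonzero(kept):
                        maps.append({
                            "condition": c, "component": comp,
                            "x_mm": smap.voxel_positions[v, 0],
                            "y_mm": smap.voxel_positions[v, 1],
                            "z_mm": smap.voxel_positions[v, 2],
                            "intensity": smap.intensity[v],
                            "hemisphere": smap.hemisphere_labels[v],
                        })
            pd.DataFrame(maps).to_csv(out / "source_maps.csv", index=False)
            stages.append("localize")
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    outputs = sorted(set(out.glob("*.csv")) | set(out.glob("*.json")))
    digests = {p.name: _digest(p) for p in outputs if p.name != "manifest.json"}
    manifest = RunManifest(
        config_hash=config.hash(), seed=config.seed,
        package_version=__version__, stages=stages,
        trial_counts=counts, segments_found=segments,
        windows={c: {k: (dataclasses.asdict(w) if w else None)
                     for k, w in windows[c].items()} for c in conds},
        snr_by_subject=snrs, output_digests=digests,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def _erp_as_epochs(erp: np.ndarray, time_ms: np.ndarray,
                   config: PipelineConfig, condition: str, category: str,
                   montage) -> TrialEpochs:
    """Wrap a grand-average ERP as a single-trial container for localization."""
    return TrialEpochs(
        data=erp[None, :, :], time_ms=time_ms,
        sampling_rate_hz=config.sim.sampling_rate_hz, condition=condition,
        category=np.array([category], dtype=object),
        subject_id="grand", montage=montage,
    )
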