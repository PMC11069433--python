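"""Reading and writing epochs: EDF+ interchange and a lossless fixture format.

EDF+ is the interchange format (16-bit; epochs are laid out as consecutive
data records with an annotation channel carrying ``cond:<code>/cat:<label>``
markers at each epoch onset plus one metadata annotation).  Reading goes
through MNE's EDF reader.  The fixture format is a NumPy ``.npz`` archive
that round-trips bit-identically and is intended for tests and intermediate
pipeline products.
"""
from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .epochs import TrialEpochs
from .montage import SensorMontage

__all__ = ["write_edf", "read_edf", "write_fixture", "read_fixture",
           "write_epochs", "read_epochs"]


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(epochs: TrialEpochs, path) -> None:
    """Write epochs to EDF+C, one data record per epoch.

    Signals are scaled to the 16-bit digital range per channel; trial labels
    ride in the annotation channel as ``cond:<condition>/cat:<category>``.
    """
    path = Path(path)
    data = epochs.data
    n_trials, n_ch, n_t = data.shape
    record_dur = n_t / epochs.sampling_rate_hz

    phys_min = data.min(axis=(0, 2))
    phys_max = data.max(axis=(0, 2))
    flat = phys_max - phys_min < 1e-12
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767

    # one annotation per record: onset keeper + trial label; record 0 also
    # carries epoch metadata (tmin, sampling rate, subject)
    annots = []
    for i in range(n_trials):
        onset = i * record_dur
        tal = f"+{onset:.6f}\x14\x14\x00".encode("ascii")
        label = f"cond:{epochs.condition}/cat:{epochs.category[i]}"
        tal += f"+{onset:.6f}\x14{label}\x14\x00".encode("ascii")
        if i == 0:
            meta = (f"meta:tmin_ms={epochs.time_ms[0]:g};"
                    f"fs={epochs.sampling_rate_hz:g};"
                    f"subject={epochs.subject_id}")
            tal += f"+0.000000\x14{meta}\x14\x00".encode("ascii")
        annots.append(tal)
    annot_len = max(len(a) for a in annots)
    annot_len += (-annot_len) % 2  # even byte count -> whole int16 samples
    annot_samples = annot_len // 2

    n_signals = n_ch + 1
    header_bytes = 256 * (n_signals + 1)
    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(f"X X X {epochs.subject_id or 'X'}", 80))
        fh.write(_edf_field("Startdate X X X X", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(header_bytes), 8))
        fh.write(_edf_field("EDF+C", 44))
        fh.write(_edf_field(str(n_trials), 8))
        fh.write(_edf_field(f"{record_dur:.6f}"[:8], 8))
        fh.write(_edf_field(str(n_signals), 4))
        names = list(epochs.montage.channel_names) + ["EDF Annotations"]
        for nm in names:
            fh.write(_edf_field(nm, 16))
        for _ in names:
            fh.write(_edf_field("", 80))  # transducer
        for i in range(n_signals):
            fh.write(_edf_field("uV" if i < n_ch else "", 8))
        for i in range(n_signals):
            fh.write(_edf_field(f"{phys_min[i]:.8g}"[:8] if i < n_ch else "-1", 8))
        for i in range(n_signals):
            fh.write(_edf_field(f"{phys_max[i]:.8g}"[:8] if i < n_ch else "1", 8))
        for i in range(n_signals):
            fh.write(_edf_field(str(dig_min), 8))
        for i in range(n_signals):
            fh.write(_edf_field(str(dig_max), 8))
        for _ in range(n_signals):
            fh.write(_edf_field("", 80))  # prefiltering
        for i in range(n_signals):
            fh.write(_edf_field(str(n_t if i < n_ch else annot_samples), 8))
        for _ in range(n_signals):
            fh.write(_edf_field("", 32))

        # physical limits were truncated to 8 chars; recompute the scaling
        # actually encoded in the header so read(write(x)) matches exactly
        pmin = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
        pmax = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
        scale = (dig_max - dig_min) / (pmax - pmin)
        for i in range(n_trials):
            dig = np.round((data[i] - pmin[:, None]) * scale[:, None]) + dig_min
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            fh.write(dig.tobytes())
            fh.write(annots[i].ljust(annot_len, b"\x00"))


_LABEL_RE = re.compile(r"cond:(?P<cond>[^/]+)/cat:(?P<cat>\w+)")
_META_RE = re.compile(
    r"meta:tmin_ms=(?P<tmin>-?[\d.]+);fs=(?P<fs>[\d.]+);subject=(?P<subj>.*)")


def read_edf(path, montage: SensorMontage | None = None) -> TrialEpochs:
    """Read epochs written by :func:`write_edf` via MNE's EDF reader."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels, onsets = [], []
    meta = None
    for onset, _, desc in zip(raw.annotations.onset, raw.annotations.duration,
                              raw.annotations.description):
        m = _LABEL_RE.search(desc)
        if m:
            onsets.append(float(onset))
            labels.append((m["cond"], m["cat"]))
        mm = _META_RE.search(desc)
        if mm:
            meta = mm
    if not labels:
        raise ValueError(
            "no trial annotations found; expected 'cond:<code>/cat:<label>' "
            "markers as written by write_edf"
        )
    if meta is None:
        raise ValueError("missing 'meta:' annotation with tmin/fs/subject")
    fs = float(meta["fs"])
    tmin_ms = float(meta["tmin"])
    ch_names = [n for n in raw.ch_names if n != "EDF Annotations"]
    if montage is not None:
        if set(ch_names) != set(montage.channel_names):
            missing = sorted(set(montage.channel_names) - set(ch_names))
            raise ValueError(
                f"channel mismatch between file and montage; missing {missing}"
            )
    else:
        # positions are not stored in EDF: synthesize placeholder directions
        from .montage import default_montage

        std = default_montage()
        if set(ch_names) <= set(std.channel_names):
            pos = np.array([std.positions[std.index(n)] for n in ch_names])
        else:
            pos = np.random.default_rng(0).normal(size=(len(ch_names), 3))
        montage = SensorMontage(ch_names, pos)
    picks = [raw.ch_names.index(n) for n in montage.channel_names]
    sig = raw.get_data(picks=picks) * 1e6  # MNE returns volts
    n_t = int(round((len(raw.times) / len(labels))))
    n_trials = len(labels)
    data = sig[:, : n_trials * n_t].reshape(len(picks), n_trials, n_t)
    data = np.moveaxis(data, 0, 1)
    time_ms = tmin_ms + 1000.0 / fs * np.arange(n_t)
    conds = {c for c, _ in labels}
    if len(conds) != 1:
        raise ValueError(f"mixed conditions in one file: {sorted(conds)}")
    return TrialEpochs(
        data=data, time_ms=time_ms, sampling_rate_hz=fs,
        condition=labels[0][0],
        category=np.array([cat for _, cat in labels], dtype=object),
        subject_id=meta["subj"].strip(), montage=montage,
    )


def write_fixture(epochs: TrialEpochs, path) -> None:
    """Lossless binary fixture (NumPy archive)."""
    np.savez(
        path,
        data=epochs.data,
        time_ms=epochs.time_ms,
        sampling_rate_hz=epochs.sampling_rate_hz,
        condition=epochs.condition,
        category=epochs.category.astype(str),
        subject_id=epochs.subject_id,
        channel_names=np.array(epochs.montage.channel_names),
        positions=epochs.montage.positions,
        reference_label=epochs.montage.reference_label,
    )


def read_fixture(path) -> TrialEpochs:
    with np.load(path, allow_pickle=False) as z:
        montage = SensorMontage(
            [str(n) for n in z["channel_names"]], z["positions"],
            str(z["reference_label"]),
        )
        return TrialEpochs(
            data=z["data"], time_ms=z["time_ms"],
            sampling_rate_hz=float(z["sampling_rate_hz"]),
            condition=str(z["condition"]),
            category=z["category"].astype(object),
            subject_id=str(z["subject_id"]), montage=montage,
        )


def write_epochs(epochs: TrialEpochs, path, format: str | None = None) -> None:
    fmt = format or ("edf" if str(path).lower().endswith(".edf") else "fixture")
    if fmt == "edf":
        write_edf(epochs, path)
    elif fmt == "fixture":
        write_fixture(epochs, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_epochs(path, format: str | None = None,
                montage: SensorMontage | None = None) -> TrialEpochs:
    fmt = format or ("edf" if str(path).lower().endswith(".edf") else "fixture")
    if fmt == "edf":
        return read_edf(path, montage=montage)
    if fmt == "fixture":
        return read_fixture(path)
    raise ValueError(f"unknown format {fmt!r}")
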