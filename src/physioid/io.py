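"""Reading and writing waveform records and derived tables.

Two record formats are supported:

* **Delimited text** (comma): ``#``-prefixed ``key=value`` header lines
  (``subject``, ``fs``, ``t0`` and optionally ``modality``), then a CSV
  header naming a ``time_s`` column plus one column per channel, then data
  rows.  This is the format the synthetic generator writes and the format
  bench acquisitions are expected in.
* **WFDB**, single-segment format 16 (text ``.hea`` header plus int16
  little-endian ``.dat``).  Implemented in-house and deliberately minimal:
  one ``.dat`` per record, format 16 only.

Channel names are normalized to modalities through a case-insensitive map
(default: II/ECG/MLII/V5 -> ECG, PLETH/PPG -> PPG, RESP -> RESP).

Quality policy for real records: runs of missing samples (NaN) no longer
than 0.5 s are linearly interpolated; longer gaps split the record into
separate :class:`~physioid.types.SignalRecord` pieces.  Non-finite values
never propagate out of a reader.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .types import MODALITIES, SignalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "DEFAULT_CHANNEL_MAP",
    "read_record",
    "write_record",
    "write_records_text",
    "write_wfdb",
    "read_annotations",
    "write_annotations",
    "read_feature_table",
    "write_feature_table",
]


class FormatError(ValueError):
    """A file could not be interpreted as a waveform record or table."""


#: modality -> accepted channel names (matched case-insensitively).
DEFAULT_CHANNEL_MAP = {
    "ECG": ("ECG", "II", "MLII", "V5", "I", "V"),
    "PPG": ("PLETH", "PPG"),
    "RESP": ("RESP", "RESPIRATION"),
}

#: Missing-sample runs up to this many seconds are linearly interpolated.
MAX_GAP_S = 0.5


def _modality_for_channel(name: str, channel_map: dict) -> str | None:
    for modality, aliases in channel_map.items():
        if name.upper() in tuple(a.upper() for a in aliases):
            return modality
    return None


def _repair_gaps(values: np.ndarray, fs: float):
    """Interpolate short NaN runs; yield (start_index, segment) pieces split
    at gaps longer than :data:`MAX_GAP_S`."""
    values = np.asarray(values, dtype=float)
    if np.any(np.isinf(values)):
        raise FormatError("record contains infinite sample values")
    finite = np.isfinite(values)
    if finite.all():
        yield 0, values
        return
    max_gap = int(round(MAX_GAP_S * fs))
    # Identify NaN runs.
    idx = np.flatnonzero(~finite)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    long_runs = [r for r in runs if r.size > max_gap]
    short_runs = [r for r in runs if r.size <= max_gap]
    x = values.copy()
    if short_runs:
        good = np.flatnonzero(finite)
        fill = np.concatenate(short_runs)
        x[fill] = np.interp(fill, good, values[good])
        logger.warning("interpolated %d missing samples in %d short gap(s)",
                       fill.size, len(short_runs))
    # Split at the remaining long gaps.
    cut_points = [0]
    for r in long_runs:
        cut_points.extend([int(r[0]), int(r[-1]) + 1])
    cut_points.append(values.size)
    for lo, hi in zip(cut_points[::2], cut_points[1::2]):
        seg = x[lo:hi]
        if seg.size >= 2 and np.all(np.isfinite(seg)):
            if long_runs:
                logger.warning("record split at long gap: segment [%d:%d)", lo, hi)
            yield lo, seg


# ---------------------------------------------------------------------------
# Delimited-text records
# ---------------------------------------------------------------------------

def write_record(rec: SignalRecord, path) -> Path:
    """Write one record as single-channel delimited text (time_s, value)."""
    return write_records_text([rec], path)


def write_records_text(records: list[SignalRecord], path) -> Path:
    """Write one or more aligned records as delimited text.

    All records must share ``fs``, ``t0``, length and subject.  Column
    headers are the modality names, which the default channel map
    round-trips.
    """
    path = Path(path)
    first = records[0]
    for r in records[1:]:
        if r.fs != first.fs or r.n_samples != first.n_samples or r.t0 != first.t0:
            raise ValueError("records written to one file must be aligned")
    header = [
        f"# subject={first.subject_id}",
        f"# fs={first.fs!r}",
        f"# t0={first.t0!r}",
    ]
    t = first.times
    cols = [f"{r.modality}" for r in records]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write(",".join(["time_s"] + cols) + "\n")
        data = np.column_stack([t] + [r.values for r in records])
        for row in data:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    return path


def _read_text_record(path: Path, modalities, channel_map) -> list[SignalRecord]:
    meta = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip().lower()] = val.strip()
    try:
        df = pd.read_csv(path, skiprows=header_lines, float_precision="round_trip")
    except Exception as exc:  # malformed CSV body
        raise FormatError(f"{path}: cannot parse delimited record: {exc}") from exc
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing required 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: record has fewer than 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or (dt.max() - dt.min()) > 1e-6 * dt.mean():
        raise FormatError(f"{path}: non-uniform sampling in 'time_s'")
    fs = float(meta.get("fs", 1.0 / dt.mean()))
    t0 = float(meta.get("t0", t[0]))
    subject = meta.get("subject", path.stem)
    try:
        subject = int(subject)
    except (TypeError, ValueError):
        pass

    channels = [c for c in df.columns if c != "time_s"]
    available = {}
    for name in channels:
        mod = _modality_for_channel(name, channel_map)
        if mod is None and name.upper() == "VALUE":
            mod = str(meta.get("modality", "")).upper() or None
        if mod is not None and mod not in available:
            available[mod] = name
    wanted = list(modalities) if modalities else list(available)
    records = []
    for mod in wanted:
        if mod not in available:
            raise FormatError(
                f"{path}: no channel for requested modality {mod}; "
                f"channels present: {channels}"
            )
        raw = df[available[mod]].to_numpy(dtype=float)
        for start, seg in _repair_gaps(raw, fs):
            records.append(
                SignalRecord(subject, mod, fs, seg, t0=t0 + start / fs,
                             provenance="csv")
            )
    return records


# ---------------------------------------------------------------------------
# Minimal WFDB (single-segment, format 16)
# ---------------------------------------------------------------------------

def write_wfdb(records: list[SignalRecord], record_name: str, directory) -> Path:
    """Write aligned records as a WFDB record (format 16, one .dat file).

    Samples are quantized with a per-channel gain of 1000 ADC units per
    physical unit; quantization is the only loss.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    first = records[0]
    n_sig, n_samp = len(records), first.n_samples
    gain = 1000.0
    adc = np.column_stack(
        [np.clip(np.round(r.values * gain), -32768, 32767).astype("<i2")
         for r in records]
    )
    dat_name = f"{record_name}.dat"
    (directory / dat_name).write_bytes(adc.tobytes())
    lines = [f"{record_name} {n_sig} {first.fs:g} {n_samp}"]
    for r in records:
        units = "mV" if r.modality == "ECG" else "NU"
        chan = {"ECG": "II", "PPG": "PLETH", "RESP": "RESP"}[r.modality]
        lines.append(f"{dat_name} 16 {gain:g}/{units} 16 0 0 0 0 {chan}")
    lines.append(f"# subject={first.subject_id}")
    (directory / f"{record_name}.hea").write_text("\n".join(lines) + "\n")
    return directory / f"{record_name}.hea"


def _read_wfdb(path: Path, modalities, channel_map) -> list[SignalRecord]:
    try:
        lines = [ln.strip() for ln in path.read_text().splitlines()
                 if ln.strip() and not ln.startswith("#")]
        comments = [ln for ln in path.read_text().splitlines() if ln.startswith("#")]
        rec_line = lines[0].split()
        record_name, n_sig = rec_line[0], int(rec_line[1])
        fs = float(rec_line[2]) if len(rec_line) > 2 else 250.0
        n_samp = int(rec_line[3]) if len(rec_line) > 3 else 0
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed WFDB header: {exc}") from exc
    subject = path.stem
    for c in comments:
        if "subject=" in c:
            subject = c.split("subject=", 1)[1].strip()
            try:
                subject = int(subject)
            except ValueError:
                pass
    sig_lines = lines[1:1 + n_sig]
    if len(sig_lines) != n_sig:
        raise FormatError(f"{path}: header promises {n_sig} signals, "
                          f"found {len(sig_lines)} signal lines")
    dat_files, gains, baselines, names = [], [], [], []
    for ln in sig_lines:
        tok = ln.split()
        dat_files.append(tok[0])
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        if fmt != "16":
            raise FormatError(f"{path}: unsupported WFDB format {fmt!r} "
                              "(only format 16 is supported)")
        gain_spec = tok[2] if len(tok) > 2 else "200"
        g = gain_spec.split("/")[0]
        if "(" in g:
            g, base = g.split("(")
            baselines.append(int(base.rstrip(")")))
        else:
            baselines.append(0)
        gains.append(float(g) or 200.0)
        names.append(tok[8] if len(tok) > 8 else f"ch{len(names)}")
    if len(set(dat_files)) != 1:
        raise FormatError(f"{path}: multi-file WFDB records are not supported")
    raw = np.frombuffer((path.parent / dat_files[0]).read_bytes(), dtype="<i2")
    if n_samp:
        raw = raw[: n_samp * n_sig]
    sig = raw.reshape(-1, n_sig).astype(float)
    available = {}
    for j, name in enumerate(names):
        mod = _modality_for_channel(name, channel_map)
        if mod is not None and mod not in available:
            available[mod] = j
    wanted = list(modalities) if modalities else list(available)
    records = []
    for mod in wanted:
        if mod not in available:
            raise FormatError(
                f"{path}: no channel for requested modality {mod}; "
                f"channels present: {names}"
            )
        j = available[mod]
        values = (sig[:, j] - baselines[j]) / gains[j]
        for start, seg in _repair_gaps(values, fs):
            records.append(SignalRecord(subject, mod, fs, seg,
                                        t0=start / fs, provenance="wfdb"))
    return records


def read_record(path, modalities=None, channel_map=None) -> list[SignalRecord]:
    """Read a waveform record file into one SignalRecord per modality.

    ``path`` may be a delimited-text record or a WFDB ``.hea`` header.
    ``modalities`` limits/orders the requested modalities (default: all
    recognizable channels).  ``channel_map`` overrides
    :data:`DEFAULT_CHANNEL_MAP`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"record file not found: {path}")
    cmap = dict(DEFAULT_CHANNEL_MAP)
    if channel_map:
        cmap.update({k.upper(): tuple(v) for k, v in channel_map.items()})
    if modalities is not None:
        modalities = [str(m).upper() for m in modalities]
        for m in modalities:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}")
    if path.suffix == ".hea":
        return _read_wfdb(path, modalities, cmap)
    return _read_text_record(path, modalities, cmap)


# ---------------------------------------------------------------------------
# Annotations and feature tables
# ---------------------------------------------------------------------------

def write_annotations(times, labels, path) -> Path:
    """Write event annotations as comma text (time_s, label)."""
    path = Path(path)
    times = np.asarray(times, dtype=float)
    labels = list(labels)
    if len(labels) == 1:
        labels = labels * times.size
    if len(labels) != times.size:
        raise ValueError("times and labels must have equal length")
    with open(path, "w") as fh:
        fh.write("time_s,label\n")
        for t, lab in zip(times, labels):
            fh.write(f"{float(t)!r},{lab}\n")
    return path


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "label"]:
        raise FormatError(f"{path}: expected columns time_s,label")
    return df


def write_feature_table(matrix: FeatureMatrix, path) -> Path:
    """Write a labeled feature matrix as delimited text (lossless floats)."""
    if matrix.n_samples == 0:
        raise ValueError("refusing to write an empty feature matrix")
    path = Path(path)
    df = matrix.to_frame()
    # repr-based float formatting round-trips exactly.
    with open(path, "w") as fh:
        if matrix.modality:
            fh.write(f"# modality={matrix.modality}\n")
        fh.write(",".join(df.columns) + "\n")
        for _, row in df.iterrows():
            cells = [str(row.iloc[0]), str(row.iloc[1])]
            cells += [repr(float(v)) for v in row.iloc[2:]]
            fh.write(",".join(cells) + "\n")
    return path


def read_feature_table(path) -> FeatureMatrix:
    path = Path(path)
    modality = None
    skip = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            skip = 1
            if "modality=" in first:
                modality = first.split("modality=", 1)[1].strip()
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    if df.columns[0] != "subject" or df.columns[1] != "window":
        raise FormatError(f"{path}: expected leading columns subject,window")
    if not np.all(np.isfinite(df.iloc[:, 2:].to_numpy(dtype=float))):
        raise FormatError(f"{path}: feature table contains non-finite values")
    return FeatureMatrix(
        X=df.iloc[:, 2:].to_numpy(dtype=float),
        labels=df["subject"].to_numpy(),
        feature_names=list(df.columns[2:]),
        window_ids=df["window"].to_numpy(),
        modality=modality,
    )
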