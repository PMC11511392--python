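"""Cycle detection, fiducial localization and single-period segmentation.

ECG beats are found with the classic Pan-Tompkins chain (band-pass 5-15 Hz,
five-point derivative, squaring, 150 ms moving-window integration, dual
adaptive thresholds with search-back and a 200 ms refractory period), then
P/Q/R/S/T fiducials are localized around each R peak inside the T1 (pre-R,
encloses the P wave) and T2 (post-R, encloses the T wave) windows.  PPG
cycles are cut foot-to-foot between systolic peaks; respiration cycles are
cut trough-to-trough from the sign changes of a smoothed first difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import SignalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "EcgFiducials",
    "PpgFiducials",
    "RespFiducials",
    "CycleSegment",
    "ComplexVector",
    "detect_r_peaks",
    "locate_pqrst",
    "segment_ecg",
    "segment_ppg",
    "segment_resp",
    "build_complex",
]

#: Default pre-R / post-R windows (s): T1 spans back past the P wave,
#: T2 forward past the T wave.
T1_DEFAULT = 0.25
T2_DEFAULT = 0.45


@dataclass
class EcgFiducials:
    """Sample indices of the five reference points of one beat."""

    p_idx: int
    q_idx: int
    r_idx: int
    s_idx: int
    t_idx: int
    t1_window: float = T1_DEFAULT
    t2_window: float = T2_DEFAULT

    def __post_init__(self) -> None:
        if not self.p_idx < self.q_idx < self.r_idx < self.s_idx < self.t_idx:
            raise ValueError(
                "fiducials must be ordered p < q < r < s < t, got "
                f"{(self.p_idx, self.q_idx, self.r_idx, self.s_idx, self.t_idx)}"
            )


@dataclass
class PpgFiducials:
    peak_idx: int   # systolic peak
    foot_idx: int   # cycle onset


@dataclass
class RespFiducials:
    peak_idx: int
    trough_idx: int


@dataclass
class CycleSegment:
    """A single-period waveform slice with its fiducial points.

    Fiducial indices are relative to the start of ``values``; ``t_start``
    places the slice on the source record's timeline.
    """

    modality: str
    values: np.ndarray
    fs: float
    fiducials: object
    t_start: float
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.size
        for name in ("p_idx", "q_idx", "r_idx", "s_idx", "t_idx",
                     "peak_idx", "foot_idx", "trough_idx"):
            idx = getattr(self.fiducials, name, None)
            if idx is not None and not 0 <= idx < n:
                raise ValueError(f"fiducial {name}={idx} outside segment of {n} samples")

    @property
    def duration(self) -> float:
        return self.values.size / self.fs


# ---------------------------------------------------------------------------
# Pan-Tompkins R-peak detection
# ---------------------------------------------------------------------------

def _pt_preprocess(x: np.ndarray, fs: float):
    """Band-pass -> derivative -> square -> moving-window integration."""
    nyq = fs / 2.0
    b, a = sps.butter(3, [5.0 / nyq, min(15.0, 0.9 * nyq) / nyq], btype="band")
    bp = sps.filtfilt(b, a, x)
    # Five-point derivative (1/8)(2x[n] + x[n-1] - x[n-3] - 2x[n-4]).
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * fs / 8.0
    deriv = np.convolve(bp, kernel, mode="same")
    sq = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")
    return bp, mwi


def detect_r_peaks(rec: SignalRecord) -> np.ndarray:
    """R-peak sample indices by the Pan-Tompkins algorithm.

    Candidate peaks of the integrated signal pass a dual adaptive threshold
    (signal/noise running estimates, 200 ms refractory); a half-threshold
    search-back fires when no beat arrives within 1.66 times the running RR
    average.  Accepted peaks are refined to the local maximum of the input
    ECG within +/-75 ms.  Returns an empty array (with a warning) if no
    peaks survive.
    """
    if rec.modality != "ECG":
        raise ValueError(f"detect_r_peaks expects an ECG record, got {rec.modality}")
    if rec.duration < 3.0:
        raise ValueError(f"record too short for QRS detection: {rec.duration:.2f} s")
    x = rec.values
    fs = rec.fs
    if np.ptp(x) == 0:
        logger.warning("flat ECG record %s: no R peaks", rec.subject_id)
        return np.array([], dtype=int)
    _, mwi = _pt_preprocess(x, fs)

    cand, _ = sps.find_peaks(mwi, distance=max(1, int(0.2 * fs)))
    if cand.size == 0:
        logger.warning("no integration-wave peaks in record %s", rec.subject_id)
        return np.array([], dtype=int)

    # Robust initialization of the running signal/noise levels.
    spki = 0.6 * np.percentile(mwi, 98)
    npki = float(np.median(mwi))
    rr_avg = 60.0 / 75.0  # seconds, seeded at 75 bpm
    refractory = int(round(0.2 * fs))

    accepted: list[int] = []
    last_peak = -10 * fs

    def _accept(idx: int, level: float):
        nonlocal spki, last_peak, rr_avg
        spki = 0.125 * level + 0.875 * spki
        if accepted:
            rr = (idx - accepted[-1]) / fs
            if 0.3 < rr < 3.0:
                rr_avg = 0.125 * rr + 0.875 * rr_avg
        accepted.append(idx)
        last_peak = idx

    for idx in cand:
        level = mwi[idx]
        thr1 = npki + 0.25 * (spki - npki)
        if idx - last_peak < refractory:
            continue
        if level > thr1:
            _accept(idx, level)
        else:
            npki = 0.125 * level + 0.875 * npki
            # Search-back: no beat for 1.66 RR -> retry at half threshold.
            if accepted and (idx - accepted[-1]) / fs > 1.66 * rr_avg:
                if level > 0.5 * thr1:
                    _accept(idx, level)

    if not accepted:
        logger.warning("no R peaks above threshold in record %s", rec.subject_id)
        return np.array([], dtype=int)

    # Refine to the local maximum of the (filtered) ECG within +/-75 ms.
    half = int(round(0.075 * fs))
    refined = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(x.size, idx + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    # Enforce the refractory period after refinement as well.
    out = [int(refined[0])]
    for idx in refined[1:]:
        if idx - out[-1] >= refractory:
            out.append(int(idx))
        elif x[idx] > x[out[-1]]:
            out[-1] = int(idx)
    return np.asarray(out, dtype=int)


def locate_pqrst(rec: SignalRecord, r_idx: int, t1: float = T1_DEFAULT,
                 t2: float = T2_DEFAULT) -> EcgFiducials | None:
    """Locate P, Q, S, T around a detected R peak.

    Q and S are troughs within 50 ms before/after R; P is the maximum of
    the (r - t1, q) window and T the maximum of the (s, r + t2) window.
    Returns ``None`` (logged, not raised) when the windows exceed the
    record bounds, so boundary beats are skipped rather than padded.
    """
    x = rec.values
    fs = rec.fs
    w50 = max(1, int(round(0.05 * fs)))
    lo = r_idx - int(round(t1 * fs))
    hi = r_idx + int(round(t2 * fs))
    if lo < 0 or hi > x.size:
        logger.debug("beat at %d skipped: window [%d, %d) out of bounds", r_idx, lo, hi)
        return None
    q_idx = r_idx - w50 + int(np.argmin(x[r_idx - w50:r_idx]))
    s_idx = r_idx + 1 + int(np.argmin(x[r_idx + 1:r_idx + 1 + w50]))
    if q_idx <= lo or s_idx >= hi - 1:
        logger.debug("beat at %d skipped: degenerate Q/S windows", r_idx)
        return None
    p_idx = lo + int(np.argmax(x[lo:q_idx]))
    t_idx = s_idx + 1 + int(np.argmax(x[s_idx + 1:hi]))
    try:
        return EcgFiducials(p_idx, q_idx, r_idx, s_idx, t_idx,
                            t1_window=t1, t2_window=t2)
    except ValueError:
        logger.debug("beat at %d skipped: unordered fiducials", r_idx)
        return None


def segment_ecg(rec: SignalRecord, r_peaks: np.ndarray | None = None,
                t1: float = T1_DEFAULT, t2: float = T2_DEFAULT) -> list[CycleSegment]:
    """Cut one [r - t1, r + t2) segment per detected beat."""
    if r_peaks is None:
        r_peaks = detect_r_peaks(rec)
    out = []
    for r in np.asarray(r_peaks, dtype=int):
        fid = locate_pqrst(rec, int(r), t1=t1, t2=t2)
        if fid is None:
            continue
        lo = fid.r_idx - int(round(t1 * rec.fs))
        hi = fid.r_idx + int(round(t2 * rec.fs))
        rel = EcgFiducials(fid.p_idx - lo, fid.q_idx - lo, fid.r_idx - lo,
                           fid.s_idx - lo, fid.t_idx - lo, t1, t2)
        out.append(CycleSegment("ECG", rec.values[lo:hi], rec.fs, rel,
                                t_start=rec.t0 + lo / rec.fs,
                                source=str(rec.subject_id)))
    return out


def segment_ppg(rec: SignalRecord, min_separation: float = 0.4,
                prominence_frac: float = 0.3) -> list[CycleSegment]:
    """Foot-to-foot PPG cycles between systolic peaks.

    Systolic peaks are local maxima at least ``min_separation`` apart whose
    prominence reaches ``prominence_frac`` of the median candidate
    prominence; cycle feet are the minima between consecutive peaks.
    """
    if rec.modality != "PPG":
        raise ValueError(f"segment_ppg expects a PPG record, got {rec.modality}")
    if rec.duration < 3.0:
        raise ValueError(f"record too short for pulse segmentation: {rec.duration:.2f} s")
    x = rec.values
    dist = max(1, int(round(min_separation * rec.fs)))
    cand, props = sps.find_peaks(x, distance=dist, prominence=0.0)
    if cand.size < 2:
        logger.warning("fewer than 2 pulse peaks in record %s", rec.subject_id)
        return []
    med_prom = float(np.median(props["prominences"]))
    peaks = cand[props["prominences"] >= prominence_frac * med_prom]
    if peaks.size < 2:
        logger.warning("fewer than 2 prominent pulses in record %s", rec.subject_id)
        return []
    feet = np.array([p0 + int(np.argmin(x[p0:p1]))
                     for p0, p1 in zip(peaks[:-1], peaks[1:])], dtype=int)
    out = []
    for i in range(feet.size - 1):
        f0, f1 = int(feet[i]), int(feet[i + 1])
        inside = peaks[(peaks > f0) & (peaks < f1)]
        if inside.size == 0:
            continue
        pk = int(inside[np.argmax(x[inside])])
        fid = PpgFiducials(peak_idx=pk - f0, foot_idx=0)
        out.append(CycleSegment("PPG", x[f0:f1], rec.fs, fid,
                                t_start=rec.t0 + f0 / rec.fs,
                                source=str(rec.subject_id)))
    return out


def _alternating_extrema(x: np.ndarray, fs: float, merge_s: float = 1.0):
    """Peak/trough indices from sign changes of a smoothed first difference,
    with extrema closer than ``merge_s`` merged keeping the larger excursion."""
    win = max(1, int(round(0.25 * fs)))
    smooth = np.convolve(x, np.ones(win) / win, mode="same")
    d = np.diff(smooth)
    sign = np.sign(d)
    # Carry the previous sign through zero-derivative runs.
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    flips = np.flatnonzero(np.diff(sign) != 0) + 1
    # The smoothed derivative is an edge artifact within ~0.5 s of the
    # record boundaries; extrema there are partial cycles and are dropped.
    guard = int(round(0.5 * fs))
    peaks, troughs = [], []
    for i in flips:
        if not guard <= i <= x.size - guard:
            continue
        if sign[i - 1] > 0 and sign[i] < 0:
            peaks.append(i)
        elif sign[i - 1] < 0 and sign[i] > 0:
            troughs.append(i)

    def merge(idxs, keep_max: bool):
        if not idxs:
            return []
        gap = merge_s * fs
        merged = [idxs[0]]
        for i in idxs[1:]:
            if i - merged[-1] < gap:
                better = x[i] > x[merged[-1]] if keep_max else x[i] < x[merged[-1]]
                if better:
                    merged[-1] = i
            else:
                merged.append(i)
        return merged

    return merge(peaks, True), merge(troughs, False)


def segment_resp(rec: SignalRecord, merge_s: float = 1.0) -> list[CycleSegment]:
    """Trough-to-trough respiration cycles from derivative sign changes."""
    if rec.modality != "RESP":
        raise ValueError(f"segment_resp expects a RESP record, got {rec.modality}")
    x = rec.values
    if np.ptp(x) == 0:
        logger.warning("constant RESP record %s: no cycles", rec.subject_id)
        return []
    peaks, troughs = _alternating_extrema(x, rec.fs, merge_s=merge_s)
    if len(troughs) < 2:
        logger.warning("fewer than 2 breath troughs in record %s", rec.subject_id)
        return []
    out = []
    for t0_idx, t1_idx in zip(troughs[:-1], troughs[1:]):
        inside = [p for p in peaks if t0_idx < p < t1_idx]
        if not inside:
            continue
        pk = max(inside, key=lambda i: x[i])
        fid = RespFiducials(peak_idx=pk - t0_idx, trough_idx=0)
        out.append(CycleSegment("RESP", x[t0_idx:t1_idx], rec.fs, fid,
                                t_start=rec.t0 + t0_idx / rec.fs,
                                source=str(rec.subject_id)))
    return out


@dataclass
class ComplexVector:
    """Resampled cycle overlay ("waveform complex") and its mean template."""

    stack: np.ndarray      # (n_segments, n_points)
    template: np.ndarray   # (n_points,)


def build_complex(segments: list[CycleSegment], n_points: int = 100) -> ComplexVector:
    """Linearly resample each segment to ``n_points`` and average."""
    if not segments:
        raise ValueError("build_complex needs at least one segment")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.linspace(0.0, 1.0, n_points)
    rows = []
    for seg in segments:
        src = np.linspace(0.0, 1.0, seg.values.size)
        rows.append(np.interp(grid, src, seg.values))
    stack = np.vstack(rows)
    return ComplexVector(stack=stack, template=stack.mean(axis=0))
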