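"""Per-cycle feature extraction and window aggregation.

Each single-cycle segment yields 20 features: 15 time-domain (moments,
extremes, energy, zero crossings, Hjorth parameters, cycle duration) and 5
frequency-domain (dominant frequency, spectral centroid and bandwidth,
normalized spectral entropy, and the low-band energy fraction with a
modality-specific band split: 10 Hz for ECG, 2 Hz for PPG, 0.5 Hz for
RESP).  Cycles are then binned by time into equal windows per subject and
aggregated by the per-feature median, producing one sample per window —
the 25-subject x 20-window layout gives the 500-row per-modality sample
set the identification experiments run on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .segment import CycleSegment

logger = logging.getLogger(__name__)

__all__ = [
    "TIME_FEATURES",
    "FREQ_FEATURES",
    "FEATURE_NAMES",
    "BAND_SPLIT_HZ",
    "FeatureMatrix",
    "extract_time_features",
    "extract_freq_features",
    "extract_features",
    "build_samples",
]

TIME_FEATURES = (
    "mean", "median", "std", "rms", "mad", "skewness", "kurtosis",
    "minimum", "maximum", "ptp", "energy", "zero_crossings",
    "hjorth_mobility", "hjorth_complexity", "duration_s",
)
FREQ_FEATURES = (
    "dominant_freq_hz", "spectral_centroid_hz", "spectral_bandwidth_hz",
    "spectral_entropy", "low_band_fraction",
)
FEATURE_NAMES = TIME_FEATURES + FREQ_FEATURES

#: Low/high band split (Hz) per modality for the band-energy feature.
BAND_SPLIT_HZ = {"ECG": 10.0, "PPG": 2.0, "RESP": 0.5}


def extract_time_features(seg: CycleSegment) -> dict:
    """The 15 time-domain features of one cycle, in fixed order.

    Degenerate constant segments take skewness = kurtosis = mobility =
    complexity = 0 by convention (logged at debug level).
    """
    x = np.asarray(seg.values, dtype=float)
    if x.size < 4:
        raise ValueError(f"segment too short for time features: {x.size} samples")
    mu = float(np.mean(x))
    sd = float(np.std(x))
    constant = sd == 0.0
    if constant:
        logger.debug("constant segment: moment features defined 0 by convention")
        skew = kurt = mobility = complexity = 0.0
        zc = 0
    else:
        skew = float(sstats.skew(x))
        kurt = float(sstats.kurtosis(x))
        centered = x - mu
        zc = int(np.sum(np.diff(np.signbit(centered)) != 0))
        dx = np.diff(x)
        var_x, var_dx = np.var(x), np.var(dx)
        mobility = float(np.sqrt(var_dx / var_x))
        if var_dx > 0:
            ddx = np.diff(dx)
            mob_dx = np.sqrt(np.var(ddx) / var_dx)
            complexity = float(mob_dx / mobility) if mobility > 0 else 0.0
        else:
            complexity = 0.0
    vals = (
        mu,
        float(np.median(x)),
        sd,
        float(np.sqrt(np.mean(x ** 2))),
        float(np.mean(np.abs(x - mu))),
        skew,
        kurt,
        float(np.min(x)),
        float(np.max(x)),
        float(np.ptp(x)),
        float(np.sum(x ** 2)),
        float(zc),
        mobility,
        complexity,
        x.size / seg.fs,
    )
    return dict(zip(TIME_FEATURES, vals))


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def extract_freq_features(seg: CycleSegment) -> dict:
    """The 5 frequency-domain features from a zero-padded periodogram.

    The DC bin is excluded from the dominant-frequency search and from the
    entropy normalization.  All-zero segments take entropy 0 and band
    fraction 1 by convention.
    """
    x = np.asarray(seg.values, dtype=float)
    if x.size < 8:
        raise ValueError(f"segment too short for spectral features: {x.size} samples")
    nfft = max(256, _next_pow2(4 * x.size))
    spec = np.abs(np.fft.rfft(x - np.mean(x), n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / seg.fs)
    p = spec[1:]          # drop DC
    f = freqs[1:]
    total = float(np.sum(p))
    if total <= 0.0:
        logger.debug("all-zero segment: entropy 0, band fraction 1 by convention")
        return dict(zip(FREQ_FEATURES, (0.0, 0.0, 0.0, 0.0, 1.0)))
    w = p / total
    centroid = float(np.sum(f * w))
    bandwidth = float(np.sqrt(np.sum((f - centroid) ** 2 * w)))
    nz = w[w > 0]
    entropy = float(-np.sum(nz * np.log(nz)) / np.log(w.size))
    split = BAND_SPLIT_HZ.get(seg.modality, 1.0)
    low = float(np.sum(w[f <= split]))
    vals = (
        float(f[int(np.argmax(p))]),
        centroid,
        bandwidth,
        entropy,
        low,
    )
    return dict(zip(FREQ_FEATURES, vals))


def extract_features(seg: CycleSegment) -> np.ndarray:
    """All 20 features of one cycle as an array ordered per FEATURE_NAMES."""
    d = extract_time_features(seg)
    d.update(extract_freq_features(seg))
    return np.array([d[name] for name in FEATURE_NAMES])


@dataclass
class FeatureMatrix:
    """Labeled samples-by-features table for one modality (or fused)."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: list
    window_ids: np.ndarray | None = None
    modality: str | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.labels.size != self.X.shape[0]:
            raise ValueError("labels must align with feature rows")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names must align with feature columns")
        if self.window_ids is None:
            self.window_ids = np.zeros(self.X.shape[0], dtype=int)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "window", self.window_ids)
        df.insert(0, "subject", self.labels)
        return df

    def select(self, mask) -> "FeatureMatrix":
        return FeatureMatrix(self.X[mask], self.labels[mask],
                             list(self.feature_names),
                             self.window_ids[mask], self.modality)


def build_samples(
    cycles_by_subject: dict,
    windows_per_subject: int = 20,
    span: tuple | None = None,
) -> FeatureMatrix:
    """Aggregate per-cycle features into per-window samples.

    Each subject's cycles are binned by start time into
    ``windows_per_subject`` equal windows (over ``span`` seconds, default
    the subject's own cycle-time range) and each window becomes one sample:
    the per-feature **median** over its cycles, robust against missed or
    spurious cycles.  Empty windows are dropped with a warning; a subject
    keeping fewer than half its windows is dropped entirely.
    """
    if windows_per_subject < 1:
        raise ValueError("windows_per_subject must be >= 1")
    rows, labels, window_ids = [], [], []
    modality = None
    for subject, cycles in cycles_by_subject.items():
        if not cycles:
            logger.warning("subject %s has no cycles; dropped", subject)
            continue
        modality = cycles[0].modality
        t = np.array([c.t_start for c in cycles])
        lo, hi = span if span is not None else (t.min(), t.max() + 1e-9)
        edges = np.linspace(lo, hi, windows_per_subject + 1)
        bins = np.clip(np.searchsorted(edges, t, side="right") - 1,
                       0, windows_per_subject - 1)
        feats = np.vstack([extract_features(c) for c in cycles])
        kept = []
        for w in range(windows_per_subject):
            members = feats[bins == w]
            if members.shape[0] == 0:
                logger.warning("subject %s window %d empty; dropped", subject, w)
                continue
            kept.append((w, np.median(members, axis=0)))
        if len(kept) < windows_per_subject / 2:
            logger.warning("subject %s kept only %d/%d windows; subject dropped",
                           subject, len(kept), windows_per_subject)
            continue
        for w, vec in kept:
            rows.append(vec)
            labels.append(subject)
            window_ids.append(w)
    if not rows:
        raise ValueError("no samples survived window aggregation")
    return FeatureMatrix(
        X=np.vstack(rows),
        labels=np.asarray(labels),
        feature_names=list(FEATURE_NAMES),
        window_ids=np.asarray(window_ids),
        modality=modality,
    )
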