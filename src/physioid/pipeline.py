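"""End-to-end orchestration: synthetic cohort -> aligned feature matrices.

The default protocol mirrors a bench acquisition campaign: 25 subjects,
10 records of 60 s each per subject on a concatenated timeline, all three
modalities, moderate noise.  Cycles from all records of one subject are
binned into 20 equal 30 s windows, yielding 20 samples per subject and a
500-row sample set per modality, row-aligned across modalities on the
(subject, window) key.
"""

from __future__ import annotations

import logging

import numpy as np

from . import preprocess, segment, synth
from .features import FeatureMatrix, build_samples
from .types import MODALITIES, SignalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_N_SUBJECTS", "DEFAULT_RECORDS", "DEFAULT_DURATION", "DEFAULT_FS",
    "preprocess_record", "segment_record", "build_cohort_matrices",
]

DEFAULT_N_SUBJECTS = 25
DEFAULT_RECORDS = 10
DEFAULT_DURATION = 60.0
DEFAULT_FS = 125.0
DEFAULT_WINDOWS = 20


def preprocess_record(rec: SignalRecord,
                      denoise_cfg: preprocess.DenoiseConfig | None = None,
                      fir_cutoff: float = 1.0,
                      fir_numtaps: int | None = None) -> SignalRecord:
    """Modality dispatch: wavelet denoising for ECG/PPG, FIR for RESP."""
    if rec.modality == "RESP":
        return preprocess.fir_lowpass(rec, cutoff=fir_cutoff, numtaps=fir_numtaps)
    return preprocess.wavelet_denoise(rec, denoise_cfg)


def segment_record(rec: SignalRecord, t1: float = segment.T1_DEFAULT,
                   t2: float = segment.T2_DEFAULT) -> list[segment.CycleSegment]:
    """Modality dispatch to the per-modality segmenters."""
    if rec.modality == "ECG":
        return segment.segment_ecg(rec, t1=t1, t2=t2)
    if rec.modality == "PPG":
        return segment.segment_ppg(rec)
    return segment.segment_resp(rec)


def build_cohort_matrices(
    n_subjects: int = DEFAULT_N_SUBJECTS,
    records_per_subject: int = DEFAULT_RECORDS,
    duration: float = DEFAULT_DURATION,
    fs: float = DEFAULT_FS,
    noise: synth.NoiseSpec = synth.DEFAULT_NOISE,
    master_seed: int = 0,
    modalities=MODALITIES,
    windows_per_subject: int = DEFAULT_WINDOWS,
    denoise_cfg: preprocess.DenoiseConfig | None = None,
) -> dict:
    """Generate, preprocess, segment and featurize a whole cohort.

    Returns ``{modality: FeatureMatrix}`` with rows aligned across
    modalities on the (subject, window) key; windows missing in any
    modality are dropped from all of them.
    """
    modalities = [str(m).upper() for m in modalities]
    cohort = synth.sample_cohort(n_subjects, master_seed)
    matrices = {}
    span = (0.0, records_per_subject * duration)
    for mod in modalities:
        cycles_by_subject = {}
        for profile in cohort:
            cycles = []
            for ri in range(records_per_subject):
                rec, _ = synth.generate_record(
                    profile, mod, duration=duration, fs=fs, noise=noise,
                    record_index=ri, t0=ri * duration,
                )
                rec = preprocess_record(rec, denoise_cfg=denoise_cfg)
                cycles.extend(segment_record(rec))
            cycles_by_subject[profile.subject_id] = cycles
        matrices[mod] = build_samples(
            cycles_by_subject, windows_per_subject=windows_per_subject, span=span)
        logger.info("%s: %d samples x %d features", mod,
                    matrices[mod].n_samples, matrices[mod].n_features)
    return _align(matrices)


def _align(matrices: dict) -> dict:
    """Keep only (subject, window) rows present in every modality."""
    keysets = []
    for fm in matrices.values():
        keysets.append({(l, w) for l, w in zip(fm.labels.tolist(),
                                               fm.window_ids.tolist())})
    common = set.intersection(*keysets)
    out = {}
    for mod, fm in matrices.items():
        keys = list(zip(fm.labels.tolist(), fm.window_ids.tolist()))
        mask = np.array([k in common for k in keys])
        sel = fm.select(mask)
        order = np.lexsort((sel.window_ids, sel.labels))
        out[mod] = sel.select(order)
        if not np.all(mask):
            logger.warning("%s: dropped %d rows missing in other modalities",
                           mod, int(np.sum(~mask)))
    return out
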