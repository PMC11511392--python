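"""Core waveform container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Modalities handled by the pipeline.
MODALITIES = ("ECG", "PPG", "RESP")


@dataclass
class SignalRecord:
    """One subject's waveform for one modality.

    Parameters
    ----------
    subject_id
        Integer or string label identifying the subject.
    modality
        One of ``"ECG"``, ``"PPG"``, ``"RESP"``.
    fs
        Sampling rate in Hz (uniform sampling assumed).
    values
        Amplitude series; mV for ECG, arbitrary units for PPG/RESP.
    t0
        Time of the first sample in seconds (lets several records of one
        subject live on a common timeline).
    provenance
        Where the record came from: ``"wfdb"``, ``"csv"`` or ``"synthetic"``.
    """

    subject_id: object
    modality: str
    fs: float
    values: np.ndarray
    t0: float = 0.0
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.modality = str(self.modality).upper()
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("values must be a 1-D series with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ValueError(
                f"record {self.subject_id}/{self.modality} contains a non-finite "
                f"sample at index {bad}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (``t0`` offset included)."""
        return self.t0 + np.arange(self.values.size) / self.fs

    def with_values(self, values: np.ndarray, provenance: str | None = None) -> "SignalRecord":
        """Copy of this record carrying new sample values."""
        rec = replace(self, values=np.asarray(values, dtype=float))
        if provenance is not None:
            rec.provenance = provenance
        return rec
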