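"""Core containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SourceSeriesSet"]


@dataclass
class SourceSeriesSet:
    """One subject/timepoint's ROI source time series.

    Parameters
    ----------
    subject_id, timepoint
        Free-form labels (e.g. ``"S01"``, ``"baseline"``, ``"free_access"``).
    fs
        Sampling rate in Hz.
    roi_labels
        Unique label per ROI; defines row order of ``data``.
    data
        Real-valued matrix of shape (n_rois, n_samples).
    """

    subject_id: str
    timepoint: str
    fs: float
    roi_labels: list[str]
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_labels = list(self.roi_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_rois, n_samples) matrix")
        n, t = self.data.shape
        if n < 2:
            raise ValueError("a source series set needs at least 2 ROIs")
        if len(self.roi_labels) != n:
            raise ValueError(
                f"{len(self.roi_labels)} labels for {n} data rows"
            )
        if len(set(self.roi_labels)) != n:
            raise ValueError("roi_labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        if t < 2 * self.fs:
            raise ValueError(
                f"need at least 2 s of data ({int(2 * self.fs)} samples at "
                f"fs={self.fs} Hz), got {t}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def index_of(self, label: str) -> int:
        return self.roi_labels.index(label)
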