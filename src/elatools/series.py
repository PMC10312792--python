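"""Containers for continuous and binarized multichannel time series.

Both containers store an (N, tmax) matrix whose rows are regions of interest
(ROIs) and whose columns are time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ContinuousTimeSeries", "BinaryTimeSeries"]


def _default_labels(n: int) -> list[str]:
    return [f"roi{i}" for i in range(n)]


@dataclass
class ContinuousTimeSeries:
    """Real-valued ROI × time signal matrix."""

    values: np.ndarray
    roi_labels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be an (N, tmax) matrix")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("values must be finite (no missing entries)")
        if not self.roi_labels:
            self.roi_labels = _default_labels(self.values.shape[0])
        if len(self.roi_labels) != self.values.shape[0]:
            raise ValueError("roi_labels length must match the number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def t_max(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryTimeSeries:
    """±1-valued ROI × time activity matrix."""

    values: np.ndarray
    roi_labels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be an (N, tmax) matrix")
        if not np.all(np.isin(self.values, (-1, 1))):
            raise ValueError("binary series entries must be -1 or +1")
        self.values = self.values.astype(np.int8)
        if not self.roi_labels:
            self.roi_labels = _default_labels(self.values.shape[0])
        if len(self.roi_labels) != self.values.shape[0]:
            raise ValueError("roi_labels length must match the number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def t_max(self) -> int:
        return self.values.shape[1]
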