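"""Global-signal z-scoring and mean-threshold binarization.

The z-scoring step standardizes each time point *across ROIs*:

    z_it = (x_it − m_t) / s_t

where m_t and s_t are the mean and standard deviation of x_it over the N ROIs
at fixed t.  Subtracting m_t removes the global signal (the common cross-ROI
offset at each volume, dominated by physiological and scanner noise in fMRI).

Binarization then thresholds each ROI at its own time average: σ_it = +1 iff
z_it exceeds the time mean of z_i·, else −1 (ties map to −1 for determinism;
exact ties have measure zero in real-valued data).
"""

from __future__ import annotations

import numpy as np

from .series import BinaryTimeSeries, ContinuousTimeSeries

__all__ = ["zscore_global", "binarize"]


def zscore_global(x: ContinuousTimeSeries, ddof: int = 0) -> ContinuousTimeSeries:
    """Standardize across ROIs at each time point, removing the global signal.

    ``ddof=0`` (population standard deviation over the N ROIs) is the default
    convention; pass ``ddof=1`` for the sample convention.  Raises if some
    time point has zero cross-ROI variance (a constant volume), naming the
    offending time index.
    """
    if x.n < 2:
        raise ValueError("z-scoring across ROIs requires N >= 2")
    v = x.values
    mt = v.mean(axis=0)
    st = v.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(st == 0)
    if bad.size:
        raise ValueError(
            f"zero cross-ROI standard deviation at time index {bad[0]} "
            f"(constant volume); z-score undefined"
        )
    z = (v - mt) / st
    return ContinuousTimeSeries(values=z, roi_labels=list(x.roi_labels), meta=dict(x.meta))


def binarize(z: ContinuousTimeSeries) -> BinaryTimeSeries:
    """Threshold each ROI at its time average: σ_it = +1 iff z_it > mean_t(z_i·)."""
    if z.t_max < 2:
        raise ValueError("binarization threshold needs tmax >= 2")
    thr = z.values.mean(axis=1, keepdims=True)
    sigma = np.where(z.values > thr, 1, -1)
    return BinaryTimeSeries(values=sigma, roi_labels=list(z.roi_labels), meta=dict(z.meta))
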