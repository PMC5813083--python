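"""Epoched, stimulus-locked ROI time series.

The :class:`EpochSet` is the universal input container of the package: a
``(n_trials, n_roi, n_samples)`` float64 array with a sampling rate ``fs``
(Hz) and the time ``t0`` (s) of the first sample relative to stimulus
onset.  All trials share the same ROI set and length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["EpochSet", "DEFAULT_ROI_LABELS"]

#: Left/right primary (BA41) and secondary (BA42) auditory cortex.
DEFAULT_ROI_LABELS = ("lPAC", "rPAC", "lSAC", "rSAC")


@dataclass(frozen=True)
class EpochSet:
    """Multi-trial ROI time series, stimulus-locked.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_roi, n_samples)``; coerced to float64.
    roi_labels
        Ordered, unique region names, one per ROI axis entry.
    fs
        Sampling rate in Hz (> 0).
    t0
        Time of the first sample relative to stimulus onset, in seconds
        (negative for a pre-stimulus baseline).
    """

    data: np.ndarray
    roi_labels: tuple[str, ...]
    fs: float
    t0: float = 0.0
    _skip_validation: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "roi_labels", tuple(str(r) for r in self.roi_labels))
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "t0", float(self.t0))
        if self._skip_validation:
            return
        if data.ndim != 3:
            raise ValidationError(
                f"epoch data must be (trial, roi, sample); got ndim={data.ndim}"
            )
        n_trials, n_roi, n_samples = data.shape
        if n_trials < 1 or n_samples < 1:
            raise ValidationError(f"empty EpochSet: shape {data.shape}")
        if len(self.roi_labels) != n_roi:
            raise ValidationError(
                f"{len(self.roi_labels)} roi_labels for {n_roi} ROI rows"
            )
        if len(set(self.roi_labels)) != n_roi:
            raise ValidationError(f"duplicate roi_labels: {self.roi_labels}")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if not np.isfinite(data).all():
            raise ValidationError("epoch data contains non-finite values")

    # -- shape accessors -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds relative to stimulus onset."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def roi_index(self, label: str) -> int:
        try:
            return self.roi_labels.index(label)
        except ValueError:
            raise ValidationError(
                f"unknown ROI {label!r}; have {self.roi_labels}"
            ) from None

    # -- transforms ------------------------------------------------------
    def demeaned(self) -> "EpochSet":
        """Remove the per-trial, per-ROI mean (zero-mean within each epoch)."""
        centered = self.data - self.data.mean(axis=2, keepdims=True)
        return EpochSet(centered, self.roi_labels, self.fs, self.t0,
                        _skip_validation=True)

    def select_trials(self, indices) -> "EpochSet":
        return EpochSet(self.data[np.asarray(indices)], self.roi_labels,
                        self.fs, self.t0)
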