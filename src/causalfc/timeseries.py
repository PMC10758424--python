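"""ROI time-series container, delimited-text I/O and light preprocessing.

The unit of analysis is one subject's regional BOLD signal: a time x region
matrix sampled at the scanner repetition time (TR).  Imaging-level
preprocessing (realignment, normalisation, parcellation) is assumed done
upstream; this module only covers what is applied to the extracted regional
series: dropping initial volumes, linear detrending and band-pass filtering.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import DataFormatError

__all__ = [
    "ROITimeSeries",
    "read_roi_timeseries",
    "write_roi_timeseries",
    "drop_initial_volumes",
    "detrend_bandpass",
]

#: Default repetition time in seconds for resting-state acquisitions.
DEFAULT_TR = 3.0


@dataclass(frozen=True)
class ROITimeSeries:
    """One subject's time x region signal matrix.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_timepoints, n_regions)``; row order is
        acquisition order.
    region_labels
        Unique region names, one per column (e.g. AAL short names such as
        ``"HES_L"``).
    sampling_interval
        Time between consecutive rows, in seconds (the TR).  Carried as
        metadata; never inferred from the data.
    """

    values: np.ndarray
    region_labels: tuple[str, ...]
    sampling_interval: float = DEFAULT_TR

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DataFormatError("values must be a 2-D time x region matrix")
        labels = tuple(str(x) for x in self.region_labels)
        if len(labels) != values.shape[1]:
            raise DataFormatError(
                f"{len(labels)} region labels for {values.shape[1]} columns"
            )
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise DataFormatError(f"duplicate region labels: {dupes}")
        if values.shape[1] < 2:
            raise DataFormatError("at least 2 regions are required")
        if values.shape[0] < 2:
            raise DataFormatError("at least 2 time points are required")
        if not np.all(np.isfinite(values)):
            t, r = np.argwhere(~np.isfinite(values))[0]
            raise DataFormatError(
                f"non-finite value at time point {t}, region {labels[r]!r}"
            )
        if not self.sampling_interval > 0:
            raise DataFormatError("sampling_interval must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_labels", labels)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in Hz implied by the sampling interval."""
        return 0.5 / self.sampling_interval


def read_roi_timeseries(
    path: str | Path,
    delimiter: str = ",",
    sampling_interval: float = DEFAULT_TR,
) -> ROITimeSeries:
    """Read a delimited-text series file (header of region names, numeric rows).

    The loader rejects rather than coerces: missing header, ragged rows,
    non-numeric or non-finite cells and duplicate labels each raise a
    :class:`~causalfc.errors.DataFormatError` naming the offending location.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if not rows:
        raise DataFormatError(f"{path}: empty file")
    header = [c.strip() for c in rows[0]]
    if all(_is_number(c) for c in header):
        raise DataFormatError(f"{path}: first row is numeric; header missing")
    if len(rows) < 2:
        raise DataFormatError(f"{path}: no data rows after header")
    ncol = len(header)
    data = np.empty((len(rows) - 1, ncol))
    for t, row in enumerate(rows[1:]):
        if len(row) != ncol:
            raise DataFormatError(
                f"{path}: row {t + 1} has {len(row)} cells, expected {ncol}"
            )
        for j, cell in enumerate(row):
            try:
                v = float(cell)
            except ValueError:
                raise DataFormatError(
                    f"{path}: non-numeric cell at row {t + 1}, "
                    f"column {header[j]!r}: {cell!r}"
                ) from None
            if not np.isfinite(v):
                raise DataFormatError(
                    f"{path}: non-finite cell at row {t + 1}, column {header[j]!r}"
                )
            data[t, j] = v
    return ROITimeSeries(data, tuple(header), sampling_interval)


def write_roi_timeseries(
    ts: ROITimeSeries, path: str | Path, delimiter: str = ","
) -> None:
    """Write a series to delimited text; round-trips through the reader."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(ts.region_labels)
        for row in ts.values:
            writer.writerow([repr(float(v)) for v in row])


def drop_initial_volumes(ts: ROITimeSeries, k: int = 4) -> ROITimeSeries:
    """Remove the first ``k`` time points (scanner-settling artifacts)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return ts
    if k >= ts.n_timepoints - 2:
        raise ValueError(
            f"cannot drop {k} of {ts.n_timepoints} time points; "
            "at least 3 must remain"
        )
    return replace(ts, values=ts.values[k:])


def detrend_bandpass(
    ts: ROITimeSeries,
    low_hz: float = 0.001,
    high_hz: float = 0.1,
    order: int = 4,
) -> ROITimeSeries:
    """Linear detrend then zero-phase Butterworth band-pass, per region.

    Each column is detrended (removing scanner drift) and filtered
    forward-backward (``filtfilt``) with a Butterworth filter of the given
    order, so no phase distortion is introduced.  ``low_hz = 0`` degrades
    gracefully to a low-pass filter.  Channels are never mixed.
    """
    nyq = ts.nyquist
    if not (0 <= low_hz < high_hz <= nyq):
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz for Nyquist {nyq:.4g} Hz"
        )
    fs = 1.0 / ts.sampling_interval
    x = signal.detrend(ts.values, axis=0, type="linear")
    if low_hz > 0:
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    else:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=0)
    return replace(ts, values=np.ascontiguousarray(y))


def _is_number(cell: str) -> bool:
    try:
        float(cell)
    except ValueError:
        return False
    return True


def stack_regions(ts: ROITimeSeries, labels: Sequence[str]) -> np.ndarray:
    """Return the columns for ``labels`` in the given order (helper)."""
    index = {lab: i for i, lab in enumerate(ts.region_labels)}
    try:
        cols = [index[lab] for lab in labels]
    except KeyError as exc:
        raise KeyError(f"unknown region label {exc.args[0]!r}") from None
    return ts.values[:, cols]
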