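"""Reading, writing and parcellating region-by-time signal matrices.

The pipeline's entry point is a parcellated matrix: one row per brain
region (by default 84 Brodmann areas), one column per imaging volume.
Matrices travel as delimited text with the region label in the first
column.  A convenience path averages a 4D volumetric series over an
integer label image (NIfTI-1 supported through nibabel); any upstream
preprocessing (realignment, normalisation, smoothing) is out of scope
and assumed done.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RegionTimeSeries",
    "read_timeseries",
    "write_timeseries",
    "parcellate",
    "parcellate_nifti",
]


@dataclass
class RegionTimeSeries:
    """A region x volume signal matrix with ordered region labels.

    Parameters
    ----------
    subject_id:
        Identifier carried through to per-subject outputs.
    signals:
        2D float array, shape ``(n_regions, n_volumes)``.  Must be finite.
    region_labels:
        One label per row, in row order.  Defaults to Brodmann-style
        integer ids ``1..n_regions``.
    """

    subject_id: str
    signals: np.ndarray
    region_labels: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError(
                f"signals must be 2D (regions x volumes), got ndim={self.signals.ndim}"
            )
        if self.region_labels is None:
            self.region_labels = list(range(1, self.signals.shape[0] + 1))
        self.region_labels = list(self.region_labels)
        if len(self.region_labels) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.region_labels)} region labels for "
                f"{self.signals.shape[0]} signal rows"
            )
        if not np.all(np.isfinite(self.signals)):
            bad = np.argwhere(~np.isfinite(self.signals))
            r, c = bad[0]
            raise ValueError(
                f"non-finite signal value at region row {r} "
                f"(label {self.region_labels[r]}), volume {c + 1}"
            )

    @property
    def n_regions(self) -> int:
        return self.signals.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.signals.shape[1]

    def zero_variance_regions(self) -> list:
        """Labels of constant-signal (zero-variance) regions."""
        sd = self.signals.std(axis=1)
        return [self.region_labels[i] for i in np.flatnonzero(sd == 0.0)]


def _sniff_delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_timeseries(
    path: str | Path,
    delimiter: str | None = None,
    subject_id: str | None = None,
) -> RegionTimeSeries:
    """Read a delimited region x volume matrix (regions as rows).

    The first column holds the region label; remaining columns are one
    signal value per volume.  Constant-signal regions load fine but are
    reported through a :class:`UserWarning` listing their labels (they
    also remain queryable via ``RegionTimeSeries.zero_variance_regions``).

    Raises
    ------
    ValueError
        On ragged rows, non-numeric cells, fewer than 2 regions or fewer
        than 2 volumes — each with a row/column diagnostic.
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    labels: list = []
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue  # blank line
            if rows and len(rec) != len(rows[0]) + 1:
                raise ValueError(
                    f"{path.name}: ragged row {lineno}: expected "
                    f"{len(rows[0]) + 1} fields, found {len(rec)}"
                )
            vals = []
            for col, cell in enumerate(rec[1:], start=2):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path.name}: non-numeric cell at row {lineno}, "
                        f"column {col}: {cell!r}"
                    ) from None
            label: object = rec[0]
            try:
                label = int(rec[0])
            except ValueError:
                pass
            labels.append(label)
            rows.append(vals)
    if len(rows) < 2:
        raise ValueError(f"{path.name}: need at least 2 regions, found {len(rows)}")
    if len(rows[0]) < 2:
        raise ValueError(
            f"{path.name}: need at least 2 volumes, found {len(rows[0])}"
        )
    ts = RegionTimeSeries(
        subject_id=subject_id or path.stem,
        signals=np.array(rows, dtype=float),
        region_labels=labels,
    )
    zv = ts.zero_variance_regions()
    if zv:
        warnings.warn(
            f"{path.name}: zero-variance (constant-signal) regions: {zv}",
            UserWarning,
            stacklevel=2,
        )
    return ts


def write_timeseries(ts: RegionTimeSeries, path: str | Path, delimiter: str | None = None) -> None:
    """Write the matrix as delimited text, region label first in each row."""
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim)
        for label, row in zip(ts.region_labels, ts.signals):
            w.writerow([label] + [repr(float(v)) for v in row])


def parcellate(
    volume_series: np.ndarray,
    labels: np.ndarray,
    subject_id: str = "parcellated",
) -> RegionTimeSeries:
    """Average a 4D signal array over an integer label volume.

    Produces one region row per nonzero label value (label 0 is
    background), ordered by ascending label.  Each volume's value for a
    region is the mean over all voxels carrying that label.  Labels
    present in the image but covering no voxels cannot occur; a label
    volume with *no* nonzero voxels is rejected.
    """
    volume_series = np.asarray(volume_series, dtype=float)
    labels = np.asarray(labels)
    if volume_series.ndim != 4:
        raise ValueError(f"volume_series must be 4D, got ndim={volume_series.ndim}")
    if labels.shape != volume_series.shape[:3]:
        raise ValueError(
            f"label shape {labels.shape} does not match spatial "
            f"dimensions {volume_series.shape[:3]}"
        )
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.all(labels == labels.astype(int)):
            raise ValueError("label volume must be integer-valued")
        labels = labels.astype(int)
    region_ids = np.unique(labels)
    region_ids = region_ids[region_ids != 0]
    if region_ids.size == 0:
        raise ValueError("no regions: label volume contains only background (0)")
    n_vol = volume_series.shape[3]
    flat = volume_series.reshape(-1, n_vol)
    flat_labels = labels.reshape(-1)
    out = np.empty((region_ids.size, n_vol), dtype=float)
    for i, rid in enumerate(region_ids):
        out[i] = flat[flat_labels == rid].mean(axis=0)
    return RegionTimeSeries(
        subject_id=subject_id,
        signals=out,
        region_labels=[int(r) for r in region_ids],
    )


def parcellate_nifti(
    series_path: str | Path,
    labels_path: str | Path,
    subject_id: str | None = None,
) -> RegionTimeSeries:
    """Load a 4D NIfTI series and a 3D integer label NIfTI, then parcellate.

    The label image must already be in the signal image's voxel space;
    no resampling is performed.
    """
    import nibabel as nib

    series = np.asanyarray(nib.load(str(series_path)).dataobj)
    labels = np.asanyarray(nib.load(str(labels_path)).dataobj)
    return parcellate(
        series, labels, subject_id=subject_id or Path(series_path).stem
    )
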