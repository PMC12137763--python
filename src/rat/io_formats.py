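"""Reading and writing the imaging and tabular formats the pipeline touches.

Volumes, maps and masks travel as NIfTI-1 (via nibabel); normative tables
and summaries as CSV (via pandas). Echo times are not stored in NIfTI
headers — NIfTI has no standard multi-echo timing field — so they are
supplied alongside the file (CLI flag or YAML config) and attached to the
in-memory :class:`MultiEchoVolume`.

Masks align to their companion volume by voxel index: the maps and masks
of one exam share a single acquisition grid and are never resampled.
Magnitude data is assumed throughout; negative intensities (interpolation
artifacts) are clamped to zero on read and the count is logged — clamped
samples fall below the fitter's signal floor and are excluded there, so
clamping never silently changes which voxels contribute downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyInputError, FormatError, MetadataError, SchemaError

logger = logging.getLogger(__name__)

#: Organ labels the pipeline quantifies.
ORGANS = ("fetal_brain", "placenta")

#: Measures for which normative curves are built.
MEASURES = ("mean_t2star", "volume")

#: Mask provenance labels.
MASK_SOURCES = ("manual", "automatic", "phantom_truth")

#: Echo-time schedule (ms) of the whole-uterus multi-echo gradient-echo
#: protocol this pipeline was designed around.
DEFAULT_ECHO_TIMES = (57.0, 152.0, 248.0, 344.0)

#: In-plane / through-plane voxel size (mm) of the same protocol.
DEFAULT_VOXEL_DIMS = (3.125, 3.125, 3.0)

#: Gestational-age validity range (weeks) for normative-table records.
GA_VALID_RANGE = (12.0, 45.0)


@dataclass
class MultiEchoVolume:
    """A 4D multi-echo magnitude volume with its acquisition metadata.

    Parameters
    ----------
    signal
        4D non-negative magnitude grid, axes (x, y, z, echo), arbitrary
        scanner units.
    echo_times
        Echo times in ms, one per entry of the 4th axis, strictly
        increasing and positive.
    voxel_dims
        Voxel edge lengths in mm (three positive floats).
    affine
        4x4 voxel-to-world transform, passed through unchanged to outputs.
    ga_weeks
        Optional gestational age at scan in decimal weeks.
    n_clamped
        Number of negative input samples clamped to zero on read.
    """

    signal: np.ndarray
    echo_times: np.ndarray
    voxel_dims: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    ga_weeks: Optional[float] = None
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.echo_times = np.asarray(self.echo_times, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.signal.ndim != 4:
            raise FormatError(f"signal must be 4D (x, y, z, echo); got {self.signal.ndim}D")
        if self.echo_times.ndim != 1 or self.signal.shape[3] != self.echo_times.size:
            raise MetadataError(
                f"echo count mismatch: signal has {self.signal.shape[3]} echoes, "
                f"echo_times has {self.echo_times.size}"
            )
        if np.any(self.echo_times <= 0) or np.any(np.diff(self.echo_times) <= 0):
            raise MetadataError("echo_times must be positive and strictly increasing")
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise MetadataError(f"voxel_dims must be three positive lengths; got {self.voxel_dims}")
        if not np.all(np.isfinite(self.signal)):
            raise FormatError("signal contains non-finite values")
        if np.any(self.signal < 0):
            raise FormatError("signal contains negative values (magnitude data expected)")
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)

    @property
    def n_echoes(self) -> int:
        return int(self.signal.shape[3])

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.signal.shape[:3])

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_dims))

    def echo(self, index: int) -> np.ndarray:
        """Return the 3D image of one echo."""
        return self.signal[..., index]


@dataclass
class OrganMask:
    """A binary organ mask on the same voxel grid as its companion volume."""

    grid: np.ndarray
    organ: str
    source: str

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise FormatError(f"mask must be 3D; got {self.grid.ndim}D")
        if self.organ not in ORGANS:
            raise MetadataError(f"unknown organ {self.organ!r}; expected one of {ORGANS}")
        if self.source not in MASK_SOURCES:
            raise MetadataError(f"unknown mask source {self.source!r}; expected one of {MASK_SOURCES}")
        uniq = np.unique(self.grid)
        if not np.all(np.isin(uniq, (0, 1))):
            raise FormatError("mask values must be exactly 0 or 1")
        self.grid = self.grid.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


def read_multi_echo(
    path: str | Path,
    echo_times: Sequence[float],
    ga_weeks: Optional[float] = None,
) -> MultiEchoVolume:
    """Load a 4D multi-echo NIfTI volume and attach its echo-time schedule.

    Negative intensities are clamped to zero (with a logged count); voxel
    dimensions and the affine come from the file header.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D multi-echo NIfTI, got {data.ndim}D")
    echo_times = np.asarray(echo_times, dtype=np.float64)
    if data.shape[3] != echo_times.size:
        raise MetadataError(
            f"{path}: file has {data.shape[3]} echoes but {echo_times.size} echo times were given"
        )
    n_clamped = int(np.count_nonzero(data < 0))
    if n_clamped:
        logger.info("read_multi_echo: clamped %d negative samples to 0 in %s", n_clamped, path)
        data = np.clip(data, 0.0, None)
    voxel_dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MultiEchoVolume(
        signal=data,
        echo_times=echo_times,
        voxel_dims=voxel_dims,
        affine=np.asarray(img.affine),
        ga_weeks=ga_weeks,
        n_clamped=n_clamped,
    )


def write_multi_echo(volume: MultiEchoVolume, path: str | Path) -> None:
    """Write a multi-echo volume as 4D NIfTI (echo times are NOT stored)."""
    img = nib.Nifti1Image(volume.signal.astype(np.float64), volume.affine)
    img.header.set_zooms(tuple(volume.voxel_dims) + (1.0,))
    nib.save(img, str(path))


def read_mask(
    path: str | Path,
    reference: MultiEchoVolume,
    organ: str,
    source: str = "automatic",
) -> OrganMask:
    """Load a 3D NIfTI mask aligned voxel-for-voxel with ``reference``.

    Values are binarized at 0.5. An empty mask warns but does not raise;
    downstream operations decide how to treat it.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask, got {data.ndim}D")
    if tuple(data.shape) != reference.spatial_shape:
        raise AlignmentError(
            f"{path}: mask shape {tuple(data.shape)} does not match volume "
            f"spatial shape {reference.spatial_shape}"
        )
    grid = (data > 0.5).astype(np.uint8)
    if not grid.any():
        warnings.warn(f"{path}: mask is empty ({organ})", stacklevel=2)
    return OrganMask(grid=grid, organ=organ, source=source)


def write_mask(mask: OrganMask, path: str | Path, affine: Optional[np.ndarray] = None) -> None:
    """Write a binary mask as uint8 NIfTI."""
    aff = np.eye(4) if affine is None else np.asarray(affine)
    nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), aff), str(path))


def write_map(grid: np.ndarray, path: str | Path, affine: Optional[np.ndarray] = None) -> None:
    """Write a 3D scalar map (e.g. T2*, S0, R2) as NIfTI."""
    aff = np.eye(4) if affine is None else np.asarray(affine)
    nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float64), aff), str(path))


NORMATIVE_COLUMNS = ("ga_weeks", "organ", "measure", "value")


def read_normative_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a normative control table.

    The CSV must have columns ``ga_weeks, organ, measure, value``. Rows with
    gestational age outside [12, 45] weeks or a non-finite / non-positive
    value are rejected, with their (0-based data) row numbers reported in a
    warning. Raises :class:`EmptyInputError` if no valid rows remain.
    """
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty normative table") from exc
    missing = [c for c in NORMATIVE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    ga = pd.to_numeric(table["ga_weeks"], errors="coerce")
    value = pd.to_numeric(table["value"], errors="coerce")
    lo, hi = GA_VALID_RANGE
    ok = ga.between(lo, hi) & np.isfinite(value) & (value > 0)
    bad = table.index[~ok].tolist()
    if bad:
        warnings.warn(f"{path}: rejected {len(bad)} invalid rows (row numbers {bad})", stacklevel=2)
    table = table.loc[ok, list(NORMATIVE_COLUMNS)].copy()
    table["ga_weeks"] = ga[ok]
    table["value"] = value[ok]
    if table.empty:
        raise EmptyInputError(f"{path}: no valid normative records")
    return table.reset_index(drop=True)


def write_normative_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a normative table CSV with the canonical column order."""
    table.loc[:, list(NORMATIVE_COLUMNS)].to_csv(path, index=False)
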