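"""Organ-level quantification: threshold-filtered mean T2* and volume.

The organ mean is taken over voxels that (a) lie in the mask, (b) have a
valid fit, and (c) have T2* at or below an organ-specific upper-limit
threshold — 500 ms for the placenta, 900 ms for the fetal brain — which
screens out partial-volume voxels dominated by long-T2* fluid. The
threshold comparison is inclusive. Organ volume is pure mask geometry:
mask voxel count times voxel volume, independent of the fit. All voxel
accounting (used / over-threshold / invalid-fit) is reported.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .fitting import T2StarMap
from .io_formats import OrganMask

logger = logging.getLogger(__name__)

#: Upper-limit T2* thresholds (ms) for the organ mean.
DEFAULT_THRESHOLDS = {"placenta": 500.0, "fetal_brain": 900.0}


@dataclass
class OrganSummary:
    """Per-organ quantification at one gestational age.

    ``mean_t2star`` is NaN when no usable voxel remains. Always:
    ``n_voxels_used + n_voxels_over_threshold + n_voxels_invalid_fit ==
    n_voxels_mask`` and ``volume_mm3 == n_voxels_mask * voxel volume``.
    """

    organ: str
    ga_weeks: Optional[float]
    mean_t2star: float
    volume_mm3: float
    n_voxels_mask: int
    n_voxels_used: int
    n_voxels_over_threshold: int
    n_voxels_invalid_fit: int
    threshold_ms: float

    def as_row(self) -> dict:
        return asdict(self)


def summarize_organ(
    t2map: T2StarMap,
    mask: OrganMask,
    voxel_dims: Sequence[float],
    ga_weeks: Optional[float] = None,
    threshold_ms: Optional[float] = None,
) -> OrganSummary:
    """Quantify one organ from a fitted map and its mask.

    ``threshold_ms`` defaults per organ (500 ms placenta, 900 ms fetal
    brain). Zero usable voxels yields a NaN mean and a warning, not an
    exception.
    """
    if tuple(mask.grid.shape) != tuple(t2map.t2star.shape):
        raise AlignmentError(
            f"mask shape {mask.grid.shape} does not match map shape {t2map.t2star.shape}"
        )
    if threshold_ms is None:
        threshold_ms = DEFAULT_THRESHOLDS[mask.organ]
    if threshold_ms <= 0:
        raise ValueError("threshold_ms must be positive")

    in_mask = mask.grid
    n_mask = int(in_mask.sum())
    valid = t2map.valid & in_mask
    n_invalid = int(n_mask - valid.sum())
    t2 = t2map.t2star[valid]
    keep = t2 <= threshold_ms  # inclusive upper limit
    n_used = int(keep.sum())
    n_over = int((~keep).sum())

    if n_used:
        mean_t2 = float(t2[keep].mean())
    else:
        mean_t2 = math.nan
        warnings.warn(f"summarize_organ: no usable voxels for {mask.organ}", stacklevel=2)

    voxel_volume = float(np.prod(np.asarray(voxel_dims, dtype=np.float64)))
    return OrganSummary(
        organ=mask.organ,
        ga_weeks=ga_weeks,
        mean_t2star=mean_t2,
        volume_mm3=n_mask * voxel_volume,
        n_voxels_mask=n_mask,
        n_voxels_used=n_used,
        n_voxels_over_threshold=n_over,
        n_voxels_invalid_fit=n_invalid,
        threshold_ms=float(threshold_ms),
    )


def summarize_exam(
    t2map: T2StarMap,
    masks: Mapping[str, OrganMask],
    voxel_dims: Sequence[float],
    ga_weeks: Optional[float] = None,
    thresholds: Optional[Mapping[str, float]] = None,
) -> list[OrganSummary]:
    """Quantify every available organ of one exam.

    Organs with no mask (or an empty one) are skipped with a log entry.
    """
    thresholds = dict(thresholds or {})
    summaries = []
    for organ in DEFAULT_THRESHOLDS:
        mask = masks.get(organ)
        if mask is None or mask.n_voxels == 0:
            logger.info("summarize_exam: organ %s missing or empty, skipped", organ)
            continue
        summaries.append(
            summarize_organ(
                t2map, mask, voxel_dims, ga_weeks=ga_weeks,
                threshold_ms=thresholds.get(organ),
            )
        )
    return summaries


SUMMARY_COLUMNS = (
    "organ", "ga_weeks", "mean_t2star", "volume_mm3", "n_voxels_mask",
    "n_voxels_used", "n_voxels_over_threshold", "n_voxels_invalid_fit", "threshold_ms",
)


def write_summaries(summaries: Sequence[OrganSummary], path: str | Path,
                    append: bool = False) -> None:
    """Write (or append) organ summaries to a CSV file."""
    df = pd.DataFrame([s.as_row() for s in summaries], columns=list(SUMMARY_COLUMNS))
    path = Path(path)
    header = not (append and path.exists())
    df.to_csv(path, mode="a" if append else "w", header=header, index=False)
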