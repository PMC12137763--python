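"""Robustness battery: Bland-Altman agreement, Dice overlap, and
repeat-acquisition consistency.

Bland-Altman differences are oriented first-listed minus second-listed
(the orientation is recorded in the labels); limits of agreement use the
standard ±1.96 × SD with the sample (n−1) standard deviation. Dice of two
empty masks is defined as 1.0 (perfect agreement about absence), and 0.0
when exactly one is empty.

Repeat consistency mirrors how intra-scan repeats are reported: all
pairwise mean-T2* differences, the centile band of each repeat against a
normative model, and a stability flag that is true only when every
repeat lands in the same band.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError, InsufficientDataError
from .io_formats import OrganMask
from .normative import NormativeModel, classify
from .quantify import OrganSummary


@dataclass
class AgreementStats:
    """Bland-Altman summary of paired measurements (a − b)."""

    n_pairs: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    label_a: str = "a"
    label_b: str = "b"


def bland_altman(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
) -> AgreementStats:
    """Bland-Altman agreement between two paired measurement series."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise InsufficientDataError(
            f"paired series must be 1D and equal length; got {a.shape} vs {b.shape}"
        )
    if a.size < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return AgreementStats(
        n_pairs=int(a.size),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        label_a=label_a,
        label_b=label_b,
    )


def bland_altman_plot(a, b, stats: Optional[AgreementStats] = None,
                      path: str | Path = "bland_altman.png", title: str = ""):
    """Mean-vs-difference scatter with limits-of-agreement lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    stats = stats or bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2, a - b, s=18)
    for y, style in ((stats.mean_diff, "-"), (stats.loa_low, "--"), (stats.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel(f"{stats.label_a} − {stats.label_b}")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def dice(mask_a: OrganMask | np.ndarray, mask_b: OrganMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two aligned binary masks.

    Both empty -> 1.0; exactly one empty -> 0.0.
    """
    a = mask_a.grid if isinstance(mask_a, OrganMask) else np.asarray(mask_a).astype(bool)
    b = mask_b.grid if isinstance(mask_b, OrganMask) else np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise AlignmentError(f"mask shapes differ: {a.shape} vs {b.shape}")
    size_a = int(a.sum())
    size_b = int(b.sum())
    if size_a == 0 and size_b == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (size_a + size_b)


@dataclass
class RepeatReport:
    """Consistency of k intra-scan repeats for one organ."""

    organ: str
    n_repeats: int
    pairwise_diffs: list[tuple[int, int, float]]  # (repeat_i, repeat_j, mean T2* diff, ms)
    bands: list[str]
    stable: bool


def repeat_consistency(
    summaries: Sequence[OrganSummary],
    models: dict[tuple[str, str], NormativeModel],
) -> RepeatReport:
    """Assess stability across repeated acquisitions of one organ.

    Emits all k·(k−1)/2 pairwise mean-T2* differences (earlier repeat
    minus later), each repeat's centile band for mean T2*, and a
    stability flag true iff all repeats share one band.
    """
    if len(summaries) < 2:
        raise InsufficientDataError("repeat consistency needs >= 2 repeats")
    organs = {s.organ for s in summaries}
    if len(organs) != 1:
        raise InsufficientDataError(f"summaries must be one organ; got {sorted(organs)}")
    organ = summaries[0].organ

    diffs = [
        (i, j, summaries[i].mean_t2star - summaries[j].mean_t2star)
        for i, j in combinations(range(len(summaries)), 2)
    ]
    model = models.get((organ, "mean_t2star"))
    if model is None:
        raise InsufficientDataError(f"no normative mean_t2star model for {organ}")
    bands = [classify(model, s.ga_weeks, s.mean_t2star).band for s in summaries]
    return RepeatReport(
        organ=organ,
        n_repeats=len(summaries),
        pairwise_diffs=diffs,
        bands=bands,
        stable=len(set(bands)) == 1,
    )
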