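"""Pluggable organ-mask provision.

Real exams are segmented by an external model (e.g. a trained nnU-Net)
outside this package; its masks enter through :func:`load_external_mask`
or the command-template hook. For synthetic phantoms a deterministic
intensity-plus-geometry segmenter recovers the generating regions from
the second-echo image — the echo conventionally used as segmentation
input in this protocol — so the rest of the pipeline can be exercised
end to end without any trained weights.
"""

from __future__ import annotations

import logging
import subprocess
import warnings
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import RatError
from .io_formats import MultiEchoVolume, OrganMask, read_mask
from .phantom import PhantomSpec

logger = logging.getLogger(__name__)

#: Second echo: the default segmentation input.
DEFAULT_SEGMENTATION_ECHO = 1


def select_segmentation_echo(
    volume: MultiEchoVolume, echo_index: int = DEFAULT_SEGMENTATION_ECHO
) -> np.ndarray:
    """Return the single-echo 3D image used as segmentation input."""
    if not 0 <= echo_index < volume.n_echoes:
        raise RatError(
            f"echo_index {echo_index} out of range for a {volume.n_echoes}-echo volume"
        )
    return volume.echo(echo_index)


def segment_phantom(
    volume: MultiEchoVolume,
    truth_geometry: PhantomSpec,
    noise_tolerance: float = 0.5,
    echo_index: int = DEFAULT_SEGMENTATION_ECHO,
) -> dict[str, OrganMask]:
    """Deterministic reference segmenter for phantom volumes.

    Thresholds the second-echo image midway (by ``noise_tolerance``)
    between the expected background and dimmest-organ intensities
    computed from the generating spec, labels connected components, and
    assigns each organ the component containing its generating center.
    On a noiseless phantom this reproduces the truth masks exactly.
    """
    img = select_segmentation_echo(volume, echo_index)
    te = float(volume.echo_times[echo_index])

    bg = truth_geometry.background_s0 * np.exp(-te / truth_geometry.background_t2star)
    organ_sig = {
        organ: truth_geometry.true_s0.get(organ, 1000.0)
        * np.exp(-te / truth_geometry.true_t2star[organ])
        for organ in truth_geometry.organ_geometries
    }
    threshold = bg + noise_tolerance * (min(organ_sig.values()) - bg)

    labels, _ = ndimage.label(img > threshold)
    masks = {}
    for organ, geom in truth_geometry.organ_geometries.items():
        center = tuple(int(round(c)) for c in geom.center)
        lab = labels[center]
        grid = (labels == lab) if lab else np.zeros(img.shape, dtype=bool)
        if not grid.any():
            warnings.warn(f"segment_phantom: empty mask for {organ}", stacklevel=2)
            logger.info("segment_phantom: empty mask for %s", organ)
        masks[organ] = OrganMask(grid=grid.astype(np.uint8), organ=organ, source="automatic")
    return masks


def load_external_mask(
    path: str | Path,
    reference: MultiEchoVolume,
    organ: str,
    source: str = "automatic",
) -> OrganMask:
    """Load a mask produced by an external segmenter (manual or automatic)."""
    return read_mask(path, reference, organ, source=source)


def run_external_segmenter(
    command_template: str,
    echo_image_path: str | Path,
    out_mask_path: str | Path,
) -> None:
    """Invoke any external segmenter via a shell command template.

    The template's ``{input}`` / ``{output}`` placeholders receive the
    echo-image and mask paths; the command must write a NIfTI mask.
    """
    cmd = command_template.format(input=str(echo_image_path), output=str(out_mask_path))
    subprocess.run(cmd, shell=True, check=True)
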