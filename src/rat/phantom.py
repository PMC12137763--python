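"""Synthetic uterine phantom and control-cohort generator.

The phantom emulates a whole-uterus multi-echo gradient-echo acquisition:
a 3D grid at the protocol's voxel size containing an ellipsoidal fetal
brain and an oblate-ellipsoidal placenta embedded in short-T2*, low-S0
background tissue. Per voxel v and echo e the magnitude signal is

    S(v, e) = S0(v) * exp(-TE_e / T2*(v)) + noise

with additive Gaussian noise by default (magnitude-bias-free, so the
fitter's no-noise-floor default is unbiased in tests) or Rician noise on
request. Organ T2* defaults follow gestational-age trends: a linear
decline for the placenta and a quadratic trend for the fetal brain, both
decreasing across the modelled GA span, with values placed in ranges
plausible for low-field (0.55 T) imaging and well below the 500/900 ms
screening thresholds. They are test constants, not physiological claims.

Confounder modes reproduce the two failure cases a real-time pipeline
must flag: a *contraction* (fractional T2* depression of a placental
sub-region, emulating transient contractile activity) and *motion*
(per-echo rigid shift of the fetal brain).

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import PhantomSpecError
from .io_formats import (
    DEFAULT_ECHO_TIMES,
    DEFAULT_VOXEL_DIMS,
    MEASURES,
    ORGANS,
    MultiEchoVolume,
    OrganMask,
)

#: Generating GA trends for the synthetic control cohort, ascending
#: polynomial coefficients in (measure units) per weeks^k. Mean T2* (ms)
#: declines with gestation for both organs; volumes (mm^3) grow. The
#: volume trends pass near the default phantom geometry's discrete organ
#: volumes at the default GA so a default phantom reads as "normal"
#: against a default cohort.
DEFAULT_TREND_COEFFS: dict[tuple[str, str], tuple[float, ...]] = {
    ("placenta", "mean_t2star"): (337.0, -4.0),
    ("fetal_brain", "mean_t2star"): (280.0, 6.5, -0.19),
    ("placenta", "volume"): (-1100.0, 3800.0),
    ("fetal_brain", "volume"): (-13150.0, 1400.0),
}

#: Residual SDs of the synthetic cohort around its generating trends.
DEFAULT_NOISE_SD: dict[tuple[str, str], float] = {
    ("placenta", "mean_t2star"): 12.0,
    ("fetal_brain", "mean_t2star"): 15.0,
    ("placenta", "volume"): 8000.0,
    ("fetal_brain", "volume"): 2500.0,
}

DEFAULT_GA_RANGE = (20.0, 40.0)


def trend_value(organ: str, measure: str, ga_weeks: float,
                coeffs: Optional[Mapping[tuple[str, str], Sequence[float]]] = None) -> float:
    """Evaluate a generating trend polynomial at a gestational age."""
    coeffs = coeffs or DEFAULT_TREND_COEFFS
    c = np.asarray(coeffs[(organ, measure)], dtype=np.float64)
    return float(np.polynomial.polynomial.polyval(ga_weeks, c))


@dataclass
class OrganGeometry:
    """Ellipsoid placement: center voxel and semi-axes in voxel units."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def indicator(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(grid_shape, dtype=np.float64)
        q = sum(((idx[a] - self.center[a]) / self.semi_axes[a]) ** 2 for a in range(3))
        return q <= 1.0


@dataclass
class ContractionSpec:
    """Fractional T2* depression of part of the placenta.

    ``depression`` is the fractional reduction (0.3 -> affected voxels at
    70% of their nominal T2*); ``region_fraction`` the fraction of
    placental voxels affected (the first floor(f*n) in C order, so a
    0.5 fraction on an even-count region is exactly half).
    """

    depression: float
    region_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.depression < 1):
            raise PhantomSpecError("contraction depression must be in (0, 1)")
        if not (0 < self.region_fraction <= 1):
            raise PhantomSpecError("contraction region_fraction must be in (0, 1]")


@dataclass
class MotionSpec:
    """Per-echo rigid shift of the fetal brain, in integer voxels."""

    shifts: tuple[tuple[int, int, int], ...]


# Default geometry: brain and placenta ellipsoids separated along x with
# a clear gap, both fully inside the default 64x64x48 grid.
def _default_geometries() -> dict[str, OrganGeometry]:
    return {
        "fetal_brain": OrganGeometry(center=(20.0, 32.0, 24.0), semi_axes=(8.0, 7.0, 6.0)),
        "placenta": OrganGeometry(center=(44.0, 32.0, 24.0), semi_axes=(14.0, 12.0, 7.0)),
    }


@dataclass
class PhantomSpec:
    """Full description of one synthetic acquisition."""

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_dims: tuple[float, float, float] = DEFAULT_VOXEL_DIMS
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES
    ga_weeks: float = 38.0
    organ_geometries: dict[str, OrganGeometry] = field(default_factory=_default_geometries)
    true_t2star: Optional[dict[str, float]] = None  # per organ, ms; None -> GA trend
    true_s0: dict[str, float] = field(
        default_factory=lambda: {"fetal_brain": 1000.0, "placenta": 1000.0}
    )
    background_t2star: float = 60.0
    background_s0: float = 250.0
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"  # or "rician"
    contraction: Optional[ContractionSpec] = None
    motion: Optional[MotionSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_t2star is None:
            self.true_t2star = {
                organ: trend_value(organ, "mean_t2star", self.ga_weeks) for organ in ORGANS
            }
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise PhantomSpecError(f"unknown noise model {self.noise_model!r}")
        for organ, t2 in self.true_t2star.items():
            if t2 <= 0:
                raise PhantomSpecError(f"true T2* for {organ} must be positive")
        if self.background_t2star <= 0:
            raise PhantomSpecError("background T2* must be positive")

    def organ_indicators(self) -> dict[str, np.ndarray]:
        """Boolean region per organ; raises if regions overlap or leave the grid."""
        regions = {}
        for organ, geom in self.organ_geometries.items():
            for a in range(3):
                if geom.center[a] - geom.semi_axes[a] < 0 or \
                        geom.center[a] + geom.semi_axes[a] > self.grid_shape[a] - 1:
                    raise PhantomSpecError(f"{organ} ellipsoid extends outside the grid")
            regions[organ] = geom.indicator(self.grid_shape)
        organs = list(regions)
        for i, a in enumerate(organs):
            for b in organs[i + 1:]:
                if np.any(regions[a] & regions[b]):
                    raise PhantomSpecError(f"organ regions {a} and {b} overlap")
        return regions


def _derive_seed(base: int, *parts: int) -> int:
    """Stable sub-seed derivation, kept below 2**31."""
    h = hashlib.sha256(("/".join(str(p) for p in (base, *parts))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[MultiEchoVolume, dict[str, OrganMask], np.ndarray]:
    """Generate one synthetic multi-echo acquisition.

    Returns the volume, the exact generating masks per organ
    (``source="phantom_truth"``), and the true T2* map (ms; contraction
    depression, when configured, is part of the truth).
    """
    regions = spec.organ_indicators()

    t2_map = np.full(spec.grid_shape, spec.background_t2star, dtype=np.float64)
    s0_map = np.full(spec.grid_shape, spec.background_s0, dtype=np.float64)
    for organ, region in regions.items():
        t2_map[region] = spec.true_t2star[organ]
        s0_map[region] = spec.true_s0.get(organ, 1000.0)

    if spec.contraction is not None:
        pl = regions["placenta"]
        idx = np.flatnonzero(pl.ravel())
        n_aff = int(np.floor(spec.contraction.region_fraction * idx.size))
        affected = np.zeros(t2_map.size, dtype=bool)
        affected[idx[:n_aff]] = True
        affected = affected.reshape(spec.grid_shape)
        t2_map[affected] *= 1.0 - spec.contraction.depression

    te = np.asarray(spec.echo_times, dtype=np.float64)
    shape4 = spec.grid_shape + (te.size,)
    signal = np.empty(shape4, dtype=np.float64)

    brain = regions.get("fetal_brain")
    for e, te_e in enumerate(te):
        t2_e, s0_e = t2_map, s0_map
        if spec.motion is not None and brain is not None:
            shift = spec.motion.shifts[e % len(spec.motion.shifts)]
            if any(shift):
                # brain voxels displaced rigidly for this echo; vacated
                # voxels revert to background
                t2_e = t2_map.copy()
                s0_e = s0_map.copy()
                t2_e[brain] = spec.background_t2star
                s0_e[brain] = spec.background_s0
                moved = np.roll(brain, shift, axis=(0, 1, 2))
                t2_e[moved] = spec.true_t2star["fetal_brain"]
                s0_e[moved] = spec.true_s0.get("fetal_brain", 1000.0)
        signal[..., e] = s0_e * np.exp(-te_e / t2_e)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "gaussian":
            signal = signal + rng.normal(0.0, spec.noise_sigma, size=shape4)
        else:
            re = signal + rng.normal(0.0, spec.noise_sigma, size=shape4)
            im = rng.normal(0.0, spec.noise_sigma, size=shape4)
            signal = np.hypot(re, im)
    signal = np.clip(signal, 0.0, None)

    volume = MultiEchoVolume(
        signal=signal,
        echo_times=te,
        voxel_dims=spec.voxel_dims,
        ga_weeks=spec.ga_weeks,
    )
    masks = {
        organ: OrganMask(grid=region.astype(np.uint8), organ=organ, source="phantom_truth")
        for organ, region in regions.items()
    }
    return volume, masks, t2_map


def first_echo_snr_sigma(spec: PhantomSpec, organ: str = "placenta") -> float:
    """Noise sigma giving a target-organ first-echo SNR of 1 (multiply by 1/SNR)."""
    te0 = spec.echo_times[0]
    return spec.true_s0.get(organ, 1000.0) * float(np.exp(-te0 / spec.true_t2star[organ]))


def spec_with_snr(spec: PhantomSpec, snr: float, organ: str = "placenta") -> PhantomSpec:
    """Copy of ``spec`` with noise_sigma set for a first-echo SNR in ``organ``."""
    from dataclasses import replace

    return replace(spec, noise_sigma=first_echo_snr_sigma(spec, organ) / snr)


def generate_control_cohort(
    n: int = 88,
    ga_range: tuple[float, float] = DEFAULT_GA_RANGE,
    trend_coeffs: Optional[Mapping[tuple[str, str], Sequence[float]]] = None,
    noise_sd: Optional[Mapping[tuple[str, str], float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a normative control cohort table.

    Each of ``n`` cases draws one GA ~ Uniform(ga_range) and one value per
    (organ, measure) from value = trend(GA) + N(0, sd). The mean-T2*
    generating trends must be decreasing across ``ga_range`` (both organs
    lose T2* over gestation); violating coefficients raise.

    Returns a DataFrame with columns ``ga_weeks, organ, measure, value``.
    """
    if n < 10:
        raise PhantomSpecError("cohort size must be >= 10")
    trend_coeffs = dict(trend_coeffs or DEFAULT_TREND_COEFFS)
    noise_sd = dict(noise_sd or DEFAULT_NOISE_SD)

    ga_grid = np.linspace(ga_range[0], ga_range[1], 64)
    for organ in ORGANS:
        c = np.asarray(trend_coeffs[(organ, "mean_t2star")], dtype=np.float64)
        vals = np.polynomial.polynomial.polyval(ga_grid, c)
        if not np.all(np.diff(vals) < 0):
            raise PhantomSpecError(
                f"mean T2* generating trend for {organ} must decrease over GA range {ga_range}"
            )

    rng = np.random.default_rng(seed)
    ga = rng.uniform(ga_range[0], ga_range[1], size=n)
    rows = []
    for organ in ORGANS:
        for measure in MEASURES:
            c = np.asarray(trend_coeffs[(organ, measure)], dtype=np.float64)
            mean = np.polynomial.polynomial.polyval(ga, c)
            sd = float(noise_sd[(organ, measure)])
            values = mean + (rng.normal(0.0, sd, size=n) if sd > 0 else 0.0)
            for g, v in zip(ga, values):
                rows.append({"ga_weeks": float(g), "organ": organ, "measure": measure,
                             "value": float(v)})
    return pd.DataFrame(rows, columns=["ga_weeks", "organ", "measure", "value"])


def generate_repeat_series(
    spec: PhantomSpec,
    k: int = 3,
    perturbations: Optional[Mapping[int, Mapping[str, object]]] = None,
) -> list[tuple[MultiEchoVolume, dict[str, OrganMask], np.ndarray]]:
    """Generate ``k`` intra-scan repeat acquisitions of one subject.

    Repeats share geometry and truth and differ only in their noise
    realization (sub-seeds derived deterministically from ``spec.seed``)
    plus any per-repeat perturbation: ``perturbations[r]`` may carry
    ``"contraction"`` (:class:`ContractionSpec`) and/or ``"motion"``
    (:class:`MotionSpec`) for repeat index ``r`` (0-based).
    """
    from dataclasses import replace

    if k < 2:
        raise PhantomSpecError("a repeat series needs k >= 2")
    perturbations = perturbations or {}
    out = []
    for r in range(k):
        pert = perturbations.get(r, {})
        rep_spec = replace(
            spec,
            seed=_derive_seed(spec.seed, r),
            contraction=pert.get("contraction", None),
            motion=pert.get("motion", None),
        )
        out.append(generate_phantom(rep_spec))
    return out
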