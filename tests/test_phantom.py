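"""Synthetic phantom and cohort generator: determinism, round trips,
and confounder modes."""

from dataclasses import replace

import numpy as np
import pytest

from rat.errors import PhantomSpecError
from rat.fitting import FitOptions, fit_volume
from rat.metrics import repeat_consistency
from rat.normative import build_normative_models
from rat.phantom import (
    ContractionSpec,
    MotionSpec,
    OrganGeometry,
    PhantomSpec,
    generate_control_cohort,
    generate_phantom,
    generate_repeat_series,
    spec_with_snr,
)
from rat.quantify import summarize_exam, summarize_organ

from conftest import small_spec


def test_seed_determinism():
    spec = spec_with_snr(small_spec(seed=5), 20.0)
    vol_a, masks_a, map_a = generate_phantom(spec)
    vol_b, masks_b, map_b = generate_phantom(spec)
    assert np.array_equal(vol_a.signal, vol_b.signal)
    assert np.array_equal(map_a, map_b)
    for organ in masks_a:
        assert np.array_equal(masks_a[organ].grid, masks_b[organ].grid)
    vol_c, _, _ = generate_phantom(replace(spec, seed=6))
    assert not np.array_equal(vol_a.signal, vol_c.signal)


def test_noiseless_generate_fit_summarize_roundtrip(noiseless_small_phantom):
    spec, volume, masks, true_map = noiseless_small_phantom
    t2map = fit_volume(volume, FitOptions())
    for organ, mask in masks.items():
        assert np.abs(t2map.t2star[mask.grid] - true_map[mask.grid]).max() < 1e-6
        s = summarize_organ(t2map, mask, volume.voxel_dims, ga_weeks=spec.ga_weeks)
        assert s.mean_t2star == pytest.approx(spec.true_t2star[organ], abs=1e-6)
        assert s.volume_mm3 == mask.n_voxels * volume.voxel_volume_mm3


def test_overlapping_organs_rejected():
    spec = small_spec(organ_geometries={
        "fetal_brain": OrganGeometry(center=(14.0, 16.0, 12.0), semi_axes=(5.0, 5.0, 5.0)),
        "placenta": OrganGeometry(center=(18.0, 16.0, 12.0), semi_axes=(6.0, 6.0, 5.0)),
    })
    with pytest.raises(PhantomSpecError, match="overlap"):
        generate_phantom(spec)


def test_organ_outside_grid_rejected():
    spec = small_spec(organ_geometries={
        "fetal_brain": OrganGeometry(center=(2.0, 16.0, 12.0), semi_axes=(5.0, 4.0, 3.0)),
        "placenta": OrganGeometry(center=(22.0, 16.0, 12.0), semi_axes=(7.0, 6.0, 3.5)),
    })
    with pytest.raises(PhantomSpecError, match="outside"):
        generate_phantom(spec)


def test_contraction_depresses_half_the_placenta():
    spec = small_spec(contraction=ContractionSpec(depression=0.3, region_fraction=0.5))
    volume, masks, true_map = generate_phantom(spec)
    pl = masks["placenta"].grid
    n = int(pl.sum())
    n_affected = n // 2
    uniform = small_spec().true_t2star["placenta"]
    expected = (n_affected * 0.7 * uniform + (n - n_affected) * uniform) / n
    assert true_map[pl].mean() == pytest.approx(expected)
    if n % 2 == 0:  # exactly half: closed form 0.85 x uniform
        assert true_map[pl].mean() == pytest.approx(0.85 * uniform)
    # fitting the noiseless contracted phantom recovers the depressed truth
    t2map = fit_volume(volume, FitOptions(method="loglinear"))
    s = summarize_organ(t2map, masks["placenta"], volume.voxel_dims)
    assert s.mean_t2star == pytest.approx(expected, abs=1e-6)


def test_contraction_validation():
    with pytest.raises(PhantomSpecError):
        ContractionSpec(depression=1.5)
    with pytest.raises(PhantomSpecError):
        ContractionSpec(depression=0.3, region_fraction=0.0)


def test_ga_dependent_truth_follows_trends():
    early = small_spec(ga_weeks=25.0)
    late = small_spec(ga_weeks=39.0)
    for organ in ("placenta", "fetal_brain"):
        assert early.true_t2star[organ] > late.true_t2star[organ]


def test_cohort_table_shape_and_validation():
    table = generate_control_cohort(n=88, seed=7)
    assert len(table) == 88 * 4
    assert table["ga_weeks"].between(20, 40).all()
    assert (table["value"] > 0).all()
    # four measures per case, common GA per case
    per_case = table.groupby("ga_weeks").size()
    assert (per_case == 4).all()


def test_cohort_requires_decreasing_t2star_trends():
    bad = dict(
        list({
            ("placenta", "mean_t2star"): (100.0, 2.0),  # increasing with GA
            ("fetal_brain", "mean_t2star"): (280.0, 6.5, -0.19),
            ("placenta", "volume"): (0.0, 3800.0),
            ("fetal_brain", "volume"): (0.0, 1400.0),
        }.items())
    )
    with pytest.raises(PhantomSpecError, match="decrease"):
        generate_control_cohort(n=88, trend_coeffs=bad, seed=0)
    with pytest.raises(PhantomSpecError):
        generate_control_cohort(n=5)


def test_quantile_intercept_tracks_gaussian_closed_form():
    """With Gaussian cohort noise the fitted 5th-centile curve sits
    z_0.05 * sigma below the generating mean curve."""
    table = generate_control_cohort(n=2000, seed=13)
    models = build_normative_models(table)
    m = models[("placenta", "mean_t2star")]
    sigma = 12.0
    ga = np.linspace(21, 39, 30)
    expected = 337.0 - 4.0 * ga - 1.6449 * sigma
    assert np.abs(m.q05_at(ga) - expected).max() < 3.0


def test_repeat_series_shares_truth_and_varies_noise():
    spec = spec_with_snr(small_spec(seed=21), 20.0)
    series = generate_repeat_series(spec, k=3)
    assert len(series) == 3
    _, masks_0, map_0 = series[0]
    for vol_r, masks_r, map_r in series[1:]:
        assert np.array_equal(map_r, map_0)
        for organ in masks_0:
            assert np.array_equal(masks_r[organ].grid, masks_0[organ].grid)
    assert not np.array_equal(series[0][0].signal, series[1][0].signal)
    # and the whole series is reproducible
    again = generate_repeat_series(spec, k=3)
    assert np.array_equal(series[2][0].signal, again[2][0].signal)


def test_motion_increases_brain_repeat_difference():
    spec = spec_with_snr(small_spec(seed=31), 20.0)

    def brain_diff(perturbations):
        series = generate_repeat_series(spec, k=2, perturbations=perturbations)
        means = []
        for vol, masks, _ in series:
            t2map = fit_volume(vol, FitOptions(method="loglinear"))
            s = summarize_organ(t2map, masks["fetal_brain"], vol.voxel_dims,
                                ga_weeks=spec.ga_weeks)
            means.append(s.mean_t2star)
        return abs(means[0] - means[1])

    motion = MotionSpec(shifts=((0, 0, 0), (2, 1, 0), (3, 2, 1), (1, 3, 0)))
    assert brain_diff({1: {"motion": motion}}) > brain_diff(None)


def test_noise_increases_repeat_scatter():
    """Repeat-to-repeat mean T2* differences grow with noise sigma."""
    scatter = []
    for sigma in (2.0, 5.0, 10.0):
        diffs = []
        for seed in range(12):
            spec = small_spec(seed=seed, noise_sigma=sigma)
            series = generate_repeat_series(spec, k=2)
            means = []
            for vol, masks, _ in series:
                t2map = fit_volume(vol, FitOptions(method="loglinear"))
                s = summarize_organ(t2map, masks["placenta"], vol.voxel_dims)
                means.append(s.mean_t2star)
            diffs.append(means[0] - means[1])
        scatter.append(np.std(diffs))
    assert scatter[0] < scatter[1] < scatter[2]
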