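import numpy as np
import pytest

from rat.phantom import OrganGeometry, PhantomSpec, generate_phantom, spec_with_snr


def small_spec(**kwargs) -> PhantomSpec:
    """Compact phantom for unit tests: same organs, quarter-size grid."""
    defaults = dict(
        grid_shape=(32, 32, 24),
        organ_geometries={
            "fetal_brain": OrganGeometry(center=(9.0, 16.0, 12.0), semi_axes=(4.0, 3.5, 3.0)),
            "placenta": OrganGeometry(center=(22.0, 16.0, 12.0), semi_axes=(7.0, 6.0, 3.5)),
        },
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def noiseless_small_phantom():
    spec = small_spec()
    volume, masks, true_map = generate_phantom(spec)
    return spec, volume, masks, true_map


@pytest.fixture(scope="session")
def snr20_small_phantom():
    spec = spec_with_snr(small_spec(seed=11), 20.0)
    volume, masks, true_map = generate_phantom(spec)
    return spec, volume, masks, true_map


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def simulate_decay_voxels(n, s0, t2, echo_times, sigma, seed):
    """n replicate noisy voxels of one (s0, t2) ground truth."""
    te = np.asarray(echo_times, dtype=np.float64)
    rng = np.random.default_rng(seed)
    clean = s0 * np.exp(-te[None, :] / t2)
    return np.clip(clean + rng.normal(0.0, sigma, size=(n, te.size)), 0.0, None)
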