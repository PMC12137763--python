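"""Independent brute-force oracles the implementation is checked against.

These deliberately avoid the package's own code paths: the exponential
fit oracle is an exhaustive 2D grid search over (s0, t2star), the Dice
oracle enumerates voxel sets, and the Bland-Altman oracle is a direct
transcription of the defining formulas.
"""

import numpy as np


def grid_search_exponential(signal, echo_times, t2_bounds=(1.0, 2000.0),
                            n_t2=800, n_s0=400):
    """Minimize sum((S - s0*exp(-TE/t2))^2) by exhaustive grid search.

    Returns (s0, t2, rss) at the best grid node.
    """
    signal = np.asarray(signal, dtype=np.float64)
    te = np.asarray(echo_times, dtype=np.float64)
    t2_grid = np.geomspace(t2_bounds[0], t2_bounds[1], n_t2)
    s0_grid = np.linspace(0.0, 2.0 * signal.max() * np.exp(te[0] / t2_bounds[1]) + 1.0, n_s0)
    decay = np.exp(-te[None, :] / t2_grid[:, None])  # (T, E)
    pred = s0_grid[:, None, None] * decay[None, :, :]  # (S, T, E)
    rss = ((pred - signal[None, None, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    return float(s0_grid[i]), float(t2_grid[j]), float(rss[i, j])


def dice_brute_force(a, b):
    """Dice from explicit voxel-coordinate sets."""
    set_a = {tuple(idx) for idx in np.argwhere(np.asarray(a, dtype=bool))}
    set_b = {tuple(idx) for idx in np.argwhere(np.asarray(b, dtype=bool))}
    if not set_a and not set_b:
        return 1.0
    return 2.0 * len(set_a & set_b) / (len(set_a) + len(set_b))


def bland_altman_brute_force(a, b):
    """Mean difference and n-1 SD straight from the definitions."""
    diffs = [x - y for x, y in zip(a, b)]
    n = len(diffs)
    mean = sum(diffs) / n
    sd = (sum((d - mean) ** 2 for d in diffs) / (n - 1)) ** 0.5
    return mean, sd


def pinball_loss(y, pred, tau):
    """Check loss summed over observations."""
    total = 0.0
    for yi, pi in zip(y, pred):
        r = yi - pi
        total += tau * r if r >= 0 else (tau - 1) * r
    return total
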