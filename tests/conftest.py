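import math

import numpy as np
import pytest

from smcotrack import SimulationConfig


@pytest.fixture
def small_config():
    """A light simulation: few molecules, short movie, no noise sources."""
    return SimulationConfig(n_receptors=20, n_frames=40, sigma_loc_nm=0.0,
                            seed=7)


def sample_rayleigh_steps(rng, d_um2_s, dt_s, n):
    """Draw 2D Brownian step lengths (nm): r^2 ~ Exp(mean 4 D dt)."""
    return np.sqrt(rng.exponential(4.0 * d_um2_s * 1e6 * dt_s, n))


def mean_field_dimer_fraction(config, n_iter=20000):
    """Deterministic fixed point of the per-frame association/dissociation
    recursion, with the same discrete probabilities the simulator uses."""
    n = config.n_receptors
    area = (config.roi_width_um * 1e3) * (config.roi_height_um * 1e3)
    rc = config.capture_radius_nm
    p_on = 1.0 - math.exp(-config.k_on_2d * 1e6 * config.frame_time_s
                          / (math.pi * rc * rc))
    p_off = 1.0 - math.exp(-config.k_off * config.frame_time_s)
    d = 0.0
    for _ in range(n_iter):
        m = n - 2.0 * d
        d = d + p_on * math.pi * rc * rc / area * m * (m - 1) / 2.0 - p_off * d
    return 2.0 * d / n
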