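import numpy as np
import pytest

import t1forge as tf

#: Noise level used in the noisy-phantom fixtures: SNR 50 relative to the
#: equilibrium signal A=1000, which yields within-vial T1 SDs in the tens
#: of ms before denoising — the regime the denoiser is designed for.
NOISE_SIGMA = 20.0


@pytest.fixture(scope="session")
def vial_spec_small():
    """Compact nine-vial phantom for unit tests (noiseless)."""
    return tf.nine_vial_spec(grid_shape=(40, 40, 4))


@pytest.fixture(scope="session")
def vial_truth_small(vial_spec_small):
    return tf.build_phantom(vial_spec_small)


@pytest.fixture(scope="session")
def noisy_vial_stack(vial_truth_small, vial_spec_small):
    from dataclasses import replace

    spec = replace(vial_spec_small, noise_sigma=NOISE_SIGMA, seed=7)
    return spec, tf.simulate_stack(vial_truth_small, spec)


@pytest.fixture()
def random_stack():
    """Small generic stack of smooth random volumes."""
    rng = np.random.default_rng(42)
    base = rng.standard_normal((8, 8, 4))
    data = np.stack([base + 0.1 * rng.standard_normal((8, 8, 4)) for _ in range(3)])
    return tf.ContrastStack(data + 3.0, [100.0, 400.0, np.inf], (1.4, 1.4, 8.0))
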