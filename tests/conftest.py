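import numpy as np
import pytest

import glymphalps as ga


@pytest.fixture(scope="session")
def scheme32():
    return ga.make_gradient_scheme(32, 1000.0, seed=1)


@pytest.fixture(scope="session")
def phantom_default():
    """Tract phantom with perivascular boost alpha = 0.25 (alps_true ~ 1.543)."""
    return ga.build_tensor_phantom(ga.PhantomSpec(alpha=0.25))


@pytest.fixture(scope="session")
def noisefree_maps(phantom_default, scheme32):
    dwi = ga.simulate_dwi(phantom_default, scheme32, s0=1.0, noise_sigma=0.0)
    return ga.tensor_to_maps(ga.fit_tensor(dwi))


def run_alps_pipeline(alpha, scheme, seed, snr=30.0, noise_model="rician", search_radius=4):
    """simulate -> fit -> place -> extract -> compute for one phantom."""
    truth = ga.build_tensor_phantom(ga.PhantomSpec(alpha=alpha, seed=seed))
    sigma = 0.0 if snr == np.inf else 1.0 / snr
    dwi = ga.simulate_dwi(truth, scheme, s0=1.0, noise_sigma=sigma, noise_model=noise_model, seed=seed)
    maps = ga.tensor_to_maps(ga.fit_tensor(dwi))
    placed = ga.place_rois(maps, ga.default_roi_set(truth.labels), search_radius=search_radius)
    return ga.compute_alps(ga.extract_roi_means(maps, placed)).alps_bilateral, truth.alps_true
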