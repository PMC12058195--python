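import numpy as np
import pytest

import arousalcpm as ac


@pytest.fixture(scope="session")
def spec400():
    return ac.DatasetSpec(tr_s=1.5, segment_tr=(400,), window_tr=30)


@pytest.fixture(scope="session")
def coupled():
    """Small coupled dataset: 8 subjects, 20 ROIs, 400 TRs, coupling 0.8."""
    cfg = ac.SyntheticConfig(
        n_subjects=8, n_roi=20, n_tr=400, coupling=0.8, n_raters=8,
        planted_edges=ac.default_planted_edges(20, 6, seed=1), seed=1,
    )
    return ac.make_dataset(cfg)


@pytest.fixture(scope="session")
def coupled_fc(coupled, spec400):
    return ac.compute_dynfc_set(coupled.bold, spec400)


@pytest.fixture(scope="session")
def coupled_target(coupled, spec400):
    panel = ac.resample_ratings(coupled.ratings, spec400)
    return ac.zscore(ac.build_group_target(panel, spec400).smoothed)


@pytest.fixture(scope="session")
def latent_target(coupled, spec400):
    """Noise-free target: the true latent, HRF-convolved and taper-smoothed."""
    conv = ac.convolve_hrf(coupled.truth.latent, spec400.tr_s)
    return ac.zscore(ac.taper_smooth(conv, spec400))
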