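import numpy as np
import pytest

import honeynir as hn
from honeynir.preprocess import PreprocessSpec, fit_apply


@pytest.fixture(scope="session")
def study78():
    """Default synthetic study: 30 CH + 30 PF + 18 MF, duplicate scans."""
    records = hn.sample_composition({"CH": 30, "PF": 30, "MF": 18}, seed=1)
    spectra = hn.simulate_spectra(records, hn.BENCHTOP, replicates=2, seed=11)
    return records, spectra


@pytest.fixture(scope="session")
def aligned_glucose(study78):
    """Aligned (X, y_glucose) on the benchtop grid, SNV + mean-centred."""
    records, spectra = study78
    ref = hn.records_to_frame(records)
    averaged = hn.average_replicates(spectra)
    X, Y, _ = hn.align(averaged, ref)
    Xp, _, _ = fit_apply(
        PreprocessSpec(scatter="snv", scaling="mean_center"), X, grid_step=0.5
    )
    return Xp, Y["glucose"].to_numpy(dtype=float)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
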