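import numpy as np
import pytest

from temweb import SyntheticSpec, generate_sheet


@pytest.fixture(scope="session")
def independent_sheet():
    """A 10x10 um dual-channel sheet with independent Poisson channels."""
    spec = SyntheticSpec(
        field_width_um=10.0,
        field_height_um=10.0,
        density_ch1=2.0,
        density_ch2=2.0,
        cluster_fwhm_mean_nm=110.0,
        cluster_fwhm_sd_nm=15.0,
        photons_per_molecule=1500.0,
        seed=42,
    )
    return spec, *generate_sheet(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
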