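import numpy as np
import pytest

import stripequant as sq

#: expected stripe centers in %EL, matching the generator defaults
REF_CENTERS = [c * 100 for c in np.linspace(0.25, 0.73, 7)]


@pytest.fixture(scope="session")
def ref_centers():
    return list(REF_CENTERS)


@pytest.fixture(scope="session")
def default_config(ref_centers):
    return sq.PipelineConfig(reference_centers=ref_centers)


@pytest.fixture(scope="session")
def noiseless_embryo():
    """Wild-type-like synthetic embryo with all noise off, plus its truth."""
    spec = sq.EmbryoImageSpec(noise_sd=0.0)
    image, truth = sq.generate_embryo_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def noiseless_quantified(noiseless_embryo, default_config):
    _, image, truth = noiseless_embryo
    table = sq.quantify_embryo(image, default_config, embryo_id="wt0")
    return table, truth
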