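import numpy as np
import pytest

from colonymorph.segmentation import GaborTextureSegmenter
from colonymorph.synthgen import (SyntheticStudySpec, archetype_defaults,
                                  generate_colony_image, generate_study)


@pytest.fixture(scope="session")
def segmenter():
    return GaborTextureSegmenter().fit()


@pytest.fixture(scope="session")
def bank(segmenter):
    return segmenter.bank_


@pytest.fixture(scope="session")
def round_colony():
    """Round colony (bright polarity) image and truth mask, seed 7."""
    spec = archetype_defaults("round")
    return generate_colony_image(spec, image_size=224, seed=7)


@pytest.fixture(scope="session")
def round_colony_dark():
    spec = archetype_defaults("round", polarity="dark_on_bright")
    return generate_colony_image(spec, image_size=224, seed=7)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study for fast unit tests: 6 lines x 8 colonies."""
    spec = SyntheticStudySpec(n_lines=6, colonies_per_line=8, image_size=224,
                              n_genes=80, de_gene_ids=(0, 1, 2), seed=11)
    return generate_study(spec)


@pytest.fixture(scope="session")
def tiny_study_zero_noise():
    """Zero-expression-noise study (8 lines x 3 colonies) for power checks."""
    spec = SyntheticStudySpec(n_lines=8, colonies_per_line=3, image_size=224,
                              n_genes=60, de_gene_ids=(0, 1), expr_noise_sd=0.0,
                              seed=5)
    return generate_study(spec)
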