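import numpy as np
import pytest

from wsimet import synthetic_data


@pytest.fixture(scope="session")
def paper_fixtures():
    """Bundled published case/control count tables."""
    return synthetic_data.load_paper_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_slide():
    """One 1024x1024 rapid-metastasis slide with a centered annotation.

    Small enough for unit tests (2x2 grid of 512-px tiles) while exercising
    the real generator.
    """
    rng = np.random.default_rng(7)
    spec = synthetic_data.SyntheticSlideSpec(
        slide_id="s_small", patient_id="p_small", cohort="rapid_met",
        width_px=1024, height_px=1024, texture_effect=1.0,
        annotation_polygons=(synthetic_data.default_annotation_polygon(
            1024, 1024, rng, radius_frac=0.45),),
        seed=99)
    image, mask = synthetic_data.generate_slide(spec)
    return spec, image, mask
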