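import dataclasses

import numpy as np
import pytest

from rpscore import pipeline, synthetic_fundus as sf


@pytest.fixture(scope="session")
def default_params():
    return sf.SynthParams()


@pytest.fixture(scope="session")
def clean_fundus():
    """One noise-free synthetic fundus with vessels and disc."""
    return sf.generate_image(sf.SynthParams(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-participant cohort at baseline noise, scored with truth masks."""
    cohort = sf.generate_cohort(
        30, sf.SynthParams(noise_sd=2.0, illumination_sd=5.0), seed=101
    )
    records = pipeline.score_records(cohort.records)
    frame = pipeline.records_to_frame(records)
    return cohort, frame


def make_image(pixels, **kwargs):
    from rpscore.fundus_io import FundusImage

    defaults = dict(image_id="t")
    defaults.update(kwargs)
    return FundusImage(pixels=np.asarray(pixels), **defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def vary(params, **kwargs):
    return dataclasses.replace(params, **kwargs)
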