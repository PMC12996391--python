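"""Shared fixtures: small seeded phantom slides and cohorts."""

import numpy as np
import pytest

from spinesrh import CLASSES
from spinesrh.preprocess import assign_patch_qc, compose_three_channel, tile_patches
from spinesrh.synth import CohortSpec, PhantomSpec, make_phantom_slide


@pytest.fixture(scope="session")
def one_slide_per_class():
    """One default-size phantom slide per class, with block ground truth."""
    out = {}
    for i, cls in enumerate(CLASSES):
        spec = PhantomSpec(class_label=cls, seed=1000 + i)
        out[cls] = make_phantom_slide(spec, slide_id=f"{cls}_fix",
                                      patient_id=f"P_{cls}", return_truth=True)
    return out


@pytest.fixture(scope="session")
def qc_patchsets(one_slide_per_class):
    """QC'd patch sets for the fixture slides."""
    out = {}
    for cls, (pair, truth) in one_slide_per_class.items():
        ps = assign_patch_qc(tile_patches(compose_three_channel(pair)))
        out[cls] = (ps, truth)
    return out


@pytest.fixture(scope="session")
def small_cohort_spec():
    return CohortSpec(patients_per_class={c: 2 for c in CLASSES},
                      slides_per_patient=(1, 2), seed=77)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
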