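import numpy as np
import pytest

from fdgir.cohort import CohortSpec, generate_cohort
from fdgir.feng import build_population_prior, fit_feng_full
from fdgir.preprocess import align_peaks, floor_low_onsets
from fdgir.tac import SubjectMeta, TimeActivityCurve


@pytest.fixture(scope="session")
def reference_cohort():
    """13 reference-like synthetic inputs, floored and peak-aligned."""
    spec = CohortSpec(n_subjects=13, seed=1)
    cohort = generate_cohort(spec)
    floored, threshold = floor_low_onsets(cohort.inputs)
    aligned, alignment = align_peaks(floored)
    return {"cohort": cohort, "aligned": aligned, "alignment": alignment,
            "floor_threshold": threshold}


@pytest.fixture(scope="session")
def reference_prior(reference_cohort):
    """Whole-curve Feng fits of the reference set and the resulting prior."""
    aligned = reference_cohort["aligned"]
    fits = [fit_feng_full(c) for c in aligned]
    prior = build_population_prior([f.params for f in fits], aligned)
    return {"fits": fits, "prior": prior}


@pytest.fixture
def simple_meta():
    return SubjectMeta(subject_id="s0", dose_mbq=187.0, weight_kg=78.0,
                       hematocrit=0.41, cbf=0.55)


@pytest.fixture
def triangle_curve():
    return TimeActivityCurve([0.0, 1.0, 2.0], [0.0, 2.0, 2.0])
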