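import numpy as np
import pytest

from tmld import ThreeLocusParams, haplotype_frequencies, validate_params

#: the population parameters used throughout the simulation study
STUDY_PARAMS = ThreeLocusParams(
    p1=0.5, p2=0.5, p3=0.5, d12=0.05, d23=0.05, d13=0.15, d123=0.04
)


@pytest.fixture(scope="session")
def study_params() -> ThreeLocusParams:
    return STUDY_PARAMS


@pytest.fixture(scope="session")
def study_dist():
    return haplotype_frequencies(STUDY_PARAMS)


def random_valid_params(rng: np.random.Generator) -> ThreeLocusParams:
    """Rejection-sample a parameter vector with admissible frequencies."""
    while True:
        p1, p2, p3 = rng.uniform(0.1, 0.9, size=3)
        scale = rng.uniform(0.0, 0.1, size=4)
        sign = rng.choice([-1, 1], size=4)
        cand = ThreeLocusParams(
            p1=p1, p2=p2, p3=p3,
            d12=sign[0] * scale[0], d23=sign[1] * scale[1],
            d13=sign[2] * scale[2], d123=sign[3] * scale[3],
        )
        if not validate_params(cand):
            return cand
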