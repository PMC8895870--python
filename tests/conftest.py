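import numpy as np
import pytest

from hmppi.simulate import sim_cohort


AA = "ACDEFGHIKLMNPQRSTVWY"


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by profile/association unit tests."""
    return sim_cohort(
        n_case=40,
        n_control=40,
        n_bacterial_clusters=60,
        n_human_targets=40,
        n_planted_targets=4,
        effect_fold=8.0,
        zero_inflation=0.3,
        seed=7,
    )
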