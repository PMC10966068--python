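import numpy as np
import pytest

import asymkit
from asymkit.simulate import SyntheticSpec


@pytest.fixture(scope="session")
def atlas():
    return asymkit.default_atlas()


@pytest.fixture(scope="session")
def small_cohort(atlas):
    """Two-group cohort with one planted planum-temporale shift."""
    spec = SyntheticSpec(
        n_control=120,
        n_per_cnv={"16p11.2del": 60},
        effect_map={("16p11.2del", "Planum Temporale"): 1.0},
        seed=42,
    )
    return asymkit.generate_cohort(spec, atlas)


@pytest.fixture(scope="session")
def small_ai(atlas, small_cohort):
    adjusted = asymkit.adjust_site(small_cohort, atlas)
    return asymkit.compute_ai(adjusted, atlas)


@pytest.fixture(scope="session")
def eight_group_ai(atlas):
    """All eight carrier groups at reduced size, raw AI matrix."""
    spec = asymkit.default_spec(seed=7)
    spec.n_control = 80
    spec.n_per_cnv = {g: 25 for g in spec.n_per_cnv}
    table = asymkit.adjust_site(asymkit.generate_cohort(spec, atlas), atlas)
    return asymkit.compute_ai(table, atlas)
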