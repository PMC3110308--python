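import numpy as np
import pytest

import tagdistort as td


@pytest.fixture(scope="session")
def small_panel() -> td.HaplotypePanel:
    """A small but LD-realistic panel shared by the simulator tests."""
    return td.generate_panel(
        n_hap=8000, n_snp=100, region_bp=50_000, seed=3
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_valid_ld(rng: np.random.Generator) -> td.TwoLocusLD:
    """A random (f_A, f_B, r) triple strictly inside the feasible region."""
    f_a = rng.uniform(0.05, 0.95)
    f_b = rng.uniform(0.05, 0.95)
    lo, hi = td.r_bounds(f_a, f_b)
    r = rng.uniform(0.999 * lo, 0.999 * hi)
    return td.TwoLocusLD(f_a, f_b, r)
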