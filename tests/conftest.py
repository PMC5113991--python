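import numpy as np
import pytest

from paracell import SOLUTION_A, BathPair, Solution, replacement_solution


@pytest.fixture
def baths_70_140() -> BathPair:
    """Apical 70 / basal 140 mM NaCl with the full shared buffer background."""
    return BathPair(replacement_solution(70), SOLUTION_A)


@pytest.fixture
def pure_baths_70_140() -> BathPair:
    """NaCl-only 70/140 mM baths (Na and Cl equal on each side)."""
    return BathPair(Solution("nacl70", nacl=70), Solution("nacl140", nacl=140))


def pure_nacl_baths(apical_mm: float, basal_mm: float) -> BathPair:
    return BathPair(Solution(f"nacl{apical_mm:g}", nacl=apical_mm),
                    Solution(f"nacl{basal_mm:g}", nacl=basal_mm))


@pytest.fixture
def symmetric_140() -> BathPair:
    return pure_nacl_baths(140, 140)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160915)
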