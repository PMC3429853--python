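import numpy as np
import pytest

from mirscan import thermo

BASES = np.array(list("ACGU"))

# frozen filter fixture: each of the first four trips exactly one filter,
# the last survives everything (and contains CCCC, which is deliberately
# not on the default motif list)
MOTIF_GUIDE = "GACUGAUGUGGCAGACCCCAAA"          # UGGC
COMPLEXITY_GUIDE = "ACACACACACACACACACACAC"      # dinucleotide repeat
SELF_STRUCT_GUIDE = "CUGUGCAGUCAAUAGACUGCUU"     # strong hairpin, dG < -2
SEED_GUIDE = "UCCUCAGGAACUCUCAUUAAGC"            # seed 2-7 = CCUCAG
CLEAN_GUIDE = "GACUGAUGUAAUAGACCCCAAA"
FIXTURE_SEED_SET = frozenset({"CCUCAG"})


@pytest.fixture(scope="session")
def params():
    return thermo.default_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rna(rng, length):
    return "".join(rng.choice(BASES, length))


def random_guide(rng):
    return random_rna(rng, 22)


@pytest.fixture
def random_guides(rng):
    return [random_guide(rng) for _ in range(50)]
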