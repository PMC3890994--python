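import pytest

from repsel.annotate import VdjAnnotator
from repsel.germline import build_toy_germline
from repsel.simulate import simulate_repertoire


@pytest.fixture(scope="session")
def germline():
    return build_toy_germline()


@pytest.fixture(scope="session")
def annotator(germline):
    return VdjAnnotator(germline)


@pytest.fixture(scope="session")
def heavy_repertoire(germline):
    return simulate_repertoire(germline, 200, rng_seed=11, chain="heavy")


@pytest.fixture(scope="session")
def light_repertoire(germline):
    return simulate_repertoire(germline, 200, rng_seed=12, chain="light")


# independent codon table for oracle translations (built from scratch, not
# from the package)
_BASES = "TCAG"
_AMINO = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
CODON_ORACLE = {a + b + c: _AMINO[16 * i + 4 * j + k]
                for i, a in enumerate(_BASES)
                for j, b in enumerate(_BASES)
                for k, c in enumerate(_BASES)}


def oracle_translate(nt: str) -> str:
    return "".join(CODON_ORACLE.get(nt[i:i + 3], "X")
                   for i in range(0, len(nt) - len(nt) % 3, 3))
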