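import pytest

from strainomics import Genome, CdsFeature, random_genome


@pytest.fixture(scope="session")
def small_genome_pair():
    """A 100-kb genome with CDS annotation, shared across tests."""
    return random_genome(100_000, 0.7114, seed=7)


@pytest.fixture()
def toy_genome():
    """A 30-codon '+'-strand CDS flanked by 10-bp pads."""
    codons = ["ATG"] + ["GGT"] * 28 + ["TAA"]
    seq = "A" * 10 + "".join(codons) + "A" * 10
    genome = Genome("toy", seq)
    cds = CdsFeature("T0001", 11, 10 + 90, "+")
    return genome, cds


# independent codon table for translation oracles (bacterial code, table 11)
CODON_TABLE = {}
_bases = "TCAG"
_aas = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _a in enumerate(_aas):
    CODON_TABLE[_bases[_i // 16] + _bases[(_i // 4) % 4] + _bases[_i % 4]] = _a

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def oracle_translate(coding: str, start_as_met: bool = True) -> str:
    """Codon-by-codon lookup translation; internal stops kept as '*'."""
    aas = [CODON_TABLE[coding[i : i + 3]] for i in range(0, len(coding), 3)]
    if start_as_met and coding[:3] in {"ATG", "GTG", "TTG"}:
        aas[0] = "M"
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)
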