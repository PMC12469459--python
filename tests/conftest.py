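"""Shared fixtures: published repeat structures and synthetic locus anatomy."""

import numpy as np
import pytest

# predominant felid exonic allele: (GAA)1 (GAG)2 (GAA)1 (GAG)7 (GAA)1
PREDOMINANT_EXON_ALLELE = "GAA" + "GAG" * 2 + "GAA" + "GAG" * 7 + "GAA"

# the two published 19-bp cryptic-simple-sequence variants replacing the
# repeat region in palm civets
CSS_PARADOXURUS = "GCGTGAGAGGGGCAGAGAA"
CSS_PAGUMA = "GCGTGGGAGGGGCAGAGAA"

# axolotl exonic structure: (GAG)1(GAA)1(GAG)1(GAA)1(GAG)1(GAT)2 GAC (GAG)1
AXOLOTL_EXON_REGION = "GAGGAAGAGGAAGAGGATGATGACGAG"

LEFT_FLANK = "ACGTTGCAACGGTACGATCCAGGTTACAGTTA"
RIGHT_FLANK = "TTGACCAGTACGGATTACAGGCATTCAGCCTA"


@pytest.fixture
def flanks():
    return LEFT_FLANK, RIGHT_FLANK


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(rng, seq, rate):
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(str(rng.choice([x for x in "ACGT" if x != c])))
        else:
            out.append(c)
    return "".join(out)
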