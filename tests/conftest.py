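from __future__ import annotations

import random

import pytest
from hypothesis import settings

from dbgalign.align import nucleotide_scheme, translated_scheme

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def nt():
    """Default nucleotide scoring, prefilter disabled for exactness on tiny data."""
    return nucleotide_scheme(word_size=0)


@pytest.fixture
def aa():
    return translated_scheme(word_size=0)


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def mutate_dna(rng: random.Random, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != ch]))
        else:
            out.append(ch)
    return "".join(out)
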