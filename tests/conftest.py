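import random

import pytest

from conifer_div._codons import SENSE_CODONS
from conifer_div.ortho import CodonAlignment


@pytest.fixture
def random_codon_alignment():
    """Factory for random sense-codon alignments (no gaps)."""

    def make(n_codons: int, seed: int, p_diff: float = 0.3) -> CodonAlignment:
        rng = random.Random(seed)
        row_a, row_b = [], []
        for _ in range(n_codons):
            ca = rng.choice(SENSE_CODONS)
            if rng.random() < p_diff:
                cb = rng.choice(SENSE_CODONS)
            else:
                cb = ca
            row_a.append(ca)
            row_b.append(cb)
        return CodonAlignment("a", "b", "".join(row_a), "".join(row_b))

    return make
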