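from itertools import product

import numpy as np
import pytest

from winhap import MISSING, GenotypeMatrix


def random_genotype_matrix(rng, n, m, p_het=0.3, missing_rate=0.0):
    """Random genotype matrix with the given heterozygote/missing rates."""
    p_hom = (1.0 - p_het) / 2.0
    cells = rng.choice(np.array([0, 1, 2], dtype=np.int8), size=(n, m),
                       p=[p_hom, p_hom, p_het])
    if missing_rate > 0:
        cells = np.where(rng.random((n, m)) < missing_rate,
                         np.int8(MISSING), cells)
    return GenotypeMatrix(cells)


def exhaustive_pair_oracle(segment: str, freqs) -> set[tuple[str, str]]:
    """All unordered haplotype pairs that expand to the segment, found by
    enumerating every per-site allele assignment, restricted to segments
    observed in the frequency table.  Independent of the package's own
    pair enumeration."""
    options = []
    for ch in segment:
        if ch == "0":
            options.append([("0", "0")])
        elif ch == "1":
            options.append([("1", "1")])
        elif ch == "2":
            options.append([("0", "1"), ("1", "0")])
        else:  # '?': anything goes
            options.append([("0", "0"), ("0", "1"), ("1", "0"), ("1", "1")])
    pairs = set()
    for combo in product(*options):
        a = "".join(x for x, _ in combo)
        b = "".join(y for _, y in combo)
        if freqs.get(a, 0) > 0 and freqs.get(b, 0) > 0:
            pairs.add((min(a, b), max(a, b)))
    return pairs


@pytest.fixture
def make_matrix():
    return random_genotype_matrix


@pytest.fixture
def pair_oracle():
    return exhaustive_pair_oracle
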