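"""Step 1 — initial phasing by chaining cis/trans decisions along a linear
tree of adjacent heterozygous SNP pairs.

For each individual the first heterozygous site is fixed to 0/1 across the
two rows; every later heterozygous site is oriented relative to its
predecessor by the population-level evidence for cis-phasing (22 -> 00/11)
versus trans-phasing (22 -> 01/10).  Evidence comes from the two-site
haplotype counts F00/F01/F10/F11 contributed by every individual whose pair
of cells at the two sites is unambiguous (no '?', not 2|2).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .model import HET, MISSING, GenotypeMatrix, PhasingSolution

__all__ = [
    "Phase",
    "PairFrequencies",
    "pair_frequencies",
    "phase_pattern",
    "phase_genotype_initial",
]


class Phase(Enum):
    """Resolution of a heterozygous site pair: cis (00/11) or trans (01/10)."""

    CIS = "cis"
    TRANS = "trans"


@dataclass(frozen=True)
class PairFrequencies:
    """Counts of the four two-site haplotypes 00/01/10/11 for a site pair."""

    f00: int
    f01: int
    f10: int
    f11: int

    @property
    def total(self) -> int:
        return self.f00 + self.f01 + self.f10 + self.f11


def pair_frequencies(G: GenotypeMatrix, i: int, j: int) -> PairFrequencies:
    """Two-site haplotype counts at sites ``(i, j)``.

    An individual contributes its two (unambiguous) haplotypes unless either
    cell is missing or both are heterozygous, in which case it contributes
    nothing.  A homozygous/homozygous individual contributes the same
    haplotype twice.
    """
    if i == j:
        raise ValueError("pair frequencies need two distinct sites")
    a = G.cells[:, i].astype(np.intp)
    b = G.cells[:, j].astype(np.intp)
    keep = (a != MISSING) & (b != MISSING) & ~((a == HET) & (b == HET))
    a, b = a[keep], b[keep]
    counts = np.zeros((2, 2), dtype=np.int64)
    hom = (a != HET) & (b != HET)
    np.add.at(counts, (a[hom], b[hom]), 2)
    ah = a == HET  # one haplotype carries 0, the other 1, both with b's allele
    np.add.at(counts, (0, b[ah]), 1)
    np.add.at(counts, (1, b[ah]), 1)
    bh = b == HET
    np.add.at(counts, (a[bh], 0), 1)
    np.add.at(counts, (a[bh], 1), 1)
    return PairFrequencies(
        int(counts[0, 0]), int(counts[0, 1]), int(counts[1, 0]), int(counts[1, 1])
    )


def phase_pattern(f: PairFrequencies) -> Phase:
    """Cis wins when the cis product dominates: F00*F11 >= F01*F10.

    Ties (including the all-zero table) resolve to cis, which pairs the two
    major alleles together — the a-priori likelier configuration.
    """
    return Phase.CIS if f.f00 * f.f11 >= f.f01 * f.f10 else Phase.TRANS


def phase_genotype_initial(G: GenotypeMatrix) -> PhasingSolution:
    """Resolve every genotype into an initial haplotype pair.

    Homozygous sites are copied to both rows and '?' cells stay '?'.  Row
    ``2i`` carries allele 0 at the individual's first heterozygous site
    (canonical orientation); each subsequent heterozygous site keeps the row
    assignment under cis and flips it under trans.  Pair decisions are cached
    by site pair, so the pass costs O(nm) overall.
    """
    n, m = G.n, G.m
    H = np.empty((2 * n, m), dtype=np.int8)
    cache: dict[tuple[int, int], Phase] = {}
    for i in range(n):
        g = G.cells[i]
        h1 = g.copy()
        h2 = g.copy()
        hets = np.flatnonzero(g == HET)
        if hets.size:
            allele = 0
            h1[hets[0]] = 0
            h2[hets[0]] = 1
            for prev, cur in zip(hets[:-1], hets[1:]):
                key = (int(prev), int(cur))
                pat = cache.get(key)
                if pat is None:
                    pat = phase_pattern(pair_frequencies(G, *key))
                    cache[key] = pat
                if pat is Phase.TRANS:
                    allele = 1 - allele
                h1[cur] = allele
                h2[cur] = 1 - allele
        H[2 * i] = h1
        H[2 * i + 1] = h2
    return PhasingSolution(H, G)
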