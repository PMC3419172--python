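"""Synthetic block-structured populations with known true haplotypes.

Real chromosomes decompose into blocks of consecutive SNPs inside which a
handful of *common haplotypes* carry almost all of the frequency mass —
linkage-disequilibrium surveys report four main patterns covering ~97% of
the haplotypes per block, with block lengths rarely above 10 SNPs.  The
generator emulates exactly that: per block it draws a small pool of common
segments (plus a few rare ones), chromosomes follow a lineage through the
block pools with occasional switches at block boundaries (a crude
recombination stand-in), individuals pair two independent chromosomes, and
genotype cells are masked to '?' at a configurable rate.  Allele 0 is
recoded to be the major allele at every site.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import HET, MISSING, GenotypeMatrix, PhasingSolution, hap_row

__all__ = [
    "BlockPoolSpec",
    "UNEVEN_BLOCK_POOL",
    "uneven_block_fixture",
    "generate_population",
]


@dataclass(frozen=True)
class BlockPoolSpec:
    """Parameters of the block-structured population model.

    n_blocks: number of haplotype blocks (ignored when ``generate_population``
        is given an explicit ``total_sites``).
    block_len_range: inclusive (min, max) block length in SNP sites.
    n_common: common haplotype segments per block.
    common_mass: total frequency mass on the common segments.
    rare_count: rare segments per block sharing the remaining mass (clipped
        when the block is too short to hold that many distinct segments).
    recomb_rate: probability, at each block boundary, that a chromosome's
        lineage through the pools is redrawn.
    missing_rate: per-genotype-cell probability of masking to '?'.
    seed: RNG seed; same spec + same n means identical output.
    """

    n_blocks: int = 15
    block_len_range: tuple[int, int] = (3, 10)
    n_common: int = 4
    common_mass: float = 0.97
    rare_count: int = 3
    recomb_rate: float = 0.02
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.common_mass <= 1:
            raise ValueError("common_mass must be in (0, 1]")
        for name in ("recomb_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.block_len_range
        if not 1 <= lo <= hi:
            raise ValueError("block_len_range must satisfy 1 <= min <= max")
        if self.n_common < 1 or self.n_blocks < 1 or self.rare_count < 0:
            raise ValueError("counts must be positive")

    def with_seed(self, seed: int) -> "BlockPoolSpec":
        return replace(self, seed=seed)


#: A classic five-SNP block with a heavily uneven haplotype distribution:
#: four common patterns carry 106 of 109 chromosomes (~97%).
UNEVEN_BLOCK_POOL: list[tuple[str, int]] = [
    ("00000", 66),
    ("01001", 24),
    ("11110", 10),
    ("01000", 6),
    ("11000", 1),
    ("11011", 1),
    ("00001", 1),
]


def uneven_block_fixture() -> tuple[list[tuple[str, int]], GenotypeMatrix, PhasingSolution]:
    """Deterministic population built from the classic uneven block pool.

    The seven haplotypes are expanded by their counts (109 chromosomes in
    pool order) and paired round-robin: chromosome ``i`` with chromosome
    ``i + ceil(109/2)``, cyclically, dropping the single unpaired leftover.
    Returns ``(pool, genotypes, truth)`` with 54 genotypes of 5 sites.
    """
    expanded = [h for h, c in UNEVEN_BLOCK_POOL for _ in range(c)]
    total = len(expanded)
    half = (total + 1) // 2
    pairs = [(expanded[i], expanded[i + half]) for i in range(total - half)]
    H = np.vstack([hap_row(h) for pair in pairs for h in pair])
    truth = PhasingSolution.from_hap_strings(
        [h for pair in pairs for h in pair]
    )
    return UNEVEN_BLOCK_POOL, truth.genotypes, truth


def _int_to_bits(values: np.ndarray, length: int) -> np.ndarray:
    out = np.empty((values.size, length), dtype=np.int8)
    for bit in range(length):
        out[:, length - 1 - bit] = (values >> bit) & 1
    return out


def _draw_block(
    rng: np.random.Generator, length: int, spec: BlockPoolSpec
) -> tuple[np.ndarray, np.ndarray]:
    space = 2 ** length
    if spec.n_common > space:
        raise ValueError(
            f"cannot place {spec.n_common} distinct common haplotypes in a "
            f"block of {length} sites"
        )
    k_rare = min(spec.rare_count, space - spec.n_common)
    ids = rng.choice(space, size=spec.n_common + k_rare, replace=False)
    segs = _int_to_bits(np.asarray(ids, dtype=np.int64), length)
    # Decreasing Dirichlet concentration mimics the uneven within-block
    # distribution (one dominant pattern, a short tail).
    alpha = np.arange(spec.n_common, 0, -1, dtype=float)
    p_common = rng.dirichlet(alpha)
    if k_rare:
        p_common = p_common * spec.common_mass
        p_rare = np.full(k_rare, (1.0 - spec.common_mass) / k_rare)
        probs = np.concatenate([p_common, p_rare])
    else:
        probs = p_common
    return segs, probs / probs.sum()


def generate_population(
    spec: BlockPoolSpec,
    n: int,
    total_sites: int | None = None,
) -> tuple[GenotypeMatrix, PhasingSolution]:
    """Simulate ``n`` diploid individuals; returns ``(genotypes, truth)``.

    ``truth.genotypes`` is the returned (masked) matrix, so the truth
    solution is directly usable as the evaluation reference with the matrix
    as the missingness mask.  With ``total_sites`` the block lengths are
    drawn until they cover exactly that many sites (the last block is
    trimmed); otherwise ``spec.n_blocks`` blocks are drawn.
    """
    if n < 1:
        raise ValueError("need at least one individual")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.block_len_range
    lengths: list[int] = []
    if total_sites is not None:
        covered = 0
        while covered < total_sites:
            rem = total_sites - covered
            L = min(int(rng.integers(lo, hi + 1)), rem)
            if 0 < rem - L < lo:
                L = rem  # absorb a too-short remainder into the final block
            lengths.append(L)
            covered += L
    else:
        lengths = [int(v) for v in rng.integers(lo, hi + 1, size=spec.n_blocks)]
    blocks = [_draw_block(rng, L, spec) for L in lengths]
    m = int(sum(lengths))
    n_chrom = 2 * n
    H = np.empty((n_chrom, m), dtype=np.int8)
    for c in range(n_chrom):
        pos = 0
        idx = -1
        for b, (segs, probs) in enumerate(blocks):
            if b == 0 or idx >= len(probs) or rng.random() < spec.recomb_rate:
                idx = int(rng.choice(len(probs), p=probs))
            L = segs.shape[1]
            H[c, pos : pos + L] = segs[idx]
            pos += L
    # Recode so 0 is the major allele at every site (ties keep 0 as-is).
    flip = H.mean(axis=0) > 0.5
    H[:, flip] = 1 - H[:, flip]
    h1, h2 = H[0::2], H[1::2]
    cells = np.where(h1 == h2, h1, np.int8(HET)).astype(np.int8)
    if spec.missing_rate > 0:
        masked = rng.random(cells.shape) < spec.missing_rate
        cells = np.where(masked, np.int8(MISSING), cells)
    G = GenotypeMatrix(cells)
    truth = PhasingSolution(H, G)
    return G, truth
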