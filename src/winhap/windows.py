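"""Step 2 — correction of haplotypes with scalable sliding windows.

A window is a run of consecutive SNP sites shared by all individuals.  For
each window the current haplotype rows define a frequency table of haplotype
segments; for each individual the *compatible pairs* of its genotype segment
are the unordered pairs of observed segments whose combination reproduces the
segment ('?' matches anything).  Pair ``i`` gets weight

    w_i = F1_i * F2_i / sum_j F1_j * F2_j ,

the product of its two segment frequencies normalized over all compatible
pairs.  When the top weight exceeds the threshold ``tau`` the individual's
rows are overwritten with that common pair.  Windows of every length from
``l_min`` to ``l_max`` slide left to right across the chromosome.

Heterozygous site pairs further apart than ``l_max`` are never covered by one
window; those long gaps are fixed separately by Hamming-distance voting over
the interval between the two sites (:func:`long_gap_correction`).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Mapping

import numpy as np

from .model import (
    HET,
    MISSING,
    PhasingSolution,
    geno_row,
    geno_str,
    hap_row,
)

__all__ = [
    "PairCandidate",
    "WindowPairTable",
    "window_frequencies",
    "compatible_pairs",
    "apply_window",
    "sweep_windows",
    "find_long_gaps",
    "long_gap_correction",
    "correct_long_gaps",
]


@dataclass(frozen=True)
class PairCandidate:
    """One compatible haplotype-segment pair with its frequencies and weight."""

    hap_a: str
    hap_b: str
    freq_a: int
    freq_b: int
    weight: float


@dataclass
class WindowPairTable:
    """All compatible pairs of one genotype segment in one window, sorted by
    weight descending (ties broken lexicographically)."""

    window: tuple[int, int]
    segment: str
    pairs: list[PairCandidate]

    @property
    def s(self) -> int:
        """Number of compatible pairs."""
        return len(self.pairs)

    def top_rows(self) -> tuple[np.ndarray, np.ndarray]:
        """The dominant pair as int8 rows (parsed once, reused per window)."""
        cached = getattr(self, "_top_rows", None)
        if cached is None:
            top = self.pairs[0]
            cached = (hap_row(top.hap_a), hap_row(top.hap_b))
            self._top_rows = cached
        return cached


def _check_window(sol: PhasingSolution, window: tuple[int, int]) -> None:
    start, length = window
    if length < 1 or start < 0 or start + length > sol.m:
        raise ValueError(
            f"window (start={start + 1}, length={length}) out of range for "
            f"{sol.m} sites"
        )


def window_frequencies(
    sol: PhasingSolution, window: tuple[int, int]
) -> dict[str, int]:
    """Count the haplotype segments of all 2n rows in a window.

    Segments containing '?' are not realized haplotypes and are excluded.
    """
    _check_window(sol, window)
    start, length = window
    seg = sol.haplotypes[:, start : start + length]
    ok = (seg != MISSING).all(axis=1)
    if not ok.any():
        return {}
    ascii_rows = seg[ok].astype(np.uint8) + ord("0")
    uniq, counts = np.unique(ascii_rows, axis=0, return_counts=True)
    return {u.tobytes().decode("ascii"): int(c) for u, c in zip(uniq, counts)}


def _pair_matches(segment: str, a: str, b: str) -> bool:
    for gc, ac, bc in zip(segment, a, b):
        if gc == "?":
            continue
        if gc == "2":
            if ac == bc:
                return False
        elif ac != gc or bc != gc:
            return False
    return True


def _enumerate_pairs(
    segment: str, items: list[tuple[str, int]]
) -> list[tuple[str, str, int, int, int]]:
    """All unordered compatible pairs with their frequencies and products.

    A segment can take part in a pair only if it matches the genotype at
    every homozygous position; at heterozygous positions the two segments of
    a pair must be exact complements, so each candidate's partner pattern is
    unique.  '?' positions constrain nothing.
    """
    if not items:
        return []
    length = len(segment)
    g = geno_row(segment)
    keys = [k for k, _ in items]
    arr = np.frombuffer("".join(keys).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(keys), length) - ord("0")
    ok = np.ones(len(keys), dtype=bool)
    for allele in (0, 1):
        cols = g == allele
        if cols.any():
            ok &= ~(arr[:, cols] != allele).any(axis=1)
    cand = np.flatnonzero(ok)
    het_cols = np.flatnonzero(g == HET)
    raw: list[tuple[str, str, int, int, int]] = []
    if het_cols.size == 0:
        # no complement constraint: every unordered combination qualifies
        for x, y in combinations_with_replacement(cand, 2):
            a, fa = items[x]
            b, fb = items[y]
            raw.append((a, b, fa, fb, fa * fb))
        return raw
    patterns = arr[np.ix_(cand, het_cols)]
    groups: dict[bytes, list[int]] = {}
    for idx, pat in zip(cand, patterns):
        groups.setdefault(pat.tobytes(), []).append(int(idx))
    for pat, members in groups.items():
        comp = bytes(1 - v for v in pat)
        partners = groups.get(comp)
        if partners is None or comp < pat:
            continue
        for x in members:
            for y in partners:
                a, fa = items[x]
                b, fb = items[y]
                if a > b:
                    a, b, fa, fb = b, a, fb, fa
                raw.append((a, b, fa, fb, fa * fb))
    return raw


def compatible_pairs(
    segment, freqs: Mapping[str, int], window: tuple[int, int] | None = None
) -> WindowPairTable:
    """Enumerate the compatible haplotype pairs of a genotype segment.

    ``segment`` is a string over ``{0,1,2,?}`` or an int8 row; ``freqs`` maps
    observed haplotype segments to their counts.  The pair list may be empty.
    """
    if not isinstance(segment, str):
        segment = geno_str(np.asarray(segment, dtype=np.int8))
    items = sorted((k, v) for k, v in freqs.items() if v > 0)
    raw = _enumerate_pairs(segment, items)
    total = sum(p[4] for p in raw)
    pairs = [
        PairCandidate(a, b, fa, fb, prod / total)
        for a, b, fa, fb, prod in raw
    ]
    pairs.sort(key=lambda p: (-p.weight, p.hap_a, p.hap_b))
    if window is None:
        window = (0, len(segment))
    return WindowPairTable(window, segment, pairs)


def _mismatches(candidate: np.ndarray, current: np.ndarray) -> int:
    known = current != MISSING
    return int(np.count_nonzero(candidate[known] != current[known]))


def _apply_table(
    sol: PhasingSolution,
    individual: int,
    window: tuple[int, int],
    table: WindowPairTable,
    tau: float,
) -> bool:
    if not table.pairs:
        return False
    top = table.pairs[0]
    if top.weight <= tau:
        return False
    start, length = window
    r1 = sol.haplotypes[2 * individual, start : start + length]
    r2 = sol.haplotypes[2 * individual + 1, start : start + length]
    a, b = table.top_rows()
    # Orient the pair to minimize Hamming distance to the current rows; on a
    # tie the lexicographically smaller segment goes to row 2i.
    if _mismatches(b, r1) + _mismatches(a, r2) < _mismatches(a, r1) + _mismatches(b, r2):
        a, b = b, a
    changed = not (np.array_equal(a, r1) and np.array_equal(b, r2))
    r1[:] = a
    r2[:] = b
    return changed


def apply_window(
    sol: PhasingSolution,
    individual: int,
    window: tuple[int, int],
    tau: float = 0.70,
    freqs: Mapping[str, int] | None = None,
) -> bool:
    """Replace one individual's window segment by the dominant compatible
    pair when its weight exceeds ``tau``; in-place.  Returns whether the rows
    changed.  Segments without a heterozygous site are never touched.
    """
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    _check_window(sol, window)
    start, length = window
    g = sol.genotypes.cells[individual, start : start + length]
    if HET not in g:
        return False
    if freqs is None:
        freqs = window_frequencies(sol, window)
    table = compatible_pairs(g, freqs, window)
    return _apply_table(sol, individual, window, table, tau)


def sweep_windows(
    sol: PhasingSolution,
    l_min: int = 3,
    l_max: int = 10,
    tau: float = 0.70,
) -> PhasingSolution:
    """Slide windows of every length ``l_min..l_max`` left to right and apply
    the common-pair replacement to every individual; in-place, deterministic.

    The frequency table is recomputed from the current (progressively
    corrected) solution at each window and held fixed while the window's
    individuals are processed.
    """
    if l_min > l_max:
        raise ValueError(f"l_min={l_min} exceeds l_max={l_max}")
    if l_min < 1:
        raise ValueError("l_min must be at least 1")
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    m = sol.m
    cells = sol.genotypes.cells
    for start in range(m):
        top = min(l_max, m - start)
        for length in range(l_min, top + 1):
            window = (start, length)
            gwin = cells[:, start : start + length]
            hetmask = (gwin == HET).any(axis=1)
            if not hetmask.any():
                continue
            freqs = window_frequencies(sol, window)
            if not freqs:
                continue
            tables: dict[bytes, WindowPairTable] = {}
            for i in np.flatnonzero(hetmask):
                key = gwin[i].tobytes()
                table = tables.get(key)
                if table is None:
                    table = compatible_pairs(gwin[i], freqs, window)
                    tables[key] = table
                _apply_table(sol, int(i), window, table, tau)
    return sol


def find_long_gaps(
    sol: PhasingSolution, l_max: int = 10
) -> list[tuple[int, int, int]]:
    """(individual, p_s, p_e) for every pair of consecutive heterozygous
    sites further apart than ``l_max`` (no single window covers both)."""
    out: list[tuple[int, int, int]] = []
    for i in range(sol.n):
        hets = sol.genotypes.het_sites(i)
        for p, q in zip(hets[:-1], hets[1:]):
            if q - p > l_max:
                out.append((i, int(p), int(q)))
    return out


def long_gap_correction(
    sol: PhasingSolution, individual: int, p_s: int, p_e: int
) -> bool:
    """Re-orient one long heterozygote gap by Hamming-distance voting.

    Every other haplotype row with known alleles at both ``p_s`` and ``p_e``
    is classified by those alleles into 00/11/01/10; its Hamming distance to
    the individual's genotype segment strictly between the two sites ('?'
    positions skipped) is added to its class sum.  The cis weight is the
    product of the 00 and 11 sums, the trans weight the product of the 01 and
    10 sums; an empty class makes its pattern's weight +inf.  Smaller weight
    (greater similarity) wins; if it contradicts the current phasing, the two
    rows exchange their suffixes from ``p_e`` rightward.  Returns whether a
    flip happened.
    """
    H = sol.haplotypes
    r1, r2 = 2 * individual, 2 * individual + 1
    target = sol.genotypes.cells[individual, p_s + 1 : p_e]
    tmask = target != MISSING
    sums = [0, 0, 0, 0]  # class index 2*allele(p_s) + allele(p_e)
    seen = [False, False, False, False]
    for j in range(H.shape[0]):
        if j == r1 or j == r2:
            continue
        a_s, a_e = int(H[j, p_s]), int(H[j, p_e])
        if a_s == MISSING or a_e == MISSING:
            continue
        seg = H[j, p_s + 1 : p_e]
        valid = tmask & (seg != MISSING)
        d = int(np.count_nonzero(seg[valid] != target[valid]))
        c = 2 * a_s + a_e
        sums[c] += d
        seen[c] = True
    inf = float("inf")
    w_cis = float(sums[0b00] * sums[0b11]) if seen[0b00] and seen[0b11] else inf
    w_trans = float(sums[0b01] * sums[0b10]) if seen[0b01] and seen[0b10] else inf
    if w_cis == w_trans:  # includes both +inf: keep the current phasing
        return False
    want_cis = w_cis < w_trans
    current_cis = H[r1, p_s] == H[r1, p_e]
    if want_cis == bool(current_cis):
        return False
    tmp = H[r1, p_e:].copy()
    H[r1, p_e:] = H[r2, p_e:]
    H[r2, p_e:] = tmp
    return True


def correct_long_gaps(sol: PhasingSolution, l_max: int = 10) -> int:
    """Run :func:`long_gap_correction` once per qualifying gap, left to right
    per individual; returns the number of flips applied."""
    flips = 0
    for i, p_s, p_e in find_long_gaps(sol, l_max):
        flips += long_gap_correction(sol, i, p_s, p_e)
    return flips
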