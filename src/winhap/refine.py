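"""Step 3 — missing-allele imputation and maximum-parsimony refinement.

Imputation: each residual '?' in a haplotype row is voted on by all other
rows inside a length-9 window centered on the missing column (truncated at
chromosome ends).  Rows carrying 0 at the column contribute their Hamming
distance to the target row to W0, rows carrying 1 to W1; the allele with the
*smaller* summed distance (greater similarity) wins, with ties and empty
classes falling back to the major allele 0.

Parsimony: the distinct-haplotype set is shrunk by accepting single
recombinations — exchanging the suffixes of an individual's two rows at a
heterozygous site — whenever the swap strictly decreases the number of
distinct haplotype rows in the whole solution.  At most one recombination is
accepted per individual per pass; passes repeat until none is accepted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .model import MISSING, PhasingSolution, hap_row, hap_str

__all__ = [
    "ImputationVote",
    "RecombinationMove",
    "impute_missing",
    "recombine_at",
    "parsimony_refine",
]


@dataclass(frozen=True)
class ImputationVote:
    """Summed similarity weights supporting allele 0 / allele 1 at one
    missing position (smaller distance = stronger support)."""

    w0: float
    w1: float


@dataclass(frozen=True)
class RecombinationMove:
    """An accepted suffix exchange: individual, 0-based switch site, and the
    (negative) change in the distinct-haplotype count."""

    individual: int
    site: int
    delta: int


def _vote(H: np.ndarray, row: int, col: int) -> ImputationVote:
    m = H.shape[1]
    lo, hi = max(0, col - 4), min(m, col + 5)
    win = np.arange(lo, hi)
    win = win[(win != col) & (H[row, win] != MISSING)]
    target = H[row, win]
    alleles = H[:, col]
    seg = H[:, win]
    diff = (seg != target) & (seg != MISSING)
    d = diff.sum(axis=1)
    cand = alleles != MISSING
    cand[row] = False
    class0 = cand & (alleles == 0)
    class1 = cand & (alleles == 1)
    inf = float("inf")
    w0 = float(d[class0].sum()) if class0.any() else inf
    w1 = float(d[class1].sum()) if class1.any() else inf
    return ImputationVote(w0, w1)


def impute_missing(sol: PhasingSolution) -> PhasingSolution:
    """Fill every '?' by windowed similarity voting; returns a new solution.

    Missing cells are processed in row-major order, so an allele imputed
    early participates in later votes.  Both rows of an individual are voted
    independently (the genotype cell is '?', so any resulting pair is legal).
    Non-missing cells are never altered.
    """
    out = sol.copy()
    H = out.haplotypes
    for row, col in zip(*np.nonzero(H == MISSING)):
        v = _vote(H, int(row), int(col))
        if v.w0 == v.w1 == float("inf"):
            H[row, col] = 0  # no informed voter anywhere: major allele
        else:
            H[row, col] = 0 if v.w0 <= v.w1 else 1
    return out


def recombine_at(h1, h2, k: int):
    """Exchange the suffixes of two haplotype rows at site ``k``.

    Prefixes ``[0, k)`` are kept, suffixes ``[k, m)`` swapped.  The switched
    site must be heterozygous (the two rows differ there), so compatibility
    with the genotype is preserved.  Applying the operation twice at the same
    site restores the input.  Accepts strings or int8 rows.
    """
    str_in = isinstance(h1, str)
    a = hap_row(h1) if isinstance(h1, str) else np.asarray(h1, dtype=np.int8)
    b = hap_row(h2) if isinstance(h2, str) else np.asarray(h2, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("haplotype length mismatch")
    if not 0 <= k < a.size:
        raise ValueError(f"switch site {k + 1} out of range")
    if a[k] == MISSING or b[k] == MISSING or a[k] == b[k]:
        raise ValueError(f"switched site {k + 1} must be heterozygous")
    na = np.concatenate([a[:k], b[k:]]).astype(np.int8)
    nb = np.concatenate([b[:k], a[k:]]).astype(np.int8)
    if str_in:
        return hap_str(na), hap_str(nb)
    return na, nb


def _distinct_delta(
    counter: Counter, removed: tuple[bytes, bytes], added: tuple[bytes, bytes]
) -> int:
    adj: dict[bytes, int] = {}
    delta = 0
    for key in removed:
        c = counter[key] + adj.get(key, 0)
        adj[key] = adj.get(key, 0) - 1
        if c == 1:
            delta -= 1
    for key in added:
        c = counter[key] + adj.get(key, 0)
        adj[key] = adj.get(key, 0) + 1
        if c == 0:
            delta += 1
    return delta


def parsimony_refine(
    sol: PhasingSolution,
    record: list[RecombinationMove] | None = None,
    max_passes: int | None = None,
) -> PhasingSolution:
    """Shrink the distinct-haplotype set with single recombinations.

    Each pass visits individuals in input order; for each, heterozygous
    sites are scanned left to right and the FIRST suffix exchange that
    strictly decreases the solution-wide distinct-haplotype count is applied
    (at most one per individual per pass).  The distinct count strictly
    decreases every accepting pass, so the procedure terminates.  Requires a
    fully imputed solution; returns a new one.
    """
    if sol.has_missing():
        raise ValueError("parsimony refinement requires a fully imputed solution")
    out = sol.copy()
    H = out.haplotypes
    counter: Counter = Counter(H[r].tobytes() for r in range(H.shape[0]))
    passes = 0
    while True:
        accepted_any = False
        for i in range(out.n):
            r1, r2 = H[2 * i], H[2 * i + 1]
            hets = np.flatnonzero(r1 != r2)
            if not hets.size:
                continue
            old1, old2 = r1.tobytes(), r2.tobytes()
            for k in hets:
                k = int(k)
                new1 = r1[:k].tobytes() + r2[k:].tobytes()
                new2 = r2[:k].tobytes() + r1[k:].tobytes()
                delta = _distinct_delta(counter, (old1, old2), (new1, new2))
                if delta < 0:
                    counter[old1] -= 1
                    counter[old2] -= 1
                    counter[new1] += 1
                    counter[new2] += 1
                    for key in (old1, old2):
                        if counter[key] == 0:
                            del counter[key]
                    tail = r1[k:].copy()
                    r1[k:] = r2[k:]
                    r2[k:] = tail
                    if record is not None:
                        record.append(RecombinationMove(i, k, delta))
                    accepted_any = True
                    break
        passes += 1
        if not accepted_any or (max_passes is not None and passes >= max_passes):
            break
    return out
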