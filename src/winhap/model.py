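"""Core containers for unphased genotypes and phased haplotypes, plus text I/O.

Encoding conventions used throughout the package
------------------------------------------------
A *genotype* cell takes one of four symbols: ``0`` (homozygous for the major
allele), ``1`` (homozygous minor), ``2`` (heterozygous) or ``?`` (missing).
A *haplotype* cell is ``0``, ``1`` or ``?``.  Internally both are stored as
``int8`` arrays with ``-1`` standing for ``?`` (constant :data:`MISSING`) and
``2`` for a heterozygote (constant :data:`HET`).

The text dialect is one individual per line, one character per SNP site, no
header and no separators; whitespace inside a line is tolerated and stripped.
Sites are 0-based internally; all user-facing messages are 1-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Union

import numpy as np

__all__ = [
    "MISSING",
    "HET",
    "FormatError",
    "GenotypeMatrix",
    "PhasingSolution",
    "EvalReport",
    "expand_pair",
    "read_genotype_matrix",
    "read_phasing",
    "write_phasing",
    "is_compatible",
    "assert_compatible",
    "geno_row",
    "geno_str",
    "hap_row",
    "hap_str",
]

MISSING: int = -1
HET: int = 2

_GENO_FROM_CHAR = {"0": 0, "1": 1, "2": HET, "?": MISSING}
_CHAR_FROM_GENO = {0: "0", 1: "1", HET: "2", MISSING: "?"}
_HAP_FROM_CHAR = {"0": 0, "1": 1, "?": MISSING}
_CHAR_FROM_HAP = {0: "0", 1: "1", MISSING: "?"}

Source = Union[str, os.PathLike, IO[str], Iterable[str]]


class FormatError(ValueError):
    """An input file violates the genotype/haplotype text dialect."""


def _row_from_str(s: str, mapping: dict, lineno: int | None = None) -> np.ndarray:
    out = np.empty(len(s), dtype=np.int8)
    for pos, ch in enumerate(s):
        try:
            out[pos] = mapping[ch]
        except KeyError:
            where = f" at line {lineno}," if lineno is not None else ""
            raise FormatError(
                f"illegal character {ch!r}{where} site {pos + 1}"
            ) from None
    return out


def geno_row(s: str) -> np.ndarray:
    """Parse a genotype string over ``{0,1,2,?}`` into an int8 row."""
    return _row_from_str(s, _GENO_FROM_CHAR)


def hap_row(s: str) -> np.ndarray:
    """Parse a haplotype string over ``{0,1,?}`` into an int8 row."""
    return _row_from_str(s, _HAP_FROM_CHAR)


def geno_str(row: np.ndarray) -> str:
    return "".join(_CHAR_FROM_GENO[int(v)] for v in row)


def hap_str(row: np.ndarray) -> str:
    return "".join(_CHAR_FROM_HAP[int(v)] for v in row)


@dataclass
class GenotypeMatrix:
    """``n`` individuals x ``m`` SNP sites of genotype symbols.

    ``cells`` is an ``(n, m)`` int8 array over ``{0, 1, HET, MISSING}``.
    """

    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.ndim != 2:
            raise ValueError("genotype cells must be a 2-D array")
        if self.cells.shape[0] < 1 or self.cells.shape[1] < 1:
            raise ValueError("genotype matrix needs at least 1 individual and 1 site")
        bad = ~np.isin(self.cells, (0, 1, HET, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"illegal genotype value {int(self.cells[i, j])} for "
                f"individual {i + 1}, site {j + 1}"
            )

    @property
    def n(self) -> int:
        return self.cells.shape[0]

    @property
    def m(self) -> int:
        return self.cells.shape[1]

    @classmethod
    def from_strings(cls, rows: Iterable[str]) -> "GenotypeMatrix":
        parsed = [geno_row(r) for r in rows]
        return cls(np.vstack(parsed))

    def to_strings(self) -> list[str]:
        return [geno_str(r) for r in self.cells]

    def het_sites(self, individual: int) -> np.ndarray:
        """0-based indices of the heterozygous sites of one individual."""
        return np.flatnonzero(self.cells[individual] == HET)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.cells.copy())


@dataclass
class PhasingSolution:
    """A working ``2n x m`` haplotype matrix; rows ``2i`` and ``2i+1`` resolve
    individual ``i`` of the attached :class:`GenotypeMatrix`."""

    haplotypes: np.ndarray
    genotypes: GenotypeMatrix

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D array")
        if self.haplotypes.shape != (2 * self.genotypes.n, self.genotypes.m):
            raise ValueError(
                f"haplotype matrix shape {self.haplotypes.shape} does not match "
                f"2x{self.genotypes.n} individuals x {self.genotypes.m} sites"
            )
        bad = ~np.isin(self.haplotypes, (0, 1, MISSING))
        if bad.any():
            r, j = np.argwhere(bad)[0]
            raise ValueError(
                f"illegal haplotype value {int(self.haplotypes[r, j])} in row "
                f"{r + 1}, site {j + 1}"
            )

    @property
    def n(self) -> int:
        return self.genotypes.n

    @property
    def m(self) -> int:
        return self.genotypes.m

    def pair(self, individual: int) -> tuple[np.ndarray, np.ndarray]:
        """The two haplotype rows of one individual (views, not copies)."""
        return self.haplotypes[2 * individual], self.haplotypes[2 * individual + 1]

    def expand(self, individual: int) -> np.ndarray:
        """Genotype row implied by the individual's current haplotype pair."""
        return expand_pair(*self.pair(individual))

    def has_missing(self) -> bool:
        return bool((self.haplotypes == MISSING).any())

    def distinct_haplotype_count(self) -> int:
        return len({row.tobytes() for row in self.haplotypes})

    def copy(self) -> "PhasingSolution":
        return PhasingSolution(self.haplotypes.copy(), self.genotypes)

    @classmethod
    def from_hap_strings(
        cls, rows: Iterable[str], genotypes: GenotypeMatrix | None = None
    ) -> "PhasingSolution":
        """Build a solution from haplotype strings; if no genotype matrix is
        given, derive one by expanding each consecutive pair of rows."""
        H = np.vstack([hap_row(r) for r in rows])
        if H.shape[0] % 2:
            raise ValueError("haplotype rows must come in pairs")
        if genotypes is None:
            pairs = [expand_pair(H[2 * i], H[2 * i + 1]) for i in range(H.shape[0] // 2)]
            genotypes = GenotypeMatrix(np.vstack(pairs))
        return cls(H, genotypes)

    def to_strings(self) -> list[str]:
        return [hap_str(r) for r in self.haplotypes]


@dataclass(frozen=True)
class EvalReport:
    """IER/SER accuracy report against ground-truth haplotypes.

    ``ier1``/``ser1`` exclude masked (missing) genotype cells from the
    comparison; ``ier2``/``ser2`` include them.  ``n_switch_errors`` and
    ``n_het_loci`` are the pooled counts behind ``ser2``.
    """

    ier1: float
    ier2: float
    ser1: float
    ser2: float
    n_switch_errors: int
    n_het_loci: int


def expand_pair(h1, h2):
    """Combine two haplotype rows into the genotype they imply.

    Per site: (0,0) -> 0, (1,1) -> 1, {0,1} -> 2, any '?' -> '?'.  The order
    of the two haplotypes is irrelevant.  Accepts strings or int8 rows and
    returns the same kind.
    """
    str_in = isinstance(h1, str)
    a = hap_row(h1) if isinstance(h1, str) else np.asarray(h1, dtype=np.int8)
    b = hap_row(h2) if isinstance(h2, str) else np.asarray(h2, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError(f"haplotype length mismatch: {a.size} vs {b.size}")
    out = np.where(
        (a == MISSING) | (b == MISSING),
        np.int8(MISSING),
        np.where(a == b, a, np.int8(HET)),
    ).astype(np.int8)
    return geno_str(out) if str_in else out


def _iter_lines(source: Source) -> Iterator[str]:
    if hasattr(source, "read"):
        yield from source  # type: ignore[misc]
    elif isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def read_genotype_matrix(source: Source) -> GenotypeMatrix:
    """Read a genotype matrix from a path, open text stream, or line iterable.

    Blank lines are ignored; whitespace between characters is stripped.
    Ragged rows and illegal characters raise :class:`FormatError` naming the
    offending line (1-based).
    """
    rows: list[np.ndarray] = []
    width: int | None = None
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        symbols = "".join(raw.split())
        if not symbols:
            continue
        row = _row_from_str(symbols, _GENO_FROM_CHAR, lineno)
        if width is None:
            width = row.size
        elif row.size != width:
            raise FormatError(
                f"ragged row at line {lineno}: expected {width} symbols, "
                f"got {row.size}"
            )
        rows.append(row)
    if not rows:
        raise FormatError("no genotype rows found")
    return GenotypeMatrix(np.vstack(rows))


def read_phasing(
    source: Source, genotypes: GenotypeMatrix | None = None
) -> PhasingSolution:
    """Read 2n haplotype lines (two consecutive lines per individual)."""
    rows: list[np.ndarray] = []
    width: int | None = None
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        symbols = "".join(raw.split())
        if not symbols:
            continue
        row = _row_from_str(symbols, _HAP_FROM_CHAR, lineno)
        if width is None:
            width = row.size
        elif row.size != width:
            raise FormatError(
                f"ragged row at line {lineno}: expected {width} symbols, "
                f"got {row.size}"
            )
        rows.append(row)
    if not rows:
        raise FormatError("no haplotype rows found")
    if len(rows) % 2:
        raise FormatError("haplotype file must contain an even number of rows")
    H = np.vstack(rows)
    if genotypes is None:
        pairs = [expand_pair(H[2 * i], H[2 * i + 1]) for i in range(H.shape[0] // 2)]
        genotypes = GenotypeMatrix(np.vstack(pairs))
    return PhasingSolution(H, genotypes)


def write_phasing(
    solution: PhasingSolution, sink: Union[str, os.PathLike, IO[str]], *,
    allow_missing: bool = False,
) -> None:
    """Write 2n haplotype lines, two consecutive lines per individual.

    By default the solution must be fully imputed (no ``?``); pass
    ``allow_missing=True`` to write residual ``?`` symbols.
    """
    if not allow_missing and solution.has_missing():
        r, j = np.argwhere(solution.haplotypes == MISSING)[0]
        raise ValueError(
            f"unresolved '?' in haplotype row {r + 1}, site {j + 1} "
            "(pass allow_missing=True to write it anyway)"
        )
    text = "\n".join(solution.to_strings()) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)  # type: ignore[union-attr]
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)


def is_compatible(sol: PhasingSolution) -> bool:
    """True iff the solution resolves its genotype matrix.

    Checks the two clauses of the phasing contract: at every non-missing
    genotype cell the haplotype pair expands back to the cell value, and a
    haplotype carries ``?`` only where the genotype itself is missing.
    """
    H, Gc = sol.haplotypes, sol.genotypes.cells
    h1, h2 = H[0::2], H[1::2]
    exp = np.where(
        (h1 == MISSING) | (h2 == MISSING),
        np.int8(MISSING),
        np.where(h1 == h2, h1, np.int8(HET)),
    )
    known = Gc != MISSING
    return bool(np.array_equal(exp[known], Gc[known]))


def assert_compatible(sol: PhasingSolution, stage: str = "") -> None:
    """Raise ``ValueError`` naming the first offending individual/site if the
    solution does not resolve its genotypes."""
    if is_compatible(sol):
        return
    for i in range(sol.n):
        exp = sol.expand(i)
        g = sol.genotypes.cells[i]
        known = g != MISSING
        bad = np.flatnonzero(known & (exp != g))
        if bad.size:
            j = int(bad[0])
            label = f" after {stage}" if stage else ""
            raise ValueError(
                f"incompatible phasing{label}: individual {i + 1}, site {j + 1} "
                f"expands to {_CHAR_FROM_GENO[int(exp[j])]} but genotype is "
                f"{_CHAR_FROM_GENO[int(g[j])]}"
            )
    raise ValueError("incompatible phasing")  # pragma: no cover
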