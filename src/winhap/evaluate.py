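"""Phasing accuracy metrics: individual error rate and switch error rate.

IER is the fraction of individuals whose unordered haplotype pair differs
from the truth anywhere over the evaluated sites.  SER is the pooled number
of switch errors — flips of the predicted orientation relative to truth
between consecutive evaluated heterozygous sites — divided by the pooled
number of evaluated heterozygous loci.

Each metric comes in two variants when genotypes were masked: variant 1
excludes masked ('?') cells from the evaluation, variant 2 includes them —
so variant 2 additionally penalizes imputation mistakes.
"""

from __future__ import annotations

import numpy as np

from .model import MISSING, EvalReport, GenotypeMatrix, PhasingSolution

__all__ = ["individual_error_rate", "switch_error_rate", "evaluate", "EvalReport"]


def _check(pred: PhasingSolution, truth: PhasingSolution, mask: GenotypeMatrix):
    if (pred.n, pred.m) != (truth.n, truth.m):
        raise ValueError(
            f"prediction is {pred.n}x{pred.m} but truth is {truth.n}x{truth.m}"
        )
    if truth.has_missing():
        raise ValueError("ground truth must not contain '?'")
    if (mask.n, mask.m) != (pred.n, pred.m):
        raise ValueError("mask shape does not match the solutions")


def individual_error_rate(
    pred: PhasingSolution,
    truth: PhasingSolution,
    include_missing: bool = True,
    mask: GenotypeMatrix | None = None,
) -> float:
    """Fraction of individuals whose unordered haplotype pair is wrong.

    With ``include_missing=False`` only sites that are non-'?' in ``mask``
    (default: the prediction's genotype matrix) are compared.
    """
    mask = mask if mask is not None else pred.genotypes
    _check(pred, truth, mask)
    P1, P2 = pred.haplotypes[0::2], pred.haplotypes[1::2]
    T1, T2 = truth.haplotypes[0::2], truth.haplotypes[1::2]
    if include_missing:
        ignore = np.zeros_like(P1, dtype=bool)
    else:
        ignore = mask.cells == MISSING
    direct = np.all(((P1 == T1) & (P2 == T2)) | ignore, axis=1)
    crossed = np.all(((P1 == T2) & (P2 == T1)) | ignore, axis=1)
    errors = int(np.count_nonzero(~(direct | crossed)))
    return errors / pred.n


def switch_error_rate(
    pred: PhasingSolution,
    truth: PhasingSolution,
    include_missing: bool = True,
    mask: GenotypeMatrix | None = None,
) -> tuple[float, int, int]:
    """Pooled switch error rate; returns ``(ser, n_switch_errors, n_het_loci)``.

    Heterozygous loci are taken from the truth.  Per individual the first
    evaluated heterozygous site anchors the orientation and contributes no
    error; each later one contributes a switch error when the predicted
    orientation relative to truth flips.  Sites where the prediction is not
    heterozygous (possible only at masked cells) cannot be oriented and are
    skipped in the chain, but still count as heterozygous loci.  The
    denominator pools heterozygous loci over all individuals; an individual
    with none contributes nothing to either sum.
    """
    mask = mask if mask is not None else pred.genotypes
    _check(pred, truth, mask)
    n_switch = 0
    n_het = 0
    for i in range(pred.n):
        p1, p2 = pred.pair(i)
        t1, t2 = truth.pair(i)
        het = t1 != t2
        if not include_missing:
            het &= mask.cells[i] != MISSING
        sites = np.flatnonzero(het)
        n_het += sites.size
        prev = -1
        for j in sites:
            a, b = int(p1[j]), int(p2[j])
            if a == MISSING or b == MISSING or a == b:
                continue
            orient = 0 if a == t1[j] else 1
            if prev >= 0 and orient != prev:
                n_switch += 1
            prev = orient
    ser = n_switch / n_het if n_het else 0.0
    return ser, n_switch, n_het


def evaluate(
    pred: PhasingSolution,
    truth: PhasingSolution,
    mask: GenotypeMatrix | None = None,
) -> EvalReport:
    """Bundle IER1/IER2/SER1/SER2 (1 = excluding masked cells, 2 = including).

    The raw counts stored in the report are those of the include-missing
    variant (SER2).
    """
    mask = mask if mask is not None else pred.genotypes
    ier1 = individual_error_rate(pred, truth, include_missing=False, mask=mask)
    ier2 = individual_error_rate(pred, truth, include_missing=True, mask=mask)
    ser1, _, _ = switch_error_rate(pred, truth, include_missing=False, mask=mask)
    ser2, n_sw, n_het = switch_error_rate(pred, truth, include_missing=True, mask=mask)
    return EvalReport(ier1, ier2, ser1, ser2, n_sw, n_het)
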