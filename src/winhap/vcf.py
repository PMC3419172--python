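"""VCF adapters: unphased diploid GT fields <-> the internal genotype matrix.

Only biallelic sites are supported; multi-allelic records are skipped with a
logged warning on reading and on writing alike, so the site indices of a
matrix read from a VCF always line up with the records written back from it.
"""

from __future__ import annotations

import logging
import os
from typing import Union

import numpy as np
import pysam

from .model import HET, MISSING, FormatError, GenotypeMatrix, PhasingSolution

__all__ = ["vcf_to_matrix", "solution_to_vcf"]

log = logging.getLogger(__name__)

PathLike = Union[str, os.PathLike]


def _is_biallelic(rec) -> bool:
    return len(rec.alts or ()) == 1


def vcf_to_matrix(path: PathLike) -> GenotypeMatrix:
    """Read unphased diploid GT fields into a genotype matrix.

    ``0/0 -> 0``, ``1/1 -> 1``, ``0/1`` or ``1/0 -> 2``, ``./. -> ?``.
    Sites become columns in record order; samples become rows.
    """
    with pysam.VariantFile(str(path)) as vf:
        if "GT" not in vf.header.formats:
            raise FormatError("VCF has no GT format field")
        samples = list(vf.header.samples)
        if not samples:
            raise FormatError("VCF has no sample columns")
        columns: list[np.ndarray] = []
        for rec in vf:
            if not _is_biallelic(rec):
                log.warning(
                    "skipping multi-allelic site %s:%d", rec.chrom, rec.pos
                )
                continue
            col = np.full(len(samples), MISSING, dtype=np.int8)
            for k, sample in enumerate(rec.samples.values()):
                gt = sample.get("GT")
                if gt is None or len(gt) != 2 or None in gt:
                    continue
                a, b = gt
                if a == b == 0:
                    col[k] = 0
                elif a == b == 1:
                    col[k] = 1
                elif {a, b} == {0, 1}:
                    col[k] = HET
                else:
                    raise FormatError(
                        f"unexpected allele index in GT at {rec.chrom}:{rec.pos}"
                    )
            columns.append(col)
    if not columns:
        raise FormatError("VCF contains no usable biallelic sites")
    return GenotypeMatrix(np.column_stack(columns))


def solution_to_vcf(
    solution: PhasingSolution,
    template: PathLike,
    out: PathLike,
    *,
    allow_missing: bool = False,
) -> None:
    """Write a phased VCF (``a|b`` GT fields) using ``template`` for all site
    and sample metadata.

    The template is normally the file the genotype matrix was read from; its
    biallelic records, in order, must match the solution's sites.
    """
    if not allow_missing and solution.has_missing():
        raise ValueError(
            "solution contains unresolved '?' (pass allow_missing=True)"
        )
    with pysam.VariantFile(str(template)) as vf:
        samples = list(vf.header.samples)
        if len(samples) != solution.n:
            raise ValueError(
                f"template has {len(samples)} samples but solution phases "
                f"{solution.n} individuals"
            )
        h1 = solution.haplotypes[0::2]
        h2 = solution.haplotypes[1::2]
        with pysam.VariantFile(str(out), "w", header=vf.header) as out_vf:
            site = 0
            for rec in vf:
                if not _is_biallelic(rec):
                    log.warning(
                        "skipping multi-allelic site %s:%d", rec.chrom, rec.pos
                    )
                    continue
                if site >= solution.m:
                    raise ValueError(
                        "template has more biallelic sites than the solution"
                    )
                for k, sample in enumerate(rec.samples.values()):
                    a, b = int(h1[k, site]), int(h2[k, site])
                    sample["GT"] = (
                        None if a == MISSING else a,
                        None if b == MISSING else b,
                    )
                    sample.phased = True
                out_vf.write(rec)
                site += 1
    if site != solution.m:
        raise ValueError(
            f"template has {site} biallelic sites but the solution has "
            f"{solution.m}"
        )
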