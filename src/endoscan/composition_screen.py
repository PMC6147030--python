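"""Codon-position GC statistics and the 1.5-delta compositional screen.

Horizontally acquired genes tend to retain the nucleotide composition of
their donor.  The screen computes, for every gene, the GC fraction at the
three codon positions and over the whole gene (GC1, GC2, GC3, GCT), fits a
genome-wide background (mean and standard deviation delta of each statistic,
over genes of at least 300 bp), and flags a gene as compositionally atypical
when either

* its GCT deviates from the background mean by more than ``k * delta`` (k=1.5), or
* its GC1 and GC3 deviations share the same sign and at least one of them
  exceeds ``k`` times its delta.

Short genes are excluded only from the background fit; they remain eligible
for flagging.  Ambiguous bases (N) are excluded position-wise from both
numerator and denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome_io import GeneModel, GenomeSequence, ValidationError, extract_cds


@dataclass(frozen=True)
class CodonGCProfile:
    """Per-gene GC fractions at codon positions 1, 2, 3 and overall."""

    gene_id: str
    length_bp: int
    gc1: float
    gc2: float
    gc3: float
    gct: float


@dataclass(frozen=True)
class BackgroundModel:
    """Genome-wide means and standard deviations (delta) of the four GC statistics."""

    mean1: float
    mean2: float
    mean3: float
    meanT: float
    delta1: float
    delta2: float
    delta3: float
    deltaT: float
    n_genes_used: int
    min_len_bp: int


@dataclass(frozen=True)
class AtypicalCall:
    """Flag decision for one gene with its signed deviations (d1, d2, d3, dT)."""

    gene_id: str
    flagged: bool
    rule_total: bool
    rule_positions: bool
    deviations: tuple[float, float, float, float]


def codon_gc(cds: str, gene_id: str = "") -> CodonGCProfile:
    """GC fractions by codon position for a coding-strand sequence.

    A trailing partial codon is truncated with a warning; N positions drop
    out of both numerator and denominator.
    """
    seq = cds.upper()
    n = len(seq)
    if n < 3:
        raise ValidationError(f"gene {gene_id!r}: sequence shorter than one codon")
    if n % 3 != 0:
        warnings.warn(
            f"gene {gene_id!r}: length {n} not a multiple of 3; trailing partial codon ignored",
            stacklevel=2,
        )
        seq = seq[: 3 * (n // 3)]
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    is_gc = (arr == b"G") | (arr == b"C")
    is_n = arr == b"N"
    gc_pos: list[float] = []
    total_gc = 0
    total_def = 0
    for k in range(3):
        gc_k = int(is_gc[k::3].sum())
        defined_k = int((~is_n[k::3]).sum())
        if defined_k == 0:
            raise ValidationError(f"gene {gene_id!r}: codon position {k + 1} entirely ambiguous")
        gc_pos.append(gc_k / defined_k)
        total_gc += gc_k
        total_def += defined_k
    return CodonGCProfile(
        gene_id=gene_id,
        length_bp=n,
        gc1=gc_pos[0],
        gc2=gc_pos[1],
        gc3=gc_pos[2],
        gct=total_gc / total_def,
    )


def profiles_from_genome(
    genome: GenomeSequence, genes: Sequence[GeneModel]
) -> list[CodonGCProfile]:
    """Convenience: extract each gene's coding-strand CDS and profile it."""
    return [codon_gc(extract_cds(genome, g), gene_id=g.gene_id) for g in genes]


def fit_background(
    profiles: Iterable[CodonGCProfile], min_len_bp: int = 300
) -> BackgroundModel:
    """Fit per-statistic means and sample standard deviations over genes >= ``min_len_bp``.

    Shorter genes are more likely to be foreign, so they are excluded from
    the fit (they are still screened afterwards).
    """
    # sorted so the fit is exactly invariant to input order (float summation)
    used = sorted(
        (p for p in profiles if p.length_bp >= min_len_bp), key=lambda p: p.gene_id
    )
    if len(used) < 2:
        raise ValidationError(
            f"background fit needs >=2 genes of length >= {min_len_bp} bp, found {len(used)}"
        )
    mat = np.array([[p.gc1, p.gc2, p.gc3, p.gct] for p in used])
    means = mat.mean(axis=0)
    deltas = mat.std(axis=0, ddof=1)
    return BackgroundModel(
        mean1=float(means[0]),
        mean2=float(means[1]),
        mean3=float(means[2]),
        meanT=float(means[3]),
        delta1=float(deltas[0]),
        delta2=float(deltas[1]),
        delta3=float(deltas[2]),
        deltaT=float(deltas[3]),
        n_genes_used=len(used),
        min_len_bp=min_len_bp,
    )


def flag_gene(profile: CodonGCProfile, model: BackgroundModel, k: float = 1.5) -> AtypicalCall:
    """Apply the two 1.5-delta rules to one gene.

    All comparisons are strict (">"), so with a degenerate zero delta any
    nonzero deviation flags.  A zero deviation at position 1 or 3 never
    satisfies the same-sign rule.
    """
    d1 = profile.gc1 - model.mean1
    d2 = profile.gc2 - model.mean2
    d3 = profile.gc3 - model.mean3
    dT = profile.gct - model.meanT
    rule_total = abs(dT) > k * model.deltaT
    same_sign = (d1 > 0 and d3 > 0) or (d1 < 0 and d3 < 0)
    rule_positions = same_sign and (abs(d1) > k * model.delta1 or abs(d3) > k * model.delta3)
    return AtypicalCall(
        gene_id=profile.gene_id,
        flagged=rule_total or rule_positions,
        rule_total=rule_total,
        rule_positions=rule_positions,
        deviations=(d1, d2, d3, dT),
    )


def screen_profiles(
    profiles: Sequence[CodonGCProfile],
    min_len_bp: int = 300,
    k: float = 1.5,
    model: BackgroundModel | None = None,
) -> tuple[BackgroundModel, list[AtypicalCall]]:
    """Fit the background (unless given) and flag every profile against it."""
    if model is None:
        model = fit_background(profiles, min_len_bp=min_len_bp)
    calls = [flag_gene(p, model, k=k) for p in profiles]
    return model, calls
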