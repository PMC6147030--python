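"""Genome-level descriptive statistics.

* GC content over unambiguous bases.
* Coding density as the sum of annotated gene lengths over genome length
  (overlapping genes count twice; this matches the CDS-count x mean-length
  arithmetic used in genome tables).
* Self-alignment redundancy: fraction of the genome covered by
  high-identity self-alignments other than the trivial full-length hit.
* Fragment-based two-way ANI in the Goris convention: consecutive 1020-bp
  fragments of one genome are aligned against the other; fragments passing
  30% identity / 70% alignable-coverage contribute their identity, and the
  two directions are averaged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .genome_io import GeneModel, GenomeSequence, ValidationError


@dataclass(frozen=True)
class SelfAlignment:
    """One self-search alignment; coordinates are 1-based inclusive."""

    qstart: int
    qend: int
    sstart: int
    send: int
    pct_identity: float
    evalue: float


@dataclass(frozen=True)
class RedundancyResult:
    genome_id: str
    covered_bp: int
    genome_len: int
    redundancy_pct: float
    intervals: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class AniResult:
    genome_a: str
    genome_b: str
    ani_pct: float
    n_fragments_used: int
    fragment_len: int


def gc_content(seq: str) -> float:
    """(G+C) over unambiguous bases, percent."""
    if not seq:
        raise ValidationError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    defined = len(seq) - seq.count("N")
    if defined == 0:
        raise ValidationError("sequence is entirely ambiguous")
    return gc / defined * 100.0


def coding_density(genes: Iterable[GeneModel], genome_len: int) -> float:
    """Sum of gene lengths over genome length, percent (overlaps counted twice)."""
    if genome_len <= 0:
        raise ValidationError("genome length must be positive")
    total = sum(g.length_bp for g in genes)
    return total / genome_len * 100.0


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def self_redundancy(
    alignments: Sequence[SelfAlignment],
    genome_len: int,
    genome_id: str = "",
    min_identity: float = 95.0,
    max_evalue: float = 1e-20,
) -> RedundancyResult:
    """Merged query-side coverage of non-trivial self-alignments over genome length.

    The trivial full-diagonal hit (identical query and subject intervals) is
    discarded; remaining alignments must exceed ``min_identity`` (strict,
    "over 95%") and pass the e-value cutoff.  Both copies of a repeat
    contribute coverage.
    """
    keep: list[tuple[int, int]] = []
    for a in alignments:
        if not (1 <= a.qstart <= a.qend <= genome_len):
            raise ValidationError(f"alignment interval {a.qstart}..{a.qend} out of range 1..{genome_len}")
        if (a.qstart, a.qend) == (a.sstart, a.send):
            continue
        if a.pct_identity > min_identity and a.evalue <= max_evalue:
            keep.append((a.qstart, a.qend))
    merged = merge_intervals(keep)
    covered = sum(e - s + 1 for s, e in merged)
    return RedundancyResult(
        genome_id=genome_id,
        covered_bp=covered,
        genome_len=genome_len,
        redundancy_pct=covered / genome_len * 100.0,
        intervals=tuple(merged),
    )


def find_self_repeats(
    seq: str, min_len: int = 100, k: int = 32, max_occ: int = 50
) -> list[SelfAlignment]:
    """Exact repeats of length >= ``min_len`` found by k-mer diagonal chaining.

    Serves as the internal self-aligner: every maximal run of co-diagonal
    exact k-mer matches (off the trivial diagonal) becomes a 100%-identity
    alignment with e-value 0.  K-mers occurring more than ``max_occ`` times
    are skipped, so extremely high-copy repeats are underestimated.
    """
    n = len(seq)
    index: dict[str, list[int]] = {}
    for i in range(0, n - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    # seed positions per diagonal (offset = j - i), ordered pairs i != j
    diagonals: dict[int, list[int]] = {}
    for positions in index.values():
        if len(positions) < 2 or len(positions) > max_occ:
            continue
        for i in positions:
            for j in positions:
                if i != j:
                    diagonals.setdefault(j - i, []).append(i)
    out: list[SelfAlignment] = []
    for diag, starts in diagonals.items():
        starts = sorted(set(starts))
        run_start = starts[0]
        prev = starts[0]
        runs: list[tuple[int, int]] = []
        for s in starts[1:]:
            if s == prev + 1:
                prev = s
                continue
            runs.append((run_start, prev))
            run_start = prev = s
        runs.append((run_start, prev))
        for s0, s1 in runs:
            length = s1 - s0 + k
            if length >= min_len:
                out.append(
                    SelfAlignment(
                        qstart=s0 + 1,
                        qend=s0 + length,
                        sstart=s0 + diag + 1,
                        send=s0 + diag + length,
                        pct_identity=100.0,
                        evalue=0.0,
                    )
                )
    out.sort(key=lambda a: (a.qstart, a.qend, a.sstart))
    return out


def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(matches, alignment_columns, query_consumed) from an extended cigar."""
    matches = columns = query = 0
    for num, op in re.findall(r"(\d+)([=XIDM])", cigar):
        num = int(num)
        columns += num
        if op == "=":
            matches += num
            query += num
        elif op in ("X", "M"):
            query += num
        elif op == "I":  # insertion relative to target consumes query
            query += num
    return matches, columns, query


def _kmer_index(seq: str, k: int, step: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(0, len(seq) - k + 1, step):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _one_way_ani(
    query: str,
    target: str,
    fragment_len: int,
    min_frag_identity: float,
    min_frag_coverage: float,
    seed_k: int = 16,
) -> tuple[list[float], int]:
    """Identities of accepted query fragments against target (k-mer seeded)."""
    index = _kmer_index(target, seed_k, step=1)
    identities: list[float] = []
    n_fragments = len(query) // fragment_len
    for f in range(n_fragments):
        frag = query[f * fragment_len : (f + 1) * fragment_len]
        votes: dict[int, int] = {}
        for off in range(0, fragment_len - seed_k + 1, seed_k):
            for pos in index.get(frag[off : off + seed_k], ())[:20]:
                diag = pos - off
                votes[diag] = votes.get(diag, 0) + 1
        if not votes:
            continue  # unalignable fragment: rejected
        best_diag = max(votes, key=lambda d: (votes[d], -abs(d)))
        pad = 100
        w_start = max(0, best_diag - pad)
        w_end = min(len(target), best_diag + fragment_len + pad)
        window = target[w_start:w_end]
        res = edlib.align(frag, window, mode="HW", task="path")
        matches, columns, query_used = _cigar_stats(res["cigar"])
        if columns == 0:
            continue
        identity = matches / columns * 100.0
        coverage = query_used / fragment_len * 100.0
        if identity >= min_frag_identity and coverage >= min_frag_coverage:
            identities.append(identity)
    return identities, n_fragments


def ani(
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    fragment_len: int = 1020,
    min_frag_identity: float = 30.0,
    min_frag_coverage: float = 70.0,
) -> AniResult:
    """Two-way fragment-based average nucleotide identity."""
    if genome_a.length_bp < fragment_len or genome_b.length_bp < fragment_len:
        raise ValidationError(f"both genomes must be at least {fragment_len} bp")
    ids_ab, _ = _one_way_ani(genome_a.seq, genome_b.seq, fragment_len, min_frag_identity, min_frag_coverage)
    ids_ba, _ = _one_way_ani(genome_b.seq, genome_a.seq, fragment_len, min_frag_identity, min_frag_coverage)
    if not ids_ab or not ids_ba:
        raise ValidationError(
            f"ANI undefined: no accepted fragments between {genome_a.id!r} and {genome_b.id!r}"
        )
    two_way = (float(np.mean(ids_ab)) + float(np.mean(ids_ba))) / 2.0
    return AniResult(
        genome_a=genome_a.id,
        genome_b=genome_b.id,
        ani_pct=two_way,
        n_fragments_used=len(ids_ab) + len(ids_ba),
        fragment_len=fragment_len,
    )


def read_self_alignments(path) -> list[SelfAlignment]:
    """Read a self-alignment TSV: qstart, qend, sstart, send, identity, evalue."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 6:
                raise ValidationError(f"{path}:{lineno}: expected 6 columns, found {len(cols)}")
            out.append(
                SelfAlignment(
                    qstart=int(cols[0]),
                    qend=int(cols[1]),
                    sstart=int(cols[2]),
                    send=int(cols[3]),
                    pct_identity=float(cols[4]),
                    evalue=float(cols[5]),
                )
            )
    return out
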