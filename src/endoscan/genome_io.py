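"""Readers, writers and domain records for the plain-text formats the pipeline touches.

Sequences travel as FASTA (via Biopython), gene models as GFF3 ``CDS`` rows,
similarity hits as 14-column tab-separated tables (the 12 classic tabular
BLAST columns plus query coverage and a semicolon-delimited taxonomy
lineage), ortholog maps as two-column TSV and trees as Newick (via dendropy).

Coordinates follow the GFF3 convention throughout: 1-based, inclusive on
both ends.  Conversion to half-open indexing happens only inside functions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq


class ParseError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


_DNA_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class GenomeSequence:
    """A contig or chromosome; uppercase DNA over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("genome sequence id must be non-empty")
        bad = set(self.seq) - _DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: 1-based inclusive coordinates on a contig."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid coordinates {self.start}..{self.end}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HitRecord:
    """One similarity hit with alignment quality and subject taxonomy."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    evalue: float
    bitscore: float
    query_coverage: float
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: identity out of range")
        if not (0.0 <= self.query_coverage <= 100.0):
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: coverage out of range")
        if self.evalue < 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: negative e-value")
        if not self.lineage:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: empty lineage")

    @property
    def subject_genome(self) -> str:
        """Genome label encoded in the subject id as ``genome|gene``, else the id itself."""
        return self.subject_id.split("|", 1)[0]


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read FASTA records as uppercase DNA; duplicate ids are rejected."""
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), 1):
        if not rec.id:
            raise ParseError(f"{path}: record {i} has an empty header")
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(id=rec.id, seq=str(rec.seq).upper()))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _gff_attribute(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def read_gff(path: str | Path, feature_type: str = "CDS") -> list[GeneModel]:
    """Read gene models from GFF3 rows of ``feature_type``.

    The gene id is taken from the ``ID=`` attribute (fallback ``locus_tag=``).
    Ids must be unique within the file.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, found {len(cols)}")
            if cols[2] != feature_type:
                continue
            gene_id = _gff_attribute(cols[8], "ID") or _gff_attribute(cols[8], "locus_tag")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: {feature_type} row lacks ID/locus_tag attribute")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id=gene_id, contig=cols[0], start=start, end=end, strand=cols[6]))
    return genes


def write_gff(genes: Iterable[GeneModel], path: str | Path, source: str = "endoscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\t{source}\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\tID={g.gene_id}\n"
            )


def extract_cds(genome: GenomeSequence, gene: GeneModel) -> str:
    """Coding-strand sequence of ``gene``: the slice for '+', its reverse complement for '-'."""
    if gene.end > genome.length_bp:
        raise ValidationError(
            f"gene {gene.gene_id!r} ({gene.start}..{gene.end}) exceeds contig "
            f"{genome.id!r} length {genome.length_bp}"
        )
    sub = genome.seq[gene.start - 1 : gene.end]
    if gene.strand == "-":
        return str(Seq(sub).reverse_complement())
    return sub


_HIT_COLUMNS = 14  # 12 tabular-BLAST columns + query coverage + lineage


def parse_hit_line(line: str, where: str = "<line>") -> HitRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) != _HIT_COLUMNS:
        raise ParseError(f"{where}: expected {_HIT_COLUMNS} columns, found {len(cols)}")
    try:
        pct_identity = float(cols[2])
        aln_len = int(cols[3])
        evalue = float(cols[10])
        bitscore = float(cols[11])
        query_coverage = float(cols[12])
    except ValueError as exc:
        raise ParseError(f"{where}: non-numeric field ({exc})") from exc
    lineage = tuple(t.strip() for t in cols[13].split(";") if t.strip())
    return HitRecord(
        query_id=cols[0],
        subject_id=cols[1],
        pct_identity=pct_identity,
        aln_len=aln_len,
        evalue=evalue,
        bitscore=bitscore,
        query_coverage=query_coverage,
        lineage=lineage,
    )


def read_hits(path: str | Path) -> dict[str, list[HitRecord]]:
    """Read a hit table grouped per query, preserving file order within each query."""
    grouped: dict[str, list[HitRecord]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            rec = parse_hit_line(line, where=f"{path}:{lineno}")
            grouped.setdefault(rec.query_id, []).append(rec)
    return grouped


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_len),
                        "0",  # mismatches / gap opens / coordinates are not
                        "0",  # consumed downstream; placeholders keep the
                        "1",  # 14-column dialect intact
                        str(h.aln_len),
                        "1",
                        str(h.aln_len),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                        f"{h.query_coverage:.2f}",
                        ";".join(h.lineage),
                    ]
                )
                + "\n"
            )


def read_ortholog_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read ``gene_id<TAB>comma,separated,genome,labels`` (second field may be empty)."""
    mapping: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, found {len(cols)}")
            gene_id = cols[0]
            if gene_id in mapping:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            labels = frozenset(t for t in cols[1].split(",") if t)
            mapping[gene_id] = labels
    return mapping


def write_ortholog_map(mapping: dict[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id in sorted(mapping):
            fh.write(f"{gene_id}\t{','.join(sorted(mapping[gene_id]))}\n")


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a Newick tree from a path or a literal string; leaf labels must be unique."""
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"tree leaf labels must be unique: {exc}") from exc
    except Exception as exc:
        raise ParseError(f"invalid newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise ValidationError("tree must have at least 2 leaves")
    if len(set(labels)) != len(labels):
        raise ValidationError("tree leaf labels must be unique")
    return tree
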