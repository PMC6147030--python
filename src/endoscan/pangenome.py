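"""Protein clustering across genomes and core/shared/specific partitioning.

Clustering mirrors BLASTClust semantics: pairwise local alignments are
thresholded on identity and on coverage of the shorter member, and clusters
are the single-linkage connected components of the resulting graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import ValidationError

Member = tuple[str, str]  # (genome_label, gene_id)


@dataclass(frozen=True)
class SimilarityEdge:
    gene_a: Member
    gene_b: Member
    pct_identity: float
    coverage: float  # of the shorter member, percent


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    members: frozenset[Member]
    category: str | None = None  # "core" | "shared" | "specific"

    @property
    def genomes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.members)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_pair(seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None) -> tuple[float, float]:
    """Local-alignment identity and shorter-sequence coverage (both percent)."""
    if not seq_a or not seq_b:
        raise ValidationError("empty protein sequence")
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    identities = counts.identities
    if columns == 0:
        return 0.0, 0.0
    identity = identities / columns * 100.0
    coverage = columns / min(len(seq_a), len(seq_b)) * 100.0
    return identity, coverage


def pairwise_similarity(proteins: Mapping[Member, str]) -> list[SimilarityEdge]:
    """All-vs-all local alignment of a protein set (small inputs; no prefilter)."""
    aligner = _make_aligner()
    members = sorted(proteins)
    edges: list[SimilarityEdge] = []
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            identity, coverage = align_pair(proteins[a], proteins[b], aligner)
            edges.append(SimilarityEdge(gene_a=a, gene_b=b, pct_identity=identity, coverage=coverage))
    return edges


def cluster(
    edges: Iterable[SimilarityEdge],
    min_identity: float = 50.0,
    min_coverage: float = 70.0,
    members: Iterable[Member] = (),
) -> list[GeneCluster]:
    """Single-linkage components over edges passing both thresholds.

    ``members`` may supply genes with no edge at all (they become
    singletons); nodes of sub-threshold edges are kept as singletons too.
    Cluster ids are assigned by the sorted smallest member of each component.
    """
    graph: nx.Graph = nx.Graph()
    for m in members:
        graph.add_node(m)
    for e in edges:
        graph.add_node(e.gene_a)
        graph.add_node(e.gene_b)
        if e.pct_identity >= min_identity and e.coverage >= min_coverage:
            graph.add_edge(e.gene_a, e.gene_b)
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    width = max(4, len(str(len(components))))
    return [
        GeneCluster(cluster_id=f"CL{i:0{width}d}", members=frozenset(comp))
        for i, comp in enumerate(sorted(components, key=min), 1)
    ]


def categorize(clusters: Sequence[GeneCluster], genomes: Iterable[str]) -> list[GeneCluster]:
    """Assign core (all genomes) / shared (>1, not all) / specific (exactly 1)."""
    universe = frozenset(genomes)
    out = []
    for cl in clusters:
        unknown = cl.genomes - universe
        if unknown:
            raise ValidationError(f"cluster {cl.cluster_id}: unknown genome labels {sorted(unknown)}")
        k = len(cl.genomes)
        category = "core" if cl.genomes == universe else ("specific" if k == 1 else "shared")
        out.append(GeneCluster(cluster_id=cl.cluster_id, members=cl.members, category=category))
    return out


def partition(
    clusters: Sequence[GeneCluster],
    genomes: Iterable[str] = ("cSfur", "cEper1", "cBtQ1"),
) -> pd.DataFrame:
    """Per-genome counts and percentages of core/shared/specific clusters.

    The percentage for a genome and category is the number of that genome's
    clusters in the category over the number of clusters containing the
    genome, times 100 (2 decimals).
    """
    universe = sorted(set(genomes))
    clusters = categorize(clusters, universe)
    rows = []
    for genome in universe:
        containing = [cl for cl in clusters if genome in cl.genomes]
        total = len(containing)
        counts = {cat: sum(1 for cl in containing if cl.category == cat) for cat in ("core", "shared", "specific")}
        for cat in ("core", "shared", "specific"):
            rows.append(
                {
                    "genome": genome,
                    "category": cat,
                    "n_clusters": counts[cat],
                    "n_total": total,
                    "pct": round(counts[cat] / total * 100, 2) if total else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["genome", "category", "n_clusters", "n_total", "pct"])


def clusters_to_frame(clusters: Sequence[GeneCluster]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": cl.cluster_id,
            "category": cl.category or "",
            "members": ",".join(f"{g}|{x}" for g, x in sorted(cl.members)),
        }
        for cl in clusters
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "category", "members"])
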