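"""Taxonomic-discordance screen, evidence combination, donor and age calls.

A gene is a taxonomy candidate when its filtered similarity hits exist and
none of the top hits (at most 10) comes from the genome's own phylum-level
group (Bacteroidetes for *Cardinium*).  Hits against the two sister strains
are excluded before ranking.  Genes positive under BOTH the compositional
and the taxonomic screen are horizontal-transfer candidates; each candidate
can then receive a donor (nearest tree neighbor by node count) and an age
class (ancient if an ortholog exists in either sister genome, else recent).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .genome_io import HitRecord, ValidationError, read_newick


@dataclass(frozen=True)
class TaxonomyCall:
    gene_id: str
    is_candidate: bool
    n_qualified_hits: int
    top_hits_examined: int


@dataclass(frozen=True)
class HgtCandidate:
    """A gene supported by both evidence lines; donor/age may be filled later."""

    gene_id: str
    donor_taxon: str | None = None
    age: str | None = None  # "ancient" | "recent"


def qualify_hits(
    hits: Sequence[HitRecord],
    min_identity: float = 50.0,
    max_evalue: float = 1e-5,
    min_coverage: float = 70.0,
    exclude_subject_genomes: Iterable[str] = (),
) -> list[HitRecord]:
    """Filter one gene's hits by the identity/e-value/coverage cutoffs and sort.

    Cutoffs are inclusive (identity >= 50, coverage >= 70, e-value <= 1e-5).
    Hits whose subject belongs to an excluded genome (the sister strains)
    are removed.  Order: bitscore desc, e-value asc, identity desc,
    subject_id lexicographic.
    """
    excluded = set(exclude_subject_genomes)
    kept = [
        h
        for h in hits
        if h.pct_identity >= min_identity
        and h.evalue <= max_evalue
        and h.query_coverage >= min_coverage
        and h.subject_genome not in excluded
    ]
    kept.sort(key=lambda h: (-h.bitscore, h.evalue, -h.pct_identity, h.subject_id))
    return kept


def taxonomy_candidate(
    gene_id: str,
    qualified: Sequence[HitRecord],
    n_top: int = 10,
    self_group: str = "Bacteroidetes",
) -> TaxonomyCall:
    """Candidate iff there is at least one qualified hit and no top hit is self-group.

    When fewer than ``n_top`` hits qualify, all available hits must be
    foreign.  Genes with zero qualified hits are not candidates: absence of
    hits is not evidence of foreign affinity.
    """
    top = list(qualified[:n_top])
    for h in top:
        if not h.lineage:
            raise ValidationError(f"hit {h.query_id}->{h.subject_id}: missing lineage")
    is_candidate = bool(top) and all(self_group not in h.lineage for h in top)
    return TaxonomyCall(
        gene_id=gene_id,
        is_candidate=is_candidate,
        n_qualified_hits=len(qualified),
        top_hits_examined=len(top),
    )


def screen_hits(
    hits_by_gene: Mapping[str, Sequence[HitRecord]],
    gene_universe: Iterable[str],
    min_identity: float = 50.0,
    max_evalue: float = 1e-5,
    min_coverage: float = 70.0,
    exclude_subject_genomes: Iterable[str] = (),
    n_top: int = 10,
    self_group: str = "Bacteroidetes",
) -> list[TaxonomyCall]:
    """Run the taxonomy screen over a whole gene universe (no-hit genes included)."""
    calls = []
    for gene_id in sorted(gene_universe):
        qualified = qualify_hits(
            hits_by_gene.get(gene_id, ()),
            min_identity=min_identity,
            max_evalue=max_evalue,
            min_coverage=min_coverage,
            exclude_subject_genomes=exclude_subject_genomes,
        )
        calls.append(taxonomy_candidate(gene_id, qualified, n_top=n_top, self_group=self_group))
    return calls


def combine_evidence(
    composition_flags: Mapping[str, bool],
    taxonomy_calls: Sequence[TaxonomyCall],
) -> list[HgtCandidate]:
    """Strict intersection of the two screens over the same gene universe."""
    tax = {c.gene_id: c.is_candidate for c in taxonomy_calls}
    if set(tax) != set(composition_flags):
        diff = sorted(set(tax) ^ set(composition_flags))
        raise ValidationError(f"screens ran on different gene universes; difference: {diff}")
    return [
        HgtCandidate(gene_id=g)
        for g in sorted(composition_flags)
        if composition_flags[g] and tax[g]
    ]


def _depths_to_root(node: dendropy.Node) -> dict[int, int]:
    depths: dict[int, int] = {}
    d = 0
    while node is not None:
        depths[id(node)] = d
        node = node.parent_node
        d += 1
    return depths


def nearest_neighbor(tree: dendropy.Tree | str, query_leaf: str) -> str:
    """Leaf label closest to ``query_leaf`` by the number of nodes on the path.

    The path length is counted in edges via depth-to-common-ancestor, an
    ordering identical to counting intermediate nodes.  Ties break
    lexicographically by leaf label.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = read_newick(tree)
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    if query_leaf not in leaves:
        raise ValidationError(f"query leaf {query_leaf!r} not in tree")
    qdepths = _depths_to_root(leaves[query_leaf])
    best: tuple[int, str] | None = None
    for label, leaf in leaves.items():
        if label == query_leaf:
            continue
        node = leaf
        steps = 0
        while id(node) not in qdepths:
            node = node.parent_node
            steps += 1
        dist = steps + qdepths[id(node)]
        cand = (dist, label)
        if best is None or cand < best:
            best = cand
    assert best is not None  # >=2 leaves guaranteed by read_newick
    return best[1]


def classify_age(
    gene_id: str,
    ortholog_map: Mapping[str, frozenset[str] | set[str]],
    other_genomes: Iterable[str] = ("cEper1", "cBtQ1"),
) -> str:
    """"ancient" iff the gene has an ortholog in at least one sister genome."""
    if gene_id not in ortholog_map:
        raise ValidationError(f"gene {gene_id!r} absent from ortholog map")
    return "ancient" if set(ortholog_map[gene_id]) & set(other_genomes) else "recent"


def donor_summary(
    candidates: Sequence[HgtCandidate],
    donor_groups: Mapping[str, Sequence[str]],
    transposase_genes: Iterable[str] = (),
) -> pd.DataFrame:
    """Fractions of non-transposase candidates per donor group.

    ``donor_groups`` maps a group label to the set of donor taxa it covers
    (a donor may fall in several groups, e.g. Wolbachia within
    Proteobacteria), so fractions of nested groups are reported separately
    and need not sum to 1.  Transposase labels come from input annotation.
    """
    transposases = set(transposase_genes)
    pool = [c for c in candidates if c.gene_id not in transposases and c.donor_taxon]
    rows = []
    for group in sorted(donor_groups):
        taxa = set(donor_groups[group])
        count = sum(1 for c in pool if c.donor_taxon in taxa)
        rows.append(
            {
                "donor_group": group,
                "count": count,
                "n_non_transposase": len(pool),
                "fraction_pct": round(count / len(pool) * 100, 2) if pool else float("nan"),
            }
        )
    df = pd.DataFrame(rows, columns=["donor_group", "count", "n_non_transposase", "fraction_pct"])
    return df if pool else df.iloc[0:0]


def assign_donors_and_age(
    candidates: Sequence[HgtCandidate],
    trees: Mapping[str, dendropy.Tree | str],
    ortholog_map: Mapping[str, frozenset[str] | set[str]],
    other_genomes: Iterable[str] = ("cEper1", "cBtQ1"),
) -> list[HgtCandidate]:
    """Fill donor (nearest tree neighbor, where a tree exists) and age per candidate."""
    out = []
    for c in candidates:
        donor = nearest_neighbor(trees[c.gene_id], c.gene_id) if c.gene_id in trees else None
        age = classify_age(c.gene_id, ortholog_map, other_genomes=other_genomes)
        out.append(replace(c, donor_taxon=donor, age=age))
    return out
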