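import networkx as nx
import numpy as np
import pytest

from endoscan.genome_io import HitRecord, ValidationError, read_newick
from endoscan.taxonomy_screen import (
    HgtCandidate,
    classify_age,
    combine_evidence,
    donor_summary,
    nearest_neighbor,
    qualify_hits,
    taxonomy_candidate,
)

FOREIGN = ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Wolbachia")
SELF = ("Bacteria", "Bacteroidetes", "Cytophagales", "Cardinium")


def _hit(subject="x|p1", identity=80.0, evalue=1e-30, coverage=90.0, bitscore=300.0, lineage=FOREIGN):
    return HitRecord(
        query_id="q", subject_id=subject, pct_identity=identity, aln_len=100,
        evalue=evalue, bitscore=bitscore, query_coverage=coverage, lineage=lineage,
    )


def test_qualify_hits_cutoffs_inclusive():
    hits = [
        _hit(subject="keep|a", identity=50.0, coverage=70.0, evalue=1e-5),
        _hit(subject="drop|id", identity=49.9),
        _hit(subject="drop|cov", coverage=69.9),
        _hit(subject="drop|ev", evalue=2e-5),
    ]
    kept = qualify_hits(hits)
    assert [h.subject_id for h in kept] == ["keep|a"]


def test_qualify_hits_excludes_sister_genomes():
    hits = [_hit(subject="cEper1|g5", bitscore=999.0), _hit(subject="ok|g1")]
    kept = qualify_hits(hits, exclude_subject_genomes=("cEper1", "cBtQ1"))
    assert [h.subject_id for h in kept] == ["ok|g1"]


def test_qualify_hits_tie_break_order():
    hits = [
        _hit(subject="b|2", bitscore=300.0, evalue=1e-20),
        _hit(subject="a|1", bitscore=300.0, evalue=1e-30),
        _hit(subject="c|3", bitscore=300.0, evalue=1e-20),
        _hit(subject="d|4", bitscore=400.0, evalue=1e-10),
    ]
    kept = qualify_hits(hits)
    assert [h.subject_id for h in kept] == ["d|4", "a|1", "b|2", "c|3"]


def test_taxonomy_candidate_rules():
    foreign10 = [_hit(subject=f"f|{i}", bitscore=400 - i) for i in range(10)]
    call = taxonomy_candidate("q", foreign10)
    assert call.is_candidate and call.top_hits_examined == 10

    with_self = foreign10[:9] + [_hit(subject="s|1", lineage=SELF, bitscore=100.0)]
    assert not taxonomy_candidate("q", with_self).is_candidate

    # self-group hit beyond the top 10 does not veto
    eleven = foreign10 + [_hit(subject="s|1", lineage=SELF, bitscore=1.0)]
    assert taxonomy_candidate("q", eleven).is_candidate

    assert not taxonomy_candidate("q", []).is_candidate  # no hits, no evidence


def test_combine_evidence_strict_intersection():
    comp = {"a": True, "b": True, "c": False}
    tax = [
        taxonomy_candidate("a", [_hit()]),
        taxonomy_candidate("b", []),
        taxonomy_candidate("c", [_hit()]),
    ]
    out = combine_evidence(comp, tax)
    assert [c.gene_id for c in out] == ["a"]
    with pytest.raises(ValidationError, match="universe"):
        combine_evidence({"a": True}, tax)


@pytest.mark.parametrize(
    "newick,query,expected",
    [
        ("((A,B),C);", "A", "B"),
        ("((A,B),(C,D));", "A", "B"),
        ("(A,B,C);", "A", "B"),  # tie between B and C -> lexicographic
        ("((A,C),(B,D));", "A", "C"),
    ],
)
def test_nearest_neighbor_examples(newick, query, expected):
    assert nearest_neighbor(newick, query) == expected


def test_nearest_neighbor_missing_query():
    with pytest.raises(ValidationError):
        nearest_neighbor("((A,B),C);", "Z")


def _random_newick(rnd: np.random.Generator, n_leaves: int) -> str:
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rnd.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def _bfs_oracle(newick: str, query: str) -> str:
    """Independent all-pairs path-length oracle: BFS over the tree graph."""
    tree = read_newick(newick)
    g = nx.Graph()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            g.add_edge(id(edge.tail_node), id(edge.head_node))
    leaves = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
    dist = nx.single_source_shortest_path_length(g, leaves[query])
    return min((dist[node], label) for label, node in leaves.items() if label != query)[1]


def test_nearest_neighbor_agrees_with_bfs_oracle():
    rnd = np.random.default_rng(42)
    for trial in range(120):
        newick = _random_newick(rnd, 10)
        query = f"L{int(rnd.integers(0, 10))}"
        assert nearest_neighbor(newick, query) == _bfs_oracle(newick, query), newick


def test_classify_age():
    omap = {"a": frozenset({"cEper1"}), "b": frozenset(), "c": frozenset({"other"})}
    assert classify_age("a", omap) == "ancient"
    assert classify_age("b", omap) == "recent"
    assert classify_age("c", omap) == "recent"  # ortholog outside the sister set
    with pytest.raises(ValidationError):
        classify_age("zzz", omap)


def test_age_partition_is_complete(sim_dir):
    sim, _ = sim_dir
    from endoscan.synthetic import simulate_orthologs

    omap = simulate_orthologs(sim.truth, np.random.default_rng(1))
    ages = [classify_age(g, omap) for g in sim.truth.gene_id]
    assert len(ages) == len(sim.truth)
    assert set(ages) <= {"ancient", "recent"}


def test_donor_summary_fractions():
    cands = [HgtCandidate(f"g{i}", donor_taxon="Wolbachia|w") for i in range(16)]
    cands += [HgtCandidate(f"h{i}", donor_taxon="Bacillus|b") for i in range(9)]
    cands += [HgtCandidate(f"t{i}", donor_taxon="Wolbachia|w") for i in range(5)]  # transposases
    groups = {
        "Proteobacteria": {"Wolbachia|w"},
        "Wolbachia": {"Wolbachia|w"},
        "Firmicutes": {"Bacillus|b"},
    }
    table = donor_summary(cands, groups, transposase_genes=[f"t{i}" for i in range(5)])
    by_group = dict(zip(table.donor_group, table.fraction_pct))
    assert by_group["Proteobacteria"] == 64.0  # 16 of 25 non-transposase
    assert by_group["Wolbachia"] == 64.0  # nested group reported separately
    assert by_group["Firmicutes"] == 36.0
    assert donor_summary([], groups).empty
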