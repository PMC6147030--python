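import numpy as np
import pytest

from endoscan.genome_io import ValidationError
from endoscan.pangenome import (
    GeneCluster,
    SimilarityEdge,
    align_pair,
    categorize,
    cluster,
    pairwise_similarity,
    partition,
)
from endoscan.synthetic import simulate_proteomes


def test_align_pair_identical():
    identity, coverage = align_pair("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
    assert identity == pytest.approx(100.0)
    assert coverage == pytest.approx(100.0)


def test_align_pair_exact_substring_covers_shorter():
    long = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQV"
    short = long[10:40]
    identity, coverage = align_pair(short, long)
    assert identity == pytest.approx(100.0)
    assert coverage == pytest.approx(100.0)  # measured against the shorter member


def test_align_pair_empty_rejected():
    with pytest.raises(ValidationError):
        align_pair("", "MKT")


def _edge(a, b, identity, coverage=90.0):
    return SimilarityEdge(gene_a=("G", a), gene_b=("G", b), pct_identity=identity, coverage=coverage)


def test_cluster_single_linkage_chains():
    edges = [_edge("A", "B", 55.0), _edge("B", "C", 55.0), _edge("A", "C", 30.0)]
    out = cluster(edges)
    assert len(out) == 1 and out[0].members == {("G", "A"), ("G", "B"), ("G", "C")}


def test_cluster_below_threshold_gives_singletons():
    edges = [_edge("A", "B", 40.0), _edge("B", "C", 49.9)]
    out = cluster(edges)
    assert sorted(len(c.members) for c in out) == [1, 1, 1]


def test_cluster_coverage_threshold():
    out = cluster([_edge("A", "B", 90.0, coverage=69.9)])
    assert len(out) == 2


def test_cluster_is_a_partition_and_monotone():
    rnd = np.random.default_rng(7)
    genes = [("G", f"p{i}") for i in range(8)]
    for _ in range(100):
        edges = []
        for i in range(8):
            for j in range(i + 1, 8):
                edges.append(
                    SimilarityEdge(genes[i], genes[j], float(rnd.uniform(0, 100)), float(rnd.uniform(0, 100)))
                )
        out = cluster(edges, members=genes)
        all_members = [m for c in out for m in c.members]
        assert sorted(all_members) == sorted(genes)  # partition
        # brute-force transitive closure oracle (no graph library)
        parent = {g: g for g in genes}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for e in edges:
            if e.pct_identity >= 50.0 and e.coverage >= 70.0:
                parent[find(e.gene_a)] = find(e.gene_b)
        oracle = {}
        for g in genes:
            oracle.setdefault(find(g), set()).add(g)
        assert sorted(map(frozenset, oracle.values()), key=min) == sorted(
            (c.members for c in out), key=min
        )
        # lowering the identity threshold can only merge, never split
        relaxed = cluster(edges, min_identity=30.0, members=genes)
        assert len(relaxed) <= len(out)


def _mk_clusters(spec):
    out = []
    i = 0
    for genomes, count in spec:
        for _ in range(count):
            i += 1
            out.append(
                GeneCluster(cluster_id=f"CL{i:04d}", members=frozenset((g, f"x{i}_{g}") for g in genomes))
            )
    return out


def test_partition_published_style_counts():
    clusters = _mk_clusters(
        [
            (("cSfur", "cEper1", "cBtQ1"), 524),
            (("cSfur", "cEper1"), 17),
            (("cSfur", "cBtQ1"), 6),
            (("cEper1", "cBtQ1"), 50),
            (("cSfur",), 179),
            (("cEper1",), 185),
            (("cBtQ1",), 78),
        ]
    )
    table = partition(clusters)
    row = table[(table.genome == "cSfur") & (table.category == "specific")].iloc[0]
    assert row.n_total == 726
    assert row.pct == 24.66
    core = table[(table.genome == "cSfur") & (table.category == "core")].iloc[0]
    assert core.n_clusters == 524
    # per genome the three category counts sum to the clusters containing it
    for genome, sub in table.groupby("genome"):
        assert sub.n_clusters.sum() == sub.n_total.iloc[0]


def test_partition_all_core_and_enumeration():
    clusters = _mk_clusters([(("a", "b"), 5)])
    table = partition(clusters, genomes=("a", "b"))
    assert (table[table.category == "core"].pct == 100.0).all()
    toy = _mk_clusters([(("a", "b"), 2), (("a",), 2), (("b",), 1)])
    t = partition(toy, genomes=("a", "b"))
    a_specific = t[(t.genome == "a") & (t.category == "specific")].iloc[0]
    assert (a_specific.n_clusters, a_specific.n_total, a_specific.pct) == (2, 4, 50.0)


def test_partition_unknown_genome_label():
    with pytest.raises(ValidationError):
        categorize(_mk_clusters([(("mystery",), 1)]), genomes=("a", "b"))


def test_planted_proteome_partition_recovered(rng):
    proteins, expected = simulate_proteomes(rng, n_core=6, n_shared=3, n_specific=5)
    edges = pairwise_similarity(proteins)
    clusters = cluster(edges, members=proteins)
    genomes = sorted({g for g, _ in proteins})
    clusters = categorize(clusters, genomes)
    counts = {"core": 0, "shared": 0, "specific": 0}
    for c in clusters:
        counts[c.category] += 1
    assert counts == expected
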