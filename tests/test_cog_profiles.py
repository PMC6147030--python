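from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from endoscan.cog_profiles import (
    COG_CATEGORIES,
    cluster_profiles,
    group_compare,
    relative_abundance,
    wilcoxon_exact,
)
from endoscan.genome_io import ValidationError
from endoscan.synthetic import simulate_cog_assignments


def _assign(rows):
    return pd.DataFrame(rows, columns=["genome", "cluster_id", "cog_letters"])


def test_relative_abundance_single_category():
    mat = relative_abundance(_assign([("g1", "c1", "J"), ("g1", "c2", "J")]))
    assert mat.loc["g1", "J"] == pytest.approx(100.0)
    assert mat.loc["g1", "K"] == 0.0


def test_relative_abundance_mixture_and_fractional_split():
    mat = relative_abundance(_assign([("g1", "c1", "J"), ("g1", "c2", "J"), ("g1", "c3", "K")]))
    assert mat.loc["g1", "J"] == pytest.approx(200 / 3)
    assert mat.loc["g1", "K"] == pytest.approx(100 / 3)
    mat2 = relative_abundance(_assign([("g1", "c1", "JK")]))
    assert mat2.loc["g1", "J"] == pytest.approx(50.0)
    assert mat2.loc["g1", "K"] == pytest.approx(50.0)


def test_relative_abundance_unknown_category():
    with pytest.raises(ValidationError, match="unknown COG"):
        relative_abundance(_assign([("g1", "c1", "X")]))


def test_cog_category_set():
    assert len(COG_CATEGORIES) == 22
    assert len(set(COG_CATEGORIES)) == 22


def test_wilcoxon_complete_separation_4_vs_13():
    p = wilcoxon_exact([1, 2, 3, 4], list(range(5, 18)))
    assert p == pytest.approx(2 / 2380)


def test_wilcoxon_minimum_achievable_p_4_vs_13():
    # only one of the C(17,4)=2380 assignments attains the minimal rank sum
    assert 2 / comb(17, 4) == pytest.approx(2 / 2380)
    shifted = wilcoxon_exact([10, 20, 30, 40], [x * 100 for x in range(5, 18)])
    assert shifted == pytest.approx(2 / 2380)  # rank-based: scale-free floor


def test_wilcoxon_trivial_cases():
    assert wilcoxon_exact([5, 5, 5], [5, 5, 5]) == 1.0
    assert wilcoxon_exact([1, 2], [3, 4]) == pytest.approx(1 / 3)
    with pytest.raises(ValidationError):
        wilcoxon_exact([], [1.0])


def test_wilcoxon_symmetry(rng):
    for _ in range(20):
        x = rng.normal(size=int(rng.integers(2, 6)))
        y = rng.normal(size=int(rng.integers(2, 6)))
        assert wilcoxon_exact(x, y) == pytest.approx(wilcoxon_exact(y, x))


def test_wilcoxon_matches_scipy_exact_on_tie_free_instances(rng):
    """Independent oracle: scipy's exact Mann-Whitney U on 100+ random tie-free samples."""
    for _ in range(120):
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 7))
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        expected = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert wilcoxon_exact(x, y) == pytest.approx(expected, rel=1e-9)


def _enumeration_oracle(x, y):
    """Direct U-statistic tail enumeration over value comparisons (handles ties)."""
    values = list(x) + list(y)
    n1, n = len(x), len(values)

    def u_of(idx):
        xs = [values[i] for i in idx]
        ys = [values[i] for i in range(n) if i not in set(idx)]
        return sum(1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys)

    u_obs = u_of(tuple(range(n1)))
    eps = 1e-9
    total = lo = hi = 0
    for idx in combinations(range(n), n1):
        u = u_of(idx)
        total += 1
        lo += u <= u_obs + eps
        hi += u >= u_obs - eps
    return min(1.0, 2 * min(lo / total, hi / total))


@pytest.mark.parametrize(
    "x,y",
    [
        ([1, 1, 2], [1, 2, 2, 3]),
        ([0, 0, 0, 1], [0, 1, 1]),
        ([3, 3], [3, 3, 4]),
        ([1.5, 2.5, 2.5], [2.5, 2.5, 9.0]),
    ],
)
def test_wilcoxon_tied_samples_match_enumeration_oracle(x, y):
    assert wilcoxon_exact(x, y) == pytest.approx(_enumeration_oracle(x, y))


def test_wilcoxon_monte_carlo_agrees_with_enumeration(rng):
    x = list(rng.normal(size=5))
    y = list(rng.normal(loc=1.0, size=6))
    exact = wilcoxon_exact(x, y)
    mc = wilcoxon_exact(x, y, max_enumeration=1, n_permutations=40_000, rng=np.random.default_rng(0))
    # one-tail standard error at p/2
    se = 2 * np.sqrt(exact / 2 * (1 - exact / 2) / 40_000)
    assert abs(mc - exact) <= 3 * se + 1e-4


def _toy_matrix():
    data = {
        "J": [30.0, 28.0, 10.0, 11.0],
        "G": [2.0, 2.5, 8.0, 7.5],
        "M": [7.0, 7.2, 7.1, 6.9],
    }
    mat = pd.DataFrame(0.0, index=["h1", "h2", "f1", "f2"], columns=list(COG_CATEGORIES))
    for k, v in data.items():
        mat[k] = v
    return mat


def test_group_compare_toy_matches_enumeration():
    mat = _toy_matrix()
    groups = {"h1": "host-dependent", "h2": "host-dependent", "f1": "free-living", "f2": "free-living"}
    table = group_compare(mat, groups)
    p_j = float(table[table.category == "J"].p_value.iloc[0])
    assert p_j == pytest.approx(_enumeration_oracle([30.0, 28.0], [10.0, 11.0]))
    assert p_j == pytest.approx(1 / 3)  # complete separation at 2 vs 2


def test_group_compare_identical_groups_not_significant():
    mat = pd.DataFrame(5.0, index=["a", "b", "c", "d"], columns=list(COG_CATEGORIES))
    groups = {"a": "host-dependent", "b": "host-dependent", "c": "free-living", "d": "free-living"}
    table = group_compare(mat, groups)
    assert not table.significant.any()
    assert (table.p_value == 1.0).all()


def test_group_compare_validation():
    mat = _toy_matrix()
    with pytest.raises(ValidationError, match="unlabeled"):
        group_compare(mat, {"h1": "host-dependent"})
    groups = {g: "host-dependent" for g in mat.index}
    with pytest.raises(ValidationError, match="non-empty"):
        group_compare(mat, groups)


def test_group_compare_detects_planted_effect(rng):
    assignments, groups = simulate_cog_assignments(rng, n_host=4, n_free=13)
    mat = relative_abundance(assignments)
    table = group_compare(mat, groups).set_index("category")
    # strong planted shifts: J inflated, G deflated in host-dependent genomes
    assert table.loc["J", "p_value"] < 0.01
    assert table.loc["G", "p_value"] < 0.01
    assert table.loc["J", "mean_host-dependent"] > table.loc["J", "mean_free-living"]
    assert table.loc["G", "mean_host-dependent"] < table.loc["G", "mean_free-living"]
    # no planted effect on M: should not reach the floor p-value
    assert table.loc["M", "p_value"] > 2 / 2380


def test_cluster_profiles_duplicates_adjacent():
    mat = _toy_matrix()
    mat.loc["h1_copy"] = mat.loc["h1"]
    order, _ = cluster_profiles(mat)
    i, j = order.index("h1"), order.index("h1_copy")
    assert abs(i - j) == 1
    hosts = {order.index("h1"), order.index("h1_copy"), order.index("h2")}
    frees = {order.index("f1"), order.index("f2")}
    assert max(hosts) < min(frees) or max(frees) < min(hosts)


def test_cluster_profiles_constant_column_ok():
    mat = pd.DataFrame(1.0, index=["a", "b"], columns=list(COG_CATEGORIES))
    order, link = cluster_profiles(mat)
    assert sorted(order) == ["a", "b"]
    assert link[0, 2] == pytest.approx(0.0)  # identical rows merge at distance 0
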