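import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from guildlink import (
    AbundanceTable,
    ValueKind,
    cluster_features,
    cooccurrence_network,
    guild_abundance,
    spearman_matrix,
)


def _table(values, features=None, kind=ValueKind.intensity):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    return AbundanceTable(pd.DataFrame(values, index=features, columns=samples), kind)


# ---------------------------------------------------------------------------
# Spearman matrix
# ---------------------------------------------------------------------------

def test_monotone_and_antitone_pairs():
    t = _table([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]])
    rho, p = spearman_matrix(t)
    assert rho.loc["f0", "f1"] == pytest.approx(1.0)
    assert rho.loc["f0", "f2"] == pytest.approx(-1.0)
    assert (np.diag(rho) == 1.0).all()


def test_tied_ranks_average_rank_pearson():
    # x=[1,2,3,4] ranks 1..4; y=[1,1,2,2] average ranks [1.5,1.5,3.5,3.5]
    t = _table([[1, 2, 3, 4], [1, 1, 2, 2]])
    rho, _ = spearman_matrix(t)
    expected = np.corrcoef([1, 2, 3, 4], [1.5, 1.5, 3.5, 3.5])[0, 1]
    assert rho.loc["f0", "f1"] == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.894427, abs=1e-6)


def test_exact_p_matches_permutation_enumeration():
    """For n<=9 tie-free data the p-value must equal the exhaustive
    permutation tail probability of |rho|."""
    rng = np.random.default_rng(0)
    for n in (4, 5, 6):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        t = _table(np.vstack([x, y]), kind=ValueKind.scaled)
        rho, p = spearman_matrix(t)
        r_obs = rho.loc["f0", "f1"]
        rx = stats.rankdata(x)
        count = 0
        total = 0
        for perm in itertools.permutations(stats.rankdata(y)):
            r = np.corrcoef(rx, perm)[0, 1]
            total += 1
            if abs(r) >= abs(r_obs) - 1e-12:
                count += 1
        assert p.loc["f0", "f1"] == pytest.approx(count / total, abs=1e-12)


def test_constant_feature_flagged():
    t = _table([[1, 2, 3, 4], [5, 5, 5, 5]])
    rho, p = spearman_matrix(t)
    assert rho.loc["f0", "f1"] == 0.0
    assert p.loc["f0", "f1"] == 1.0


def test_large_n_p_uses_t_approximation():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(30)
    y = 0.5 * x + rng.standard_normal(30)
    t = _table(np.vstack([x, y]), kind=ValueKind.scaled)
    rho, p = spearman_matrix(t)
    ref_r, ref_p = stats.spearmanr(x, y)
    assert rho.loc["f0", "f1"] == pytest.approx(ref_r, abs=1e-12)
    assert p.loc["f0", "f1"] == pytest.approx(ref_p, rel=1e-6)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _rho_frame(arr, ids):
    return pd.DataFrame(arr, index=ids, columns=ids)


def test_two_planted_pairs_cut_at_height_04():
    ids = ["A", "B", "C", "D"]
    arr = np.eye(4)
    arr[0, 1] = arr[1, 0] = 0.9
    arr[2, 3] = arr[3, 2] = 0.9
    assign = cluster_features(_rho_frame(arr, ids), height=0.4)
    labels = assign.assignment
    assert labels["A"] == labels["B"]
    assert labels["C"] == labels["D"]
    assert labels["A"] != labels["C"]
    assert len(assign.labels()) == 2


def test_uncorrelated_features_stay_singletons():
    ids = list("ABCD")
    assign = cluster_features(_rho_frame(np.eye(4), ids), height=0.4)
    assert len(assign.labels()) == 4


def test_huge_height_merges_everything():
    ids = list("ABCDE")
    rng = np.random.default_rng(2)
    m = rng.uniform(-0.5, 0.5, (5, 5))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    assign = cluster_features(_rho_frame(m, ids), height=2.0)
    assert len(assign.labels()) == 1


def test_anticorrelated_features_not_merged_with_default_distance():
    ids = ["up", "down"]
    arr = np.array([[1.0, -0.95], [-0.95, 1.0]])
    assign = cluster_features(_rho_frame(arr, ids), height=0.4)
    assert len(assign.labels()) == 2
    assign_abs = cluster_features(_rho_frame(arr, ids), height=0.4,
                                  distance="1-|rho|")
    assert len(assign_abs.labels()) == 1


def test_partition_invariant_to_feature_order():
    rng = np.random.default_rng(3)
    n = 12
    m = rng.uniform(-1, 1, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    ids = [f"f{i}" for i in range(n)]
    base = cluster_features(_rho_frame(m, ids), height=0.7)
    order = rng.permutation(n)
    shuffled_ids = [ids[i] for i in order]
    shuffled = _rho_frame(m[np.ix_(order, order)], shuffled_ids)
    other = cluster_features(shuffled, height=0.7)

    def partition(assign):
        groups = {}
        for f, lab in assign.assignment.items():
            groups.setdefault(lab, set()).add(f)
        return {frozenset(g) for g in groups.values()}

    assert partition(base) == partition(other)


def brute_force_average_linkage(d: np.ndarray, height: float):
    """Independent agglomerator: repeatedly merge the pair of clusters with
    the smallest mean pairwise (original) distance while it is <= height."""
    clusters = [{i} for i in range(d.shape[0])]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or dist < best[0] - 1e-12:
                best = (dist, a, b)
        if best[0] > height:
            break
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return {frozenset(c) for c in clusters}


def test_oracle_equivalence_on_random_instances():
    rng = np.random.default_rng(4)
    for _ in range(100):
        n = 6
        m = rng.uniform(-1, 1, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ids = [f"f{i}" for i in range(n)]
        height = rng.uniform(0.2, 1.5)
        assign = cluster_features(_rho_frame(m, ids), height=height)
        groups = {}
        for f, lab in assign.assignment.items():
            groups.setdefault(lab, set()).add(int(f[1:]))
        ours = {frozenset(g) for g in groups.values()}
        oracle = brute_force_average_linkage(1.0 - m, height)
        assert ours == oracle


def test_labels_ordered_by_guild_size():
    ids = ["a", "b", "c", "z"]
    arr = np.eye(4)
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        arr[i, j] = arr[j, i] = 0.9
    assign = cluster_features(_rho_frame(arr, ids), height=0.4, label_prefix="M")
    assert assign.assignment["a"] == "M1"      # the size-3 guild is M1
    assert assign.assignment["z"] == "M2"


# ---------------------------------------------------------------------------
# guild abundance
# ---------------------------------------------------------------------------

def test_guild_abundance_conservation(small_cohort):
    from guildlink import GuildAssignment
    table = small_cohort.microbiome
    labels = {f: small_cohort.truth.species_cags[f] for f in table.feature_ids}
    assign = GuildAssignment(labels, height=0.5, distance="1-rho",
                             label_prefix="CAG")
    abund = guild_abundance(table, assign)
    assert np.allclose(abund.matrix().sum(axis=0), table.matrix().sum(axis=0))
    assert abund.value_kind is table.value_kind


def test_guild_abundance_singletons_identity(tiny_table):
    from guildlink import GuildAssignment
    assign = GuildAssignment({f: f"G{i+1}" for i, f in
                              enumerate(tiny_table.feature_ids)},
                             height=0.4, distance="1-rho")
    abund = guild_abundance(tiny_table, assign)
    assert np.allclose(abund.matrix(), tiny_table.matrix())


def test_guild_abundance_requires_full_assignment(tiny_table):
    from guildlink import GuildAssignment
    assign = GuildAssignment({"f1": "G1"}, height=0.4, distance="1-rho")
    with pytest.raises(ValueError, match="without a guild"):
        guild_abundance(tiny_table, assign)


# ---------------------------------------------------------------------------
# co-occurrence network
# ---------------------------------------------------------------------------

def test_network_edge_rules():
    ids = list("abc")
    rho = _rho_frame(np.array([[1.0, 0.50, -0.60],
                               [0.50, 1.0, 0.46],
                               [-0.60, 0.46, 1.0]]), ids)
    p = _rho_frame(np.array([[0.0, 0.001, 0.001],
                             [0.001, 0.0, 0.001],
                             [0.001, 0.001, 0.0]]), ids)
    net = cooccurrence_network(rho, p, threshold=0.46, alpha=0.05)
    pairs = {(e["source"], e["target"]): e["sign"] for e in net.edges}
    assert pairs[("a", "b")] == "+"
    assert pairs[("a", "c")] == "-"
    assert ("b", "c") not in pairs            # rho == threshold: strict


def test_network_q_filter():
    ids = ["x", "y"]
    rho = _rho_frame(np.array([[1.0, -0.6], [-0.6, 1.0]]), ids)
    p = _rho_frame(np.array([[0.0, 0.20], [0.20, 0.0]]), ids)
    net = cooccurrence_network(rho, p)
    assert net.edges == []


def test_network_bh_over_upper_triangle():
    # 3 pairwise tests: BH of [0.01, 0.02, 0.04] -> [0.03, 0.03, 0.04]
    ids = list("abc")
    rho = np.full((3, 3), 0.9)
    np.fill_diagonal(rho, 1.0)
    p = np.zeros((3, 3))
    p[0, 1] = p[1, 0] = 0.01
    p[0, 2] = p[2, 0] = 0.02
    p[1, 2] = p[2, 1] = 0.04
    net = cooccurrence_network(_rho_frame(rho, ids), _rho_frame(p, ids),
                               threshold=0.46, alpha=0.05)
    qs = sorted(round(e["q"], 10) for e in net.edges)
    assert qs == [0.03, 0.03, 0.04]
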