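"""Response matrices, correlation networks, hierarchical clustering."""
import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

import vitiphenol as vp
from vitiphenol.io_model import QuantTable, UnitBasis
from vitiphenol.response import (ClusterTree, ResponseMatrix,
                                 correlation_distance, correlation_network,
                                 cut_subgroups, hierarchical_cluster,
                                 response_matrix, subgroup_frame)

rng = np.random.default_rng(11)


# ----------------------------------------------------------- response matrix

def test_response_matrix_elementwise_oracle(cohort2014, imputed, indices):
    resp = response_matrix(cohort2014, imputed, indices)
    c = cohort2014.cultivars[0]
    ir, ni = cohort2014.ir_samples[c], cohort2014.ni_samples[c]
    for var in ["s_FA", imputed.panel.abbreviations[0]]:
        expect = np.log10(imputed.values.loc[ir, var]
                          / imputed.values.loc[ni, var]) \
            if var not in indices.values.columns else \
            np.log10(indices.values.loc[ir, var] / indices.values.loc[ni, var])
        assert resp.values.loc[var, c] == pytest.approx(expect, rel=1e-12)
    assert resp.variables == (imputed.panel.abbreviations
                              + list(indices.values.columns))
    assert resp.cultivars == cohort2014.cultivars


def test_response_matrix_requires_per_berry(cohort2014, imputed, small_meta):
    per_g = vp.convert_units(imputed, small_meta, "per_gram")
    with pytest.raises(ValueError, match="per-berry"):
        response_matrix(cohort2014, per_g)


def test_response_matrix_rejects_nonpositive(cohort2014, small_table, panel):
    # raw table may contain zeros below the LOQ: must impute first
    values = small_table.values.copy()
    values.iloc[0, 0] = 0.0
    table = QuantTable(values, UnitBasis.PER_BERRY, panel)
    with pytest.raises(ValueError, match="imputation"):
        response_matrix(cohort2014, table)


def test_standardized_rows(cohort2014, imputed):
    resp = response_matrix(cohort2014, imputed)
    std, flat = resp.standardized()
    assert flat == []
    assert np.allclose(std.mean(axis=1), 0.0, atol=1e-12)
    assert np.allclose(std.std(axis=1, ddof=0), 1.0, rtol=1e-12)


def test_standardized_drops_flat_rows():
    values = pd.DataFrame([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]],
                          index=["a", "b"], columns=["x", "y", "z"])
    std, flat = ResponseMatrix(values).standardized()
    assert flat == ["b"]
    assert list(std.index) == ["a"]


def test_log_base_conversion(cohort2014, imputed):
    r10 = response_matrix(cohort2014, imputed, log_base=10.0)
    r2 = response_matrix(cohort2014, imputed, log_base=2.0)
    assert np.allclose(r2.values, r10.values * np.log2(10.0), rtol=1e-12)


# ----------------------------------------------------------------- network

def test_network_brute_force_oracle():
    x = pd.DataFrame(rng.normal(size=(12, 25)),
                     index=[f"v{i:02d}" for i in range(12)])
    # plant some strong correlations
    x.iloc[1] = x.iloc[0] + rng.normal(0, 0.1, 25)
    x.iloc[2] = -x.iloc[0] + rng.normal(0, 0.1, 25)
    threshold = 0.5
    net = correlation_network(x, threshold=threshold)
    expected = set()
    for i in range(12):
        for j in range(i + 1, 12):
            r = pearsonr(x.iloc[i], x.iloc[j]).statistic
            if r > threshold:
                expected.add((x.index[i], x.index[j]))
    got = {(row["source"], row["target"])
           for _, row in net.edge_table().iterrows()}
    assert got == expected
    assert ("v00", "v01") in got
    assert ("v00", "v02") not in got  # negative correlation, signed rule


def test_network_absolute_flag():
    x = pd.DataFrame(rng.normal(size=(3, 30)), index=["a", "b", "c"])
    x.iloc[1] = -x.iloc[0]
    net = correlation_network(x, threshold=0.8, absolute=False)
    assert not net.graph.has_edge("a", "b")
    net_abs = correlation_network(x, threshold=0.8, absolute=True)
    assert net_abs.graph.has_edge("a", "b")
    assert net_abs.graph.edges["a", "b"]["r"] == pytest.approx(-1.0)


def test_network_threshold_is_strict():
    # r exactly at the threshold must not create an edge
    x = pd.DataFrame([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0]], index=["a", "b"])
    net = correlation_network(x, threshold=0.999999)
    assert net.graph.has_edge("a", "b")  # r = 1 > threshold
    y = pd.DataFrame([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]], index=["a", "b"])
    with pytest.raises(ValueError, match="threshold"):
        correlation_network(y, threshold=1.0)


def test_network_zero_variance_excluded():
    x = pd.DataFrame(rng.normal(size=(3, 10)), index=["a", "b", "c"])
    x.iloc[2] = 7.0
    with pytest.warns(UserWarning, match="zero-variance"):
        net = correlation_network(x, threshold=0.5)
    assert net.excluded == ["c"]
    assert "c" not in net.nodes


def test_network_components_and_exports(tmp_path, panel):
    x = pd.DataFrame(rng.normal(size=(4, 40)),
                     index=["a", "b", "c", "d"])
    x.iloc[1] = x.iloc[0] + rng.normal(0, 0.05, 40)
    x.iloc[3] = x.iloc[2] + rng.normal(0, 0.05, 40)
    net = correlation_network(x, threshold=0.9)
    assert net.components() == [["a", "b"], ["c", "d"]]
    sif = tmp_path / "net.sif"
    net.write_sif(sif)
    lines = sif.read_text().strip().split("\n")
    assert "a\tcorr\tb" in lines and "c\tcorr\td" in lines
    gml = tmp_path / "net.graphml"
    net.write_graphml(gml)
    assert b"graphml" in gml.read_bytes()


def test_network_isolated_nodes_in_sif(tmp_path):
    x = pd.DataFrame(rng.normal(size=(3, 50)), index=["a", "b", "c"])
    net = correlation_network(x, threshold=0.95)
    sif = tmp_path / "net.sif"
    net.write_sif(sif)
    body = sif.read_text()
    for node in "abc":
        assert node in body


def test_network_family_attribute(panel, imputed):
    logs = np.log10(imputed.values).T
    net = correlation_network(logs, threshold=0.99, panel=panel)
    some = net.nodes[0]
    assert net.graph.nodes[some]["family"] == panel[some].family


# ---------------------------------------------------------------- distance

def test_correlation_distance_range_and_landmarks():
    x = pd.DataFrame(rng.normal(size=(6, 20)))
    d = correlation_distance(x).to_numpy()
    assert ((d >= 0.0) & (d <= 1.0)).all()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)
    y = pd.DataFrame([[0.0, 1.0, 2.0], [0.0, 2.0, 4.0], [4.0, 2.0, 0.0]],
                     index=["a", "b", "c"])
    dy = correlation_distance(y)
    assert dy.loc["a", "b"] == pytest.approx(0.0)   # r = 1
    assert dy.loc["a", "c"] == pytest.approx(1.0)   # r = -1
    with pytest.raises(ValueError, match="zero-variance"):
        correlation_distance(pd.DataFrame([[1.0, 1.0], [0.0, 2.0]]))


# ---------------------------------------------------------------- clustering

def _scipy_merges(matrix):
    d = correlation_distance(matrix).to_numpy()
    z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    labels = list(matrix.index)
    members = {i: frozenset([labels[i]]) for i in range(len(labels))}
    merges = []
    for step, (i, j, dist, _) in enumerate(z):
        a, b = members[int(i)], members[int(j)]
        merges.append((dist, {a, b}))
        members[len(labels) + step] = a | b
    return merges


@pytest.mark.parametrize("n", [4, 6, 8])
def test_cluster_matches_scipy_oracle(n):
    g = np.random.default_rng(n)
    x = pd.DataFrame(g.normal(size=(n, 15)),
                     index=[f"r{i}" for i in range(n)])
    tree = hierarchical_cluster(x)
    expected = _scipy_merges(x)
    assert len(tree.merges) == n - 1
    for (d, m1, m2), (de, pair) in zip(tree.merges, expected):
        assert d == pytest.approx(de, abs=1e-12)
        assert {frozenset(m1), frozenset(m2)} == pair


def test_cluster_axis_cultivars():
    x = pd.DataFrame(rng.normal(size=(5, 8)),
                     index=[f"v{i}" for i in range(5)],
                     columns=[f"c{i}" for i in range(8)])
    tree = hierarchical_cluster(x, axis="cultivars")
    assert sorted(tree.leaves) == sorted(x.columns)
    with pytest.raises(ValueError, match="axis"):
        hierarchical_cluster(x, axis="rows")
    with pytest.raises(ValueError, match="at least 2"):
        hierarchical_cluster(x.iloc[:1])


def test_cluster_tie_break_deterministic():
    # four identical-correlation pairs: ties resolved lexicographically
    base = np.array([0.0, 1.0, 2.0, 3.0])
    x = pd.DataFrame([base, base * 2.0, -base, -base * 3.0],
                     index=["d", "c", "b", "a"])
    tree = hierarchical_cluster(x)
    # first merge must be the lexicographically smallest zero-distance pair:
    # {a, b} (both are -base multiples, r = 1)
    d0, m1, m2 = tree.merges[0]
    assert d0 == pytest.approx(0.0)
    assert tuple(sorted(m1 + m2)) == ("a", "b")
    # permuting the row order must not change the merge history
    perm = x.iloc[[2, 0, 3, 1]]
    tree2 = hierarchical_cluster(perm)
    assert [(m1, m2) for _, m1, m2 in tree.merges] == \
        [(m1, m2) for _, m1, m2 in tree2.merges]


def test_newick_output():
    x = pd.DataFrame(rng.normal(size=(4, 10)),
                     index=["a", "b", "c", "d"])
    tree = hierarchical_cluster(x)
    nwk = tree.to_newick()
    assert nwk.endswith(";")
    for leaf in "abcd":
        assert leaf in nwk
    assert nwk.count("(") == nwk.count(")") == 3
    assert tree.leaf_order() and sorted(tree.leaf_order()) == ["a", "b", "c", "d"]


def test_cut_subgroups_depths():
    g = np.random.default_rng(2)
    x = pd.DataFrame(g.normal(size=(8, 30)),
                     index=[f"r{i}" for i in range(8)])
    tree = hierarchical_cluster(x)
    top = cut_subgroups(tree, depth=1)
    assert set(top.values()) == {"1", "2"}
    assert set(top) == set(x.index)
    deep = cut_subgroups(tree, depth=3)
    assert all(code.count("-") <= 2 for code in deep.values())
    # depth-1 labels are prefixes of the deeper labels
    for leaf in x.index:
        assert deep[leaf].startswith(top[leaf])
    with pytest.raises(ValueError, match="depth"):
        cut_subgroups(tree, depth=0)


def test_cut_subgroups_truncation_warning():
    x = pd.DataFrame(rng.normal(size=(2, 12)), index=["a", "b"])
    tree = hierarchical_cluster(x)
    with pytest.warns(UserWarning, match="depth exceeds"):
        labels = cut_subgroups(tree, depth=4)
    assert set(labels.values()) == {"1", "2"}


def test_subgroup_frame():
    df = subgroup_frame({"b": "1", "a": "2"})
    assert list(df["item"]) == ["a", "b"]
    assert list(df.columns) == ["item", "subgroup"]


def test_log_base_invariance_of_standardized_clustering(cohort2014, imputed):
    r10 = response_matrix(cohort2014, imputed, log_base=10.0)
    r2 = response_matrix(cohort2014, imputed, log_base=2.0)
    s10, _ = r10.standardized()
    s2, _ = r2.standardized()
    assert np.allclose(s10, s2, atol=1e-9)
    t10 = hierarchical_cluster(s10, axis="cultivars")
    t2 = hierarchical_cluster(s2, axis="cultivars")
    assert cut_subgroups(t10, depth=3) == cut_subgroups(t2, depth=3)
    assert t10.to_newick() == t2.to_newick()
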