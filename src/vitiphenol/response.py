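"""Drought-response analysis: log-ratio matrices, thresholded Pearson
correlation networks, and two-way hierarchical clustering.

The response of a cultivar is summarized per variable as
log10(value under irrigation / value when not irrigated) on the per-berry
basis. Variables (rows) are standardized (centered, unit variance) before
clustering; the clustering distance is d = (1 − Pearson r) / 2 with
complete linkage, mapping r ∈ [−1, 1] onto [0, 1]. Cultivar subgroups are
read off the top binary splits of the cultivar dendrogram and labelled
"1-2-1"-style. Networks connect variable pairs whose signed correlation
exceeds a threshold (0.8 by default).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .indices import IndexTable
from .io_model import PairedCohort, QuantTable, UnitBasis
from .panel import CompoundPanel


# --------------------------------------------------------------------------
# response matrix
# --------------------------------------------------------------------------

@dataclass
class ResponseMatrix:
    """Variables × cultivars matrix of log10(IR / NI) responses."""

    values: pd.DataFrame
    log_base: float = 10.0

    @property
    def variables(self) -> list[str]:
        return list(self.values.index)

    @property
    def cultivars(self) -> list[str]:
        return list(self.values.columns)

    def standardized(self) -> tuple[pd.DataFrame, list[str]]:
        """Rows centered to mean 0 and scaled to sd 1.

        Returns the standardized matrix and the list of zero-variance rows
        that were excluded (e.g. a variable censored everywhere).
        """
        mean = self.values.mean(axis=1)
        sd = self.values.std(axis=1, ddof=0)
        flat = list(sd.index[sd == 0.0])
        keep = self.values.drop(index=flat)
        out = keep.sub(mean.drop(index=flat), axis=0).div(sd.drop(index=flat), axis=0)
        return out, flat


def response_matrix(cohort: PairedCohort, table: QuantTable,
                    indices: IndexTable | None = None,
                    extra: pd.DataFrame | None = None,
                    log_base: float = 10.0) -> ResponseMatrix:
    """log(IR/NI) per cultivar for every compound (and calculated variable).

    Requires the per-berry basis and LOQ-imputed values (all strictly
    positive; a non-positive value signals missing imputation). Percentage
    and dp variables go through the same transform on their positive
    values. *extra* may add covariate rows (e.g. berry weight) indexed by
    sample id.
    """
    if table.unit_basis != UnitBasis.PER_BERRY:
        raise ValueError("response matrix is defined on the per-berry basis")
    frames = [table.values]
    if indices is not None:
        frames.append(indices.values)
    if extra is not None:
        frames.append(extra)
    wide = pd.concat(frames, axis=1)

    ir_ids = [cohort.ir_samples[c] for c in cohort.cultivars]
    ni_ids = [cohort.ni_samples[c] for c in cohort.cultivars]
    ir = wide.loc[ir_ids].to_numpy(dtype=float)
    ni = wide.loc[ni_ids].to_numpy(dtype=float)
    if (ir <= 0).any() or (ni <= 0).any():
        raise ValueError("non-positive value in response inputs; "
                         "apply below-LOQ imputation first")
    ratio = np.log(ir / ni) / np.log(log_base)
    values = pd.DataFrame(ratio.T, index=wide.columns, columns=cohort.cultivars)
    return ResponseMatrix(values, log_base=log_base)


# --------------------------------------------------------------------------
# correlation network
# --------------------------------------------------------------------------

@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    threshold: float
    absolute: bool
    excluded: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def components(self) -> list[list[str]]:
        """Connected components, each sorted, ordered by smallest member."""
        comps = [sorted(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: c[0])

    def edge_table(self) -> pd.DataFrame:
        rows = [{"source": min(u, v), "target": max(u, v), "r": d["r"]}
                for u, v, d in self.graph.edges(data=True)]
        return (pd.DataFrame(rows, columns=["source", "target", "r"])
                .sort_values(["source", "target"]).reset_index(drop=True))

    def write_sif(self, path: str | Path, relation: str = "corr") -> None:
        with open(path, "w") as fh:
            for _, row in self.edge_table().iterrows():
                fh.write(f"{row['source']}\t{relation}\t{row['target']}\n")
            for node in self.nodes:
                if self.graph.degree(node) == 0:
                    fh.write(f"{node}\n")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


def correlation_network(matrix: pd.DataFrame, threshold: float = 0.8,
                        absolute: bool = False,
                        panel: CompoundPanel | None = None) -> CorrelationNetwork:
    """Threshold the all-pairs Pearson correlations of *matrix* rows.

    *matrix* is variables × observations. An edge joins two variables when
    their signed correlation exceeds *threshold* (``absolute=True``
    thresholds |r| instead; the signed rule is the default since the
    clusters of interest are co-varying groups). Zero-variance variables
    are excluded with a warning. Nodes carry the compound family when a
    panel is given.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 observations per variable")
    sd = matrix.std(axis=1, ddof=0)
    excluded = list(sd.index[sd == 0.0])
    if excluded:
        warnings.warn(f"excluding zero-variance variable(s): {excluded[:5]}")
    kept = matrix.drop(index=excluded)
    labels = list(kept.index)
    corr = np.corrcoef(kept.to_numpy(dtype=float))
    graph = nx.Graph()
    for lab in labels:
        attrs = {}
        if panel is not None and lab in panel:
            attrs["family"] = panel[lab].family
        graph.add_node(lab, **attrs)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            r = float(corr[i, j])
            stat = abs(r) if absolute else r
            if stat > threshold:
                graph.add_edge(labels[i], labels[j], r=r)
    return CorrelationNetwork(graph, threshold, absolute, excluded)


# --------------------------------------------------------------------------
# hierarchical clustering with d = (1 - r) / 2, complete linkage
# --------------------------------------------------------------------------

@dataclass
class ClusterNode:
    members: tuple[str, ...]
    height: float
    left: "ClusterNode | None" = None
    right: "ClusterNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class ClusterTree:
    root: ClusterNode
    leaves: list[str]
    #: merge history: (height, members of first cluster, members of second)
    merges: list[tuple[float, tuple[str, ...], tuple[str, ...]]]

    def leaf_order(self) -> list[str]:
        order: list[str] = []

        def walk(node: ClusterNode) -> None:
            if node.is_leaf:
                order.append(node.members[0])
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return order

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""

        def fmt(node: ClusterNode, parent_height: float) -> str:
            length = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{node.members[0]}:{length:.6g}"
            inner = ",".join(fmt(ch, node.height) for ch in (node.left, node.right))
            return f"({inner}):{length:.6g}"

        if self.root.is_leaf:
            return f"{self.root.members[0]};"
        inner = ",".join(fmt(ch, self.root.height)
                         for ch in (self.root.left, self.root.right))
        return f"({inner});"


def correlation_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise d = (1 − Pearson r) / 2 between rows; range [0, 1]."""
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = list(matrix.index[sd == 0])
        raise ValueError(f"zero-variance row(s): {bad[:5]}")
    r = np.corrcoef(x)
    d = (1.0 - np.clip(r, -1.0, 1.0)) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "variables") -> ClusterTree:
    """Agglomerative complete-linkage clustering with the (1−r)/2 distance.

    *matrix* is a standardized response matrix (variables × cultivars);
    ``axis="variables"`` clusters rows, ``axis="cultivars"`` columns. Ties
    between equal merge distances are broken deterministically by merging
    the pair whose combined, sorted member labels are lexicographically
    smallest. Children of each merge are ordered with the
    lexicographically smaller cluster first, which fixes the "1"/"2"
    branch codes used for subgroup labels.
    """
    if axis == "cultivars":
        matrix = matrix.T
    elif axis != "variables":
        raise ValueError("axis must be 'variables' or 'cultivars'")
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to cluster")
    dist = correlation_distance(matrix)
    labels = [str(l) for l in matrix.index]

    clusters: dict[int, ClusterNode] = {
        i: ClusterNode(members=(lab,), height=0.0) for i, lab in enumerate(labels)}
    dmat: dict[tuple[int, int], float] = {}
    darr = dist.to_numpy()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            dmat[(i, j)] = float(darr[i, j])

    merges: list[tuple[float, tuple[str, ...], tuple[str, ...]]] = []
    next_id = len(labels)
    while len(clusters) > 1:
        best = None
        best_d = None
        best_members = None
        for (i, j), d in dmat.items():
            if best is not None and d > best_d:
                continue
            members = tuple(sorted(clusters[i].members + clusters[j].members))
            if best is None or d < best_d or members < best_members:
                best, best_d, best_members = (i, j), d, members
        i, j = best
        d = dmat[(i, j)]
        a, b = clusters[i], clusters[j]
        first, second = (a, b) if sorted(a.members) <= sorted(b.members) else (b, a)
        merges.append((d, first.members, second.members))
        node = ClusterNode(members=tuple(sorted(a.members + b.members)),
                           height=d, left=first, right=second)
        del clusters[i], clusters[j]
        # complete linkage: distance to the union is the max of the parts
        new_d = {}
        for k in clusters:
            dik = dmat[(min(i, k), max(i, k))]
            djk = dmat[(min(j, k), max(j, k))]
            new_d[k] = max(dik, djk)
        dmat = {(a_, b_): v for (a_, b_), v in dmat.items()
                if i not in (a_, b_) and j not in (a_, b_)}
        for k, v in new_d.items():
            dmat[(min(k, next_id), max(k, next_id))] = v
        clusters[next_id] = node
        next_id += 1

    root = next(iter(clusters.values()))
    return ClusterTree(root=root, leaves=labels, merges=merges)


def cut_subgroups(tree: ClusterTree, depth: int = 3) -> dict[str, str]:
    """Label each leaf by its branch path through the top *depth* splits.

    Labels are "1-2-1"-style codes: at every split down to *depth*, the
    first child contributes "1" and the second "2". Depth 3 yields up to
    eight subgroups. A depth exceeding the tree height returns the finest
    available labelling with a warning.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    labels: dict[str, str] = {}
    truncated = False

    def walk(node: ClusterNode, path: list[str]) -> None:
        nonlocal truncated
        if len(path) == depth or node.is_leaf:
            if node.is_leaf and len(path) < depth:
                truncated = True
            code = "-".join(path) if path else "1"
            for leaf in node.members:
                labels[leaf] = code
            return
        walk(node.left, path + ["1"])
        walk(node.right, path + ["2"])

    walk(tree.root, [])
    if truncated:
        warnings.warn("cut depth exceeds tree height for some branches; "
                      "returning the finest available labelling")
    return labels


def subgroup_frame(labels: dict[str, str]) -> pd.DataFrame:
    return (pd.DataFrame({"item": list(labels), "subgroup": list(labels.values())})
            .sort_values("item").reset_index(drop=True))
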