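"""Cross-disorder comparison of module score profiles.

Given the shared module structure at each spatiotemporal point, disorders
are compared through their Zn score vectors: hierarchical clustering of
disorders (1 - Pearson distance, average linkage), mean-Zm landscapes over
the 12 points, overlap of significant modules/genes, and merged top-module
subnetworks with their hub genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from coppinet.module_search import Module


@dataclass
class DisorderDendrogram:
    """Average-linkage merge tree over disorder score profiles at one point."""

    point: str
    labels: list[str]
    linkage: np.ndarray

    def _merge_sets(self) -> list[set[str]]:
        clusters = {i: {lab} for i, lab in enumerate(self.labels)}
        merges = []
        n = len(self.labels)
        for step, (i, j, _, _) in enumerate(self.linkage):
            merged = clusters[int(i)] | clusters[int(j)]
            clusters[n + step] = merged
            merges.append(merged)
        return merges

    def clustered_together(self, a: str, b: str) -> bool:
        """True iff {a, b} merge before any third disorder joins either."""
        for merged in self._merge_sets():
            if a in merged or b in merged:
                return merged == {a, b}
        raise ValueError(f"labels {a!r}/{b!r} not found in dendrogram")

    def cophenetic(self) -> pd.DataFrame:
        d = hierarchy.cophenet(self.linkage)
        return pd.DataFrame(squareform(d), index=self.labels, columns=self.labels)

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.left), walk(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


@dataclass
class MergedSubnetwork:
    """Union of a disorder's top modules at one point, with its hub gene."""

    disorder: str
    point: str
    graph: nx.Graph
    hub: str
    node_table: pd.DataFrame = field(repr=False)


def cluster_disorders(
    zn: pd.DataFrame,
    point: str = "",
    subset: str = "all",
    module_variance: pd.Series | None = None,
    metric: str = "pearson",
    linkage_method: str = "average",
) -> DisorderDendrogram:
    """Cluster disorder columns of a Zn matrix.

    Distance is 1 - Pearson correlation between Zn vectors (``metric``
    may also be 'euclidean'); linkage defaults to average. ``subset``
    restricts to the most variable modules ('top25pct'/'top50pct') ranked
    by ``module_variance`` (a cross-point variance series indexed like the
    matrix rows) or, if none is supplied, by the row variance of this
    matrix.
    """
    if zn.shape[1] < 2:
        raise ValueError("need >=2 disorders to cluster")
    frac = {"all": 1.0, "top50pct": 0.5, "top25pct": 0.25}.get(subset)
    if frac is None:
        raise ValueError(f"unknown subset {subset!r}")
    if frac < 1.0:
        var = (
            module_variance.reindex(zn.index)
            if module_variance is not None
            else zn.var(axis=1)
        )
        keep = var.sort_values(ascending=False).index[
            : max(int(np.ceil(frac * zn.shape[0])), 0)
        ]
        zn = zn.loc[keep]
    if zn.shape[0] < 2:
        raise ValueError(f"fewer than 2 modules after subsetting ({subset})")

    x = zn.to_numpy(dtype=float).T  # disorders x modules
    if metric == "pearson":
        r = np.corrcoef(x)
        if np.any(~np.isfinite(r)):
            raise ValueError("degenerate (constant) score column; distance undefined")
        d = np.clip(1.0 - r, 0.0, None)
        np.fill_diagonal(d, 0.0)
        condensed = squareform(d, checks=False)
    elif metric == "euclidean":
        condensed = hierarchy.distance.pdist(x, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    link = hierarchy.linkage(condensed, method=linkage_method)
    return DisorderDendrogram(point=point, labels=list(zn.columns), linkage=link)


def mean_z_landscape(zm_by_point: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean Zm per (disorder, point); empty points yield NaN cells."""
    cols = {}
    for point in zm_by_point:
        zm = zm_by_point[point]
        cols[point] = zm.mean(axis=0) if zm.shape[0] else pd.Series(dtype=float)
    return pd.DataFrame(cols)


def peak_stage(landscape: pd.DataFrame) -> pd.DataFrame:
    """Per (disorder, region): the stage with the highest mean Zm."""
    rows = []
    regions = sorted({p.split("_")[0] for p in landscape.columns})
    for disorder in landscape.index:
        for region in regions:
            pts = [p for p in landscape.columns if p.startswith(region + "_")]
            series = landscape.loc[disorder, pts].dropna()
            if series.empty:
                continue
            best = series.idxmax()
            rows.append((disorder, region, best.split("_", 1)[1], series[best]))
    return pd.DataFrame(rows, columns=["disorder", "region", "stage", "mean_zm"])


def overlap_analysis(sets_by_disorder: Mapping[str, Iterable]) -> pd.DataFrame:
    """Multiplicity of items (module keys or genes) across disorders.

    Returns a table (item, disorders, multiplicity) sorted by descending
    multiplicity. The k-way intersection is the set of items with
    multiplicity >= k, so the (k+1)-way intersection is always contained in
    the k-way one.
    """
    membership: dict = {}
    for disorder in sorted(sets_by_disorder):
        for item in set(sets_by_disorder[disorder]):
            membership.setdefault(item, []).append(disorder)
    rows = [
        (item, ";".join(ds), len(ds))
        for item, ds in sorted(membership.items())
    ]
    out = pd.DataFrame(rows, columns=["item", "disorders", "multiplicity"])
    return out.sort_values(
        by=["multiplicity", "item"], ascending=[False, True]
    ).reset_index(drop=True)


def kway_intersection(sets_by_disorder: Mapping[str, Iterable], k: int) -> set:
    """Items present in at least k of the disorders' sets."""
    table = overlap_analysis(sets_by_disorder)
    return set(table.loc[table["multiplicity"] >= k, "item"])


def merge_top_and_hub(
    modules: Sequence[Module],
    disorder: str = "",
    gwas_p: Mapping[str, float] | pd.Series | None = None,
) -> MergedSubnetwork:
    """Union the top modules of one disorder and identify the hub gene.

    The hub is the node of maximum degree in the merged subnetwork; ties
    break by larger summed incident edge weight, then lexicographically
    smaller gene symbol. Node annotations carry the GWAS p-value when
    supplied (for rendering: node size proportional to p, edge width to
    PCC).
    """
    if not modules:
        raise ValueError("no modules to merge")
    point = modules[0].point
    g = nx.Graph()
    for m in modules:
        for u, v, w in m.edges:
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)
    strength = {n: sum(d["weight"] for _, _, d in g.edges(n, data=True)) for n in g}
    hub = min(g.nodes, key=lambda n: (-g.degree(n), -strength[n], n))
    rows = []
    for n in sorted(g.nodes):
        p = float(gwas_p[n]) if gwas_p is not None and n in gwas_p else np.nan
        rows.append((n, g.degree(n), strength[n], p, n == hub))
    table = pd.DataFrame(
        rows, columns=["gene", "degree", "strength", "gwas_p", "is_hub"]
    )
    return MergedSubnetwork(
        disorder=disorder, point=point, graph=g, hub=hub, node_table=table
    )


def pair_first_rates(
    dendrograms: Iterable[DisorderDendrogram],
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Fraction of points at which each pair clusters together first."""
    dends = list(dendrograms)
    rows = []
    for a, b in pairs:
        hits = sum(d.clustered_together(a, b) for d in dends)
        rows.append((a, b, hits, len(dends), hits / len(dends)))
    return pd.DataFrame(
        rows, columns=["disorder_a", "disorder_b", "n_first", "n_points", "rate"]
    )


def all_pairs(labels: Sequence[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(sorted(labels), 2))
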