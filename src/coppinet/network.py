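"""Reference PPI assembly and per-point CoPPI construction.

A CoPPI network is the reference PPI restricted to genes expressed at one
spatiotemporal point, with every surviving edge weighted by the absolute
Pearson correlation (|PCC|) of its two endpoint genes' expression profiles
across that point's samples. Genes are called expressed when their RPKM
exceeds 1 in at least one sample at the point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_REGIONS = ("FC", "SM", "SC", "TP")
DEFAULT_STAGES = ("ST1", "ST2", "ST3")


@dataclass(frozen=True)
class SpatioTemporalPoint:
    """One brain region at one developmental stage, e.g. FC_ST1.

    The default vocabulary is the 4 regions (frontal cortex, sensory-motor,
    sub-cortical, temporal-parietal) crossed with 3 stages (prenatal, birth
    to 11 years, 13 years and older), giving 12 points, but any region/stage
    labels are accepted.
    """

    region: str
    stage: str

    @property
    def label(self) -> str:
        return f"{self.region}_{self.stage}"

    @classmethod
    def parse(cls, label: str) -> "SpatioTemporalPoint":
        region, _, stage = label.partition("_")
        if not region or not stage:
            raise ValueError(f"malformed spatiotemporal label: {label!r}")
        return cls(region, stage)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def default_points(
    regions: Sequence[str] = DEFAULT_REGIONS,
    stages: Sequence[str] = DEFAULT_STAGES,
) -> list[SpatioTemporalPoint]:
    """The region-major list of spatiotemporal points (12 by default)."""
    return [SpatioTemporalPoint(r, s) for r in regions for s in stages]


@dataclass
class CoppiNetwork:
    """Co-expression-weighted PPI network for one spatiotemporal point.

    ``graph`` is an undirected networkx graph whose edges carry a ``weight``
    attribute equal to |PCC| in [0, 1]. ``report`` summarizes what was
    dropped during construction (edges touching unexpressed genes and edges
    with a zero-variance endpoint, for which PCC is undefined).
    """

    point: str
    graph: nx.Graph
    report: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def merge_ppi(*edge_lists: Iterable[tuple[str, str]]) -> nx.Graph:
    """Merge one or more edge lists into a simple undirected PPI network.

    Self-interactions and duplicate edges (in either orientation) are
    removed; nodes left without any edge are dropped. Raises ``ValueError``
    if nothing survives filtering.
    """
    g = nx.Graph()
    for edges in edge_lists:
        for u, v in edges:
            if not u or not v:
                raise ValueError(f"empty gene identifier in edge ({u!r}, {v!r})")
            if u == v:
                continue
            g.add_edge(str(u), str(v))
    if g.number_of_edges() == 0:
        raise ValueError("no edges after filtering")
    # rebuild with sorted node insertion for deterministic iteration order
    out = nx.Graph()
    out.add_nodes_from(sorted(g.nodes))
    out.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in g.edges))
    return out


def expressed_genes(expression: pd.DataFrame, threshold: float = 1.0) -> set[str]:
    """Genes whose RPKM is strictly greater than ``threshold`` in >=1 sample.

    ``expression`` is a genes x samples matrix. Negative entries are
    rejected (RPKM is non-negative by definition).
    """
    if expression.shape[1] < 1 or expression.shape[0] < 1:
        raise ValueError("expression matrix is empty")
    values = expression.to_numpy(dtype=float)
    neg_rows = expression.index[(values < 0).any(axis=1)]
    if len(neg_rows) > 0:
        raise ValueError(
            f"negative RPKM values in rows: {', '.join(map(str, neg_rows[:10]))}"
        )
    keep = values.max(axis=1) > threshold
    return set(expression.index[keep])


def samples_for_point(
    metadata: pd.DataFrame, point: SpatioTemporalPoint | str
) -> list[str]:
    """Sample ids assigned to ``point`` in a (sample, region, stage) table."""
    pt = SpatioTemporalPoint.parse(point) if isinstance(point, str) else point
    mask = (metadata["region"] == pt.region) & (metadata["stage"] == pt.stage)
    if not mask.any():
        raise ValueError(f"no samples for spatiotemporal point {pt.label!r}")
    return metadata.loc[mask, "sample"].tolist()


def build_coppi(
    ppi: nx.Graph,
    expression: pd.DataFrame,
    point: SpatioTemporalPoint | str,
    transform: str = "log2p1",
    expr_threshold: float = 1.0,
) -> CoppiNetwork:
    """Weight the PPI by co-expression at one spatiotemporal point.

    For every PPI edge whose two endpoints are both expressed, the weight is
    the absolute Pearson correlation of the two genes' expression vectors
    across the point's samples, optionally after a log2(x+1) transform
    (``transform='log2p1'``, the default) or on the raw values
    (``transform='none'``). Edges touching an unexpressed gene are omitted;
    edges with a zero-variance endpoint (undefined PCC) are omitted and
    counted in the build report.
    """
    if transform not in ("log2p1", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    if expression.shape[1] < 3:
        raise ValueError(
            f"need >=3 samples to compute PCC, got {expression.shape[1]}"
        )
    label = point.label if isinstance(point, SpatioTemporalPoint) else str(point)

    expressed = expressed_genes(expression, expr_threshold)
    genes = sorted(expressed & set(ppi.nodes))
    index = {g: i for i, g in enumerate(genes)}
    x = expression.loc[genes].to_numpy(dtype=float)
    if transform == "log2p1":
        x = np.log2(x + 1.0)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((x * x).sum(axis=1))

    graph = nx.Graph()
    n_unexpressed = 0
    n_zero_var = 0
    for u, v in ppi.edges:
        iu, iv = index.get(u), index.get(v)
        if iu is None or iv is None:
            n_unexpressed += 1
            continue
        if norms[iu] == 0.0 or norms[iv] == 0.0:
            n_zero_var += 1
            continue
        w = abs(float(x[iu] @ x[iv]) / (norms[iu] * norms[iv]))
        graph.add_edge(u, v, weight=min(w, 1.0))

    report = {
        "point": label,
        "n_ppi_edges": ppi.number_of_edges(),
        "n_expressed_genes": len(expressed),
        "n_edges": graph.number_of_edges(),
        "n_nodes": graph.number_of_nodes(),
        "n_dropped_unexpressed": n_unexpressed,
        "n_dropped_zero_variance": n_zero_var,
        "transform": transform,
        "expr_threshold": expr_threshold,
    }
    return CoppiNetwork(point=label, graph=graph, report=report)
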