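"""Module-level disorder association scores Zm and Zn.

For a fixed module list at one spatiotemporal point, each disorder's
gene scores Gw are overlaid on the modules:

    Zm = sum(Gw over the module's scored genes) / sqrt(#scored genes)

and the raw Zm values are standardized within each (point, disorder)
column to Zn = (Zm - mean) / sd. The module structure is identical across
disorders at a point; only the scores differ.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from coppinet.module_search import Module

log = logging.getLogger(__name__)


def module_z(
    module_genes: Iterable[str],
    scores: Mapping[str, float] | pd.Series,
    missing_policy: str = "drop",
) -> float:
    """Raw module score Zm = sum(Gw) / sqrt(#genes) for one disorder.

    ``scores`` maps gene -> Gw. With ``missing_policy='drop'`` (default),
    genes without a score are excluded from both the numerator and the gene
    count; with ``'impute'`` they contribute Gw = 0 but still count in the
    denominator. A module with no scored gene yields NaN, to be flagged and
    excluded downstream.
    """
    if missing_policy not in ("drop", "impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    genes = list(module_genes)
    if not genes:
        raise ValueError("module has no genes")
    gw = [scores[g] for g in genes if g in scores]
    if not gw:
        return float("nan")
    n = len(genes) if missing_policy == "impute" else len(gw)
    return float(sum(gw)) / math.sqrt(n)


def score_modules(
    modules: list[Module],
    score_tables: Mapping[str, pd.DataFrame],
    missing_policy: str = "drop",
) -> pd.DataFrame:
    """Zm matrix (modules x disorders) for one spatiotemporal point.

    ``score_tables`` maps disorder -> (gene, p, gw) table. Row index is the
    module id (sorted, semicolon-joined gene list).
    """
    ids = [m.module_id for m in modules]
    data = {}
    for disorder in sorted(score_tables):
        t = score_tables[disorder]
        gw = pd.Series(t["gw"].to_numpy(), index=t["gene"]).to_dict()
        data[disorder] = [module_z(m.nodes, gw, missing_policy) for m in modules]
    return pd.DataFrame(data, index=pd.Index(ids, name="module_id"))


def normalize_z(zm_column: pd.Series | np.ndarray, name: str = "") -> np.ndarray:
    """Standardize one Zm column to Zn with the sample (n-1) sd.

    Requires at least two finite values and positive spread; a constant
    column is an error naming the column.
    """
    x = np.asarray(zm_column, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise ValueError(f"column {name!r}: need >=2 finite Zm values")
    sd = finite.std(ddof=1)
    if sd == 0:
        raise ValueError(f"column {name!r}: zero standard deviation")
    return (x - finite.mean()) / sd


def normalize_matrix(zm: pd.DataFrame) -> pd.DataFrame:
    """Apply normalize_z to every disorder column of a Zm matrix."""
    return pd.DataFrame(
        {col: normalize_z(zm[col], name=str(col)) for col in zm.columns},
        index=zm.index,
    )


def select_significant(
    zn: pd.DataFrame, threshold: float = 1.96
) -> dict[str, dict]:
    """Per disorder: the modules with Zn strictly above ``threshold``.

    Returns, per disorder, the selected module ids, the unique-gene union
    across those modules, and the two summary counts (modules, genes).
    Module ids are semicolon-joined gene lists, so the gene union is
    recovered from the ids themselves.
    """
    out = {}
    for disorder in zn.columns:
        col = zn[disorder]
        ids = sorted(col.index[col > threshold])
        genes = set()
        for mid in ids:
            genes.update(mid.split(";"))
        out[disorder] = {
            "module_ids": ids,
            "genes": genes,
            "n_modules": len(ids),
            "n_genes": len(genes),
        }
    return out


def proportion_above(zm: pd.DataFrame, threshold: float = 1.96) -> pd.Series:
    """Fraction of modules with raw Zm above ``threshold``, per disorder."""
    if zm.shape[0] == 0:
        raise ValueError("no modules at this point")
    return (zm > threshold).mean(axis=0)


def top_modules(
    zn: pd.DataFrame, zm: pd.DataFrame | None = None, k: int = 10
) -> dict[str, list[str]]:
    """The k highest-Zn module ids per disorder.

    Ties resolve by higher raw Zm, then lexicographic module id. If fewer
    than k modules exist, all are returned with a warning.
    """
    if zn.shape[0] < k:
        log.warning("requested top %d modules but only %d exist", k, zn.shape[0])
    out = {}
    for disorder in zn.columns:
        frame = pd.DataFrame({"zn": zn[disorder]})
        frame["zm"] = zm[disorder] if zm is not None else frame["zn"]
        frame["mid"] = frame.index
        frame = frame.sort_values(
            by=["zn", "zm", "mid"], ascending=[False, False, True]
        )
        out[disorder] = frame["mid"].head(k).tolist()
    return out
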