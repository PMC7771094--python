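"""Over-representation analysis with family-wide Bonferroni control.

Gene sets (GMT-style collections) are tested against a query gene list with
the hypergeometric upper tail. The Bonferroni family spans all tested terms
across all disorders and all spatiotemporal points, e.g. 0.05/(1658*5*12)
~ 5.0e-7 for 1658 biological-process terms, 5 disorders and 12 points.
Genes in the high-LD MHC region (chr6:25.5-33.5 Mb on hg19) can be excluded
before testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

MHC_REGION = ("chr6", 25_500_000, 33_500_000)
MHC_BUILD = "hg19"


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe."""

    sets: dict[str, set[str]]  # term id -> member genes
    names: dict[str, str]
    universe: set[str]

    def __post_init__(self):
        empty = [t for t, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")
        self.sets = {t: s & self.universe for t, s in self.sets.items()}

    @property
    def n_terms(self) -> int:
        return len(self.sets)


def bonferroni_threshold(
    alpha: float = 0.05,
    n_terms: int = 1,
    n_disorders: int = 1,
    n_points: int = 1,
) -> float:
    """Per-test threshold alpha / (n_terms * n_disorders * n_points)."""
    if min(n_terms, n_disorders, n_points) < 1:
        raise ValueError("all family counts must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / (n_terms * n_disorders * n_points)


def hypergeom_ora(
    query,
    collection: GeneSetCollection,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of ``query`` in every term.

    Query genes outside the universe are dropped with a warning. For each
    term the reported p is P(overlap >= observed) under sampling
    |query| genes from the universe. ``threshold`` (e.g. from
    bonferroni_threshold) sets the ``significant`` flag; without one the
    flag column is absent.
    """
    q = set(query)
    dropped = q - collection.universe
    if dropped:
        warnings.warn(f"{len(dropped)} query genes outside the universe dropped")
        q &= collection.universe
    if not q:
        raise ValueError("empty query after intersecting with the universe")
    m = len(collection.universe)
    n_q = len(q)
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term]
        k = len(q & members)
        # P(X >= k) for X ~ Hypergeom(M=m, n=|term|, N=|query|)
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n_q)) if k > 0 else 1.0
        rows.append(
            (term, collection.names.get(term, term), k, n_q, len(members), m, min(p, 1.0))
        )
    out = pd.DataFrame(
        rows,
        columns=["term", "name", "overlap", "query_size", "term_size", "universe_size", "p"],
    )
    if threshold is not None:
        out["significant"] = out["p"] < threshold
    return out.sort_values(by=["p", "term"]).reset_index(drop=True)


def exclude_mhc(
    gene_coords: pd.DataFrame,
    region: tuple[str, int, int] = MHC_REGION,
    region_build: str = MHC_BUILD,
    build: str = MHC_BUILD,
) -> tuple[set[str], list[str]]:
    """Remove genes overlapping the MHC high-LD interval.

    ``gene_coords`` columns: gene, chrom, start, end (0-based half-open);
    rows with missing coordinates are retained with a warning, since they
    cannot be located. The interval is half-open, matching BED. Returns the
    retained gene set and the list of removed genes. Genome-build tags must
    agree (the interval is defined on hg19).
    """
    if build != region_build:
        raise ValueError(
            f"genome build mismatch: coordinates are {build!r} but the "
            f"exclusion region is defined on {region_build!r}"
        )
    chrom, start, end = region
    kept: set[str] = set()
    removed: list[str] = []
    n_missing = 0
    for row in gene_coords.itertuples(index=False):
        if pd.isna(row.chrom) or pd.isna(row.start) or pd.isna(row.end):
            n_missing += 1
            kept.add(row.gene)
            continue
        overlaps = row.chrom == chrom and int(row.start) < end and int(row.end) > start
        if overlaps:
            removed.append(row.gene)
        else:
            kept.add(row.gene)
    if n_missing:
        warnings.warn(
            f"{n_missing} genes without coordinates retained (cannot be excluded)"
        )
    return kept, sorted(removed)
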