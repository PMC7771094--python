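"""Gene-level disorder scores from GWAS summary statistics.

Two entry points:

* gene-level p-values supplied directly (the common case when a gene-based
  association tool has already been run) are carried through unchanged and
  converted to probit scores Gw = Phi^-1(1 - p_g);
* SNP-level summary statistics are aggregated to a gene-based empirical
  p-value with a VEGAS-style test: the observed statistic is the sum of
  1-df chi-squares of the gene's SNPs, and its null distribution is
  simulated from a multivariate normal with the gene's LD correlation
  matrix, so correlated SNPs are not double counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PROBIT_EPS = 1e-12


@dataclass
class GeneSnpAssignment:
    """The SNPs mapped to one gene, with their p-values and LD correlation.

    ``sigma`` is the SNP x SNP LD correlation matrix; ``None`` means
    independence (identity).
    """

    gene: str
    snp_ids: list[str]
    p_values: np.ndarray
    sigma: np.ndarray | None = None
    repaired: bool = field(default=False, compare=False)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def probit_score(p_g, eps: float = PROBIT_EPS):
    """Gene score Gw = Phi^-1(1 - p_g), monotone decreasing in p_g.

    ``p_g`` must lie in (0, 1]; values are clamped into [eps, 1 - eps]
    before inversion so extreme p-values stay finite. Accepts scalars or
    arrays.
    """
    p = np.asarray(p_g, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        bad = p[~(np.isfinite(p) & (p > 0) & (p <= 1))]
        raise ValueError(f"gene p-values must be in (0, 1]; offending: {bad[:5]}")
    clamped = np.clip(p, eps, 1.0 - eps)
    gw = stats.norm.isf(clamped)  # Phi^-1(1 - p)
    return float(gw) if np.isscalar(p_g) else gw


def gene_score_table(gene_p: pd.DataFrame, disorder: str | None = None) -> pd.DataFrame:
    """Build a (gene, p, gw) score table from a (gene, p) table."""
    if not {"gene", "p"} <= set(gene_p.columns):
        raise ValueError("gene-level table must have columns 'gene' and 'p'")
    out = gene_p[["gene", "p"]].copy()
    out["gw"] = probit_score(out["p"].to_numpy())
    if disorder is not None:
        out.insert(0, "disorder", disorder)
    return out.reset_index(drop=True)


def _check_chrom_style(snp_chroms: set, bed_chroms: set) -> None:
    snp_pref = {str(c).startswith("chr") for c in snp_chroms}
    bed_pref = {str(c).startswith("chr") for c in bed_chroms}
    if snp_pref and bed_pref and snp_pref != bed_pref and not (snp_chroms & bed_chroms):
        raise ValueError(
            "chromosome naming mismatch between SNP table and gene BED "
            f"(e.g. {sorted(map(str, snp_chroms))[:3]} vs "
            f"{sorted(map(str, bed_chroms))[:3]})"
        )


def map_snps_to_genes(
    snp_table: pd.DataFrame,
    gene_bed: pd.DataFrame,
    flank_bp: int = 50_000,
) -> dict[str, GeneSnpAssignment]:
    """Assign SNPs to genes within the gene body +/- ``flank_bp``.

    ``snp_table`` columns: snp, chr, bp (1-based), p. ``gene_bed`` columns:
    chrom, start, end (0-based half-open), gene. A SNP belongs to a gene iff
    start - flank < pos0 < end + flank with pos0 = bp - 1; SNPs may map to
    several genes, and genes with no SNP are simply absent from the result.
    """
    for col in ("snp", "chr", "bp", "p"):
        if col not in snp_table.columns:
            raise ValueError(f"SNP table missing column {col!r}")
    for col in ("chrom", "start", "end", "gene"):
        if col not in gene_bed.columns:
            raise ValueError(f"gene BED missing column {col!r}")
    _check_chrom_style(set(snp_table["chr"].unique()), set(gene_bed["chrom"].unique()))

    out: dict[str, GeneSnpAssignment] = {}
    pos0 = snp_table["bp"].to_numpy(dtype=np.int64) - 1
    chroms = snp_table["chr"].to_numpy()
    for row in gene_bed.itertuples(index=False):
        mask = (
            (chroms == row.chrom)
            & (row.start - flank_bp < pos0)
            & (pos0 < row.end + flank_bp)
        )
        if not mask.any():
            continue
        sub = snp_table.loc[mask]
        out[row.gene] = GeneSnpAssignment(
            gene=row.gene,
            snp_ids=sub["snp"].tolist(),
            p_values=sub["p"].to_numpy(dtype=float),
        )
    return out


def repair_correlation(sigma: np.ndarray, floor: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Force a symmetric matrix to a positive-definite correlation matrix.

    Symmetrizes, clips eigenvalues at ``floor``, and renormalizes the
    diagonal to 1. Returns the repaired matrix and whether any repair was
    needed.
    """
    s = np.asarray(sigma, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("LD matrix must be square")
    sym = (s + s.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    needed = bool(vals.min() < floor) or not np.allclose(np.diag(sym), 1.0, atol=1e-8)
    if needed:
        vals = np.clip(vals, floor, None)
        sym = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(sym))
        sym = sym / np.outer(d, d)
        np.fill_diagonal(sym, 1.0)
    return sym, needed


def vegas_empirical_p(
    assignment: GeneSnpAssignment,
    n_sims: int = 1000,
    rng_seed: int | np.random.Generator | None = 0,
) -> float:
    """LD-aware empirical gene p-value from SNP-level p-values.

    The observed statistic is T = sum_j [Phi^-1(1 - p_j/2)]^2 over the
    gene's SNPs (two-sided p-values assumed). Null replicates draw
    z ~ MVN(0, Sigma) with Sigma the LD correlation matrix and take
    T* = sum z_j^2; the empirical p is (#{T* >= T} + 1) / (n_sims + 1),
    which is never zero.
    """
    if assignment.n_snps < 1:
        raise ValueError(f"gene {assignment.gene}: no SNPs assigned")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for a usable empirical p-value")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    p = np.clip(np.asarray(assignment.p_values, dtype=float), 1e-300, 1.0)
    z_obs = stats.norm.isf(p / 2.0)
    t_obs = float(np.sum(z_obs**2))

    k = assignment.n_snps
    if assignment.sigma is None:
        null = rng.standard_normal((n_sims, k))
    else:
        sigma, repaired = repair_correlation(assignment.sigma)
        assignment.repaired = repaired
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - repair should prevent
            raise ValueError(
                f"gene {assignment.gene}: LD matrix not repairable to "
                "positive semi-definite"
            ) from exc
        null = rng.standard_normal((n_sims, k)) @ chol.T
    t_null = (null**2).sum(axis=1)
    return (int(np.count_nonzero(t_null >= t_obs)) + 1) / (n_sims + 1)


def vegas_score_table(
    assignments: dict[str, GeneSnpAssignment],
    n_sims: int = 1000,
    rng_seed: int = 0,
    disorder: str | None = None,
    ld_matrices: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Run the empirical gene test for every assigned gene.

    One substream of ``rng_seed`` is used per gene (ordered by gene name),
    so results do not depend on dict insertion order.
    """
    genes = sorted(assignments)
    rows = []
    for i, gene in enumerate(genes):
        a = assignments[gene]
        if ld_matrices is not None and gene in ld_matrices:
            a.sigma = ld_matrices[gene]
        rng = np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(4, i)))
        p_g = vegas_empirical_p(a, n_sims=n_sims, rng_seed=rng)
        rows.append((gene, p_g, a.n_snps))
    table = pd.DataFrame(rows, columns=["gene", "p", "n_snps"])
    table["gw"] = probit_score(table["p"].to_numpy())
    if disorder is not None:
        table.insert(0, "disorder", disorder)
    n_repaired = sum(assignments[g].repaired for g in genes)
    if n_repaired:
        warnings.warn(f"repaired indefinite LD matrices for {n_repaired} genes")
    return table[
        (["disorder"] if disorder is not None else []) + ["gene", "p", "gw", "n_snps"]
    ]
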