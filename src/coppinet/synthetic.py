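"""Synthetic study generator with planted ground truth.

Emulates the statistical structure of the real inputs — a background PPI,
RPKM-like spatiotemporal expression with co-expressed modules active at
designated points, and per-disorder GWAS gene p-values with planted risk
genes (including shared risk between designated disorder pairs) — while
recording the planted truth so recovery can be tested.

Co-expression follows a single-factor equicorrelation model: at a point
where a planted module is active, each member gene's latent value is
z_g = sqrt(rho) * f + sqrt(1 - rho) * eps_g with a shared per-sample factor
f, so the expected latent Pearson correlation between two members is
exactly rho. Latent values are mapped to the RPKM scale by exponentiation
(log-normal), which preserves the correlation sign structure and guarantees
non-negative values; the log2(x+1) transform used downstream approximately
restores linearity for well-expressed genes. A configurable fraction of
genes is silenced (scaled so every sample sits below RPKM 1) at each point
to exercise the expression filter boundary.

Reproducibility: one global integer seed fans out to fixed substreams
(PPI, per-point expression, risk-set assignment, per-disorder p-values,
SNP-level statistics), so e.g. adding a disorder does not perturb the
expression draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from coppinet.network import DEFAULT_REGIONS, DEFAULT_STAGES

DEFAULT_DISORDERS = ("ADHD", "ASD", "BIP", "MDD", "SCZ")

# latent-to-RPKM map: rpkm = exp(LOGNORMAL_SIGMA * z + LOGNORMAL_MU)
LOGNORMAL_MU = 2.0
LOGNORMAL_SIGMA = 0.8


def gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


@dataclass(frozen=True)
class PlantedModule:
    """A gene set co-expressed (at correlation rho) at designated points."""

    genes: tuple[str, ...]
    active_points: tuple[str, ...]
    rho: float


@dataclass
class SyntheticConfig:
    n_genes: int = 250
    n_ppi_edges: int = 900
    regions: tuple[str, ...] = DEFAULT_REGIONS
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_samples_per_point: int = 30
    planted_modules: tuple[PlantedModule, ...] = ()
    disorders: tuple[str, ...] = DEFAULT_DISORDERS
    risk_genes_per_disorder: int = 40
    shared_risk_pairs: tuple[tuple[str, str, int], ...] = ()
    risk_p_shape: float = 0.1
    silenced_fraction: float = 0.05
    risk_architecture: str = "uniform"  # or "modular"
    risk_unique_modules: int = 2
    rng_seed: int = 0

    @property
    def point_labels(self) -> list[str]:
        return [f"{r}_{s}" for r in self.regions for s in self.stages]

    @property
    def n_points(self) -> int:
        return len(self.regions) * len(self.stages)

    @property
    def universe(self) -> list[str]:
        return gene_names(self.n_genes)

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        max_edges = self.n_genes * (self.n_genes - 1) // 2
        if self.n_ppi_edges > max_edges:
            raise ValueError(
                f"n_ppi_edges={self.n_ppi_edges} exceeds the {max_edges} "
                f"possible pairs of {self.n_genes} genes"
            )
        if self.n_samples_per_point < 3:
            raise ValueError("need >=3 samples per point")
        if not 0 < self.risk_p_shape < 1:
            raise ValueError("risk_p_shape must lie in (0, 1)")
        if not 0 <= self.silenced_fraction < 1:
            raise ValueError("silenced_fraction must lie in [0, 1)")
        universe = set(self.universe)
        labels = set(self.point_labels)
        seen: set[str] = set()
        for pm in self.planted_modules:
            if len(pm.genes) < 4:
                raise ValueError("planted modules need >=4 genes")
            if not set(pm.genes) <= universe:
                raise ValueError(f"planted genes outside the universe: {pm.genes}")
            if set(pm.genes) & seen:
                raise ValueError("planted modules must not share genes")
            seen |= set(pm.genes)
            unknown = set(pm.active_points) - labels
            if unknown:
                raise ValueError(f"unknown point label(s): {sorted(unknown)}")
            if not 0 < pm.rho < 1:
                raise ValueError("module rho must lie in (0, 1)")
        disorders = set(self.disorders)
        for a, b, n_shared in self.shared_risk_pairs:
            if a not in disorders or b not in disorders:
                raise ValueError(f"shared-risk pair ({a}, {b}) names unknown disorder")
            if n_shared > self.risk_genes_per_disorder:
                raise ValueError(
                    f"shared count {n_shared} exceeds risk_genes_per_disorder="
                    f"{self.risk_genes_per_disorder}"
                )
        if self.risk_genes_per_disorder > self.n_genes:
            raise ValueError("more risk genes than genes")
        if self.risk_architecture not in ("uniform", "modular"):
            raise ValueError(f"unknown risk_architecture {self.risk_architecture!r}")


@dataclass
class SyntheticStudy:
    """The full planted-truth bundle a study run consumes."""

    config: SyntheticConfig
    ppi: list[tuple[str, str]]
    expression: dict[str, pd.DataFrame]  # point label -> genes x samples RPKM
    sample_metadata: pd.DataFrame  # sample, region, stage
    gwas: dict[str, pd.DataFrame]  # disorder -> (gene, p)
    truth: dict = field(repr=False)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_ppi(config: SyntheticConfig) -> list[tuple[str, str]]:
    """Background PPI: planted modules connected, remaining edges random.

    Each planted module receives a random spanning tree over its genes plus
    each remaining within-module pair with probability 0.5; the rest of the
    budget is uniform random pairs. Undirected and simple by construction.
    """
    rng = _stream(config.rng_seed, 0)
    genes = config.universe
    edges: set[tuple[str, str]] = set()

    def add(u: str, v: str) -> None:
        if u != v:
            edges.add((u, v) if u < v else (v, u))

    for pm in config.planted_modules:
        members = list(pm.genes)
        order = list(rng.permutation(len(members)))
        for i in range(1, len(order)):  # random tree: attach to a prior node
            j = int(rng.integers(0, i))
            add(members[order[i]], members[order[j]])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < 0.5:
                    add(members[i], members[j])
    if len(edges) > config.n_ppi_edges:
        raise ValueError(
            f"planted-module edges ({len(edges)}) already exceed "
            f"n_ppi_edges={config.n_ppi_edges}"
        )
    n = config.n_genes
    while len(edges) < config.n_ppi_edges:
        i, j = rng.integers(0, n, size=2)
        if i != j:
            add(genes[int(i)], genes[int(j)])
    return sorted(edges)


def generate_expression(
    config: SyntheticConfig, points: Sequence[str] | None = None
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-point RPKM matrices plus the sample metadata table."""
    labels = list(points) if points is not None else config.point_labels
    known = set(config.point_labels)
    for lab in labels:
        if lab not in known:
            raise ValueError(f"unknown point label: {lab!r}")
    genes = config.universe
    gene_index = {g: i for i, g in enumerate(genes)}
    n, s = config.n_genes, config.n_samples_per_point

    expression: dict[str, pd.DataFrame] = {}
    meta_rows = []
    for lab in labels:
        point_pos = config.point_labels.index(lab)
        rng = _stream(config.rng_seed, 1, point_pos)
        z = rng.standard_normal((n, s))
        active_genes: set[str] = set()
        for pm in config.planted_modules:
            if lab not in pm.active_points:
                continue
            f = rng.standard_normal(s)
            rows = [gene_index[g] for g in pm.genes]
            z[rows] = np.sqrt(pm.rho) * f + np.sqrt(1.0 - pm.rho) * z[rows]
            active_genes |= set(pm.genes)
        rpkm = np.exp(LOGNORMAL_SIGMA * z + LOGNORMAL_MU)

        n_silenced = int(np.floor(config.silenced_fraction * n))
        eligible = sorted(set(genes) - active_genes)
        if n_silenced > 0 and eligible:
            chosen = rng.choice(len(eligible), size=min(n_silenced, len(eligible)),
                                replace=False)
            for k in chosen:
                i = gene_index[eligible[int(k)]]
                rpkm[i] *= 0.99 / rpkm[i].max()

        samples = [f"{lab}_s{j:02d}" for j in range(s)]
        expression[lab] = pd.DataFrame(rpkm, index=pd.Index(genes, name="gene"),
                                       columns=samples)
        region, _, stage = lab.partition("_")
        meta_rows += [(smp, region, stage) for smp in samples]
    metadata = pd.DataFrame(meta_rows, columns=["sample", "region", "stage"])
    return expression, metadata


def assign_risk_genes(config: SyntheticConfig) -> dict[str, set[str]]:
    """Risk-gene sets per disorder honoring the shared-risk pair counts.

    Two architectures:

    * ``uniform`` — risk genes sampled uniformly from the universe (shared
      sets first, then per-disorder fill);
    * ``modular`` — shared risk is built from whole planted modules (risk
      converging on co-expressed pathways, the premise of the analysis),
      each disorder additionally receives ``risk_unique_modules`` whole
      modules of its own, and the remainder is uniform scatter. Module
      assignments are disjoint across pairs and disorders.
    """
    rng = _stream(config.rng_seed, 2, 0)
    genes = np.array(config.universe)
    risk: dict[str, set[str]] = {d: set() for d in config.disorders}

    if config.risk_architecture == "modular":
        mods = list(config.planted_modules)
        order = iter(rng.permutation(len(mods)))

        def next_module_genes() -> set[str]:
            try:
                return set(mods[int(next(order))].genes)
            except StopIteration:
                raise ValueError(
                    "not enough planted modules for the modular risk "
                    "architecture; add modules or reduce shared counts"
                ) from None

        for a, b, n_shared in config.shared_risk_pairs:
            got: set[str] = set()
            while len(got) < n_shared:
                got |= next_module_genes()
            got = set(sorted(got)[:n_shared])
            risk[a] |= got
            risk[b] |= got
        for d in config.disorders:
            for _ in range(config.risk_unique_modules):
                risk[d] |= next_module_genes()
    else:
        for a, b, n_shared in config.shared_risk_pairs:
            shared = rng.choice(len(genes), size=n_shared, replace=False)
            shared_set = {genes[int(i)] for i in shared}
            risk[a] |= shared_set
            risk[b] |= shared_set

    for d in config.disorders:
        need = config.risk_genes_per_disorder - len(risk[d])
        if need < 0:
            raise ValueError(
                f"disorder {d}: shared/module risk already exceeds "
                f"risk_genes_per_disorder={config.risk_genes_per_disorder}"
            )
        pool = np.array(sorted(set(genes) - risk[d]))
        extra = rng.choice(len(pool), size=need, replace=False)
        risk[d] |= {pool[int(i)] for i in extra}
    return risk


def generate_gwas(
    config: SyntheticConfig, risk: dict[str, set[str]] | None = None
) -> tuple[dict[str, pd.DataFrame], dict[str, set[str]]]:
    """Per-disorder (gene, p) tables: risk genes Beta(a, 1), null Uniform."""
    if risk is None:
        risk = assign_risk_genes(config)
    genes = config.universe
    gwas: dict[str, pd.DataFrame] = {}
    for j, d in enumerate(config.disorders):
        rng = _stream(config.rng_seed, 2, j + 1)
        p = rng.uniform(size=len(genes))
        is_risk = np.array([g in risk[d] for g in genes])
        p[is_risk] = rng.beta(config.risk_p_shape, 1.0, size=int(is_risk.sum()))
        p = np.clip(p, 1e-300, 1.0)
        gwas[d] = pd.DataFrame({"gene": genes, "p": p})
    return gwas, risk


def make_gene_bed(genes: Sequence[str], gene_length: int = 10_000,
                  spacing: int = 150_000, chrom: str = "chr1") -> pd.DataFrame:
    """Evenly spaced gene bodies on one chromosome (0-based half-open).

    Spacing exceeds gene length + 2 x 50 kb so default flanks never overlap
    a neighboring gene.
    """
    rows = []
    for i, g in enumerate(sorted(genes)):
        start = 100_000 + i * spacing
        rows.append((chrom, start, start + gene_length, g))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def generate_snp_level(
    gene_table: pd.DataFrame,
    snps_per_gene: int,
    ld_rho: float,
    rng_seed: int,
    risk_genes: set[str] | None = None,
    risk_shift: float = 2.5,
    gene_bed: pd.DataFrame | None = None,
    flank_bp: int = 50_000,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], pd.DataFrame]:
    """SNP-level summary statistics with compound-symmetric LD per gene.

    Per gene, SNP z-scores are drawn from MVN(mu, Sigma) with Sigma the
    equicorrelation matrix at ``ld_rho`` and mu = ``risk_shift`` for risk
    genes (0 otherwise); p-values are the two-sided normal tail. SNP
    positions fall inside the gene body or its ``flank_bp`` flanks. Returns
    the SNP table, the per-gene LD matrices, and the gene BED.
    """
    if snps_per_gene < 1:
        raise ValueError("snps_per_gene must be >= 1")
    if not 0 <= ld_rho < 1:
        raise ValueError("ld_rho must lie in [0, 1) for a positive-definite LD matrix")
    risk_genes = risk_genes or set()
    genes = gene_table["gene"].tolist()
    if gene_bed is None:
        gene_bed = make_gene_bed(genes)
    bed = gene_bed.set_index("gene")

    k = snps_per_gene
    sigma = np.full((k, k), ld_rho)
    np.fill_diagonal(sigma, 1.0)
    chol = np.linalg.cholesky(sigma)

    rng = np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(3,)))
    rows = []
    ld: dict[str, np.ndarray] = {}
    for gene in genes:
        start, end, chrom = int(bed.at[gene, "start"]), int(bed.at[gene, "end"]), bed.at[gene, "chrom"]
        # 1-based positions with pos0 strictly inside (start - flank, end + flank)
        pos = rng.integers(start - flank_bp + 2, end + flank_bp, size=k)
        z = chol @ rng.standard_normal(k)
        if gene in risk_genes:
            z = z + risk_shift
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
        for j in range(k):
            rows.append((f"{gene}_snp{j}", chrom, int(pos[j]), float(p[j])))
        ld[gene] = sigma.copy()
    snp_table = pd.DataFrame(rows, columns=["snp", "chr", "bp", "p"])
    return snp_table, ld, gene_bed


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate the full synthetic study bundle with ground truth."""
    ppi = generate_ppi(config)
    expression, metadata = generate_expression(config)
    gwas, risk = generate_gwas(config)
    truth = {
        "planted_modules": [
            {"genes": sorted(pm.genes), "active_points": list(pm.active_points),
             "rho": pm.rho}
            for pm in config.planted_modules
        ],
        "risk_genes": {d: sorted(risk[d]) for d in config.disorders},
    }
    return SyntheticStudy(
        config=config,
        ppi=ppi,
        expression=expression,
        sample_metadata=metadata,
        gwas=gwas,
        truth=truth,
    )


def generate_gene_sets(
    config: SyntheticConfig,
    n_terms: int = 200,
    size_range: tuple[int, int] = (10, 50),
    n_pathway_terms: int = 10,
) -> dict[str, set[str]]:
    """A GMT-style collection over the gene universe.

    Mostly random terms, plus ``n_pathway_terms`` terms built from unions
    of planted modules (padded with random genes) so over-representation
    of module genes is discoverable.
    """
    rng = _stream(config.rng_seed, 5)
    genes = np.array(config.universe)
    sets: dict[str, set[str]] = {}
    mods = list(config.planted_modules)
    for t in range(n_pathway_terms):
        members: set[str] = set()
        if mods:
            for _ in range(2):
                members |= set(mods[int(rng.integers(0, len(mods)))].genes)
        pad = rng.choice(len(genes), size=int(rng.integers(5, 15)), replace=False)
        members |= {genes[int(i)] for i in pad}
        sets[f"PATH{t:04d}"] = members
    for t in range(n_terms - n_pathway_terms):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        picks = rng.choice(len(genes), size=size, replace=False)
        sets[f"TERM{t:04d}"] = {genes[int(i)] for i in picks}
    return sets


def default_config(rng_seed: int = 0, **overrides) -> SyntheticConfig:
    """The package's reference study conditions.

    250 genes, 1000 PPI edges, the 4x3 spatiotemporal grid with 30 samples
    per point, 30 planted 5-gene modules (rho 0.9, each active at 6 of the
    12 points), five disorders with 40 risk genes each, shared risk between
    SCZ-BIP and ASD-ADHD (25 genes per pair) allocated with the modular
    risk architecture, and Beta(0.1, 1) risk-gene p-values. Module
    membership and activity are drawn deterministically from the seed
    before the config is built.
    """
    base = dict(
        n_genes=250,
        n_ppi_edges=1000,
        n_samples_per_point=30,
        risk_genes_per_disorder=40,
        shared_risk_pairs=(("SCZ", "BIP", 25), ("ASD", "ADHD", 25)),
        risk_p_shape=0.1,
        silenced_fraction=0.05,
        risk_architecture="modular",
        rng_seed=rng_seed,
    )
    base.update({k: v for k, v in overrides.items() if k != "planted_modules"})
    n_modules = overrides.pop("n_planted_modules", 30)
    module_size = overrides.pop("module_size", 5)
    active_per_module = overrides.pop("active_points_per_module", 6)
    rho = overrides.pop("module_rho", 0.9)

    probe = SyntheticConfig(**{k: v for k, v in base.items()
                               if k in SyntheticConfig.__dataclass_fields__})
    rng = _stream(rng_seed, 9)
    genes = np.array(probe.universe)
    picks = rng.choice(len(genes), size=n_modules * module_size, replace=False)
    labels = probe.point_labels
    planted = []
    for m in range(n_modules):
        members = tuple(sorted(genes[picks[m * module_size:(m + 1) * module_size]]))
        active = rng.choice(len(labels), size=active_per_module, replace=False)
        planted.append(
            PlantedModule(
                genes=members,
                active_points=tuple(labels[int(i)] for i in sorted(active)),
                rho=rho,
            )
        )
    base["planted_modules"] = tuple(planted)
    return SyntheticConfig(**{k: v for k, v in base.items()
                              if k in SyntheticConfig.__dataclass_fields__})
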