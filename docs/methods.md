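# Methods

## Model and procedure

The pipeline treats disorder genetics as a signal to be localized on a
fixed co-expression scaffold. At each spatiotemporal point (brain region ×
developmental stage) the reference PPI is restricted to expressed genes
and each surviving edge is weighted by `e_PCC`, the absolute Pearson
correlation of the endpoint genes' expression across that point's
samples. Modules are grown on this weighted graph by a greedy dense
module search, *before* any GWAS data are seen; the module structure at a
point is therefore identical for all disorders, and only the overlaid
gene scores differ. This separation is what makes the per-point disorder
comparison meaningful: two disorders are compared through their score
profiles over the same module list.

### Dense module search

A module's score is the mean of its component-edge weights,
`Em = Σ e_PCC / #edges`. Seeds are all edges with `e_PCC ≥ 0.5`
(boundary inclusive). Growth considers every network edge not yet in the
module with at least one endpoint among the module's nodes — both edges
that bring in a new node and edges that densify the current node set —
and accepts the candidate maximizing the resulting `Em` only if it
*strictly* improves it. Since the new score `(S + w)/(m + 1)` is
increasing in the candidate weight `w` for a fixed module, the best
candidate is always the maximum-weight one and the acceptance test is
equivalent to `w > Em`; the implementation exploits this with a max-heap,
and the test suite checks it against a naive oracle that recomputes `Em`
per candidate. Two consequences are guaranteed by construction and
asserted in tests: the final `Em` never falls below the seed weight, and
every accepted edge's weight exceeds the module score at the moment of
acceptance, so all component edges stay at or above the seed threshold.

Ties (a candidate exactly equal to the current `Em`, or equal-weight
candidates) are resolved conservatively: equal scores do not extend a
module (this guarantees termination), and equal-weight candidates are
taken in lexicographic endpoint order (this makes the search
deterministic). Modules with fewer than 4 nodes are discarded —
the observed module-size regime starts at 4 and tiny seed pairs are not
interpretable as modules — and growths converging to the same node set
are collapsed to the higher-scoring realization, since two growths
reaching the same genes describe one biological module. Both knobs
(`min_nodes`, deduplication) are explicit parameters.

### Gene and module scores

Gene-level p-values map to probit scores `Gw = Φ⁻¹(1 − p_g)` after
clamping into `[1e−12, 1 − 1e−12]`. When only SNP-level summary
statistics are available, a gene's p-value is computed by an LD-aware
Monte-Carlo test: the observed statistic is `T = Σ_j [Φ⁻¹(1 − p_j/2)]²`
over the SNPs in the gene body ± 50 kb (two-sided SNP p-values assumed),
and the null distribution is simulated as `T* = Σ z_j²` with
`z ~ MVN(0, Σ)` for the gene's LD correlation matrix `Σ`. The empirical
p-value `(#{T* ≥ T} + 1)/(n_sims + 1)` is never zero and is
conservative-unbiased at fixed `n_sims`; the adaptive staging of the
original gene-based tools is intentionally not reproduced — at the
problem sizes used here (≈10³ genes × 500–1000 simulations) a fixed
simulation count is simpler and fully calibrated (checked: type-I error
at α = 0.05 within 3 binomial standard errors over 1000 null genes).
Indefinite `Σ` is repaired by eigenvalue clipping at 1e−8 followed by
diagonal renormalization, and the repair is flagged per gene.

Module association is `Zm = Σ Gw / √(#genes)` over the module's scored
genes. Genes without a GWAS score are dropped from numerator and
denominator (`missing_policy="drop"`, the default) rather than imputed at
`Gw = 0`; imputation systematically deflates `Zm` for poorly covered
modules, but remains available (`"impute"`). `Zm` columns are
standardized to `Zn = (Zm − mean)/sd` with the sample (n−1) standard
deviation — the n vs n−1 difference is negligible at realistic module
counts — within each (point, disorder) column by default. Normalizing
per point makes `Zn` comparable across points, which the cross-point
comparisons require; a global per-disorder scope across all points is
available as a config option since the choice is genuinely open. A point
with fewer than two modules cannot be standardized and is skipped with a
manifest entry. Significance is `Zn > 1.96` (strict).

### Cross-disorder comparison

Disorders are clustered per point on their `Zn` vectors with
1 − Pearson-correlation distance and average linkage; the metric is
scale-free (appropriate for standardized scores) and the linkage robust
for 5 leaves. Euclidean distance and other linkages are exposed as
options. "Clustered together" is operationalized as: the pair merges
before any third disorder joins either member. Restricting clustering to
the most variable 25%/50% of modules (by cross-point `Zn` variance) is
supported as a robustness check. The hub of a disorder's merged top-k
(default 10) modules is the maximum-degree node, ties broken by larger
summed incident edge weight, then lexicographically — degree in the
merged subnetwork is the simplest defensible operationalization of
"hub", and the tie chain makes it deterministic.

### Enrichment

Over-representation uses the plain hypergeometric upper tail against a
configurable background universe (default: the PPI node set), with the
Bonferroni family spanning terms × disorders × points — for 1658 terms,
5 disorders and 12 points the per-test threshold is
0.05/99 480 ≈ 5.0 × 10⁻⁷. The EASE-style modification of Fisher's test
used by some enrichment servers is deliberately not reproduced; the
quantity of interest here is the family-wide error control, not a
particular test variant. MHC exclusion removes genes overlapping
chr6:25 500 000–33 500 000 (half-open, matching BED convention) on hg19;
genes lacking coordinates are retained with a warning since they cannot
be located, and the operation is idempotent.

## Synthetic data: what it emulates and what it does not

The generator plants known structure so that recovery is testable:

* **Co-expression** follows a single-factor equicorrelation model: at a
  point where a module is active, each member's latent value is
  `z_g = √ρ·f + √(1−ρ)·ε_g` with a shared per-sample factor `f`, giving
  expected latent pairwise correlation exactly ρ — the simplest model
  with a closed-form target for analytic checks. Latent values map to
  RPKM as `exp(0.8·z + 2)`; the monotone map preserves sign structure,
  guarantees non-negativity, and the default `log2(x+1)` transform used
  before PCC approximately restores linearity for well-expressed genes.
* **Expression filtering** is exercised by silencing a fraction (default
  5%) of genes per point, scaling them just below the RPKM = 1 threshold
  rather than zeroing them, so the strict `> 1` boundary is tested.
  Silenced genes are drawn from genes *not* in modules active at that
  point, so silencing never contradicts planted activity.
* **PPI**: each planted module receives a random spanning tree plus each
  remaining within-module pair with probability 0.5; the rest of the
  edge budget is uniform random pairs.
* **GWAS**: risk genes draw `p ~ Beta(a, 1)` with `a = 0.1`
  (stochastically small; median ≈ 10⁻³), null genes `Uniform(0, 1)`.
  Shared-risk pairs (SCZ–BIP, ASD–ADHD) receive overlapping risk sets.
  The default *modular* risk architecture allocates shared risk as whole
  planted modules plus uniform scatter, and gives each disorder two
  private modules of its own: this encodes the analysis' own premise
  that GWAS risk converges on co-expressed pathways. A design-stage
  power analysis showed that fully uniform risk placement (~0.5 risk
  genes per 5-gene module) dilutes `Zm` below detectability and yields
  chance-level disorder clustering; uniform placement remains available
  (`risk_architecture="uniform"`) and is what the null-clustering
  exchangeability check uses.
* **SNP-level statistics**: per gene, SNP z-scores are
  `MVN(μ, Σ)` with compound-symmetric LD at `ld_rho` and `μ = 2.5` for
  risk genes; positions fall in the gene body ± 50 kb on a synthetic BED
  with genes spaced so flanks never overlap.
* **Reproducibility**: one global seed fans out to fixed substreams
  (PPI; per-point expression; risk assignment; per-disorder p-values;
  SNP statistics), so regeneration is bit-identical and adding a
  disorder does not perturb expression draws.

Deliberately **not** emulated: realistic LD block structure and allele
frequencies, developmental expression trajectories, gene-length and
GC biases, sample-level batch effects, and any dependence between
expression and GWAS noise. Passing recovery tests therefore demonstrates
the pipeline's correctness and statistical behavior under its own model
assumptions, not performance on real cohort data.

## Default study conditions and problem sizes

The reference synthetic study uses 250 genes, 1000 PPI edges, the 4 × 3
spatiotemporal grid with 30 samples per point, 30 planted 5-gene modules
(ρ = 0.9, each active at 6 of 12 points), 5 disorders × 40 risk genes,
25 shared genes per designated pair, and `a = 0.1`. These sizes keep a
full replicate (12 CoPPI builds + searches + scoring + clustering) at
well under a second, so the statistical tests run 50 independent
replicates. The gene-test calibration uses 1000 null genes × 5 SNPs ×
500 simulations plus 400 single-SNP genes × 1000 simulations. The
acceptance computation uses a 200-gene Erdős–Rényi network (edge
probability 0.05) with Uniform(0, 1) weights.

## Numerical choices and degenerate inputs

* PCC is computed on centered vectors with explicit norms; zero-variance
  genes make PCC undefined, so their edges are omitted and counted in
  the build report rather than imputed at 0.
* Whether to correlate raw or `log2(x+1)` RPKM is exposed
  (`transform`), defaulting to the transform because RPKM is
  heavy-tailed and the `|PCC| ≥ 0.5` regime is transform-sensitive; the
  choice is recorded in output provenance.
* Probit clamping at `eps = 1e−12` keeps `Gw` finite for p-values at the
  boundaries; `p = 0.5 ⟺ Gw = 0` holds exactly.
* A constant `Zm` column, an empty module edge set, an empty PPI after
  filtering, fewer than 3 samples at a point, and chromosome-naming
  mismatches (chr1 vs 1) all fail fast with messages naming the
  offending column/point/chromosomes.
* Empirical p-values use the `+1/+1` estimator and so never return 0.

## Known limitations

* The greedy search is locally optimal by construction but makes no
  global optimality claim; overlapping near-duplicate modules (differing
  by one node) are kept unless their node sets coincide exactly.
* The Monte-Carlo gene test's resolution is bounded below by
  `1/(n_sims+1)`; very small gene p-values saturate there.
* Per-point normalization makes `Zn` incomparable with analyses that
  standardize globally; both scopes are provided but must not be mixed.
* With five leaves, dendrogram topology is sensitive to sampling noise
  when module counts per point are small; the pair-first indicator is
  reported per point rather than aggregated into a single tree.
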