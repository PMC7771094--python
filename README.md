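# coppinet

Spatiotemporal co-expression PPI network analysis of GWAS summary
statistics for psychiatric disorders.

Psychiatric disorders such as schizophrenia (SCZ), bipolar disorder (BIP),
major depressive disorder (MDD), attention-deficit/hyperactivity disorder
(ADHD) and autism spectrum disorder (ASD) are polygenic and tied to brain
development: the same gene can matter in one brain region at one
developmental stage and be irrelevant elsewhere. `coppinet` implements a
network pipeline that localizes GWAS risk signal in space and time:

1. **CoPPI construction** — a reference protein–protein interaction (PPI)
   network (self-interactions and isolated nodes removed) is re-weighted,
   at each of 12 spatiotemporal points (4 brain regions × 3 developmental
   stages), by the co-expression of each edge's endpoint genes:
   `e_PCC = |PCC|` of the two genes' expression across that point's
   samples. Genes with RPKM ≤ 1 in all samples at a point are treated as
   unexpressed and their edges dropped.
2. **Dense module search** — modules are grown greedily from every seed
   edge with `e_PCC ≥ 0.5`, always adding the best edge connected to the
   current module, for as long as the module score
   `Em = Σ e_PCC / #edges` strictly improves. Every returned module
   therefore has `Em > 0.5` with all component edges ≥ 0.5.
3. **Disorder scoring** — per-disorder gene p-values (either supplied
   gene-level, or aggregated from SNP-level statistics by an LD-aware
   Monte-Carlo gene test in the VEGAS style) become probit scores
   `Gw = Φ⁻¹(1 − p_g)`; each module gets `Zm = Σ Gw / √(#genes)`, and the
   per-point, per-disorder `Zm` columns are standardized to `Zn`.
   Modules with `Zn > 1.96` are called significant.
4. **Cross-disorder comparison** — disorders are clustered by their `Zn`
   profiles at each point (1 − Pearson distance, average linkage),
   mean-`Zm` landscapes locate each disorder's peak stage per region,
   significant modules/genes are intersected across disorders, and each
   disorder's top-10 modules are merged into a subnetwork whose
   highest-degree node is its hub gene.
5. **Enrichment** — hypergeometric over-representation of the significant
   genes against a gene-set collection, Bonferroni-corrected over the full
   family (terms × disorders × points), with optional exclusion of genes
   in the high-LD MHC region (chr6:25.5–33.5 Mb, hg19).

Because the original expression and GWAS datasets are access-restricted,
the package ships a synthetic-data generator (`coppinet.synthetic`) that
emulates their statistical structure — planted co-expression modules
driven by a single latent factor, RPKM-like log-normal expression, and
planted risk genes with shared risk between designated disorder pairs —
with full ground truth for recovery testing.

## Worked example

The analysis is organized as numbered drivers that communicate through
plain-text files under `results/`:

```
python analysis/01_simulate.py --seed 0      # synthetic study + truth
python analysis/02_build_coppi.py            # 12 CoPPI networks
python analysis/03_search_modules.py         # dense module search
python analysis/04_score_disorders.py        # Gw, Zm, Zn, selections
python analysis/05_cross_disorder.py         # clustering, overlaps, hubs
python analysis/06_enrichment.py             # Bonferroni-corrected ORA
```

With the default study (250 genes, 1000 PPI edges, 30 planted 5-gene
modules at ρ = 0.9, five disorders with SCZ–BIP and ASD–ADHD shared
risk), the drivers print, among other things:

```
total modules: 395; mean size 4.50 nodes (range 4-9)
planted-module recovery (Jaccard >= 0.8): 178/180

pairs clustering together first (fraction of points):
disorder_a disorder_b  n_first  n_points     rate
      ADHD        ASD       12        12 1.000000
       BIP        SCZ       10        12 0.833333

Bonferroni family: 200 terms x 5 disorders x 12 points -> per-test threshold 4.17e-06
19 (point, disorder, term) enrichments below the family-wide threshold
```

i.e. 178 of the 180 (module, active-point) occurrences are recovered at
Jaccard ≥ 0.8, and the two planted shared-risk pairs are the two pairs
that cluster together first at most spatiotemporal points — the
qualitative signature the method is designed to expose. The same flow is
available as a library (`coppinet.pipeline.run_pipeline`) and as a CLI
(`coppinet demo --seed 0 --out <dir>`).

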